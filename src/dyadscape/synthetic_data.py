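"""Seeded synthetic-microscopy generators with ground-truth sidecars.

Every input modality of the analysis pipeline can be emulated here:

* striated t-tubule networks (transverse elements at sarcomere spacing,
  longitudinal connectors at a controllable areal density) rendered with a
  Gaussian PSF and photon-limited noise;
* paired punctate RyR / LTCC channels with controllable per-orientation
  colocalized fractions and "orphaned" Z-lines bearing RyR but no tubule;
* Ca2+ release videos with site-wise release delays and propagation-limited
  release at pixels far from the tubule network;
* voltage-dye videos in which a controllable fraction of the skeleton
  depolarizes, followed by contraction movement.

All generators are deterministic given (spec, seed) and return a
:class:`GroundTruth` sidecar holding the true skeleton and branch labels,
masks, colocalization fractions, per-pixel delay field, or depolarized set, so
every downstream measurement can be checked against construction-time truth.

Phenotype presets (``developing``, ``adult``, ``hf``) bundle parameter values
that caricature sparse longitudinal-dominant developing cells, dense
transverse-dominant adult cells, and failing cells with orphaned gaps and
delayed local release. The preset values are illustrative, chosen to mirror
the qualitative contrasts between those cell states, not fitted to any
measured dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import morphology

from .image_core import BinaryMask, Image2D, VideoStack
from .tubule_morphometry import (
    LONGITUDINAL,
    TRANSVERSE,
    Skeleton,
    skeletonize_mask,
)

__all__ = [
    "TubuleNetworkSpec",
    "DyadSpec",
    "CalciumSpec",
    "VoltageSpec",
    "GroundTruth",
    "generate_tubule_image",
    "generate_dyad_pair",
    "generate_calcium_video",
    "generate_voltage_video",
    "network_spec_for_transverse_fraction",
    "PHENOTYPES",
    "phenotype_network",
    "phenotype_dyad",
    "phenotype_calcium",
    "phenotype_voltage",
]

PHENOTYPES = ("developing", "adult", "hf")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TubuleNetworkSpec:
    """Geometry, optics, and noise of a synthetic t-tubule micrograph.

    Transverse elements are laid at Z-line positions (pitch =
    ``sarcomere_spacing_um``, each position occupied with probability
    ``transverse_occupancy``); longitudinal connectors are horizontal segments
    spanning ``longitudinal_span_pitches`` sarcomeres, at
    ``longitudinal_density_per_um2`` connectors per square micrometre of cell
    area. Noise is Poisson-like (``photon_scale`` photons per intensity unit;
    ``inf`` disables it) plus Gaussian read noise.
    """

    cell_length_um: float = 40.0
    cell_width_um: float = 18.0
    sarcomere_spacing_um: float = 1.8
    transverse_occupancy: float = 0.9
    longitudinal_density_per_um2: float = 0.02
    longitudinal_span_pitches: int = 1
    tubule_width_um: float = 0.35
    psf_sigma_um: float = 0.15
    photon_scale: float = 20.0
    background_level: float = 20.0
    signal_level: float = 100.0
    read_noise_sd: float = 1.0
    pixel_size_um: float = 0.16
    margin_um: float = 2.0
    zline_jitter_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cell_length_um", "cell_width_um", "sarcomere_spacing_um",
                     "tubule_width_um", "psf_sigma_um", "pixel_size_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.transverse_occupancy <= 1.0):
            raise ValueError("transverse_occupancy must lie in [0, 1]")
        if self.cell_length_um < 2 * self.sarcomere_spacing_um:
            raise ValueError("cell must span at least one sarcomere")


@dataclass(frozen=True)
class DyadSpec:
    """Paired punctate RyR / LTCC channels over a tubule network.

    RyR puncta sit along transverse Z-lines and longitudinal elements at
    ``ryr_cluster_pitch_um``. For each orientation, a fraction
    ``coloc_fraction_*`` of LTCC puncta coincide with their RyR partner; the
    remainder are displaced off the parent element by at least
    ``min_displacement_um`` plus a half-normal offset of scale
    ``displacement_sigma_um``. ``orphan_gap_count`` Z-lines carry RyR puncta
    but no tubule and no LTCC.
    """

    network: TubuleNetworkSpec = field(default_factory=lambda: TubuleNetworkSpec(
        cell_length_um=14.0, cell_width_um=7.0, pixel_size_um=0.04,
        margin_um=1.0, tubule_width_um=0.25, psf_sigma_um=0.10,
        longitudinal_density_per_um2=0.14, longitudinal_span_pitches=2,
    ))
    ryr_cluster_pitch_um: float = 0.2
    coloc_fraction_transverse: float = 0.9
    coloc_fraction_longitudinal: float = 0.3
    displacement_sigma_um: float = 0.15
    min_displacement_um: float = 0.35
    max_displacement_um: float = 0.45
    orphan_gap_count: int = 0
    punctum_sigma_um: float = 0.07
    punctum_amplitude: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("coloc_fraction_transverse", "coloc_fraction_longitudinal"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ryr_cluster_pitch_um < self.network.psf_sigma_um:
            import warnings
            warnings.warn("RyR pitch below the PSF sigma is unresolvable")


@dataclass(frozen=True)
class CalciumSpec:
    """Phenomenological Ca2+ release video over a tubule network.

    Each pixel's fluorescence follows baseline + amplitude *
    (1 - exp(-(t - t0)/rise_tau)) * exp(-(t - t0)/decay_tau) for t > t0.
    At pixels within ``tubule_halo_um`` of the skeleton, t0 = stimulus + a
    site-wise delay (drawn per ~``site_block_um`` skeleton segment from
    N(site_delay_mean_ms, site_delay_sd_ms), then standardized so the
    per-pixel delay field has exactly the requested mean and SD). Beyond the
    halo, release waits for propagation: t0 gains (distance - halo) /
    ``orphan_propagation_speed_um_per_ms``.
    """

    network: TubuleNetworkSpec = field(default_factory=lambda: TubuleNetworkSpec(
        cell_length_um=11.0, cell_width_um=9.0, pixel_size_um=0.16,
        margin_um=0.8, photon_scale=math.inf,
    ))
    baseline: float = 100.0
    amplitude: float = 150.0
    rise_tau_ms: float = 12.0
    decay_tau_ms: float = 200.0
    site_delay_mean_ms: float = 10.0
    site_delay_sd_ms: float = 4.0
    orphan_propagation_speed_um_per_ms: float = math.inf
    tubule_halo_um: float = 0.4
    site_block_um: float = 2.0
    frame_interval_ms: float = 1.5
    stimulus_frame: int = 20
    n_frames: int = 160
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.rise_tau_ms > 0 and self.decay_tau_ms > 0):
            raise ValueError("rise and decay time constants must be > 0")
        if not self.orphan_propagation_speed_um_per_ms > 0:
            raise ValueError("propagation speed must be > 0")
        if self.site_delay_sd_ms < 0:
            raise ValueError("site_delay_sd_ms must be >= 0")


@dataclass(frozen=True)
class VoltageSpec:
    """Voltage-dye video: a subset of skeleton branches steps up, then the
    cell moves."""

    network: TubuleNetworkSpec = field(default_factory=lambda: TubuleNetworkSpec(
        cell_length_um=30.0, cell_width_um=14.0, pixel_size_um=0.16,
        margin_um=1.5,
    ))
    depolarized_fraction: float = 0.5
    step_amplitude_percent: float = 12.0
    onset_frame: int = 5
    contraction_frame: int = 12
    motion_amplitude_px: int = 2
    n_frames: int = 18
    frame_interval_ms: float = 10.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.depolarized_fraction <= 1.0):
            raise ValueError("depolarized_fraction must lie in [0, 1]")
        if self.contraction_frame <= self.onset_frame + 3:
            raise ValueError("contraction_frame must exceed onset_frame + 3")
        if self.n_frames <= self.contraction_frame:
            raise ValueError("n_frames must exceed contraction_frame")


@dataclass
class GroundTruth:
    """Construction-time truth accompanying a generated image or video."""

    seed: int
    spec: object
    pixel_size_um: float
    footprint: Optional[np.ndarray] = None
    interior_roi: Optional[np.ndarray] = None
    skeleton_mask: Optional[np.ndarray] = None
    transverse_skeleton: Optional[np.ndarray] = None
    longitudinal_skeleton: Optional[np.ndarray] = None
    branch_lengths_um: Optional[List[Tuple[str, float]]] = None
    transverse_fraction: Optional[float] = None
    tubule_mask: Optional[np.ndarray] = None
    density_percent: Optional[float] = None
    # dyads
    coloc_fraction: Optional[Dict[str, float]] = None
    ryr_points: Optional[np.ndarray] = None        # (n, 2) row/col
    ryr_labels: Optional[List[str]] = None
    ltcc_points: Optional[np.ndarray] = None
    coloc_flags: Optional[np.ndarray] = None
    orphan_zline_cols: Optional[List[int]] = None
    # calcium
    delay_field_ms: Optional[np.ndarray] = None
    distance_to_skeleton_um: Optional[np.ndarray] = None
    membrane_image: Optional[Image2D] = None
    # voltage
    depolarized_mask: Optional[np.ndarray] = None
    depolarized_fraction: Optional[float] = None

    def true_skeleton(self) -> Skeleton:
        """Skeleton object built from the true network mask."""
        if self.skeleton_mask is None:
            raise ValueError("no skeleton truth available")
        return skeletonize_mask(self.skeleton_mask, self.pixel_size_um)


# ---------------------------------------------------------------------------
# Network geometry
# ---------------------------------------------------------------------------

@dataclass
class _Network:
    shape: Tuple[int, int]
    footprint: np.ndarray
    skeleton: np.ndarray
    branches: List[Tuple[np.ndarray, str]]  # (coords, label)
    zline_cols: List[int]                   # all Z-line columns (um grid)
    occupied: List[bool]
    centre: Tuple[float, float]


def _ellipse_mask(shape, centre, semi_r, semi_c) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return ((rr - centre[0]) / semi_r) ** 2 + ((cc - centre[1]) / semi_c) ** 2 <= 1.0


def _build_network(spec: TubuleNetworkSpec, rng: np.random.Generator) -> _Network:
    ps = spec.pixel_size_um
    H = int(round((spec.cell_width_um + 2 * spec.margin_um) / ps))
    W = int(round((spec.cell_length_um + 2 * spec.margin_um) / ps))
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    b = spec.cell_width_um / 2.0 / ps   # row semi-axis
    a = spec.cell_length_um / 2.0 / ps  # col semi-axis
    footprint = _ellipse_mask((H, W), (cy, cx), b, a)

    inset = 0.5 / ps  # tubules stop slightly inside the sarcolemma
    a_in, b_in = max(a - inset, 1.0), max(b - inset, 1.0)

    pitch = spec.sarcomere_spacing_um
    n_lines = int((spec.cell_length_um - pitch) // pitch)
    xs_um = (np.arange(n_lines) - (n_lines - 1) / 2.0) * pitch
    xs_um = xs_um + rng.uniform(-1, 1, n_lines) * spec.zline_jitter_fraction * pitch
    # stratified occupancy: the occupied count is fixed at its expectation,
    # positions are random — keeps per-cell density at the programmed level
    n_occ = int(round(spec.transverse_occupancy * n_lines))
    occupied = np.zeros(n_lines, dtype=bool)
    occupied[rng.choice(n_lines, size=n_occ, replace=False)] = True

    skeleton = np.zeros((H, W), dtype=bool)
    branches: List[Tuple[np.ndarray, str]] = []
    zline_cols: List[int] = []

    def _chord_rows(col: int) -> Tuple[int, int]:
        u = (col - cx) / a_in
        if abs(u) >= 1.0:
            return 0, -1
        h = b_in * math.sqrt(1.0 - u * u)
        return int(math.ceil(cy - h)), int(math.floor(cy + h))

    for i in range(n_lines):
        col = int(round(cx + xs_um[i] / ps))
        zline_cols.append(col)
        if not occupied[i]:
            continue
        r0, r1 = _chord_rows(col)
        if r1 <= r0:
            continue
        rows = np.arange(r0, r1 + 1)
        coords = np.stack([rows, np.full_like(rows, col)], axis=1)
        skeleton[rows, col] = True
        branches.append((coords, TRANSVERSE))

    area_um2 = math.pi * (spec.cell_length_um / 2) * (spec.cell_width_um / 2)
    n_long = int(round(spec.longitudinal_density_per_um2 * area_um2))
    span = max(1, spec.longitudinal_span_pitches)
    # real longitudinal elements do not stack into slabs: keep connectors in
    # the same inter-Z-line corridor vertically separated
    min_sep = max(3, int(round(1.0 / ps)))
    used_rows: Dict[int, List[int]] = {}
    for _ in range(n_long):
        if n_lines < span + 1:
            break
        for _attempt in range(20):
            i = int(rng.integers(0, n_lines - span))
            c0, c1 = zline_cols[i], zline_cols[i + span]
            lo0, hi0 = _chord_rows(c0)
            lo1, hi1 = _chord_rows(c1)
            lo, hi = max(lo0, lo1), min(hi0, hi1)
            if hi <= lo:
                continue
            row = int(rng.integers(lo, hi + 1))
            corridors = range(i, i + span)
            if any(abs(row - r) < min_sep
                   for j in corridors for r in used_rows.get(j, [])):
                continue
            for j in corridors:
                used_rows.setdefault(j, []).append(row)
            cols = np.arange(min(c0, c1), max(c0, c1) + 1)
            coords = np.stack([np.full_like(cols, row), cols], axis=1)
            skeleton[row, cols] = True
            branches.append((coords, LONGITUDINAL))
            break

    return _Network((H, W), footprint, skeleton, branches, zline_cols,
                    list(occupied), (cy, cx))


def _branch_length_um(coords: np.ndarray, ps: float) -> float:
    if len(coords) < 2:
        return 0.0
    steps = np.diff(coords.astype(float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum()) * ps


def _render(
    mask: np.ndarray, spec: TubuleNetworkSpec, rng: np.random.Generator
) -> np.ndarray:
    """Blur a binary structure with the PSF, add background and noise."""
    clean = (spec.background_level
             + spec.signal_level
             * ndimage.gaussian_filter(mask.astype(float),
                                       spec.psf_sigma_um / spec.pixel_size_um))
    return _apply_noise(clean, spec, rng)


def _apply_noise(
    clean: np.ndarray, spec: TubuleNetworkSpec, rng: np.random.Generator
) -> np.ndarray:
    out = clean
    if math.isfinite(spec.photon_scale):
        out = rng.poisson(np.clip(clean, 0, None) * spec.photon_scale) / spec.photon_scale
        if spec.read_noise_sd > 0:
            out = out + rng.normal(0.0, spec.read_noise_sd, clean.shape)
    return np.clip(out, 0.0, None)


def _interior_roi(footprint: np.ndarray, ps: float, margin_um: float = 1.0) -> np.ndarray:
    return ndimage.binary_erosion(
        footprint, structure=morphology.disk(max(1, math.ceil(margin_um / ps))))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_tubule_image(spec: TubuleNetworkSpec) -> Tuple[Image2D, GroundTruth]:
    """Render a single-channel tubule-stain micrograph plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    net = _build_network(spec, rng)
    ps = spec.pixel_size_um
    half_w = max(0, int(round(spec.tubule_width_um / 2.0 / ps)))
    tubule_mask = (
        ndimage.binary_dilation(net.skeleton, structure=morphology.disk(half_w))
        if half_w > 0 else net.skeleton.copy()
    )
    pixels = _render(tubule_mask, spec, rng)
    img = Image2D(pixels, ps, channel_name="membrane")

    lengths = [(label, _branch_length_um(coords, ps)) for coords, label in net.branches]
    t_len = sum(l for lab, l in lengths if lab == TRANSVERSE)
    total = sum(l for _, l in lengths)
    interior = _interior_roi(net.footprint, ps)
    density = (100.0 * float((tubule_mask & interior).sum()) / interior.sum()
               if interior.any() else math.nan)
    truth = GroundTruth(
        seed=spec.seed, spec=spec, pixel_size_um=ps,
        footprint=net.footprint, interior_roi=interior,
        skeleton_mask=net.skeleton,
        transverse_skeleton=_label_mask(net, TRANSVERSE),
        longitudinal_skeleton=_label_mask(net, LONGITUDINAL),
        branch_lengths_um=lengths,
        transverse_fraction=(t_len / total) if total > 0 else math.nan,
        tubule_mask=tubule_mask,
        density_percent=density,
    )
    return img, truth


def _label_mask(net: _Network, label: str) -> np.ndarray:
    out = np.zeros(net.shape, dtype=bool)
    for coords, lab in net.branches:
        if lab == label:
            out[coords[:, 0], coords[:, 1]] = True
    return out


def network_spec_for_transverse_fraction(
    target_fraction: float,
    seed: int = 0,
    base: Optional[TubuleNetworkSpec] = None,
) -> TubuleNetworkSpec:
    """A network spec whose expected skeleton transverse fraction is
    ``target_fraction``.

    The expected transverse length is the occupancy-weighted sum of Z-line
    chord lengths through the elliptical footprint; the longitudinal connector
    density is then solved so the expected longitudinal length gives the
    requested split. Longitudinal-dominant targets use a lower occupancy and
    longer connectors so the mesh stays resolvable.
    """
    if not (0.0 < target_fraction < 1.0):
        raise ValueError("target_fraction must lie strictly in (0, 1)")
    if base is None:
        base = TubuleNetworkSpec()
    if target_fraction >= 0.65:
        occ, span = 0.9, 1
    elif target_fraction >= 0.4:
        occ, span = 0.55, 2
    else:
        occ, span = 0.2, 3

    # expected transverse length: occupancy-weighted chords at nominal Z-lines
    pitch = base.sarcomere_spacing_um
    n_lines = int((base.cell_length_um - pitch) // pitch)
    xs = (np.arange(n_lines) - (n_lines - 1) / 2.0) * pitch
    a_in = base.cell_length_um / 2.0 - 0.5
    b_in = base.cell_width_um / 2.0 - 0.5
    u = np.clip(xs / a_in, -1, 1)
    chords = 2.0 * b_in * np.sqrt(1.0 - u ** 2)
    t_expected = occ * float(chords.sum())

    l_expected = t_expected * (1.0 / target_fraction - 1.0)
    area = math.pi * (base.cell_length_um / 2) * (base.cell_width_um / 2)
    density = l_expected / (span * pitch) / area
    return replace(base, transverse_occupancy=occ,
                   longitudinal_density_per_um2=density,
                   longitudinal_span_pitches=span, seed=seed)


# -- dyads ------------------------------------------------------------------

def generate_dyad_pair(spec: DyadSpec):
    """Render an aligned RyR / LTCC channel pair plus ground truth.

    Returns ``(ChannelPair, GroundTruth)``. Imported lazily to avoid a module
    cycle with :mod:`dyad_colocalization`.
    """
    from .dyad_colocalization import ChannelPair

    rng = np.random.default_rng(spec.seed)
    net = _build_network(spec.network, rng)
    ps = spec.network.pixel_size_um
    H, W = net.shape

    # pick orphan Z-lines among occupied transverse branches: they keep RyR
    # but lose their tubule and receive no LTCC
    t_branch_ids = [i for i, (_, lab) in enumerate(net.branches) if lab == TRANSVERSE]
    orphan_ids: List[int] = []
    if spec.orphan_gap_count > 0 and t_branch_ids:
        k = min(spec.orphan_gap_count, len(t_branch_ids))
        orphan_ids = list(rng.choice(t_branch_ids, size=k, replace=False))

    pitch_px = max(1, int(round(spec.ryr_cluster_pitch_um / ps)))
    # longitudinal clusters sit along the mid-segment of connectors, clear of
    # the ambiguous junction zone at the Z-lines
    end_margin_px = int(round(0.7 / ps))
    ryr_pts: List[Tuple[int, int]] = []
    ryr_labels: List[str] = []
    parent_axis: List[str] = []   # "v" for vertical elements, "h" horizontal
    is_orphan: List[bool] = []
    zcols = np.array(net.zline_cols)
    for i, (coords, lab) in enumerate(net.branches):
        if lab == LONGITUDINAL:
            # keep clusters clear of every Z-line a connector touches or
            # crosses, not just its endpoints
            clear = np.abs(coords[:, 1][:, None] - zcols[None, :]).min(axis=1) \
                >= end_margin_px
            sub = coords[clear][::pitch_px]
            if len(sub) == 0:
                continue
        else:
            sub = coords[::pitch_px]
        for r, c in sub:
            ryr_pts.append((int(r), int(c)))
            ryr_labels.append(lab)
            parent_axis.append("v" if lab == TRANSVERSE else "h")
            is_orphan.append(i in orphan_ids)

    p_by_label = {TRANSVERSE: spec.coloc_fraction_transverse,
                  LONGITUDINAL: spec.coloc_fraction_longitudinal}
    ltcc_pts: List[Tuple[int, int]] = []
    coloc_flags: List[bool] = []
    drawn = {TRANSVERSE: [0, 0], LONGITUDINAL: [0, 0]}  # [coloc, total]
    for (r, c), lab, axis, orphan in zip(ryr_pts, ryr_labels, parent_axis, is_orphan):
        if orphan:
            coloc_flags.append(False)
            continue
        coloc = bool(rng.random() < p_by_label[lab])
        drawn[lab][1] += 1
        if coloc:
            drawn[lab][0] += 1
            ltcc_pts.append((r, c))
            coloc_flags.append(True)
        else:
            offset_um = spec.min_displacement_um + abs(rng.normal(0.0, spec.displacement_sigma_um))
            # cap so displaced partners stay inside the parent territory
            offset_um = min(offset_um, spec.max_displacement_um)
            off = int(round(offset_um / ps)) * int(rng.choice([-1, 1]))
            rr, cc = (r, c + off) if axis == "v" else (r + off, c)
            rr, cc = int(np.clip(rr, 0, H - 1)), int(np.clip(cc, 0, W - 1))
            ltcc_pts.append((rr, cc))
            coloc_flags.append(False)

    sigma_px = spec.punctum_sigma_um / ps

    def _render_points(points: Sequence[Tuple[int, int]]) -> np.ndarray:
        delta = np.zeros((H, W))
        for r, c in points:
            delta[r, c] += 1.0
        blur = ndimage.gaussian_filter(delta, math.hypot(
            sigma_px, spec.network.psf_sigma_um / ps))
        peak = blur.max() if blur.max() > 0 else 1.0
        clean = (spec.network.background_level
                 + spec.punctum_amplitude * blur / peak)
        return _apply_noise(clean, spec.network, rng)

    ryr_img = Image2D(_render_points(ryr_pts), ps, "RyR")
    ltcc_img = Image2D(_render_points(ltcc_pts), ps, "LTCC")
    pair = ChannelPair(ryr=ryr_img, ltcc=ltcc_img,
                       cell_roi=BinaryMask(net.footprint, ps))

    realized = {
        lab: (drawn[lab][0] / drawn[lab][1]) if drawn[lab][1] else math.nan
        for lab in (TRANSVERSE, LONGITUDINAL)
    }
    # skeleton truth excludes orphaned lines (they carry no tubule)
    skel = np.zeros((H, W), dtype=bool)
    for i, (coords, _) in enumerate(net.branches):
        if i not in orphan_ids:
            skel[coords[:, 0], coords[:, 1]] = True
    truth = GroundTruth(
        seed=spec.seed, spec=spec, pixel_size_um=ps,
        footprint=net.footprint,
        skeleton_mask=skel,
        transverse_skeleton=_label_mask(net, TRANSVERSE),
        longitudinal_skeleton=_label_mask(net, LONGITUDINAL),
        coloc_fraction=realized,
        ryr_points=np.array(ryr_pts, dtype=int).reshape(-1, 2),
        ryr_labels=ryr_labels,
        ltcc_points=np.array(ltcc_pts, dtype=int).reshape(-1, 2),
        coloc_flags=np.array(coloc_flags, dtype=bool),
        orphan_zline_cols=[int(net.branches[i][0][0, 1]) for i in orphan_ids],
    )
    return pair, truth


# -- calcium ----------------------------------------------------------------

def generate_calcium_video(spec: CalciumSpec) -> Tuple[VideoStack, GroundTruth]:
    """Render a Ca2+ release video with a programmed per-pixel delay field."""
    rng = np.random.default_rng(spec.seed)
    net = _build_network(spec.network, rng)
    ps = spec.network.pixel_size_um
    H, W = net.shape
    skel = net.skeleton
    if not skel.any():
        raise ValueError("network has no tubules; no release sites to simulate")

    # site-wise delays: one draw per ~site_block_um stretch of each branch
    block_px = max(1, int(round(spec.site_block_um / ps)))
    site_delay_at_skel = np.zeros((H, W))
    for coords, _ in net.branches:
        n_blocks = max(1, math.ceil(len(coords) / block_px))
        delays = rng.normal(spec.site_delay_mean_ms, spec.site_delay_sd_ms, n_blocks)
        for bi in range(n_blocks):
            part = coords[bi * block_px:(bi + 1) * block_px]
            site_delay_at_skel[part[:, 0], part[:, 1]] = delays[bi]

    dist_px, (ir, ic) = ndimage.distance_transform_edt(
        ~skel, return_indices=True)
    dist_um = dist_px * ps
    delay_field = site_delay_at_skel[ir, ic].astype(float)

    roi = net.footprint
    # standardize the site component so the programmed per-pixel mean/SD hold
    vals = delay_field[roi]
    if spec.site_delay_sd_ms > 0 and vals.std() > 0:
        delay_field = ((delay_field - vals.mean()) / vals.std()
                       * spec.site_delay_sd_ms + spec.site_delay_mean_ms)
    else:
        delay_field = np.full_like(delay_field, spec.site_delay_mean_ms)
    delay_field = np.clip(delay_field, 0.0, None)

    if math.isfinite(spec.orphan_propagation_speed_um_per_ms):
        extra = np.clip(dist_um - spec.tubule_halo_um, 0.0, None) \
            / spec.orphan_propagation_speed_um_per_ms
        delay_field = delay_field + extra

    t_stim = spec.stimulus_frame * spec.frame_interval_ms
    total_ms = spec.n_frames * spec.frame_interval_ms
    if t_stim + float(delay_field[roi].max()) + 2 * spec.rise_tau_ms > total_ms:
        raise ValueError("frame budget too short for the programmed delays")

    times = np.arange(spec.n_frames) * spec.frame_interval_ms
    t0 = t_stim + delay_field
    u = times[:, None, None] - t0[None, :, :]
    g = np.where(
        u > 0,
        (1.0 - np.exp(-np.clip(u, 0, None) / spec.rise_tau_ms))
        * np.exp(-np.clip(u, 0, None) / spec.decay_tau_ms),
        0.0,
    )
    frames = spec.baseline + spec.amplitude * g
    frames[:, ~roi] = spec.baseline * 0.5  # dim, flat surround
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)
    video = VideoStack(frames, spec.frame_interval_ms, ps, "fluo-4")

    membrane_pixels = _render(
        ndimage.binary_dilation(skel, structure=morphology.disk(1)),
        replace(spec.network, photon_scale=200.0), rng)
    truth = GroundTruth(
        seed=spec.seed, spec=spec, pixel_size_um=ps,
        footprint=roi,
        skeleton_mask=skel,
        transverse_skeleton=_label_mask(net, TRANSVERSE),
        longitudinal_skeleton=_label_mask(net, LONGITUDINAL),
        delay_field_ms=delay_field,
        distance_to_skeleton_um=dist_um,
        membrane_image=Image2D(membrane_pixels, ps, "FM 1-43"),
    )
    return video, truth


# -- voltage ----------------------------------------------------------------

def generate_voltage_video(spec: VoltageSpec) -> Tuple[VideoStack, GroundTruth]:
    """Render a voltage-dye video with a programmed depolarized skeleton subset."""
    rng = np.random.default_rng(spec.seed)
    net = _build_network(spec.network, rng)
    ps = spec.network.pixel_size_um
    H, W = net.shape
    if not net.skeleton.any():
        raise ValueError("network has no tubules")

    lengths = [_branch_length_um(coords, ps) for coords, _ in net.branches]
    total = sum(lengths)
    order = rng.permutation(len(net.branches))
    target = spec.depolarized_fraction * total
    depol_mask = np.zeros((H, W), dtype=bool)
    cum = 0.0
    for i in order:
        if cum >= target:
            break
        coords, _ = net.branches[i]
        depol_mask[coords[:, 0], coords[:, 1]] = True
        cum += lengths[i]
    if spec.depolarized_fraction >= 1.0:
        depol_mask = net.skeleton.copy()

    realized = float(depol_mask.sum()) / float(net.skeleton.sum())

    half_w = max(1, int(round(spec.network.tubule_width_um / 2.0 / ps)))
    tubule_mask = ndimage.binary_dilation(net.skeleton, structure=morphology.disk(half_w))
    depol_region = ndimage.binary_dilation(depol_mask, structure=morphology.disk(half_w))

    base = (spec.network.background_level
            + spec.network.signal_level
            * ndimage.gaussian_filter(tubule_mask.astype(float),
                                      spec.network.psf_sigma_um / ps))
    step = np.where(depol_region, 1.0 + spec.step_amplitude_percent / 100.0, 1.0)

    frames = np.empty((spec.n_frames, H, W))
    for t in range(spec.n_frames):
        frame = base * step if t >= spec.onset_frame else base
        if t >= spec.contraction_frame:
            shift = spec.motion_amplitude_px * (t - spec.contraction_frame + 1)
            frame = np.roll(frame, shift, axis=1)
        frames[t] = frame
    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)
    video = VideoStack(frames, spec.frame_interval_ms, ps, "FluoVolt")

    truth = GroundTruth(
        seed=spec.seed, spec=spec, pixel_size_um=ps,
        footprint=net.footprint,
        skeleton_mask=net.skeleton,
        depolarized_mask=depol_mask,
        depolarized_fraction=realized,
    )
    return video, truth


# ---------------------------------------------------------------------------
# Phenotype presets
# ---------------------------------------------------------------------------

def _check_phenotype(name: str) -> None:
    if name not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {name!r}; choose from {PHENOTYPES}")


def phenotype_network(name: str, seed: int = 0) -> TubuleNetworkSpec:
    """Tubule-network parameters caricaturing each cell state."""
    _check_phenotype(name)
    params = {
        "developing": dict(transverse_occupancy=0.30,
                           longitudinal_density_per_um2=0.05,
                           longitudinal_span_pitches=2),
        "adult": dict(transverse_occupancy=0.95,
                      longitudinal_density_per_um2=0.01),
        "hf": dict(transverse_occupancy=0.55,
                   longitudinal_density_per_um2=0.03),
    }[name]
    return TubuleNetworkSpec(seed=seed, **params)


def phenotype_dyad(name: str, seed: int = 0) -> DyadSpec:
    _check_phenotype(name)
    params = {
        "developing": dict(coloc_fraction_transverse=0.85,
                           coloc_fraction_longitudinal=0.70,
                           orphan_gap_count=2),
        "adult": dict(coloc_fraction_transverse=0.90,
                      coloc_fraction_longitudinal=0.60,
                      orphan_gap_count=0),
        "hf": dict(coloc_fraction_transverse=0.60,
                   coloc_fraction_longitudinal=0.35,
                   orphan_gap_count=3),
    }[name]
    return DyadSpec(seed=seed, **params)


def phenotype_calcium(name: str, seed: int = 0) -> CalciumSpec:
    _check_phenotype(name)
    net = {
        "developing": dict(transverse_occupancy=0.45,
                           longitudinal_density_per_um2=0.08),
        "adult": dict(transverse_occupancy=0.95,
                      longitudinal_density_per_um2=0.02),
        "hf": dict(transverse_occupancy=0.55,
                   longitudinal_density_per_um2=0.04),
    }[name]
    kin = {
        "developing": dict(rise_tau_ms=25.0, site_delay_mean_ms=30.0,
                           site_delay_sd_ms=12.0,
                           orphan_propagation_speed_um_per_ms=0.10),
        "adult": dict(rise_tau_ms=12.0, site_delay_mean_ms=8.0,
                      site_delay_sd_ms=3.0,
                      orphan_propagation_speed_um_per_ms=0.30),
        "hf": dict(rise_tau_ms=25.0, site_delay_mean_ms=30.0,
                   site_delay_sd_ms=12.0,
                   orphan_propagation_speed_um_per_ms=0.08),
    }[name]
    base = CalciumSpec(seed=seed, **kin)
    return replace(base, network=replace(base.network, **net))


def phenotype_voltage(name: str, seed: int = 0) -> VoltageSpec:
    _check_phenotype(name)
    net = phenotype_network(name, seed)
    net = replace(net, cell_length_um=30.0, cell_width_um=14.0, margin_um=1.5)
    # similar depolarized extents across states (the central negative finding)
    return VoltageSpec(network=net, depolarized_fraction=0.95, seed=seed)
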