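"""Ca2+ transient kinetics: global F/F0 traces, per-pixel dyssynchrony maps,
and local 1x1 um release-site timing.

Definitions
-----------
* Global trace: spatial mean over the cell ROI per frame; F0 is the mean of
  the pre-stimulus frames; F50 is the level halfway between F0 and the
  post-stimulus peak; TF50 is the time from the stimulus to the F50 crossing
  (linear interpolation between frames).
* Dyssynchrony index (DI): the standard deviation (configurable: IQR) of the
  per-pixel time to half-maximal fluorescence across the cell ROI, in ms.
* Local TTF50: for a 1x1 um box, the time from the local start of Ca2+ rise
  (last frame before the local trace sustainably exceeds baseline + 2 SD) to
  the crossing of the *global* F50 level — long at "orphaned" sites that wait
  for Ca2+ to propagate from distant release sites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .image_core import BinaryMask, Image2D, VideoStack
from .tubule_morphometry import (
    LONGITUDINAL,
    TRANSVERSE,
    Skeleton,
    segment_in_place,
    skeletonize_mask,
)

__all__ = [
    "TransientTrace",
    "GlobalKinetics",
    "DIMap",
    "LocalSite",
    "ORPHANED",
    "global_transient",
    "dyssynchrony_map",
    "skeleton_from_membrane_frame",
    "classify_sites",
    "local_ttf50",
]

ORPHANED = "orphaned"


@dataclass(frozen=True)
class TransientTrace:
    """Region-mean fluorescence trace with baseline normalization."""

    time_ms: np.ndarray
    f: np.ndarray
    f0: float

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError("baseline f0 must be positive")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def f_norm(self) -> np.ndarray:
        return self.f / self.f0


@dataclass(frozen=True)
class GlobalKinetics:
    """Whole-region transient kinetics measured from the stimulus.

    ``rise_onset_ms`` is the absolute time of the start of the cell-wide Ca2+
    rise (last frame before the ROI-mean trace sustainably exceeds baseline +
    2 SD), used as the common timing reference for local sites.
    """

    stimulus_frame: int
    time_to_peak_ms: float
    f50_level: float
    tf50_ms: float
    rise_onset_ms: float = math.nan
    valid: bool = True


@dataclass(frozen=True)
class DIMap:
    """Per-pixel time-to-half-max field and its dispersion (the DI)."""

    tf50_map: np.ndarray  # ms; NaN where no valid crossing
    di_ms: float
    n_valid: int
    n_invalid: int
    reliable: bool = True


@dataclass(frozen=True)
class LocalSite:
    """A 1x1 um analysis box categorized by its relation to the tubule network."""

    centre_rc: Tuple[int, int]
    half_px: int
    category: str
    centre_um: Tuple[float, float] = (0.0, 0.0)

    def slices(self) -> Tuple[slice, slice]:
        r, c = self.centre_rc
        h = self.half_px
        return slice(r - h, r + h + 1), slice(c - h, c + h + 1)


def _interp_crossing(
    times: np.ndarray, values: np.ndarray, level: float, start: int
) -> Optional[float]:
    """Time of the first crossing of ``level`` at or after index ``start``
    (linear interpolation between bracketing frames); None if never reached."""
    after = values[start:]
    above = after >= level
    if not above.any():
        return None
    k = int(np.argmax(above)) + start
    if k == start or values[k - 1] >= level:
        return float(times[k])
    v0, v1 = values[k - 1], values[k]
    frac = (level - v0) / (v1 - v0)
    return float(times[k - 1] + frac * (times[k] - times[k - 1]))


def global_transient(
    video: VideoStack, roi: np.ndarray, stimulus_frame: int
) -> Tuple[TransientTrace, GlobalKinetics]:
    """ROI-mean transient and its kinetics (time to peak, F50 level, TF50)."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if stimulus_frame < 3:
        raise ValueError("need >= 3 pre-stimulus frames")
    times = video.times_ms()
    f = video.frames[:, roi].mean(axis=1)
    f0 = float(f[:stimulus_frame].mean())
    trace = TransientTrace(times, f, f0)

    post = f[stimulus_frame:]
    peak = float(post.max())
    if peak <= f0 * (1 + 1e-9):
        kin = GlobalKinetics(stimulus_frame, math.nan, math.nan, math.nan,
                             valid=False)
        return trace, kin
    f50 = f0 + 0.5 * (peak - f0)
    t_stim = times[stimulus_frame]
    t_peak = float(times[stimulus_frame + int(np.argmax(post))])
    t50 = _interp_crossing(times, f, f50, stimulus_frame)
    onset = _rise_onset_index(f, stimulus_frame)
    kin = GlobalKinetics(
        stimulus_frame=stimulus_frame,
        time_to_peak_ms=t_peak - t_stim,
        f50_level=f50,
        tf50_ms=(t50 - t_stim) if t50 is not None else math.nan,
        rise_onset_ms=float(times[onset]) if onset is not None else math.nan,
        valid=t50 is not None,
    )
    return trace, kin


def _rise_onset_index(
    trace: np.ndarray, stimulus_frame: int, sd_mult: float = 2.0
) -> Optional[int]:
    """Last frame before ``trace`` sustainably (>= 2 consecutive frames)
    exceeds its pre-stimulus baseline + ``sd_mult`` x SD; None if never."""
    base = trace[:stimulus_frame]
    thr = float(base.mean()) + sd_mult * float(base.std())
    above = trace > thr
    sustained = above[:-1] & above[1:]
    candidates = np.nonzero(sustained)[0]
    candidates = candidates[candidates >= max(stimulus_frame - 1, 1)]
    if len(candidates) == 0:
        return None
    return int(candidates[0]) - 1


def dyssynchrony_map(
    video: VideoStack,
    roi: np.ndarray,
    stimulus_frame: int,
    smooth_px: int = 3,
    statistic: str = "sd",
) -> DIMap:
    """Per-pixel time-to-half-max map and its dispersion (DI).

    Frames are smoothed spatially (``smooth_px`` x ``smooth_px`` uniform
    filter) to tame shot noise at ms sampling, then each ROI pixel's baseline,
    post-stimulus peak, and half-max crossing time are computed as for the
    global trace. DI is the SD (or IQR) of crossing times over pixels with a
    valid crossing; a map with more than half its pixels lacking a crossing is
    flagged unreliable.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if stimulus_frame < 3:
        raise ValueError("need >= 3 pre-stimulus frames")
    frames = video.frames
    if smooth_px > 1:
        frames = ndimage.uniform_filter(frames, size=(1, smooth_px, smooth_px))
    times = video.times_ms()

    f0 = frames[:stimulus_frame].mean(axis=0)
    post = frames[stimulus_frame:]
    peak = post.max(axis=0)
    half = f0 + 0.5 * (peak - f0)
    rose = peak > f0 * (1 + 1e-9)

    above = post >= half[None, :, :]
    first = np.argmax(above, axis=0)  # first post-stimulus frame at/above half
    crossed = above.any(axis=0) & rose

    tf50 = np.full(frames.shape[1:], np.nan)
    dt = video.frame_interval_ms
    # linear interpolation between the bracketing frames, vectorized
    k = first
    t_at = times[stimulus_frame + k]
    v_at = np.take_along_axis(post, k[None, :, :], axis=0)[0]
    k_prev = np.maximum(k - 1, 0)
    v_prev = np.take_along_axis(post, k_prev[None, :, :], axis=0)[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (half - v_prev) / (v_at - v_prev)
    frac = np.clip(np.nan_to_num(frac, nan=0.0), 0.0, 1.0)
    t_interp = t_at - dt + frac * dt
    t_interp = np.where(k == 0, t_at, t_interp)
    t_stim = times[stimulus_frame]
    tf50[crossed & roi] = (t_interp - t_stim)[crossed & roi]

    valid = crossed & roi
    n_valid = int(valid.sum())
    n_invalid = int(roi.sum()) - n_valid
    vals = tf50[valid]
    if n_valid == 0:
        di = math.nan
    elif statistic == "sd":
        di = float(vals.std())
    elif statistic == "iqr":
        q75, q25 = np.percentile(vals, [75, 25])
        di = float(q75 - q25)
    else:
        raise ValueError("statistic must be 'sd' or 'iqr'")
    reliable = n_valid >= n_invalid
    if not reliable:
        warnings.warn("more than half the ROI pixels lack a half-max crossing")
    return DIMap(tf50, di, n_valid, n_invalid, reliable)


# ---------------------------------------------------------------------------
# Local release sites
# ---------------------------------------------------------------------------

def skeleton_from_membrane_frame(frame: Image2D, roi: np.ndarray) -> Skeleton:
    """Segment and skeletonize a co-acquired membrane-dye frame *without*
    rotation, so the skeleton stays registered with the video."""
    mask = segment_in_place(frame).pixels & np.asarray(roi, dtype=bool)
    return skeletonize_mask(mask, frame.pixel_size_um)


def _box_half_px(pixel_size_um: float, box_um: float = 1.0) -> int:
    """Half-width so the box spans ~box_um, rounded to an odd pixel count."""
    n = max(3, round(box_um / pixel_size_um))
    if n % 2 == 0:
        n += 1
    return n // 2


def classify_sites(
    skeleton: Skeleton,
    roi: np.ndarray,
    n_sites: int = 5,
    categories: Sequence[str] = (TRANSVERSE, LONGITUDINAL, ORPHANED),
    orphan_cutoff_um: float = 0.5,
    box_um: float = 1.0,
    seed: int = 0,
) -> List[LocalSite]:
    """Select 1x1 um local-release sites of each requested category.

    Transverse / longitudinal sites are centred on skeleton pixels carrying the
    corresponding branch label; orphaned sites are centred on local maxima of
    the distance-to-skeleton field that exceed ``orphan_cutoff_um`` (gaps in
    the tubule network). Up to ``n_sites`` per category are drawn (seeded),
    enforcing that boxes lie fully inside the ROI and do not overlap within a
    category. Categories with no qualifying pixels come back empty.
    """
    roi = np.asarray(roi, dtype=bool)
    ps = skeleton.pixel_size_um
    half = _box_half_px(ps, box_um)
    rng = np.random.default_rng(seed)
    H, W = roi.shape

    fits = np.zeros_like(roi)
    fits[half:H - half, half:W - half] = True
    # boxes must lie fully inside the ROI
    roi_eroded = ndimage.binary_erosion(roi, structure=np.ones((2 * half + 1,) * 2))
    allowed = fits & roi_eroded

    sites: List[LocalSite] = []

    def _pick(coords: np.ndarray, category: str, order: Optional[np.ndarray] = None):
        if order is None:
            order = rng.permutation(len(coords))
        taken: List[Tuple[int, int]] = []
        for idx in order:
            r, c = map(int, coords[idx])
            if not allowed[r, c]:
                continue
            if any(abs(r - tr) <= 2 * half and abs(c - tc) <= 2 * half
                   for tr, tc in taken):
                continue
            taken.append((r, c))
            sites.append(LocalSite((r, c), half, category, (c * ps, r * ps)))
            if len(taken) >= n_sites:
                break

    for category in categories:
        if category in (TRANSVERSE, LONGITUDINAL):
            m = skeleton.label_mask(category)
            coords = np.argwhere(m)
            if len(coords):
                _pick(coords, category)
        elif category == ORPHANED:
            skel = skeleton.pixels.pixels
            if not skel.any():
                continue
            dist = ndimage.distance_transform_edt(~skel) * ps
            footprint = np.ones((2 * half + 1,) * 2)
            is_max = dist == ndimage.maximum_filter(dist, footprint=footprint)
            cand = is_max & (dist > orphan_cutoff_um) & allowed
            coords = np.argwhere(cand)
            if len(coords):
                order = np.argsort(-dist[cand.nonzero()])  # deepest gaps first
                _pick(coords, ORPHANED, order=order)
        else:
            raise ValueError(f"unknown site category: {category}")
    return sites


def local_ttf50(
    video: VideoStack,
    site: LocalSite,
    glob: GlobalKinetics,
    baseline_sd_mult: float = 2.0,
    reference: str = "global",
) -> Tuple[Optional[float], str]:
    """Local TTF50 of one site: time from the start of the Ca2+ rise to the
    crossing of the global F50 level by the site's 1x1 um mean trace.

    With ``reference="global"`` (default) the start of rise is the cell-wide
    rise onset (``glob.rise_onset_ms``), a common timing reference under which
    a site whose release is delayed by d ms measures d ms longer — the
    behaviour of delayed "orphaned" sites. With ``reference="local"`` the
    onset is detected on the site's own trace (last frame before it exceeds
    baseline + ``baseline_sd_mult`` x SD for >= 2 consecutive frames), which
    quantifies only the local rise shape.

    Returns (ttf50_ms, flag); flag is ``"non-responding"`` (ttf50 None) when
    the local trace never reaches the global F50 level.
    """
    if not glob.valid:
        raise ValueError("global kinetics are invalid; cannot time local sites")
    rs, cs = site.slices()
    if rs.start < 0 or cs.start < 0 or rs.stop > video.frame_shape[0] \
            or cs.stop > video.frame_shape[1]:
        raise ValueError("site box extends outside the frame")
    trace = video.frames[:, rs, cs].mean(axis=(1, 2))
    times = video.times_ms()
    stim = glob.stimulus_frame

    if reference == "global":
        if math.isnan(glob.rise_onset_ms):
            raise ValueError("global rise onset undetected")
        t_start = glob.rise_onset_ms
        search_from = stim
    elif reference == "local":
        onset_idx = _rise_onset_index(trace, stim, sd_mult=baseline_sd_mult)
        if onset_idx is None:
            return None, "non-responding"
        t_start = float(times[onset_idx])
        search_from = onset_idx
    else:
        raise ValueError("reference must be 'global' or 'local'")

    t50 = _interp_crossing(times, trace, glob.f50_level, search_from)
    if t50 is None:
        return None, "non-responding"
    return t50 - t_start, "ok"
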