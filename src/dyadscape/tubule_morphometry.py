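"""T-tubule network morphometry: segmentation, density, and orientation.

Implements the confocal t-tubule macro: background removal (rolling ball
15 px), rotation of the cell long axis to horizontal, contrast enhancement to
0.8% saturated pixels, Mexican-hat (r=3) and median (r=1) filtering, Otsu
segmentation, density measurement inside a sub-sarcolemmal ROI, and
skeletonization with decomposition of the network into transverse vs
longitudinal branches.

Orientation convention: after rotation the cell long axis is horizontal, so a
branch is *transverse* (runs across the cell) when its principal direction is
within 45 degrees of the image vertical, and *longitudinal* otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import morphology

from .image_core import (
    BinaryMask,
    CellGeometry,
    DegenerateImageError,
    Image2D,
    enhance_contrast,
    median_filter,
    mexican_hat,
    otsu_threshold,
    rotate_to_horizontal,
    subtract_background,
)

__all__ = [
    "SegmentedTubules",
    "SkeletonBranch",
    "Skeleton",
    "TubuleMetrics",
    "segment_tubules",
    "tubule_density",
    "skeletonize_mask",
    "skeletonize_network",
    "orientation_fractions",
    "analyze_tubules",
    "TRANSVERSE",
    "LONGITUDINAL",
]

TRANSVERSE = "transverse"
LONGITUDINAL = "longitudinal"

# pipeline parameters (pixels / percent), as used throughout the analyses
ROLLING_BALL_RADIUS_PX = 15
SATURATED_PERCENT = 0.8
MEXICAN_HAT_RADIUS_PX = 3
MEDIAN_RADIUS_PX = 1


@dataclass(frozen=True)
class SegmentedTubules:
    """Binary tubule mask together with the geometry of the segmented cell."""

    mask: BinaryMask
    geometry: CellGeometry

    def __post_init__(self) -> None:
        if self.mask.pixels.shape != self.geometry.footprint.pixels.shape:
            raise ValueError("mask and geometry shapes differ")


@dataclass(frozen=True)
class SkeletonBranch:
    """One junction-free branch of the skeleton.

    ``path`` is the ordered (row, col) pixel path; ``orientation_deg`` the
    principal direction vs the image horizontal in (-90, 90]; ``label`` one of
    ``transverse`` / ``longitudinal``; ``length_um`` the 8-connected step
    length (1 or sqrt(2) pixel units) in micrometres.
    """

    path: np.ndarray
    orientation_deg: float
    label: str
    length_um: float


@dataclass(frozen=True)
class Skeleton:
    """One-pixel-wide tubule network decomposed into labelled branches."""

    pixels: BinaryMask
    branches: Tuple[SkeletonBranch, ...]
    pixel_size_um: float
    n_junction_pixels: int = 0

    def total_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))

    def length_um(self, label: str) -> float:
        return float(sum(b.length_um for b in self.branches if b.label == label))

    def label_mask(self, label: str) -> np.ndarray:
        out = np.zeros(self.pixels.pixels.shape, dtype=bool)
        for b in self.branches:
            if b.label == label:
                out[b.path[:, 0], b.path[:, 1]] = True
        return out


@dataclass(frozen=True)
class TubuleMetrics:
    """Summary morphometry of one cell's t-tubule network."""

    density_percent: float
    transverse_fraction: float
    longitudinal_fraction: float
    skeleton_length_um: float
    roi_margin_um: float = 1.0

    def as_dict(self) -> Dict[str, float]:
        return {
            "density_percent": self.density_percent,
            "transverse_fraction": self.transverse_fraction,
            "longitudinal_fraction": self.longitudinal_fraction,
            "skeleton_length_um": self.skeleton_length_um,
            "roi_margin_um": self.roi_margin_um,
        }


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _segment_frame(img: Image2D) -> np.ndarray:
    """Filter chain + Otsu on an already-oriented frame; empty mask if featureless."""
    enhanced = enhance_contrast(img, SATURATED_PERCENT)
    ridge = mexican_hat(enhanced, MEXICAN_HAT_RADIUS_PX)
    smooth = median_filter(ridge, MEDIAN_RADIUS_PX)
    try:
        _, mask = otsu_threshold(smooth)
    except DegenerateImageError:
        return np.zeros(img.shape, dtype=bool)
    return mask.pixels


def segment_tubules(img: Image2D, roi_margin_um: float = 1.0) -> SegmentedTubules:
    """Segment the t-tubule network of a single membrane-stain micrograph.

    Applies, in order: background subtraction (rolling ball 15 px), rotation of
    the cell long axis to horizontal, contrast enhancement (0.8% saturated),
    Mexican hat (r=3), median filter (r=1), and Otsu thresholding. The returned
    mask is restricted to the cell footprint. A featureless interior yields an
    empty mask rather than a failure.
    """
    flattened = subtract_background(img, ROLLING_BALL_RADIUS_PX)
    # footprint and angle come from the raw micrograph: background removal
    # flattens a featureless cell body entirely, which must yield an empty
    # tubule mask, not a failed rotation
    rotated, geometry = rotate_to_horizontal(
        flattened, roi_margin_um=roi_margin_um, reference=img)
    mask = _segment_frame(rotated) & geometry.footprint.pixels
    return SegmentedTubules(BinaryMask(mask, img.pixel_size_um), geometry)


def segment_in_place(img: Image2D) -> BinaryMask:
    """Segment tubules without rotating (for frames that must stay registered
    with a co-acquired video). Background subtraction + filter chain + Otsu."""
    flattened = subtract_background(img, ROLLING_BALL_RADIUS_PX)
    return BinaryMask(_segment_frame(flattened), img.pixel_size_um)


def tubule_density(seg: SegmentedTubules) -> float:
    """Percent of the interior-ROI area covered by the tubule mask."""
    roi = seg.geometry.interior_roi.pixels
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("interior ROI is empty; cannot measure density")
    return 100.0 * float((seg.mask.pixels & roi).sum()) / n_roi


# ---------------------------------------------------------------------------
# Skeletonization and branch decomposition
# ---------------------------------------------------------------------------

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")


# circular ring order (dr, dc): N, NE, E, SE, S, SW, W, NW
_RING = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _crossing_number(skel: np.ndarray) -> np.ndarray:
    """Rutovitz crossing number: 0-to-1 transitions around each pixel's 8-ring.

    A skeleton pixel with crossing number >= 3 is a genuine junction; unlike a
    raw neighbour count this does not flag the pixels flanking a T-junction,
    so junctions stay single-pixel and branch lengths are not eroded.
    """
    padded = np.pad(skel.astype(np.uint8), 1)
    ring = np.stack([
        padded[1 + dr: padded.shape[0] - 1 + dr,
               1 + dc: padded.shape[1] - 1 + dc]
        for dr, dc in _RING
    ])
    nxt = np.roll(ring, -1, axis=0)
    return ((ring == 0) & (nxt == 1)).sum(axis=0)


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _extract_branches(skel: np.ndarray, junctions: np.ndarray) -> List[np.ndarray]:
    """Trace junction-to-junction (or junction-to-endpoint) pixel paths.

    Walks outward from every junction along non-junction skeleton pixels, then
    orders any remaining junction-free chains and loops. Candidate steps that
    are 8-adjacent to the previous pixel are deprioritized so the walk does
    not hop diagonally between two arms of the same junction.
    """
    path_px = skel & ~junctions
    coords = np.argwhere(path_px)
    path_set = {tuple(p) for p in coords}
    junction_set = {tuple(p) for p in np.argwhere(junctions)}

    def neighbors(p, pool):
        r, c = p
        return [(r + dr, c + dc) for dr, dc in _OFFSETS if (r + dr, c + dc) in pool]

    visited = set()
    branches: List[np.ndarray] = []

    def walk(start, origin):
        path = [start]
        visited.add(start)
        prev, current = origin, start
        from_junction = origin in junction_set
        while True:
            # a branch ends where it touches a junction other than its origin
            if any(q != origin for q in neighbors(current, junction_set)):
                break
            cand = [q for q in neighbors(current, path_set) if q not in visited]
            if from_junction and current == start:
                # do not hop diagonally into a sibling arm of the origin
                cand = [q for q in cand
                        if abs(q[0] - origin[0]) > 1 or abs(q[1] - origin[1]) > 1]
            if not cand:
                break
            if len(cand) > 1:
                far = [q for q in cand
                       if abs(q[0] - prev[0]) > 1 or abs(q[1] - prev[1]) > 1]
                if far:
                    cand = far
                cand.sort(key=lambda q: abs(q[0] - current[0]) + abs(q[1] - current[1]))
            prev, current = current, cand[0]
            visited.add(current)
            path.append(current)
        return np.array(path, dtype=int)

    for j in sorted(junction_set):
        for n in neighbors(j, path_set):
            if n not in visited:
                branches.append(walk(n, j))

    # junction-free chains and loops
    for p in map(tuple, coords):
        if p in visited:
            continue
        comp = [p]
        visited.add(p)
        stack = [p]
        while stack:
            q = stack.pop()
            for n in neighbors(q, path_set):
                if n not in visited:
                    visited.add(n)
                    comp.append(n)
                    stack.append(n)
        comp_set = set(comp)
        ends = [q for q in comp if len(neighbors(q, comp_set)) <= 1]
        start = ends[0] if ends else comp[0]
        for q in comp:
            visited.discard(q)
        branches.append(walk(start, start))
    return branches


def _path_length_px(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.diff(path.astype(float), axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def _branch_orientation_deg(path: np.ndarray) -> float:
    """Principal direction of a pixel path vs horizontal (y up), in (-90, 90]."""
    if len(path) < 2:
        return 0.0
    x = path[:, 1].astype(float)
    y = -path[:, 0].astype(float)
    # endpoint chord blended with PCA: PCA dominates for long/curved branches
    x0, y0 = x - x.mean(), y - y.mean()
    cov = np.array([[np.dot(x0, x0), np.dot(x0, y0)],
                    [np.dot(x0, y0), np.dot(y0, y0)]]) / len(x)
    theta = 0.5 * math.degrees(math.atan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1]))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    return theta


def _label_from_orientation(orientation_deg: float) -> str:
    # transverse = within 45 deg of the image vertical (inclusive at the tie)
    return TRANSVERSE if abs(orientation_deg) >= 45.0 else LONGITUDINAL


def skeletonize_mask(
    mask: np.ndarray, pixel_size_um: float, min_branch_px: int = 3
) -> Skeleton:
    """Thin a binary mask to 1 px width and decompose it into labelled branches.

    Junction pixels (>= 3 skeleton neighbours) separate branches and are not
    assigned to any branch for length accounting; their count is reported on
    the skeleton. Branches shorter than ``min_branch_px`` inherit the label of
    their longest neighbouring branch (tie or no neighbour: transverse).
    """
    skel = morphology.skeletonize(mask.astype(bool))
    if not skel.any():
        return Skeleton(BinaryMask(skel, pixel_size_um), (), pixel_size_um, 0)

    junctions = skel & (_crossing_number(skel) >= 3)
    paths = _extract_branches(skel, junctions)

    raw: List[Tuple[np.ndarray, float, float]] = []  # (path, orientation, length_um)
    labels = np.zeros(skel.shape, dtype=int)
    for i, path in enumerate(paths):
        labels[path[:, 0], path[:, 1]] = i + 1
        raw.append((path, _branch_orientation_deg(path),
                    _path_length_px(path) * pixel_size_um))

    # provisional labels, then let runt branches inherit from their longest neighbour
    prov = [_label_from_orientation(o) for _, o, _ in raw]
    dil = np.ones((5, 5), dtype=bool)
    for i, (path, _, _) in enumerate(raw):
        if len(path) >= min_branch_px:
            continue
        lo = np.maximum(path.min(axis=0) - 2, 0)
        hi = np.minimum(path.max(axis=0) + 3, labels.shape)
        region = labels[lo[0]:hi[0], lo[1]:hi[1]]
        neigh = np.zeros(region.shape, dtype=bool)
        neigh[path[:, 0] - lo[0], path[:, 1] - lo[1]] = True
        neigh = ndimage.binary_dilation(neigh, structure=dil)
        cand = np.unique(region[neigh])
        cand = cand[(cand != 0) & (cand != i + 1)]
        if len(cand):
            best = max(cand, key=lambda c: raw[c - 1][2])
            prov[i] = prov[best - 1]
        else:
            prov[i] = TRANSVERSE

    branches = tuple(
        SkeletonBranch(path=path, orientation_deg=o, label=prov[i], length_um=l)
        for i, (path, o, l) in enumerate(raw)
    )
    return Skeleton(
        BinaryMask(skel, pixel_size_um), branches, pixel_size_um,
        int(junctions.sum()),
    )


def skeletonize_network(seg: SegmentedTubules) -> Skeleton:
    """Skeletonize a segmented tubule network (see :func:`skeletonize_mask`)."""
    return skeletonize_mask(seg.mask.pixels, seg.mask.pixel_size_um)


def orientation_fractions(sk: Skeleton) -> Tuple[float, float, float]:
    """(transverse_fraction, longitudinal_fraction, total_length_um) of a skeleton."""
    total = sk.total_length_um()
    if total <= 0:
        raise ValueError("empty skeleton: orientation fractions undefined")
    t = sk.length_um(TRANSVERSE) / total
    return t, 1.0 - t, total


def analyze_tubules(img: Image2D, roi_margin_um: float = 1.0) -> TubuleMetrics:
    """Full morphometry of one micrograph: density plus orientation fractions."""
    seg = segment_tubules(img, roi_margin_um=roi_margin_um)
    density = tubule_density(seg)
    sk = skeletonize_network(seg)
    if sk.total_length_um() > 0:
        t_frac, l_frac, total = orientation_fractions(sk)
    else:
        t_frac = l_frac = total = float("nan")
    return TubuleMetrics(
        density_percent=density,
        transverse_fraction=t_frac,
        longitudinal_fraction=l_frac,
        skeleton_length_um=total,
        roi_margin_um=roi_margin_um,
    )
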