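"""Voltage-dye (FluoVolt) analysis: fraction of the t-tubule skeleton that
depolarizes during the action potential.

The three frames preceding cell contraction are restricted to the skeleton
pixels, normalized per pixel to the first frame of the recording (F/F0), and
the pooled normalized values are Otsu-thresholded. A skeleton pixel counts as
depolarized when it is above threshold in at least one of the three frames
(configurable to all three). When the pooled distribution is not genuinely
bimodal, the result is resolved against the early-recording baseline: a
uniformly elevated network is reported as fully depolarized, a quiescent one
as zero with a machine-readable ``no-signal`` flag — Otsu alone cannot
distinguish "everything up" from "nothing up".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .image_core import DegenerateImageError, VideoStack, _otsu_threshold_array
from .tubule_morphometry import Skeleton

__all__ = ["DepolarizationResult", "depolarized_fraction", "detect_contraction_frame"]


@dataclass(frozen=True)
class DepolarizationResult:
    """Fraction of skeleton pixels with above-threshold voltage signal."""

    fraction_depolarized: float
    above_mask: np.ndarray  # boolean, subset of the skeleton
    contraction_frame: int
    frames_used: Tuple[int, int, int]
    threshold: float
    flag: str = "ok"  # "ok" | "no-signal" | "f0-excluded"
    n_excluded_f0: int = 0


def detect_contraction_frame(
    video: VideoStack, baseline_frames: int = 5, z_mult: float = 3.0
) -> Tuple[int, str]:
    """First frame at which whole-frame motion exceeds its baseline variability.

    The motion metric is the mean absolute frame-to-frame difference divided
    by the mean intensity of the earlier frame (so the detection is invariant
    to global intensity scaling). Returns (frame_index, flag); with no motion
    detected the last frame is returned flagged ``"no-motion"`` (all frames
    usable).
    """
    if video.n_frames < 10:
        raise ValueError("need at least 10 frames for contraction detection")
    frames = video.frames
    prev_mean = frames[:-1].mean(axis=(1, 2))
    prev_mean = np.where(prev_mean > 0, prev_mean, 1.0)
    motion = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2)) / prev_mean
    base = motion[:baseline_frames]
    thr = base.mean() + z_mult * max(base.std(), 1e-12)
    above = np.nonzero(motion > thr)[0]
    if len(above) == 0:
        warnings.warn("no contraction detected; returning the last frame")
        return video.n_frames - 1, "no-motion"
    return int(above[0]) + 1, "ok"  # motion[k] compares frames k and k+1


def _bimodal(values: np.ndarray, threshold: float, sep_mult: float = 4.0) -> bool:
    lo = values[values <= threshold]
    hi = values[values > threshold]
    if len(lo) < 2 or len(hi) < 2:
        return False
    spread = max(float(lo.std()), float(hi.std()), 1e-12)
    return (hi.mean() - lo.mean()) >= sep_mult * spread


def depolarized_fraction(
    video: VideoStack,
    skeleton: Skeleton,
    contraction_frame: Optional[int] = None,
    rule: str = "any",
    baseline_frames: int = 3,
) -> DepolarizationResult:
    """Fraction of the t-tubule skeleton whose F/F0 signal rises above threshold.

    Parameters
    ----------
    video
        The voltage-dye recording.
    skeleton
        The cell's skeletonized t-tubule network (registered with the video).
    contraction_frame
        Index of the first frame with contraction movement; auto-detected when
        omitted. The three frames before it are analysed.
    rule
        ``"any"`` (default): a pixel is depolarized if above threshold in at
        least one of the three frames; ``"all"``: in all three.
    """
    skel = skeleton.pixels.pixels
    if not skel.any():
        raise ValueError("empty skeleton")
    if contraction_frame is None:
        contraction_frame, _ = detect_contraction_frame(video)
    if contraction_frame < 4:
        raise ValueError("contraction_frame must be >= 4 (need 3 prior frames)")
    frames_used = (contraction_frame - 3, contraction_frame - 2, contraction_frame - 1)

    f0 = video.frames[0]
    usable = skel & (f0 > 0)
    n_excluded = int(skel.sum()) - int(usable.sum())
    flag = "ok"
    if n_excluded > 0.2 * skel.sum():
        warnings.warn("more than 20% of skeleton pixels have zero F0; flagged")
        flag = "f0-excluded"

    stack = video.frames[list(frames_used)][:, usable] / f0[usable][None, :]
    values = stack.ravel()
    n_skel = int(skel.sum())

    degenerate = np.ptp(values) < 1e-12
    if not degenerate:
        thr, _ = _otsu_threshold_array(values.reshape(1, -1))

    if degenerate or not _bimodal(values, thr):
        # unimodal: Otsu cannot separate "everything up" from "nothing up";
        # decide against the early-recording baseline instead
        nb = max(1, min(baseline_frames, frames_used[0] - 1))
        base = video.frames[1:1 + nb][:, usable] / f0[usable][None, :]
        b_mu, b_sd = float(base.mean()), float(base.std())
        thr = b_mu + 3.0 * max(b_sd, 1e-12)
        if float(np.median(values)) <= thr:
            return DepolarizationResult(
                0.0, np.zeros_like(skel), contraction_frame, frames_used,
                thr, flag="no-signal", n_excluded_f0=n_excluded)

    above_any = (stack > thr)
    per_pixel = above_any.any(axis=0) if rule == "any" else above_any.all(axis=0)
    above_mask = np.zeros_like(skel)
    above_mask[usable] = per_pixel
    fraction = float(above_mask.sum()) / n_skel
    return DepolarizationResult(
        fraction, above_mask, contraction_frame, frames_used, float(thr),
        flag=flag, n_excluded_f0=n_excluded)
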