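"""Bragg-peak detection and frame classification.

The finder follows the gradient-search scheme classically used for
spot detection on area detectors: candidate pixels exceeding the
photon-count threshold are walked uphill to their local maximum, a
small region is grown around each maximum while counts stay above the
local background plus ``k_sigma`` background standard deviations, and
the centroid is the count-weighted mean over that region.  The local
background is the median of an annulus around the maximum, so the
25-count threshold applies to background-subtracted peak height.

Frames are classified by peak count with strict bounds: more than
``min_peaks`` (default 15) detected peaks makes a hit, ``max_peaks``
(default 200) or more flags a likely multi-crystal frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .config import PeakFindParams

__all__ = ["DetectedPeak", "FrameClassification", "find_peaks", "classify_frame"]


@dataclass(frozen=True)
class DetectedPeak:
    """One detected Bragg peak (fractional-pixel centroid)."""

    fast: float
    slow: float
    intensity: float   # integrated counts above local background
    max_count: float   # background-subtracted height of the maximum


@dataclass(frozen=True)
class FrameClassification:
    n_peaks: int
    label: str  # "blank" | "hit" | "multi"


@lru_cache(maxsize=8)
def _disc_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    keep = dy * dy + dx * dx <= radius * radius
    return dy[keep], dx[keep]


def _ascend(image: np.ndarray, slow: int, fast: int, max_steps: int = 50):
    """Steepest-ascent walk to the local maximum of a 3×3 neighborhood."""
    n_slow, n_fast = image.shape
    for _ in range(max_steps):
        s0, s1 = max(slow - 1, 0), min(slow + 2, n_slow)
        f0, f1 = max(fast - 1, 0), min(fast + 2, n_fast)
        window = image[s0:s1, f0:f1]
        ds, df = np.unravel_index(np.argmax(window), window.shape)
        ns, nf = s0 + ds, f0 + df
        if (ns, nf) == (slow, fast):
            return slow, fast
        slow, fast = ns, nf
    return slow, fast


def find_peaks(image: np.ndarray, params: PeakFindParams | None = None,
               threshold: float | None = None,
               mask: np.ndarray | None = None) -> list[DetectedPeak]:
    """Detect Bragg peaks in a photon-count image.

    Parameters mirror :class:`PeakFindParams`; ``threshold`` overrides
    the configured photon-count threshold.  ``mask`` marks bad/gap
    pixels (True = masked); peaks whose region touches a masked pixel
    or the panel border are dropped.  Returns peaks sorted by
    decreasing integrated intensity; empty list for blank frames.
    """
    params = params or PeakFindParams()
    thr = params.threshold if threshold is None else float(threshold)
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0:
        raise ValueError("image must be non-negative")
    n_slow, n_fast = img.shape
    bg_global = float(np.median(img))
    cand = np.argwhere(img >= bg_global + thr)
    if len(cand) == 0:
        return []

    # gradient ascent to local maxima, dedupe by maximum pixel
    maxima: dict[tuple[int, int], None] = {}
    for slow, fast in cand:
        maxima[_ascend(img, int(slow), int(fast))] = None

    w = params.window_radius
    rr = params.region_radius
    dy_ann, dx_ann = _annulus_offsets(rr + 1, w)
    peaks: list[DetectedPeak] = []
    for (ms, mf) in maxima:
        if not (params.border <= ms < n_slow - params.border
                and params.border <= mf < n_fast - params.border):
            continue
        ys, xs = ms + dy_ann, mf + dx_ann
        ok = (ys >= 0) & (ys < n_slow) & (xs >= 0) & (xs < n_fast)
        ys, xs = ys[ok], xs[ok]
        if mask is not None:
            good = ~mask[ys, xs]
            ys, xs = ys[good], xs[good]
        ann = img[ys, xs]
        if len(ann) < 8:
            continue
        local_bg = float(np.median(ann))
        mad = float(np.median(np.abs(ann - local_bg)))
        sigma_bg = max(1.4826 * mad, np.sqrt(max(local_bg, 0.25)))
        height = img[ms, mf] - local_bg
        if height < thr:
            continue
        # grow the connected region above the noise floor inside a disc
        s0, s1 = ms - rr, ms + rr + 1
        f0, f1 = mf - rr, mf + rr + 1
        if s0 < 0 or f0 < 0 or s1 > n_slow or f1 > n_fast:
            continue
        window = img[s0:s1, f0:f1]
        if mask is not None and mask[s0:s1, f0:f1].any():
            continue
        above = window > local_bg + params.k_sigma * sigma_bg
        labels, _ = ndimage.label(above)
        region = labels == labels[rr, rr]
        weights = np.where(region, window - local_bg, 0.0)
        weights = np.clip(weights, 0.0, None)
        total = float(weights.sum())
        if total <= 0:
            continue
        ys_g, xs_g = np.mgrid[s0:s1, f0:f1]
        centroid_slow = float((weights * ys_g).sum() / total)
        centroid_fast = float((weights * xs_g).sum() / total)
        peaks.append(DetectedPeak(fast=centroid_fast, slow=centroid_slow,
                                  intensity=total, max_count=float(height)))
    peaks.sort(key=lambda p: -p.intensity)
    return peaks


@lru_cache(maxsize=8)
def _annulus_offsets(r_in: int, r_out: int) -> tuple[np.ndarray, np.ndarray]:
    r = np.arange(-r_out, r_out + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    d2 = dy * dy + dx * dx
    keep = (d2 > r_in * r_in) & (d2 <= r_out * r_out)
    return dy[keep], dx[keep]


def classify_frame(peaks, min_peaks: int = 15, max_peaks: int = 200) -> FrameClassification:
    """Blank/weak if n ≤ ``min_peaks``; hit if strictly between the
    bounds; multi-crystal if n ≥ ``max_peaks`` (strict inequalities on
    both sides, matching "more than 15" / "less than 200")."""
    n = len(peaks) if not isinstance(peaks, int) else peaks
    if n <= min_peaks:
        label = "blank"
    elif n < max_peaks:
        label = "hit"
    else:
        label = "multi"
    return FrameClassification(n_peaks=n, label=label)
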