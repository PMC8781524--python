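"""Surface segmentation and flattening of PS-OCT B-scans.

The extraction procedure starts by locating the sample in the intensity
image: a 3x3 median filter suppresses speckle, the image is rescaled to
256 bins, and Otsu's threshold separates sample from background.  Per
column, the top surface is the first run of suprathreshold pixels, the
bottom the last; when the signal never falls back below threshold before
the bottom of the frame, the bottom surface is "not visible" and a
maximum detection depth is recorded instead.  Flattening then shifts
each column so the detected surface sits at row 0, making the sample
horizontal for lateral averaging.  Pixel counts convert to physical
thickness by assuming a refractive index of 1.4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImagingConfig
from .simulate import BScanPair

__all__ = [
    "SurfaceSegmentation",
    "FlattenedBScan",
    "otsu_threshold",
    "image_histogram",
    "detect_surfaces",
    "flatten",
    "unflatten",
    "pixels_to_physical_thickness",
]


@dataclass
class SurfaceSegmentation:
    """Per-column surface rows of a B-scan.

    ``top_index``: row of the first sample pixel; ``bottom_index``: row
    of the last sample pixel, or -1 when the bottom surface is not
    visible; ``max_detection_depth``: deepest suprathreshold row (always
    set for valid columns, and the usable depth bound whether or not the
    bottom was seen); ``valid``: False for columns with no detectable
    sample.  Invalid columns carry -1 indices.
    """

    top_index: np.ndarray
    bottom_index: np.ndarray
    max_detection_depth: np.ndarray
    valid: np.ndarray
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        v = self.valid
        last = np.where(self.bottom_index >= 0, self.bottom_index, self.max_detection_depth)
        if np.any(self.top_index[v] >= last[v]):
            raise ValueError("top_index must lie above bottom/max-detection for valid columns")

    def depth_extent(self) -> np.ndarray:
        """Per-column usable pixel depth below the surface (-1 if invalid)."""
        last = np.where(self.bottom_index >= 0, self.bottom_index, self.max_detection_depth)
        return np.where(self.valid, last - self.top_index, -1)


@dataclass
class FlattenedBScan:
    """B-scan pair with the detected surface shifted to row 0.

    Out-of-support pixels (above the surface, or shifted past the bottom
    of the frame) are NaN and excluded from every downstream average.
    ``shifts`` records the per-column upward shift for inversion.
    """

    retardation: np.ndarray
    intensity: np.ndarray
    shifts: np.ndarray
    valid: np.ndarray
    config: ImagingConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.retardation.shape


def image_histogram(image: np.ndarray, nbins: int = 256) -> tuple[np.ndarray, float, float]:
    """Counts over ``nbins`` equal-width bins after linear rescale to [min, max]."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("single-valued image: no separable classes")
    idx = np.floor((img - lo) / (hi - lo) * nbins).astype(int)
    np.clip(idx, 0, nbins - 1, out=idx)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    return counts, lo, hi


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a histogram of bin counts.

    Returns the bin index t maximizing the between-class variance of the
    split {bins < t} vs {bins >= t}; ties are broken by the smallest
    qualifying index.  Exhaustively equivalent to brute-force search
    over every candidate split.
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("histogram must be 1-D with >= 2 bins")
    if np.any(h < 0):
        raise ValueError("histogram counts must be >= 0")
    if np.count_nonzero(h) < 2:
        raise ValueError("histogram needs mass in >= 2 distinct bins (no separable classes)")

    bins = np.arange(h.size)
    total = h.sum()
    w0 = np.cumsum(h)  # mass of bins <= k
    m0 = np.cumsum(h * bins)  # first moment of bins <= k
    mu_total = m0[-1] / total

    # candidate thresholds t = 1..nbins-1 split at k = t-1
    w0c = w0[:-1] / total
    w1c = 1.0 - w0c
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0[:-1] > 0, m0[:-1] / w0[:-1], 0.0)
        mu1 = np.where(
            w0[:-1] < total, (m0[-1] - m0[:-1]) / (total - w0[:-1]), 0.0
        )
    between = w0c * w1c * (mu0 - mu1) ** 2
    between[(w0c == 0) | (w1c == 0)] = -np.inf
    return int(np.argmax(between)) + 1

def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """[start, end] (inclusive) of True runs of length >= min_run."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return [(s, e) for s, e in zip(starts, ends) if e - s + 1 >= min_run]


def detect_surfaces(
    pair: BScanPair,
    smoothing_halfwidth: int = 1,
    min_run: int = 3,
    nbins: int = 256,
    log_scale: bool = True,
) -> SurfaceSegmentation:
    """Segment top/bottom surfaces of every A-scan by Otsu thresholding.

    The intensity image is median-filtered (kernel 2*halfwidth+1 square),
    log-scaled (dB, the usual OCT display scale — exponential depth decay
    would otherwise push all but the shallowest sample pixels into the
    lowest histogram bins), rescaled to ``nbins`` bins, and thresholded
    with Otsu's method.  Per column, runs of at least ``min_run``
    consecutive suprathreshold pixels define the sample: the top surface
    is the first pixel of the first run and the deepest run pixel bounds
    the detectable depth.  If that bound touches the last row the bottom
    surface is not visible (bottom_index = -1, only a maximum detection
    depth); columns with no qualifying run are flagged invalid.
    """
    if smoothing_halfwidth < 0 or min_run < 1:
        raise ValueError("smoothing_halfwidth must be >= 0 and min_run >= 1")
    img = pair.intensity
    if smoothing_halfwidth > 0:
        size = 2 * smoothing_halfwidth + 1
        img = ndimage.median_filter(img, size=size, mode="nearest")
    if log_scale:
        floor = float(img.max()) * 1e-8
        if floor <= 0:
            raise ValueError("all-zero intensity image: no detectable sample")
        img = 10.0 * np.log10(np.maximum(img, floor))

    counts, lo, hi = image_histogram(img, nbins)
    t = otsu_threshold(counts)
    idx = np.floor((img - lo) / (hi - lo) * nbins).astype(int)
    np.clip(idx, 0, nbins - 1, out=idx)
    mask = idx >= t
    threshold_value = lo + t * (hi - lo) / nbins

    depth, lateral = mask.shape
    top = np.full(lateral, -1, dtype=int)
    bottom = np.full(lateral, -1, dtype=int)
    max_depth = np.full(lateral, -1, dtype=int)
    valid = np.zeros(lateral, dtype=bool)

    for c in range(lateral):
        runs = _runs(mask[:, c], min_run)
        if not runs:
            continue
        valid[c] = True
        top[c] = runs[0][0]
        deepest = runs[-1][1]
        max_depth[c] = deepest
        if deepest < depth - 1:
            bottom[c] = deepest

    return SurfaceSegmentation(top, bottom, max_depth, valid, threshold_value)


def flatten(pair: BScanPair, seg: SurfaceSegmentation) -> FlattenedBScan:
    """Shift each valid column up by its top index so the surface is row 0.

    Pixels shifted in from below the frame, and all pixels of invalid
    columns, become NaN; the recorded shifts allow :func:`unflatten` to
    restore the original sample region exactly.
    """
    depth, lateral = pair.shape
    if seg.top_index.size != lateral:
        raise ValueError("segmentation does not match B-scan width")

    ret = np.full(pair.shape, np.nan)
    inten = np.full(pair.shape, np.nan)
    shifts = np.where(seg.valid, seg.top_index, 0).astype(int)
    for c in range(lateral):
        if not seg.valid[c]:
            continue
        s = shifts[c]
        ret[: depth - s, c] = pair.retardation[s:, c]
        inten[: depth - s, c] = pair.intensity[s:, c]
    return FlattenedBScan(ret, inten, shifts, seg.valid.copy(), pair.config)


def unflatten(flat: FlattenedBScan) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`flatten`; returns (intensity, retardation).

    Sample-region pixels are restored exactly; above-surface pixels
    (discarded by flattening) come back as NaN.
    """
    depth, lateral = flat.shape
    ret = np.full(flat.shape, np.nan)
    inten = np.full(flat.shape, np.nan)
    for c in range(lateral):
        s = int(flat.shifts[c])
        if not flat.valid[c]:
            continue
        ret[s:, c] = flat.retardation[: depth - s, c]
        inten[s:, c] = flat.intensity[: depth - s, c]
    return inten, ret


def pixels_to_physical_thickness(
    pixel_count: float, config: ImagingConfig, refractive_index: float = 1.4
) -> float:
    """Convert an axial pixel count to physical thickness in μm.

    Pixels measure optical path in air; dividing by the refractive index
    (1.4 for PDMS/tissue by convention) gives physical thickness.
    """
    if pixel_count < 0:
        raise ValueError("pixel_count must be >= 0")
    if refractive_index < 1:
        raise ValueError("refractive_index must be >= 1")
    return pixel_count * config.axial_pixel_spacing_air_um / refractive_index
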