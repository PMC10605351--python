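"""Bimodal-threshold granule detection and granularity summaries.

The detection procedure assumes the within-nucleus intensity histogram
of a label channel is a two-mode mixture: a diffuse (non-granular)
component and a brighter granular component. The histogram is smoothed
by an iterated 3-bin moving average until exactly two local maxima j
and k survive; the granule cutoff is their midpoint t = 0.5(j + k),
computed per nucleus per channel so slide-to-slide staining differences
do not bias detection. Pixels strictly above t are granule candidates;
a mask-aware median filter suppresses isolated noise pixels; connected
components of at least 5 pixels (the diffraction-limited minimum) are
the granules.

Granularity of a nucleus is the triple (number of granules, mean
granule area in pixels, mean intensity). The intensity convention is
pixel-weighted: the mean over all granule pixels pooled, so a pixel in
a large granule counts the same as a pixel in a small one. The
granule-weighted alternative (mean of per-granule means) is emitted as
a secondary value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .image_io import ChannelRole

DEFAULT_N_BINS = 256
DEFAULT_INTENSITY_MAX = 4095
DEFAULT_MIN_SIZE_PX = 5
DEFAULT_MEDIAN_WINDOW = 3
DEFAULT_MAX_PASSES = 1000
DEFAULT_CONNECTIVITY = 8


@dataclass
class BimodalThreshold:
    """Provenance of one per-nucleus granule threshold.

    ``mode_lo`` (j) and ``mode_hi`` (k) are the bin-center intensities
    of the two local maxima of the smoothed histogram; the threshold is
    t = 0.5(j + k). ``bimodal`` is False when smoothing never reached
    exactly two maxima within the pass limit.
    """

    histogram: np.ndarray
    bin_centers: np.ndarray
    smoothed: np.ndarray
    smoothing_passes: int
    bimodal: bool
    mode_lo: float | None = None
    mode_hi: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.bimodal:
            if self.mode_lo is None or self.mode_hi is None:
                raise ValueError("bimodal result requires both modes")
            if not self.mode_lo < self.mode_hi:
                raise ValueError("mode_lo must be below mode_hi")
            expected = 0.5 * (self.mode_lo + self.mode_hi)
            if self.threshold is None:
                self.threshold = expected


@dataclass(frozen=True)
class Granule:
    granule_id: int
    pixel_count: int
    mean_intensity: float
    centroid: tuple[float, float]


@dataclass
class GranuleSet:
    """Granules of one nucleus in one channel, with threshold provenance."""

    nucleus_label: int
    channel_role: ChannelRole | None
    granules: list[Granule]
    threshold_used: BimodalThreshold | None
    min_size_px: int = DEFAULT_MIN_SIZE_PX


@dataclass(frozen=True)
class GranularitySummary:
    """Per-nucleus granularity triple.

    Means are None (absent), not 0, when the nucleus has no granules.
    ``pixelwise_mean_intensity`` pools all granule pixels with equal
    weight; ``granulewise_mean_intensity`` averages per-granule means.
    """

    nucleus_label: int
    n_granules: int
    mean_area_px: float | None
    pixelwise_mean_intensity: float | None
    granulewise_mean_intensity: float | None


def build_histogram(
    channel: np.ndarray,
    mask: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    intensity_max: int = DEFAULT_INTENSITY_MAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of within-mask intensities over uniform bins covering
    [0, intensity_max]. Returns (counts, bin_centers).

    Bin edges are placed on integer multiples of
    ``(intensity_max + 1) / n_bins`` so every bin holds the same number
    of integer intensity levels (16 for the 12-bit default with 256
    bins); unequal bins would imprint a sawtooth on the histogram of
    integer data and fabricate spurious local maxima.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("nucleus mask is empty")
    if n_bins < 1:
        raise ValueError("n_bins must be positive")
    values = np.asarray(channel)[mask]
    edges = np.linspace(0.0, float(intensity_max) + 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:]) - 0.5
    return counts.astype(np.int64), centers


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima; a plateau (run of equal values)
    higher than both sides counts once, at its midpoint bin. Boundary
    runs count when higher than their single inner neighbor."""
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok and v[i] > 0:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def _smooth_once(counts: np.ndarray) -> np.ndarray:
    # 3-bin moving average; edge bins average their available neighbors
    kernel = np.ones(3)
    num = np.convolve(counts, kernel, mode="same")
    den = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return num / den


def smooth_to_bimodal(
    histogram: np.ndarray,
    bin_centers: np.ndarray | None = None,
    max_passes: int = DEFAULT_MAX_PASSES,
    min_mode_fraction: float = 0.002,
) -> BimodalThreshold:
    """Iterate 3-bin moving-average smoothing until exactly two local
    maxima remain, then set j, k to their bin-center intensities and
    t = 0.5(j + k).

    A local maximum only counts as a mode when its smoothed height is
    at least ``min_mode_fraction`` of the tallest peak: a handful of
    extreme-value pixels in an otherwise unimodal histogram form an
    isolated tail bin that is formally a maximum but is not granulation.

    Smoothing only ever removes modes, so iteration stops early once
    fewer than two maxima remain (failure) or exactly two (success); a
    degenerate single-bin histogram is a non-bimodal result, not an
    error.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 3:
        raise ValueError("histogram must be a vector of at least 3 bins")
    if counts.sum() <= 0:
        raise ValueError("histogram has no counts")
    if bin_centers is None:
        centers = np.arange(counts.size, dtype=np.float64)
    else:
        centers = np.asarray(bin_centers, dtype=np.float64)

    smoothed = counts
    passes = 0
    while True:
        raw_maxima = _local_maxima(smoothed)
        floor = min_mode_fraction * smoothed.max()
        maxima = [i for i in raw_maxima if smoothed[i] >= floor]
        if len(maxima) == 2:
            j = float(centers[maxima[0]])
            k = float(centers[maxima[1]])
            return BimodalThreshold(
                histogram=np.asarray(histogram),
                bin_centers=centers,
                smoothed=smoothed,
                smoothing_passes=passes,
                bimodal=True,
                mode_lo=j,
                mode_hi=k,
                threshold=compute_threshold(j, k),
            )
        if len(raw_maxima) < 2 or passes >= max_passes:
            return BimodalThreshold(
                histogram=np.asarray(histogram),
                bin_centers=centers,
                smoothed=smoothed,
                smoothing_passes=passes,
                bimodal=False,
            )
        smoothed = _smooth_once(smoothed)
        passes += 1


def compute_threshold(j: float, k: float) -> float:
    """Granule cutoff t = 0.5 (j + k), the midpoint of the two modes."""
    if not j < k:
        raise ValueError("require j < k")
    return 0.5 * (float(j) + float(k))


def select_granule_pixels(channel: np.ndarray, mask: np.ndarray, t: float) -> np.ndarray:
    """Binary grid of within-mask pixels with intensity strictly above t."""
    mask = np.asarray(mask, dtype=bool)
    return (np.asarray(channel) > t) & mask


def _masked_median_filter(channel: np.ndarray, mask: np.ndarray, window: int) -> np.ndarray:
    """Median over each window restricted to within-mask pixels.

    Pixels outside the mask never enter a neighborhood's median, so
    granules at the nucleus boundary are not diluted by zeroed
    background. Output is defined (and used) only inside the mask.
    """
    half = window // 2
    img = np.asarray(channel, dtype=np.float64)
    # interior pixels have a window fully inside the mask: plain median there
    interior = ndimage.binary_erosion(mask, structure=np.ones((window, window)))
    out = np.where(interior, ndimage.median_filter(img, size=window), 0.0)
    boundary = mask & ~interior
    if boundary.any():
        padded = np.pad(
            np.where(mask, img, np.nan), half, mode="constant", constant_values=np.nan
        )
        windows = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
        rows, cols = np.nonzero(boundary)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[rows, cols] = np.nanmedian(
                windows[rows, cols].reshape(rows.size, -1), axis=1
            )
    return out


def median_refine(
    channel: np.ndarray,
    mask: np.ndarray,
    t: float,
    window: int = DEFAULT_MEDIAN_WINDOW,
) -> np.ndarray:
    """Granule selection after median substitution.

    Each within-mask pixel's intensity is replaced by the median of its
    ``window`` x ``window`` neighborhood (mask-aware), and the selection
    is re-derived by the same strict cutoff ``> t`` on the filtered
    image. Isolated bright noise pixels vanish; solid granules keep
    their interiors.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    mask = np.asarray(mask, dtype=bool)
    filtered = _masked_median_filter(channel, mask, window)
    return (filtered > t) & mask


def label_granules(
    selection: np.ndarray,
    channel: np.ndarray,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_size_px: int = DEFAULT_MIN_SIZE_PX,
    nucleus_label: int = 0,
    channel_role: ChannelRole | None = None,
    threshold_used: BimodalThreshold | None = None,
) -> GranuleSet:
    """Connected components of the selection as granules.

    Components smaller than ``min_size_px`` pixels (default 5,
    inclusive: pixel_count >= 5 is kept) are discarded as below the
    optical resolution limit. Per-granule mean intensity is computed
    from the original, unfiltered channel intensities.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if min_size_px < 1:
        raise ValueError("min_size_px must be positive")
    selection = np.asarray(selection, dtype=bool)
    labeled = cc_label(selection, connectivity=1 if connectivity == 4 else 2)
    granules: list[Granule] = []
    gid = 0
    for prop in regionprops(labeled, intensity_image=np.asarray(channel, dtype=np.float64)):
        if prop.area < min_size_px:
            continue
        gid += 1
        granules.append(
            Granule(
                granule_id=gid,
                pixel_count=int(prop.area),
                mean_intensity=float(prop.intensity_mean),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            )
        )
    return GranuleSet(
        nucleus_label=nucleus_label,
        channel_role=channel_role,
        granules=granules,
        threshold_used=threshold_used,
        min_size_px=min_size_px,
    )


def summarize_granularity(granule_set: GranuleSet) -> GranularitySummary:
    """Number, mean area and mean intensity of a nucleus's granules.

    The pooled pixelwise mean weights every granule pixel equally:
    sum over granules of (area x per-granule mean) / total granule
    pixels. With no granules the means are absent, not zero.
    """
    gs = granule_set.granules
    if not gs:
        return GranularitySummary(
            nucleus_label=granule_set.nucleus_label,
            n_granules=0,
            mean_area_px=None,
            pixelwise_mean_intensity=None,
            granulewise_mean_intensity=None,
        )
    areas = np.array([g.pixel_count for g in gs], dtype=np.float64)
    means = np.array([g.mean_intensity for g in gs], dtype=np.float64)
    return GranularitySummary(
        nucleus_label=granule_set.nucleus_label,
        n_granules=len(gs),
        mean_area_px=float(areas.mean()),
        pixelwise_mean_intensity=float((areas * means).sum() / areas.sum()),
        granulewise_mean_intensity=float(means.mean()),
    )


def analyze_granularity(
    channel: np.ndarray,
    mask: np.ndarray,
    nucleus_label: int = 0,
    channel_role: ChannelRole | None = None,
    n_bins: int = DEFAULT_N_BINS,
    intensity_max: int = DEFAULT_INTENSITY_MAX,
    max_passes: int = DEFAULT_MAX_PASSES,
    median_window: int = DEFAULT_MEDIAN_WINDOW,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_size_px: int = DEFAULT_MIN_SIZE_PX,
) -> tuple[GranuleSet, GranularitySummary | None]:
    """Full per-nucleus granule analysis for one channel.

    Returns the granule set (empty, with ``threshold_used.bimodal``
    False, when the histogram never becomes bimodal — such nuclei show
    no granulation and are excluded downstream) and the granularity
    summary (None when not bimodal).
    """
    counts, centers = build_histogram(channel, mask, n_bins, intensity_max)
    bt = smooth_to_bimodal(counts, centers, max_passes)
    if not bt.bimodal:
        empty = GranuleSet(
            nucleus_label=nucleus_label,
            channel_role=channel_role,
            granules=[],
            threshold_used=bt,
            min_size_px=min_size_px,
        )
        return empty, None
    refined = median_refine(channel, mask, bt.threshold, median_window)
    gset = label_granules(
        refined,
        channel,
        connectivity=connectivity,
        min_size_px=min_size_px,
        nucleus_label=nucleus_label,
        channel_role=channel_role,
        threshold_used=bt,
    )
    return gset, summarize_granularity(gset)
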