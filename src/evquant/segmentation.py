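"""Spot segmentation in the total-stain channel.

Pipeline: 256-bin histogram over the image's own intensity range -> global
triangle threshold -> binary mask (strict ``>``) -> morphological opening
with a disk + hole filling -> connected-component labeling -> area gating.
The resulting label map is the single mask reused by every marker channel,
so per-vesicle measurements share an identical pixel set across channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

logger = logging.getLogger(__name__)


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram: ``counts[i]`` covers ``[bin_edges[i], bin_edges[i+1])``."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the detection stage.

    The area gate defaults to [2, 100] px²: at the default PSF (sigma
    1.3 px, truncated at 4 sigma) a single spot's full footprint is ~85 px,
    so the upper bound admits one whole spot while rejecting merged
    doublets and large debris; the lower bound drops single-pixel specks.
    """

    n_bins: int = 256
    open_radius: int = 1
    min_area: int = 2
    max_area: int = 100
    connectivity: int = 8  # 4 or 8

    def __post_init__(self) -> None:
        if not 0 < self.min_area <= self.max_area:
            raise ValueError("need 0 < min_area <= max_area")
        if self.open_radius < 0:
            raise ValueError("open_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class LabelMap:
    """Connected components surviving the gate; labels are 1..K contiguous."""

    labels: np.ndarray  # 2-D int array, 0 = background
    n_components: int
    areas: np.ndarray  # (K,) pixel counts, index = label - 1
    centroids: np.ndarray  # (K, 2) (row, col) intensity-free centroids

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMap":
        labels = np.asarray(labels)
        k = int(labels.max())
        if k:
            areas = np.bincount(labels.ravel(), minlength=k + 1)[1:]
            centroids = np.array(ndimage.center_of_mass(labels > 0, labels, np.arange(1, k + 1)))
        else:
            areas = np.zeros(0, dtype=int)
            centroids = np.zeros((0, 2))
        return cls(labels=labels, n_components=k, areas=areas, centroids=centroids)


def intensity_histogram(image: np.ndarray, n_bins: int = 256) -> Histogram:
    """Histogram over [min, max] of the image itself (not the dtype range),
    which keeps the triangle geometry meaningful on low-contrast fields.

    For integer images the bin count is clamped so bins are at least one
    intensity level wide: sub-unit bins on quantized data produce an empty
    "comb" between occupied bins, and those empty bins next to the peak
    would dominate the triangle's point-to-chord distances.
    """
    image = np.asarray(image)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        # a single occupied bin; triangle_threshold will refuse it
        hi = lo + 1.0
    if np.issubdtype(image.dtype, np.integer):
        n_bins = min(n_bins, max(2, int(hi - lo)))
    counts, edges = np.histogram(image, bins=n_bins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts)


def triangle_threshold(hist: Histogram) -> float:
    """Global triangle threshold.

    Draw the chord from the histogram peak ``(b_p, h_p)`` to the farthest
    occupied bin on the peak's longer-tail side ``(b_e, h_e)``; the
    threshold bin maximizes the perpendicular distance from ``(b, h_b)``
    to that chord over bins strictly between the two. Returns the upper
    edge of the winning bin; pixels are foreground iff strictly above it.

    Ties in tail length go to the higher-intensity side; ties in distance
    go to the bin nearest the peak (then to the lower bin index).
    """
    counts = np.asarray(hist.counts, dtype=float)
    nz = np.flatnonzero(counts)
    if len(nz) < 2:
        raise DegenerateHistogramError(
            "triangle threshold needs at least two occupied histogram bins"
        )
    b_p = int(np.argmax(counts))
    left, right = int(nz[0]), int(nz[-1])
    # longer tail side; tie -> higher-intensity side
    b_e = right if (right - b_p) >= (b_p - left) else left

    lo, hi = (b_p, b_e) if b_p < b_e else (b_e, b_p)
    cand = np.arange(lo + 1, hi)
    if len(cand) == 0:
        # peak and tail end are adjacent: no interior bin, threshold at peak
        return float(hist.bin_edges[b_p + 1])

    # |cross product| formulation of point-to-line distance (common scale)
    dx, dy = float(b_e - b_p), counts[b_e] - counts[b_p]
    norm = np.hypot(dx, dy)
    dist = np.abs(dx * (counts[cand] - counts[b_p]) - dy * (cand - b_p)) / norm

    best = np.max(dist)
    ties = cand[dist == best]
    b_t = int(ties[np.lexsort((ties, np.abs(ties - b_p)))[0]])
    return float(hist.bin_edges[b_t + 1])


def morphological_clean(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Binary opening with a disk of ``open_radius`` followed by hole filling."""
    mask = np.asarray(mask, dtype=bool)
    if params.open_radius > 0:
        mask = morphology.opening(mask, morphology.disk(params.open_radius))
    return ndimage.binary_fill_holes(mask)


def area_gate(labelmap: LabelMap, min_area: int, max_area: int) -> LabelMap:
    """Drop components with area outside [min_area, max_area]; relabel 1..K."""
    keep = (labelmap.areas >= min_area) & (labelmap.areas <= max_area)
    removed = int(labelmap.n_components - keep.sum())
    if removed:
        logger.info("area gate removed %d of %d components", removed, labelmap.n_components)
    lut = np.zeros(labelmap.n_components + 1, dtype=labelmap.labels.dtype)
    lut[1:][keep] = np.arange(1, int(keep.sum()) + 1)
    return LabelMap.from_labels(lut[labelmap.labels])


def segment_field(
    total_stain_channel: np.ndarray, params: SegmentationParams | None = None
) -> LabelMap:
    """Detect vesicle spots in the total-stain channel (see module docstring)."""
    params = params or SegmentationParams()
    image = np.asarray(total_stain_channel)
    if image.ndim != 2:
        raise ValueError("expected a single 2-D channel")
    thr = triangle_threshold(intensity_histogram(image, params.n_bins))
    mask = image > thr
    mask = morphological_clean(mask, params)
    labels = measure.label(mask, connectivity=1 if params.connectivity == 4 else 2)
    return area_gate(LabelMap.from_labels(labels), params.min_area, params.max_area)


def labelmap_to_frame(labelmap: LabelMap):
    """Per-component table (label, area, centroid_x, centroid_y)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "label": np.arange(1, labelmap.n_components + 1),
            "area": labelmap.areas,
            "centroid_x": labelmap.centroids[:, 1] if labelmap.n_components else [],
            "centroid_y": labelmap.centroids[:, 0] if labelmap.n_components else [],
        }
    )
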