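"""Mask transfer, local background subtraction, positivity calls and
co-expression tabulation.

The detection mask comes from the total-stain channel only; the identical
pixel set is then measured in every channel. For each vesicle the local
background is the median over an annulus around its component (other
vesicles' pixels excluded), and a marker is called positive when the
background-corrected mean exceeds ``k_sigma`` robust standard deviations of
the channel's background noise. Fractions are always reported relative to
the total number of detected (total-stain-positive) vesicles, so the
triple-negative class is a first-class category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import LabelMap
from .synthetic_imaging import (
    ALL_COMBINATIONS,
    CHANNELS,
    MARKERS,
    MarkerCombination,
    SyntheticField,
)

logger = logging.getLogger(__name__)

_MAD_SCALE = 1.4826  # MAD -> sd for a normal distribution


@dataclass(frozen=True)
class PositivityParams:
    """Background annulus geometry and the positivity decision rule."""

    r_in: int = 2
    r_out: int = 5
    k_sigma: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.r_in < self.r_out:
            raise ValueError("need r_out > r_in >= 0")
        if self.k_sigma < 0:
            raise ValueError("k_sigma must be >= 0")


@dataclass
class EVMeasurement:
    """Per-vesicle geometry, per-channel intensities and marker calls."""

    ev_id: int
    centroid: tuple[float, float]  # (row, col)
    area: int
    raw_mean: dict[str, float]
    background: dict[str, float]
    corrected_mean: dict[str, float]  # raw - background, floored at 0
    positive: dict[str, bool]

    @property
    def combination(self) -> MarkerCombination:
        return MarkerCombination(*(self.positive[m] for m in MARKERS))


@dataclass
class CoexpressionTable:
    """Counts/fractions of the 8 marker combinations over detected vesicles."""

    n_total: int
    counts: dict[MarkerCombination, int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("combination counts must sum to n_total")

    def fraction(self, combo: MarkerCombination) -> float:
        return self.counts[combo] / self.n_total

    def marginal(self, marker: str) -> float:
        """Fraction of detected vesicles positive for ``marker`` (any combination)."""
        return (
            sum(c for combo, c in self.counts.items() if combo.has(marker))
            / self.n_total
        )

    @property
    def marginals(self) -> dict[str, float]:
        return {m: self.marginal(m) for m in MARKERS}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cd63": int(combo.cd63),
                "cd9": int(combo.cd9),
                "cd98": int(combo.cd98),
                "count": self.counts[combo],
                "fraction": self.fraction(combo),
            }
            for combo in ALL_COMBINATIONS
        ]
        return pd.DataFrame(rows)

    @staticmethod
    def pooled(tables: list["CoexpressionTable"]) -> "CoexpressionTable":
        """Pool by summing counts across fields (not by averaging fractions)."""
        counts = {c: 0 for c in ALL_COMBINATIONS}
        for t in tables:
            for combo, n in t.counts.items():
                counts[combo] += n
        return CoexpressionTable(n_total=sum(counts.values()), counts=counts)


@dataclass
class LineScanProfile:
    """Intensity profile along a segment, one trace per channel."""

    p0: tuple[float, float]  # (row, col)
    p1: tuple[float, float]
    width: int
    positions: np.ndarray  # distance along the segment, px
    profiles: dict[str, np.ndarray]


def _component_crop(labels: np.ndarray, ev_id: int, pad: int):
    rows, cols = np.nonzero(labels == ev_id)
    if len(rows) == 0:
        raise ValueError(f"component {ev_id} not present in label map")
    r0, r1 = max(rows.min() - pad, 0), min(rows.max() + pad + 1, labels.shape[0])
    c0, c1 = max(cols.min() - pad, 0), min(cols.max() + pad + 1, labels.shape[1])
    return slice(r0, r1), slice(c0, c1)


def local_background(
    channel: np.ndarray,
    labelmap: LabelMap,
    ev_id: int,
    r_in: int = 2,
    r_out: int = 5,
) -> float:
    """Median intensity over an annulus around component ``ev_id``.

    The annulus is the difference between dilations of the component by
    ``r_out`` and ``r_in``; pixels of *any* foreground component are
    excluded so a close neighbor never contaminates the estimate. If no
    pixel survives, fall back to the global image median (logged).
    """
    if not 0 <= r_in < r_out:
        raise ValueError("need r_out > r_in >= 0")
    sl = _component_crop(labelmap.labels, ev_id, pad=r_out + 1)
    lab = labelmap.labels[sl]
    comp = lab == ev_id
    inner = ndimage.binary_dilation(comp, _disk(r_in)) if r_in > 0 else comp
    outer = ndimage.binary_dilation(comp, _disk(r_out))
    annulus = outer & ~inner & (lab == 0)
    if not annulus.any():
        logger.warning("empty background annulus for EV %d; using global median", ev_id)
        return float(np.median(channel))
    return float(np.median(np.asarray(channel, dtype=float)[sl][annulus]))


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def background_sigma(channel: np.ndarray, labelmap: LabelMap, r_exclude: int = 5) -> float:
    """Robust background noise (scaled MAD) over pixels away from any vesicle."""
    fg = labelmap.labels > 0
    if fg.any():
        fg = ndimage.binary_dilation(fg, _disk(r_exclude))
    bg = np.asarray(channel, dtype=float)[~fg]
    if bg.size == 0:
        return 0.0
    return float(_MAD_SCALE * np.median(np.abs(bg - np.median(bg))))


def call_positive(corrected_mean: float, k_sigma: float, sigma_bg: float) -> bool:
    """Marker call: corrected mean above ``k_sigma`` background noise units.

    With noise disabled ``sigma_bg`` is 0 and the rule degenerates to
    "any signal at all" (corrected mean > 0).
    """
    return corrected_mean > k_sigma * sigma_bg


def measure_evs(
    field: SyntheticField | np.ndarray,
    labelmap: LabelMap,
    params: PositivityParams | None = None,
) -> list[EVMeasurement]:
    """Measure every detected component in all four channels.

    ``field`` may be a :class:`SyntheticField` or a raw (4, H, W) array in
    the fixed channel order. The same pixel set (the total-stain component)
    is used in every channel.
    """
    params = params or PositivityParams()
    channels = field.channels if isinstance(field, SyntheticField) else np.asarray(field)
    if channels.shape[0] != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} channels, got {channels.shape[0]}")
    if channels.shape[1:] != labelmap.labels.shape:
        raise ValueError("label map shape does not match the field")

    sigma_bg = {
        name: background_sigma(channels[i], labelmap, r_exclude=params.r_out)
        for i, name in enumerate(CHANNELS)
    }

    out: list[EVMeasurement] = []
    for ev_id in range(1, labelmap.n_components + 1):
        comp = labelmap.labels == ev_id
        raw, bg, corr, pos = {}, {}, {}, {}
        for i, name in enumerate(CHANNELS):
            ch = np.asarray(channels[i], dtype=float)
            raw[name] = float(ch[comp].mean())
            bg[name] = local_background(ch, labelmap, ev_id, params.r_in, params.r_out)
            corr[name] = max(0.0, raw[name] - bg[name])
            pos[name] = call_positive(corr[name], params.k_sigma, sigma_bg[name])
        out.append(
            EVMeasurement(
                ev_id=ev_id,
                centroid=tuple(labelmap.centroids[ev_id - 1]),
                area=int(labelmap.areas[ev_id - 1]),
                raw_mean=raw,
                background=bg,
                corrected_mean=corr,
                positive=pos,
            )
        )
    return out


def coexpression_table(measurements: list[EVMeasurement]) -> CoexpressionTable:
    """Tabulate the 8 marker combinations over all detected vesicles."""
    if not measurements:
        raise ValueError("cannot tabulate co-expression of an empty measurement list")
    counts = {c: 0 for c in ALL_COMBINATIONS}
    for m in measurements:
        counts[m.combination] += 1
    return CoexpressionTable(n_total=len(measurements), counts=counts)


def line_scan(
    field: SyntheticField | np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    width: int = 1,
) -> LineScanProfile:
    """Bilinear line profile from ``p0`` to ``p1`` (row, col coordinates).

    Samples at unit spacing along the segment, averaged across ``width``
    unit-spaced offsets perpendicular to it (centered on the segment).
    """
    channels = field.channels if isinstance(field, SyntheticField) else np.asarray(field)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("line scan endpoints coincide")
    h, w = channels.shape[1:]
    for p in (p0, p1):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError("line scan endpoints must lie inside the image")
    n = int(np.floor(length)) + 1
    t = np.linspace(0.0, length, n)
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = (np.arange(width) - (width - 1) / 2.0)[:, None, None]
    pts = p0[None, None, :] + t[None, :, None] * direction + offsets * normal
    coords = np.moveaxis(pts, -1, 0)  # (2, width, n)

    profiles = {}
    for i, name in enumerate(CHANNELS):
        samples = ndimage.map_coordinates(
            np.asarray(channels[i], dtype=float), coords, order=1, mode="nearest"
        )
        profiles[name] = samples.mean(axis=0)
    return LineScanProfile(
        p0=tuple(p0), p1=tuple(p1), width=width, positions=t, profiles=profiles
    )


def line_scan_frame(profile: LineScanProfile) -> pd.DataFrame:
    return pd.DataFrame({"position": profile.positions, **profile.profiles})
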