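"""Wall-layer segmentation and per-layer enrichment / correlation analysis.

The ICL-POZ-OCL-GC sequence is recovered from a Ca profile alone:

* the POZ is the contiguous Ca-poor region around the global minimum,
  delimited on each side by the midpoint between the POZ minimum and
  that side's flanking median (a half-height rule, robust to PSF blur);
* the OCL/GC boundary exploits the homogeneity of the crust: moving in
  from the outer surface, the boundary is where the rolling standard
  deviation of the Ca profile last rises above a threshold (half the
  ICL rolling-SD median -- the ICL is the banded region already known
  once the POZ is found). The reported position is corrected by half
  the rolling window so it lands at the outermost banded feature.

Orientation (inner surface first) must be declared by the caller;
auto-detection is refused so a flipped profile cannot be segmented
silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import Profile, RatioProfile
from .wall_model import LAYER_ORDER


class SegmentationError(ValueError):
    """Profile cannot be segmented into wall layers."""


@dataclass(frozen=True)
class WallSegmentation:
    """Three layer boundaries (nm) and per-position layer labels."""

    boundaries: tuple[float, float, float]   # ICL/POZ, POZ/OCL, OCL/GC
    position: np.ndarray
    labels: np.ndarray                       # layer name per position

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (b[0] < b[1] < b[2]):
            raise SegmentationError("boundaries must be strictly increasing")
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels))

    def mask(self, layer: str) -> np.ndarray:
        return self.labels == layer

    @property
    def poz_width(self) -> float:
        return self.boundaries[1] - self.boundaries[0]


@dataclass(frozen=True)
class CorrelationResult:
    """OLS fit of y on x with Pearson correlation."""

    slope: float
    intercept: float
    pearson_rho: float
    n: int
    slope_stderr: float

    @property
    def slope_ci95(self) -> tuple[float, float]:
        half = stats.t.ppf(0.975, self.n - 2) * self.slope_stderr
        return (self.slope - half, self.slope + half)


@dataclass(frozen=True)
class LayerStats:
    """Per-layer means, SDs and POZ-relative enrichments."""

    table: pd.DataFrame     # index: layer, columns: <name>_{mean,sd,enrichment}

    def mean(self, name: str, layer: str) -> float:
        return float(self.table.loc[layer, f"{name}_mean"])

    def enrichment(self, name: str, layer: str) -> float:
        return float(self.table.loc[layer, f"{name}_enrichment"])

    def to_dict(self) -> dict:
        return {layer: {c: (None if pd.isna(v) else float(v))
                        for c, v in row.items()}
                for layer, row in self.table.iterrows()}


def _labels_from_boundaries(position: np.ndarray,
                            boundaries: Sequence[float]) -> np.ndarray:
    edges = [-np.inf, *boundaries, np.inf]
    labels = np.empty(position.shape, dtype=object)
    for i, name in enumerate(LAYER_ORDER):
        labels[(position >= edges[i]) & (position < edges[i + 1])] = name
    return labels.astype(str)


def _half_height_edge(position, counts, i_min, midpoint, direction):
    """Walk from the minimum until counts cross the midpoint; interpolate."""
    i = i_min
    n = counts.size
    while 0 <= i + direction < n and counts[i + direction] < midpoint:
        i += direction
    j = i + direction
    if j < 0 or j >= n:
        raise SegmentationError("Ca minimum region reaches the profile edge")
    c0, c1 = counts[i], counts[j]
    frac = 0.0 if c1 == c0 else (midpoint - c0) / (c1 - c0)
    return float(position[i] + frac * (position[j] - position[i]))


def segment_wall(ca: Profile, inner_first: bool = True,
                 sd_window: int = 10,
                 homogeneity_factor: float = 0.5) -> WallSegmentation:
    """Segment the four wall layers from a Ca profile spanning the wall.

    ``inner_first`` declares the orientation (inner surface at the first
    sample); pass False for an outer-first profile, whose boundaries are
    computed on the reversed trace and mapped back.
    """
    if not inner_first:
        flipped = Profile(line=ca.line,
                          position=ca.position,
                          counts=ca.counts[::-1].copy(),
                          sigma=ca.sigma[::-1].copy(),
                          averaging_width=ca.averaging_width)
        seg = segment_wall(flipped, inner_first=True, sd_window=sd_window,
                           homogeneity_factor=homogeneity_factor)
        span = ca.position[0] + ca.position[-1]
        b = tuple(sorted(span - np.asarray(seg.boundaries)))
        # mirrored grid: the layer at position p is the inner-first layer
        # at span - p, so GC sits at the start of an outer-first profile
        return WallSegmentation(boundaries=b, position=ca.position,
                                labels=seg.labels[::-1].copy())
    position, counts = ca.position, ca.counts
    if counts.size < 3 * max(sd_window, 3):
        raise SegmentationError("profile too short to segment")
    if np.ptp(counts) == 0:
        raise SegmentationError("flat profile has no interior Ca minimum")
    i_min = int(np.argmin(counts))
    if i_min in (0, counts.size - 1):
        raise SegmentationError("no interior Ca minimum (monotone profile?)")
    c_min = counts[i_min]
    med_left = float(np.median(counts[:i_min]))
    med_right = float(np.median(counts[i_min + 1:]))
    if not (med_left > c_min and med_right > c_min):
        raise SegmentationError("Ca minimum is not below flanking medians")
    b_icl_poz = _half_height_edge(position, counts, i_min,
                                  0.5 * (c_min + med_left), -1)
    b_poz_ocl = _half_height_edge(position, counts, i_min,
                                  0.5 * (c_min + med_right), +1)
    # OCL/GC split: crust homogeneity of the rolling SD
    rolling = pd.Series(counts).rolling(sd_window, center=True,
                                        min_periods=2).std().to_numpy()
    icl_sel = position < b_icl_poz
    if not np.any(icl_sel):
        raise SegmentationError("empty ICL region")
    threshold = homogeneity_factor * float(np.nanmedian(rolling[icl_sel]))
    outer = position > b_poz_ocl
    idx_outer = np.nonzero(outer)[0]
    noisy = rolling[idx_outer] >= threshold
    if not noisy.any():
        raise SegmentationError("no banded OCL region found beyond the POZ")
    last_noisy = idx_outer[np.nonzero(noisy)[0][-1]]
    if last_noisy + 1 >= counts.size:
        raise SegmentationError("no homogeneous crust at the outer edge")
    # the last noisy window centre sits ~half a window beyond the
    # outermost banded feature; undo that offset
    dx = ca.spacing
    b_ocl_gc = float(position[last_noisy]) - (sd_window / 2.0) * dx
    b_ocl_gc = min(max(b_ocl_gc, b_poz_ocl + dx), float(position[-1]) - dx)
    if not (b_icl_poz < b_poz_ocl < b_ocl_gc):
        raise SegmentationError("degenerate boundary ordering")
    boundaries = (b_icl_poz, b_poz_ocl, b_ocl_gc)
    return WallSegmentation(boundaries=boundaries, position=position,
                            labels=_labels_from_boundaries(position,
                                                           boundaries))


def layer_statistics(profiles: Sequence[Profile],
                     ratio_profiles: Sequence[RatioProfile],
                     seg: WallSegmentation) -> LayerStats:
    """Per-layer mean/SD of counts and ratios plus POZ-relative enrichment."""
    traces: list[tuple[str, np.ndarray, np.ndarray]] = []
    for prof in profiles:
        traces.append((prof.line, prof.position, prof.counts))
    for rp in ratio_profiles:
        traces.append((rp.label, rp.position, rp.ratio))
    rows = {layer: {} for layer in LAYER_ORDER}
    for name, pos, values in traces:
        if pos.shape != seg.position.shape \
                or not np.allclose(pos, seg.position):
            raise SegmentationError(
                f"{name}: profile grid does not match segmentation")
        poz_vals = values[seg.mask("POZ")]
        poz_mean = float(np.nanmean(poz_vals)) if poz_vals.size else np.nan
        for layer in LAYER_ORDER:
            vals = values[seg.mask(layer)]
            if vals.size == 0:
                mean = sd = enr = np.nan   # empty layer: undefined stats
            else:
                mean = float(np.nanmean(vals))
                sd = float(np.nanstd(vals, ddof=1)) if vals.size > 1 \
                    else np.nan
                enr = mean / poz_mean if poz_mean and poz_mean > 0 else np.nan
            rows[layer][f"{name}_mean"] = mean
            rows[layer][f"{name}_sd"] = sd
            rows[layer][f"{name}_enrichment"] = enr
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(LAYER_ORDER)]
    return LayerStats(table=table)


def correlate_ratios(x: RatioProfile, y: RatioProfile,
                     seg: WallSegmentation | None = None,
                     layer: str | None = None) -> CorrelationResult:
    """OLS fit (free intercept) of y on x and their Pearson correlation.

    Uses all shared positions, optionally restricted to one layer of a
    segmentation. NaN (masked) positions are dropped.
    """
    if not np.array_equal(x.position, y.position):
        raise SegmentationError("ratio profiles do not share positions")
    sel = np.isfinite(x.ratio) & np.isfinite(y.ratio)
    if layer is not None:
        if seg is None:
            raise SegmentationError("layer restriction needs a segmentation")
        sel &= seg.mask(layer)
    xv, yv = x.ratio[sel], y.ratio[sel]
    if xv.size < 3:
        raise SegmentationError("need at least 3 points to correlate")
    if np.ptp(xv) == 0:
        raise SegmentationError("zero variance in x: slope undefined")
    fit = stats.linregress(xv, yv)
    return CorrelationResult(slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             pearson_rho=float(fit.rvalue), n=int(xv.size),
                             slope_stderr=float(fit.stderr))


def trajectory(x: Profile, y: Profile,
               seg: WallSegmentation) -> Mapping[str, np.ndarray]:
    """Per-layer ordered (x, y) point pairs for growth-trajectory scatter."""
    if not np.array_equal(x.position, y.position):
        raise SegmentationError("profiles do not share positions")
    out = {}
    for layer in LAYER_ORDER:
        m = seg.mask(layer)
        pairs = np.column_stack([x.counts[m], y.counts[m]])
        out[layer] = pairs
    return out
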