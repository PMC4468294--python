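"""Baseline estimation, pit segmentation, dent counting and pit metrics.

The analysis of one trace proceeds in four stages:

1. :func:`estimate_baseline` — a robust iterative median/MAD fit of the
   unresorbed-surface level (constant, or linear when the trend is
   significant), yielding the reference from which all depths are measured.
2. :func:`segment_pits` — sub-surface excursions of the smoothed trace deeper
   than a depth gate are grown outward to the baseline crossing; excursions
   separated by a full return to the near-baseline band for at least
   ``min_width`` are distinct pits, shorter returns leave them joined.
3. :func:`count_dents` — internal ridges of a pit that rise back to within a
   tolerance of the baseline split it into dents; one dent is *unidented*,
   two *bidented*, three or more *multidented*.
4. :func:`measure_pit` — width at the surface, maximum depth, full width at
   half maximum (FWHM, width at half of the maximum depth) and sub-surface
   cross-sectional area (trapezoidal integral of the depth deficit, μm²),
   all computed on the unsmoothed trace.

Topology decisions (segmentation seeds, ridges) use a moving-average smoothed
profile; geometry (depth, area, FWHM) is measured on the raw trace so that
smoothing does not bias the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .trace_io import RunConfig, Trace, ValidationError

__all__ = [
    "Baseline",
    "BaselineError",
    "PitExtent",
    "Pit",
    "PlanarMask",
    "SHAPE_CLASSES",
    "shape_class_from_dents",
    "estimate_baseline",
    "segment_pits",
    "count_dents",
    "measure_pit",
    "analyze_trace",
    "resorbed_area_percent",
]

SHAPE_CLASSES = ("unidented", "bidented", "multidented")

MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian noise


class BaselineError(RuntimeError):
    """The unresorbed-surface level could not be estimated reliably."""


@dataclass
class Baseline:
    """Estimated unresorbed-surface level of one trace.

    ``level`` is the baseline height at every sample position (constant or
    linear trend); ``noise_sigma`` is the robust roughness estimate of the
    unresorbed surface (1.4826·MAD of unresorbed residuals, μm).
    """

    level: np.ndarray
    noise_sigma: float
    trend: str = "constant"
    intercept: float = 0.0
    slope: float = 0.0

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=float)
        if not np.all(np.isfinite(self.level)):
            raise ValidationError("baseline level not finite everywhere")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass
class PitExtent:
    """One segmented sub-surface interval of a trace.

    ``i0``/``i1`` are the inclusive sample indices inside the interval;
    ``start_pos``/``end_pos`` the interpolated boundary positions where the
    deficit crosses the noise gate; ``boundary_deficit`` the deficit value at
    those boundaries (the noise gate used during segmentation).
    """

    i0: int
    i1: int
    start_pos: float
    end_pos: float
    boundary_deficit: float = 0.0


@dataclass
class Pit:
    """One resorption pit with its morphology metrics (all lengths μm)."""

    start_pos: float
    end_pos: float
    width: float
    depth: float
    fwhm: float
    area: float
    dent_count: int
    shape_class: str

    def __post_init__(self) -> None:
        if not self.end_pos > self.start_pos:
            raise ValidationError("pit end_pos must exceed start_pos")
        if abs(self.width - (self.end_pos - self.start_pos)) > 1e-9:
            raise ValidationError("pit width must equal end_pos - start_pos")
        if not 0 < self.fwhm <= self.width + 1e-9:
            raise ValidationError("pit fwhm must satisfy 0 < fwhm <= width")
        if not self.depth > 0:
            raise ValidationError("pit depth must be > 0")
        if not self.area > 0:
            raise ValidationError("pit area must be > 0")
        if self.dent_count < 1:
            raise ValidationError("dent_count must be >= 1")
        if self.shape_class != shape_class_from_dents(self.dent_count):
            raise ValidationError("shape_class inconsistent with dent_count")


@dataclass
class PlanarMask:
    """Binary resorption mask of a disc surface (True = resorbed)."""

    grid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValidationError("mask grid must be 2-D")
        if not self.pixel_size > 0:
            raise ValidationError("pixel_size must be > 0")
        if self.grid.all():
            raise ValidationError("mask has no unresorbed pixels")


def shape_class_from_dents(dent_count: int) -> str:
    if dent_count == 1:
        return "unidented"
    if dent_count == 2:
        return "bidented"
    return "multidented"


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------


def _robust_sigma(residuals: np.ndarray) -> float:
    """Robust noise scale from the *upper* half of the residuals.

    Erosion contaminates the height distribution only from below, so the
    median of the non-negative centred residuals (scaled by 1.4826, the
    half-Gaussian MAD constant) estimates the unresorbed-surface roughness
    without being inflated by pit flanks inside the classification band.
    """
    med = np.median(residuals)
    upper = residuals[residuals >= med] - med
    if upper.size == 0:
        return 0.0
    return MAD_SCALE * float(np.median(upper))


# half-normal quantiles: for |Z| with Z ~ N(0, 1), Q(p) = Phi^-1((1 + p) / 2)
_HN_Q25 = 0.3186394
_HN_Q75 = 1.1503494


def _upper_mass_fit(resid: np.ndarray) -> tuple[float, float]:
    """(level offset, sigma) from the upper half-sample of residuals.

    Unresorbed samples scatter symmetrically about the surface while erosion
    contaminates only from below, so the samples at or above the current
    level are (to noise crossings) a pure half-normal sample. Its 25th and
    75th percentiles identify both the level correction and the noise scale;
    iterating the threshold converges on the true surface regardless of how
    much of the scan is eroded below it.
    """
    upper = resid[resid >= 0]
    if upper.size == 0:
        return 0.0, 0.0
    q25, q75 = np.percentile(upper, [25, 75])
    sigma = float(q75 - q25) / (_HN_Q75 - _HN_Q25)
    offset = float(q25) - _HN_Q25 * sigma
    return offset, max(sigma, 0.0)


def estimate_baseline(trace: Trace, config: RunConfig | None = None) -> Baseline:
    """Robustly estimate the unresorbed-surface level of a trace.

    Starting from the height median, the level and roughness are refined by
    an upper-mass fit (see :func:`_upper_mass_fit`); a linear trend replaces
    the constant level when its slope is overwhelmingly significant (always,
    with ``baseline_trend='linear'``; never with ``'constant'``). Samples
    within ±3·noise_sigma of the final level count as unresorbed; a fraction
    below ``min_unresorbed_fraction`` raises :class:`BaselineError` — the
    signature of a fully eroded scan.
    """
    config = config or RunConfig()
    x = trace.positions
    h = trace.heights
    n = h.size

    level = np.full(n, np.median(h))
    sigma = _robust_sigma(h)
    trend = "constant"
    intercept, slope = float(level[0]), 0.0

    for iteration in range(3):
        resid = h - level
        mask = np.abs(resid) <= 3 * sigma
        # the trend is only fit once the mask has contracted to the surface
        # band; on the first pass the band can still span eroded terraces,
        # where a tilted line would be spuriously "significant"
        if (iteration > 0 and config.baseline_trend in ("linear", "auto")
                and mask.sum() >= 2):
            # OLS slope on the unresorbed band; adopt in auto mode only when
            # the slope t-statistic is overwhelming (|t| > 4)
            xm, hm = x[mask], h[mask]
            xc = xm - xm.mean()
            sxx = float(np.dot(xc, xc))
            if sxx > 0:
                b = float(np.dot(xc, hm) / sxx)
                a = float(hm.mean() - b * xm.mean())
                s = _robust_sigma(hm - (a + b * xm))
                se = (s / np.sqrt(sxx)) if s > 0 else 0.0
                if config.baseline_trend == "linear" or (se > 0 and abs(b) / se > 4):
                    trend = "linear"
                    intercept, slope = a, b
                    level = intercept + slope * x
                    resid = h - level
        offset, sigma_new = _upper_mass_fit(resid)
        intercept += offset
        level = level + offset
        sigma = sigma_new

    # sub-nanometre floor so a noiseless surface still classifies as such
    fraction = float(np.mean(np.abs(h - level) <= max(3 * sigma, 1e-9)))
    if fraction < config.min_unresorbed_fraction:
        raise BaselineError(
            f"no reliable baseline: only {100 * fraction:.1f}% of samples classified "
            "as unresorbed (fully eroded scan?)"
        )
    return Baseline(level=level, noise_sigma=sigma, trend=trend,
                    intercept=intercept, slope=slope)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _smooth_heights(heights: np.ndarray, window_um: float, dx: float) -> np.ndarray:
    size = int(round(window_um / dx)) if dx > 0 else 1
    if size <= 1:
        return heights
    if size % 2 == 0:
        size += 1
    return uniform_filter1d(heights, size=size, mode="nearest")


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), stops.tolist()))


def segment_pits(trace: Trace, baseline: Baseline, config: RunConfig | None = None
                 ) -> list[PitExtent]:
    """Segment sub-surface excursions into disjoint pit extents.

    Seeds are runs where the smoothed deficit exceeds
    ``depth_gate = max(3·noise_sigma, min_depth/2)``. Each seed grows outward
    to the nearest *separator*: a contiguous return of the raw deficit to
    within the noise gate (``2·noise_sigma``) lasting at least ``min_width``.
    Boundary positions are linearly interpolated at the noise-gate crossing.
    Extents with maximum raw drop below ``min_depth`` or width below
    ``min_width`` are discarded. Returns extents in position order.
    """
    config = config or RunConfig()
    dx = trace.median_interval
    if config.min_width < 2 * dx:
        raise ValidationError(
            f"min_width {config.min_width} μm below twice the sample interval {dx} μm"
        )
    deficit_raw = baseline.level - trace.heights
    smoothed = _smooth_heights(trace.heights, config.smoothing_window, dx)
    deficit_s = baseline.level - smoothed

    depth_gate = max(3 * baseline.noise_sigma, config.min_depth / 2)
    noise_gate = 2 * baseline.noise_sigma

    below = deficit_raw <= noise_gate
    min_sep_samples = max(2, int(np.ceil(config.min_width / dx)))
    separator = np.zeros(below.size, dtype=bool)
    for a, b in _bool_runs(below):
        if b - a + 1 >= min_sep_samples:
            separator[a : b + 1] = True

    x = trace.positions
    extents: list[PitExtent] = []
    for a, b in _bool_runs(~separator):
        if not np.any(deficit_s[a : b + 1] >= depth_gate):
            continue
        if a == 0:
            start_pos = float(x[0])
        else:
            start_pos = _interp_crossing(x[a - 1], x[a], deficit_raw[a - 1],
                                         deficit_raw[a], noise_gate)
        if b == below.size - 1:
            end_pos = float(x[-1])
        else:
            end_pos = _interp_crossing(x[b + 1], x[b], deficit_raw[b + 1],
                                       deficit_raw[b], noise_gate)
        width = end_pos - start_pos
        if width < config.min_width:
            continue
        if np.max(deficit_raw[a : b + 1]) < config.min_depth:
            continue
        extents.append(PitExtent(i0=int(a), i1=int(b), start_pos=start_pos,
                                 end_pos=end_pos, boundary_deficit=noise_gate))
    return extents


def _interp_crossing(x_out: float, x_in: float, d_out: float, d_in: float,
                     gate: float) -> float:
    """Position where the deficit crosses ``gate`` between an outside sample
    (deficit <= gate) and an inside sample (deficit > gate)."""
    if d_in == d_out:
        return float(x_out)
    frac = (gate - d_out) / (d_in - d_out)
    frac = min(max(frac, 0.0), 1.0)
    return float(x_out + frac * (x_in - x_out))


# ---------------------------------------------------------------------------
# Dent counting and metrics
# ---------------------------------------------------------------------------


def count_dents(extent: PitExtent, trace: Trace, baseline: Baseline,
                config: RunConfig | None = None) -> tuple[int, str]:
    """Count dents in a pit extent and assign its shape class.

    A separating ridge is a local maximum of the smoothed profile strictly
    inside the extent that (a) rises to within
    ``ridge_tolerance = max(2·noise_sigma, ridge_fraction·depth)`` of the
    baseline and (b) has topographic prominence of at least the depth gate,
    so that stylus noise cannot masquerade as a ridge. ``dent_count`` is one
    plus the number of such ridges.
    """
    config = config or RunConfig()
    i0, i1 = extent.i0, extent.i1
    if i1 - i0 + 1 < 4:
        raise ValidationError(f"degenerate pit extent with {i1 - i0 + 1} samples")
    dx = trace.median_interval
    deficit_raw = baseline.level[i0 : i1 + 1] - trace.heights[i0 : i1 + 1]
    depth = float(np.max(deficit_raw))
    ridge_tolerance = max(2 * baseline.noise_sigma, config.ridge_fraction * depth)
    depth_gate = max(3 * baseline.noise_sigma, config.min_depth / 2)

    smoothed = _smooth_heights(trace.heights, config.smoothing_window, dx)
    seg = smoothed[i0 : i1 + 1]
    level = baseline.level[i0 : i1 + 1]
    heights = trace.heights[i0 : i1 + 1]
    peaks, _ = find_peaks(seg, prominence=depth_gate)
    # locate ridges on the smoothed profile, but measure the apex height on
    # the raw trace (local median) — the moving average flattens a sharp
    # ridge cusp downward, which would reject genuine near-surface ridges
    n_ridges = 0
    for p in peaks:
        lo, hi = max(0, p - 2), min(heights.size, p + 3)
        apex = float(np.median(heights[lo:hi]))
        if level[p] - apex <= ridge_tolerance:
            n_ridges += 1
    dent_count = 1 + n_ridges
    return dent_count, shape_class_from_dents(dent_count)


def measure_pit(extent: PitExtent, trace: Trace, baseline: Baseline,
                dent_count: int = 1) -> Pit:
    """Compute width, maximum depth, FWHM and sub-surface area of one pit.

    All geometry is measured on the unsmoothed trace: depth is the maximum
    baseline-to-surface drop (leftmost position on ties), FWHM the distance
    between the outermost interpolated crossings of the half-depth contour,
    and area the trapezoidal integral of the deficit over the extent
    (boundary samples at the interpolated crossings).
    """
    i0, i1 = extent.i0, extent.i1
    x = trace.positions[i0 : i1 + 1]
    d = baseline.level[i0 : i1 + 1] - trace.heights[i0 : i1 + 1]
    bd = max(extent.boundary_deficit, 0.0)
    xs = np.concatenate([[extent.start_pos], x, [extent.end_pos]])
    ds = np.concatenate([[bd], d, [bd]])

    k = int(np.argmax(ds))  # leftmost maximum by argmax convention
    depth = float(ds[k])
    if depth <= 0:
        raise ValidationError("segmentation contract violated: non-positive depth")
    half = depth / 2

    above = ds >= half
    first = int(np.argmax(above))
    last = len(ds) - 1 - int(np.argmax(above[::-1]))
    if first == 0:
        x_left = float(xs[0])
    else:
        x_left = _interp_crossing(xs[first - 1], xs[first], ds[first - 1], ds[first], half)
    if last == len(ds) - 1:
        x_right = float(xs[-1])
    else:
        x_right = _interp_crossing(xs[last + 1], xs[last], ds[last + 1], ds[last], half)
    fwhm = x_right - x_left

    area = float(np.trapezoid(ds, xs))
    width = float(extent.end_pos - extent.start_pos)
    return Pit(
        start_pos=float(extent.start_pos),
        end_pos=float(extent.end_pos),
        width=width,
        depth=depth,
        fwhm=float(fwhm),
        area=area,
        dent_count=int(dent_count),
        shape_class=shape_class_from_dents(int(dent_count)),
    )


def analyze_trace(trace: Trace, config: RunConfig | None = None) -> list[Pit]:
    """Full per-trace analysis: baseline → segmentation → dents → metrics.

    Returns pits in position order; propagates :class:`BaselineError` for
    traces with no reliable unresorbed surface.
    """
    config = config or RunConfig()
    baseline = estimate_baseline(trace, config)
    pits = []
    for extent in segment_pits(trace, baseline, config):
        dents, _ = count_dents(extent, trace, baseline, config)
        pits.append(measure_pit(extent, trace, baseline, dent_count=dents))
    return pits


# ---------------------------------------------------------------------------
# Planar resorption
# ---------------------------------------------------------------------------


def resorbed_area_percent(mask: PlanarMask) -> float:
    """Percentage of the disc surface resorbed: 100 × resorbed / total pixels."""
    return 100.0 * float(mask.grid.mean())
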