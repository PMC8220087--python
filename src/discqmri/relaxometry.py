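"""Pixel-wise T1 and T2 map fitting from IR and multi-echo series.

Each pixel's time course is normalized by its maximum absolute intensity
and fitted by nonlinear least squares to one of the mono-exponential
models

    T1 (inversion recovery):   S(t) = a * (1 - 2 * exp(-t / T1))
    T2 (multi-echo decay):     S(t) = b * exp(-t / T2)

with ``a``/``b`` close to one after normalization.  For magnitude IR data
the sign of the early time points is lost; polarity restoration tests the
plausible sign patterns around the signal null and keeps the fit with the
lowest residual.  Pixels that fail to converge or carry no signal are
flagged in the validity mask rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .phantom import ImageSeries

__all__ = [
    "FitOptions",
    "RelaxationMap",
    "normalize_series",
    "fit_t1_map",
    "fit_t2_map",
    "quality_mask",
]


@dataclass(frozen=True)
class FitOptions:
    """Bounds, convergence and masking controls for the pixel-wise fits."""

    t1_bounds: tuple[float, float] = (1.0, 5000.0)
    t2_bounds: tuple[float, float] = (1.0, 1000.0)
    amplitude_bounds: tuple[float, float] = (1e-3, 10.0)
    max_iterations: int = 200
    convergence_tolerance: float = 1e-10
    #: pixels whose raw peak intensity is below this fraction of the image
    #: maximum are not fitted (background / air).
    min_signal_fraction: float = 0.15
    polarity_restoration: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.t1_bounds, self.t2_bounds, self.amplitude_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive and ordered")


@dataclass
class RelaxationMap:
    """Per-pixel relaxation time map with fit diagnostics.

    ``values`` are ms; ``amplitude`` is the fitted model amplitude on the
    normalized scale; ``rss`` the residual sum of squares of the fit;
    ``valid_mask`` marks pixels with signal that converged inside bounds.
    Invalid pixels hold NaN values, never a silent zero.
    """

    values: np.ndarray
    amplitude: np.ndarray
    rss: np.ndarray
    valid_mask: np.ndarray
    kind: str  # "T1" or "T2"
    pixel_spacing: float
    bounds: tuple[float, float] = (1.0, 5000.0)


def normalize_series(series: ImageSeries) -> ImageSeries:
    """Divide each pixel's time course by its maximum absolute intensity.

    All-zero pixels are left at zero and flagged invalid.  The per-pixel
    norms are stored on the returned series so fitting can mask background
    by raw signal level; fitted relaxation times are invariant to any
    global intensity scale.
    """
    if series.frames.shape[0] == 0:
        raise ValueError("series is empty")
    norms = np.max(np.abs(series.frames), axis=0)
    valid = norms > 0
    frames = np.where(valid[None], series.frames / np.where(valid, norms, 1.0)[None], 0.0)
    return ImageSeries(frames=frames, timing=series.timing, modality=series.modality,
                       pixel_spacing=series.pixel_spacing, signed=series.signed,
                       norms=norms, valid=valid)


def _prepare(series: ImageSeries, opts: FitOptions):
    if series.norms is None:
        series = normalize_series(series)
    fit_mask = series.valid & (series.norms >= opts.min_signal_fraction * series.norms.max())
    return series, fit_mask


def _ir_model(t, a, t1):
    return a * (1.0 - 2.0 * np.exp(-t / t1))


def _me_model(t, b, t2):
    return b * np.exp(-t / t2)


def fit_t2_map(series: ImageSeries, opts: FitOptions = FitOptions()) -> RelaxationMap:
    """Fit b*exp(-t/T2) per pixel of a multi-echo series.

    Initialization comes from a log-linear regression of the early echoes;
    bounded Levenberg-type least squares refines it.  Non-convergent
    pixels are flagged invalid in the mask.
    """
    if series.modality != "ME":
        raise ValueError("fit_t2_map requires a multi-echo (ME) series")
    if series.frames.shape[0] < 3:
        raise ValueError("T2 fitting needs at least 3 echoes")
    series, fit_mask = _prepare(series, opts)
    t = series.timing
    shape = series.frames.shape[1:]
    values = np.full(shape, np.nan)
    amplitude = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    lo = (opts.amplitude_bounds[0], opts.t2_bounds[0])
    hi = (opts.amplitude_bounds[1], opts.t2_bounds[1])
    n_init = min(8, len(t))
    for i, j in np.argwhere(fit_mask):
        y = series.frames[:, i, j]
        t2_0 = _loglin_t2(t[:n_init], y[:n_init], opts.t2_bounds)
        p0 = (max(min(y.max(), hi[0]), lo[0] * 2), t2_0)
        try:
            popt, _ = curve_fit(_me_model, t, y, p0=p0, bounds=(lo, hi),
                                maxfev=opts.max_iterations * 4,
                                xtol=opts.convergence_tolerance, ftol=opts.convergence_tolerance)
        except RuntimeError:
            continue
        amplitude[i, j] = popt[0]
        values[i, j] = popt[1]
        rss[i, j] = float(np.sum((_me_model(t, *popt) - y) ** 2))
        valid[i, j] = True
    return RelaxationMap(values=values, amplitude=amplitude, rss=rss, valid_mask=valid,
                         kind="T2", pixel_spacing=series.pixel_spacing, bounds=opts.t2_bounds)


def _loglin_t2(t, y, bounds):
    pos = y > 1e-6
    if pos.sum() < 2:
        return float(np.clip(t[-1] / 2, *bounds))
    slope, _ = np.polyfit(t[pos], np.log(y[pos]), 1)
    t2 = -1.0 / slope if slope < 0 else bounds[1] / 2
    return float(np.clip(t2, *bounds))


def fit_t1_map(series: ImageSeries, opts: FitOptions = FitOptions()) -> RelaxationMap:
    """Fit a*(1 - 2*exp(-t/T1)) per pixel of an inversion-recovery series.

    For magnitude data with ``polarity_restoration`` the early points are
    negated up to each candidate null index (the magnitude minimum and its
    neighbour) and the lowest-residual signed fit wins, recovering the
    polarity lost by the magnitude operation.
    """
    if series.modality != "IR":
        raise ValueError("fit_t1_map requires an inversion-recovery (IR) series")
    if series.frames.shape[0] < 4:
        raise ValueError("T1 fitting needs at least 4 inversion times")
    series, fit_mask = _prepare(series, opts)
    t = series.timing
    shape = series.frames.shape[1:]
    values = np.full(shape, np.nan)
    amplitude = np.full(shape, np.nan)
    rss = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    lo = (opts.amplitude_bounds[0], opts.t1_bounds[0])
    hi = (opts.amplitude_bounds[1], opts.t1_bounds[1])
    restore = (not series.signed) and opts.polarity_restoration
    for i, j in np.argwhere(fit_mask):
        y = series.frames[:, i, j]
        if restore:
            imin = int(np.argmin(np.abs(y)))
            candidates = sorted({imin, min(imin + 1, len(y))})
        else:
            candidates = [0]  # signed data: no sign flips
        best = None
        for k in candidates:
            ys = y.copy()
            if k > 0:
                ys[:k] = -np.abs(ys[:k])
            t1_0 = float(np.clip(t[int(np.argmin(np.abs(ys)))] / np.log(2.0), *opts.t1_bounds))
            p0 = (1.0, t1_0)
            try:
                popt, _ = curve_fit(_ir_model, t, ys, p0=p0, bounds=(lo, hi),
                                    maxfev=opts.max_iterations * 4,
                                    xtol=opts.convergence_tolerance,
                                    ftol=opts.convergence_tolerance)
            except RuntimeError:
                continue
            r = float(np.sum((_ir_model(t, *popt) - ys) ** 2))
            if best is None or r < best[0]:
                best = (r, popt)
        if best is None:
            continue
        r, popt = best
        amplitude[i, j] = popt[0]
        values[i, j] = popt[1]
        rss[i, j] = r
        valid[i, j] = True
    return RelaxationMap(values=values, amplitude=amplitude, rss=rss, valid_mask=valid,
                         kind="T1", pixel_spacing=series.pixel_spacing, bounds=opts.t1_bounds)


def quality_mask(rmap: RelaxationMap, rss_threshold: float = 0.05,
                 bounds_margin: float = 1.0) -> np.ndarray:
    """Exclude poorly fitted pixels and pixels pinned at a fit bound.

    A pixel passes when it is valid, its residual sum of squares is below
    ``rss_threshold`` (on the normalized intensity scale) and its value
    lies more than ``bounds_margin`` ms inside the fit bounds.
    """
    lo, hi = rmap.bounds
    with np.errstate(invalid="ignore"):
        ok = (rmap.valid_mask
              & (rmap.rss <= rss_threshold)
              & (rmap.values > lo + bounds_margin)
              & (rmap.values < hi - bounds_margin))
    return ok
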