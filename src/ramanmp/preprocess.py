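"""Averaging, smoothing and baseline correction of measurement spectra.

The processing chain for one point measurement is:

1. pointwise arithmetic mean of the single spectra;
2. boxcar smoothing (default 11 points, shrinking symmetric window at the
   spectrum ends so no data are fabricated);
3. baseline estimation by a moving-window scheme — a rolling-minimum envelope
   of configurable width (default 150 cm^-1), restored by a rolling maximum
   of the same width (a morphological opening) and smoothed by a centered
   moving average of that width — and subtraction.

The corrected spectrum plus its baseline reconstructs the input exactly by
construction. Alternative baseline estimators can be registered in
:data:`BASELINE_METHODS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .spectra_io import MeasurementSet, Spectrum

__all__ = [
    "AverageSpectrum",
    "BaselineCorrectedSpectrum",
    "BASELINE_METHODS",
    "average_measurement",
    "moving_average",
    "estimate_baseline",
    "baseline_correct",
    "preprocess_measurement",
]

DEFAULT_SMOOTH_WINDOW = 11      # points
DEFAULT_BASELINE_WINDOW = 150.0  # cm^-1


@dataclass
class AverageSpectrum(Spectrum):
    """Pointwise mean of a measurement's single spectra (optionally smoothed)."""

    n_averaged: int = 1
    smoothed: bool = False
    smoothing_window: int | None = None


@dataclass
class BaselineCorrectedSpectrum:
    """A baseline-corrected average spectrum together with its baseline.

    Invariant: ``corrected + baseline == parent.intensities`` pointwise.
    """

    shifts: np.ndarray
    corrected: np.ndarray
    baseline: np.ndarray
    parent: AverageSpectrum | None = None
    meta: dict = field(default_factory=dict)

    def as_spectrum(self) -> Spectrum:
        return Spectrum(self.shifts, self.corrected, dict(self.meta))


def shrinking_boxcar(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis; near the ends the window
    shrinks symmetrically (width ``2*min(h, i, n-1-i)+1``)."""
    y = np.asarray(y, dtype=float)
    n = y.shape[-1]
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not 1 <= window <= n:
        raise ValueError(f"window {window} outside [1, {n}]")
    if window == 1:
        return y.copy()
    half = window // 2
    cs = np.cumsum(y, axis=-1)
    cs = np.concatenate([np.zeros(y.shape[:-1] + (1,)), cs], axis=-1)
    i = np.arange(n)
    h = np.minimum(half, np.minimum(i, n - 1 - i))
    return (cs[..., i + h + 1] - cs[..., i - h]) / (2 * h + 1)


def average_measurement(ms: MeasurementSet) -> AverageSpectrum:
    """Pointwise arithmetic mean across all single spectra of a measurement."""
    mean = ms.intensities.mean(axis=0)
    return AverageSpectrum(
        ms.shifts.copy(), mean,
        {"point_id": ms.point_id, "repeat": ms.repeat, **ms.meta},
        n_averaged=ms.n_spectra,
    )


def moving_average(sp: Spectrum, window: int = DEFAULT_SMOOTH_WINDOW) -> Spectrum:
    """Boxcar-smooth a spectrum with an odd, centered window."""
    smoothed = shrinking_boxcar(sp.intensities, window)
    if isinstance(sp, AverageSpectrum):
        return AverageSpectrum(sp.shifts.copy(), smoothed, dict(sp.meta),
                               n_averaged=sp.n_averaged, smoothed=True,
                               smoothing_window=window)
    return sp.with_intensities(smoothed)


def _window_points(shifts: np.ndarray, window_cm1: float) -> int:
    """Odd number of grid points spanning ``window_cm1`` on (possibly
    non-uniform) ``shifts``; at least 3."""
    step = float(np.median(np.diff(shifts)))
    pts = int(round(window_cm1 / step))
    if pts < 3:
        raise ValueError(
            f"baseline window {window_cm1} cm^-1 covers fewer than 3 grid points"
        )
    pts = min(pts, len(shifts))
    if pts % 2 == 0:
        pts -= 1
    return max(pts, 3)


def _rolling_min_baseline(shifts, intensities, window_cm1):
    # morphological opening (erosion then dilation, same width) removes peaks
    # narrower than the window without the downward bias a bare rolling
    # minimum leaves on sloped backgrounds; a same-width boxcar smooths the
    # piecewise-flat envelope.
    pts = _window_points(shifts, window_cm1)
    envelope = minimum_filter1d(intensities, size=pts, axis=-1, mode="nearest")
    envelope = maximum_filter1d(envelope, size=pts, axis=-1, mode="nearest")
    return shrinking_boxcar(envelope, pts)


#: Registry of baseline estimators ``f(shifts, intensities, window_cm1)``.
#: ``intensities`` may be 1-D or 2-D (spectra along the first axis).
BASELINE_METHODS: dict[str, Callable] = {"rolling_min": _rolling_min_baseline}


def estimate_baseline(sp: Spectrum, window_cm1: float = DEFAULT_BASELINE_WINDOW,
                      method: str = "rolling_min") -> Spectrum:
    """Estimate the smooth background beneath the narrow Raman peaks.

    The default moving-window scheme is a morphological opening of width
    ``window_cm1`` (rolling minimum followed by rolling maximum) smoothed
    with a boxcar of the same width. The result tracks broad
    fluorescence/water background while cutting under peaks narrower than
    the window; after the final smoothing it is not guaranteed to lie below
    the spectrum everywhere.
    """
    fn = BASELINE_METHODS[method]
    return sp.with_intensities(fn(sp.shifts, sp.intensities, window_cm1))


def baseline_correct(sp: AverageSpectrum,
                     window_cm1: float = DEFAULT_BASELINE_WINDOW,
                     method: str = "rolling_min") -> BaselineCorrectedSpectrum:
    """Subtract the estimated baseline from an average spectrum."""
    baseline = estimate_baseline(sp, window_cm1, method).intensities
    return BaselineCorrectedSpectrum(
        sp.shifts.copy(), sp.intensities - baseline, baseline,
        parent=sp, meta=dict(sp.meta),
    )


def preprocess_measurement(
    ms: MeasurementSet,
    smoothing_window: int = DEFAULT_SMOOTH_WINDOW,
    baseline_window_cm1: float = DEFAULT_BASELINE_WINDOW,
    baseline_method: str = "rolling_min",
) -> BaselineCorrectedSpectrum:
    """Full chain: average, smooth, baseline-correct one measurement."""
    avg = moving_average(average_measurement(ms), smoothing_window)
    return baseline_correct(avg, baseline_window_cm1, baseline_method)
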