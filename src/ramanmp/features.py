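"""Spectrum-derived variables used for concentration estimation.

For each point measurement the pipeline computes:

* ``R``   — Pearson correlation between the (smoothed, uncorrected) average
  spectrum and the standard polymer reference spectrum;
* ``R_b`` — the same correlation after baseline correction of both sides;
  the calibration response variable;
* ``H_b@k`` — baseline-corrected peak height near each characteristic
  polyethylene band k in {1059, 1128, 1239, 1415, 1438, 2844, 2878} cm^-1;
* ``f_b`` — fraction of the single spectra in the measurement whose
  per-spectrum R_b exceeds a detection threshold (default 0.2), i.e. the
  frequency of catching a particle under the laser;
* ``m_b`` — mean per-spectrum R_b among those detections (undefined when
  there are none).

Correlations are computed over the full overlap of the two grids with the
reference linearly interpolated onto the sample grid; no band masking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    DEFAULT_BASELINE_WINDOW,
    DEFAULT_SMOOTH_WINDOW,
    BASELINE_METHODS,
    AverageSpectrum,
    BaselineCorrectedSpectrum,
    baseline_correct,
    moving_average,
    preprocess_measurement,
    shrinking_boxcar,
)
from .spectra_io import MeasurementSet, Spectrum

__all__ = [
    "PE_BANDS",
    "ReferenceSpectrum",
    "FeatureVector",
    "DetectionStats",
    "UndefinedCorrelationError",
    "pearson",
    "compute_R",
    "compute_Rb",
    "peak_height",
    "detection_stats",
    "compute_features",
    "feature_table",
]

#: Characteristic polyethylene Raman bands (cm^-1); the 2844/2878 doublet
#: dominates the C-H stretch region.
PE_BANDS = (1059, 1128, 1239, 1415, 1438, 2844, 2878)

DEFAULT_DETECTION_THRESHOLD = 0.2


class UndefinedCorrelationError(ValueError):
    """Correlation requested on zero-variance or insufficient data."""


@dataclass
class ReferenceSpectrum(Spectrum):
    """Standard polymer spectrum used as the matching target."""

    polymer: str = "PE"


@dataclass
class DetectionStats:
    """Per-spectrum detection summary of one measurement."""

    f_b: float
    m_b: float  # NaN when no spectrum exceeds the threshold
    n_detected: int
    n_spectra: int
    threshold: float

    @property
    def m_b_defined(self) -> bool:
        return self.n_detected > 0


@dataclass
class FeatureVector:
    """All spectrum-derived variables for one measurement."""

    point_id: str
    repeat: int
    R: float
    R_b: float
    H_b: dict[int, float]
    f_b: float
    m_b: float
    meta: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"point_id": self.point_id, "repeat": self.repeat,
               "R": self.R, "R_b": self.R_b}
        row.update({f"Hb_{k}": v for k, v in self.H_b.items()})
        row["f_b"] = self.f_b
        row["m_b"] = self.m_b
        row.update(self.meta)
        return row


def _overlap_pair(a: Spectrum, b: Spectrum):
    """Intensities of ``a`` and of ``b`` interpolated onto ``a``'s grid,
    restricted to the overlapping shift range."""
    lo = max(a.shifts[0], b.shifts[0])
    hi = min(a.shifts[-1], b.shifts[-1])
    mask = (a.shifts >= lo) & (a.shifts <= hi)
    if mask.sum() < 3:
        raise UndefinedCorrelationError(
            "fewer than 3 common grid points after resampling"
        )
    x = a.intensities[mask]
    y = np.interp(a.shifts[mask], b.shifts, b.intensities)
    return x, y


def pearson(a: Spectrum, b: Spectrum) -> float:
    """Pearson correlation of two spectra over their common shift range."""
    x, y = _overlap_pair(a, b)
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero-variance spectrum in correlation")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def compute_R(avg: AverageSpectrum | Spectrum, ref: ReferenceSpectrum) -> float:
    """Correlation of the uncorrected (smoothed) average spectrum with the
    reference."""
    return pearson(avg, ref)


def compute_Rb(
    cor: BaselineCorrectedSpectrum,
    ref: ReferenceSpectrum,
    correct_ref: bool = True,
    baseline_window_cm1: float = DEFAULT_BASELINE_WINDOW,
    baseline_method: str = "rolling_min",
) -> float:
    """Correlation of a baseline-corrected spectrum with the reference.

    By default the reference is baseline-corrected the same way; for a clean
    standard spectrum this has little effect, so ``correct_ref=False`` gives
    nearly identical values.
    """
    sample = cor.as_spectrum()
    if correct_ref:
        ref_avg = AverageSpectrum(ref.shifts, ref.intensities, dict(ref.meta))
        ref_sp = baseline_correct(ref_avg, baseline_window_cm1,
                                  baseline_method).as_spectrum()
    else:
        ref_sp = ref
    return pearson(sample, ref_sp)


def peak_height(cor: BaselineCorrectedSpectrum, k: float,
                tol: float = 5.0) -> float:
    """Maximum corrected intensity within ``k ± tol`` cm^-1."""
    mask = (cor.shifts >= k - tol) & (cor.shifts <= k + tol)
    if not mask.any():
        raise ValueError(f"band window {k}±{tol} cm^-1 outside the grid")
    return float(cor.corrected[mask].max())


def _rowwise_pearson(rows: np.ndarray, target: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    tc = target - target.mean()
    denom = np.sqrt((rc * rc).sum(axis=1) * float(tc @ tc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rc @ tc) / denom
    return np.clip(r, -1.0, 1.0)


def detection_stats(
    ms: MeasurementSet,
    ref: ReferenceSpectrum,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    smoothing_window: int = DEFAULT_SMOOTH_WINDOW,
    baseline_window_cm1: float = DEFAULT_BASELINE_WINDOW,
    baseline_method: str = "rolling_min",
    correct_ref: bool = True,
) -> DetectionStats:
    """Score every single spectrum of a measurement against the reference.

    Each spectrum is smoothed and baseline-corrected with the measurement-level
    configuration, then correlated with the reference processed the same way
    (so a spectrum identical to the reference scores exactly 1).
    All filtering is vectorised across the whole 2-D block.
    """
    smoothed = shrinking_boxcar(ms.intensities, smoothing_window)
    baseline = BASELINE_METHODS[baseline_method](
        ms.shifts, smoothed, baseline_window_cm1)
    corrected = smoothed - baseline

    ref = ref.with_intensities(shrinking_boxcar(ref.intensities,
                                                smoothing_window))
    if correct_ref:
        ref_avg = AverageSpectrum(ref.shifts, ref.intensities, dict(ref.meta))
        ref_sp = baseline_correct(ref_avg, baseline_window_cm1,
                                  baseline_method).as_spectrum()
    else:
        ref_sp = ref
    lo = max(ms.shifts[0], ref_sp.shifts[0])
    hi = min(ms.shifts[-1], ref_sp.shifts[-1])
    mask = (ms.shifts >= lo) & (ms.shifts <= hi)
    if mask.sum() < 3:
        raise UndefinedCorrelationError("insufficient grid overlap")
    target = np.interp(ms.shifts[mask], ref_sp.shifts, ref_sp.intensities)
    rb = _rowwise_pearson(corrected[:, mask], target)

    hits = rb > threshold
    n_det = int(hits.sum())
    f_b = n_det / ms.n_spectra
    m_b = float(rb[hits].mean()) if n_det else math.nan
    return DetectionStats(f_b, m_b, n_det, ms.n_spectra, threshold)


def compute_features(
    ms: MeasurementSet,
    ref: ReferenceSpectrum,
    bands: Sequence[int] = PE_BANDS,
    band_tol: float = 5.0,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
    smoothing_window: int = DEFAULT_SMOOTH_WINDOW,
    baseline_window_cm1: float = DEFAULT_BASELINE_WINDOW,
    baseline_method: str = "rolling_min",
    correct_ref: bool = True,
) -> FeatureVector:
    """Run the full per-measurement pipeline and collect all variables."""
    cor = preprocess_measurement(ms, smoothing_window, baseline_window_cm1,
                                 baseline_method)
    smooth_ref = moving_average(
        ReferenceSpectrum(ref.shifts, ref.intensities, dict(ref.meta),
                          polymer=getattr(ref, "polymer", "PE")),
        smoothing_window)
    R = compute_R(cor.parent, smooth_ref)
    R_b = compute_Rb(cor, smooth_ref, correct_ref, baseline_window_cm1,
                     baseline_method)
    H_b = {k: peak_height(cor, k, band_tol) for k in bands}
    det = detection_stats(ms, ref, threshold, smoothing_window,
                          baseline_window_cm1, baseline_method, correct_ref)
    return FeatureVector(ms.point_id, ms.repeat, R, R_b, H_b,
                         det.f_b, det.m_b, meta=dict(ms.meta))


def feature_table(measurements: Sequence[MeasurementSet],
                  ref: ReferenceSpectrum, **cfg) -> pd.DataFrame:
    """One feature row per measurement, as a tidy DataFrame."""
    rows = [compute_features(ms, ref, **cfg).as_row() for ms in measurements]
    return pd.DataFrame(rows)
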