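"""End-to-end drivers: directory of measurement CSVs -> feature table ->
calibration report.

These functions are the programmatic core behind the command-line interface;
each is a thin composition of the spectra_io / preprocess / features /
isotherm modules with logging and bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import features as ft
from . import isotherm as iso
from .simulate import ExperimentData
from .spectra_io import read_measurement_csv

log = logging.getLogger("ramanmp")

__all__ = ["ProcessResult", "StudyReport", "run_process", "run_full_study"]


@dataclass
class ProcessResult:
    """Outcome of processing a measurement directory."""

    table: pd.DataFrame
    n_processed: int
    n_failed: int
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def exit_code(self) -> int:
        if self.n_processed == 0:
            return 1
        return 2 if self.n_failed else 0


def run_process(
    measurement_dir: str | Path,
    ref: ft.ReferenceSpectrum,
    dialect: str = "wide",
    expected_spectra: int | None = None,
    pattern: str = "meas_*.csv",
    **feature_cfg,
) -> ProcessResult:
    """Compute one feature row per measurement file in a directory.

    Per-file failures are logged and skipped; the result's ``exit_code`` is 2
    when any file failed and 1 when nothing could be processed.
    """
    measurement_dir = Path(measurement_dir)
    paths = sorted(measurement_dir.glob(pattern))
    if not paths:
        raise FileNotFoundError(
            f"no measurement files matching {pattern!r} in {measurement_dir}")
    truth_path = measurement_dir / "truth.csv"
    meta = None
    if truth_path.exists():
        meta = pd.read_csv(truth_path).set_index("file")
    rows, failures = [], {}
    for path in paths:
        point_id, repeat = "C0", 1
        if meta is not None and path.name in meta.index:
            point_id = str(meta.loc[path.name, "point_id"])
            repeat = int(meta.loc[path.name, "repeat"])
        try:
            ms = read_measurement_csv(path, dialect=dialect,
                                      point_id=point_id, repeat=repeat,
                                      expected_spectra=expected_spectra)
            fv = ft.compute_features(ms, ref, **feature_cfg)
        except Exception as exc:  # per-file isolation, summarized at the end
            log.warning("skipping %s: %s", path.name, exc)
            failures[path.name] = str(exc)
            continue
        row = fv.as_row()
        row["file"] = path.name
        if meta is not None and path.name in meta.index:
            row["concentration"] = float(meta.loc[path.name, "concentration"])
        log.info("%s: R_b=%.3f f_b=%.3f", path.name, fv.R_b, fv.f_b)
        rows.append(row)
    table = pd.DataFrame(rows)
    return ProcessResult(table, len(rows), len(failures), failures)


@dataclass
class StudyReport:
    """Full calibration study: model comparison, selected curve, intervals."""

    feature_table: pd.DataFrame
    model_comparison: pd.DataFrame
    curve: iso.CalibrationCurve
    interval_grid: pd.DataFrame
    sensitivity: iso.SensitivityReport | None

    @property
    def selected_model(self) -> str:
        return self.curve.fit.model.name

    def to_dict(self) -> dict:
        fit = self.curve.fit
        comp = self.model_comparison.drop(columns="fit")
        out = {
            "selected_model": self.selected_model,
            "parameters": {k: float(v) for k, v in fit.param_dict.items()},
            "standard_errors": dict(zip(fit.model.param_names,
                                        map(float, fit.se))),
            "statistics": {"n": fit.n, "p": fit.p, "rss": fit.rss,
                           "mse": fit.mse, "rmse": fit.rmse, "r2": fit.r2,
                           "r2_adj": fit.r2_adj, "aic": fit.aic,
                           "bic": fit.bic},
            "model_comparison": comp.to_dict(orient="records"),
            "prediction_interval": self.interval_grid.to_dict(orient="list"),
        }
        if self.sensitivity is not None:
            s = self.sensitivity
            out["sensitivity_c0"] = {
                "correlation": s.correlation,
                "within_1se": s.within_1se,
                "all_within_1se": s.all_within_1se,
                "params_c0": {k: float(v)
                              for k, v in s.fit_c0.param_dict.items()},
            }
        return out


def run_full_study(
    data: ExperimentData | pd.DataFrame,
    ref: ft.ReferenceSpectrum | None = None,
    models: Sequence[str] | None = None,
    select: str = "langmuir",
    c0_only: bool = False,
    interval_points: int = 50,
    level: float = 0.95,
    **feature_cfg,
) -> StudyReport:
    """Run the whole calibration analysis on a simulated experiment or a
    precomputed feature table.

    ``data`` is either an in-memory :class:`ExperimentData` (features are
    computed here; ``ref`` required) or a feature DataFrame already carrying
    ``concentration``, ``point_id`` and ``R_b`` columns. The isotherm fit is
    to per-concentration mean R_b. ``select='best'`` picks the AIC winner
    instead of the default Langmuir curve. ``c0_only`` restricts the whole
    analysis to the beaker-center measurements.
    """
    if isinstance(data, ExperimentData):
        if ref is None:
            raise ValueError("a reference spectrum is required to compute "
                             "features from raw measurements")
        table = ft.feature_table(data.measurements, ref, **feature_cfg)
        table["concentration"] = [t.concentration for t in data.truths]
    else:
        table = data.copy()
    if "concentration" not in table.columns:
        raise ValueError("feature table must carry a concentration column")

    work = table[table["point_id"] == "C0"] if c0_only else table
    mean_rb = work.groupby("concentration")["R_b"].mean()
    C = mean_rb.index.to_numpy(float)
    y = mean_rb.to_numpy()
    comparison = iso.compare_models(C, y, models)
    if select == "best":
        best = comparison.iloc[0]["fit"]
    else:
        match = comparison[comparison["model"] == select]
        best = (match.iloc[0]["fit"] if len(match)
                else iso.fit(select, C, y))
    curve = iso.CalibrationCurve(best, level=level)
    grid = np.linspace(C.min(), C.max(), interval_points)
    interval = iso.prediction_interval(curve, grid, level)

    sensitivity = None
    if not c0_only and (table["point_id"] == "C0").any() \
            and table["point_id"].nunique() > 1:
        sensitivity = iso.sensitivity_c0(
            table, table[table["point_id"] == "C0"])
    return StudyReport(table, comparison, curve, interval, sensitivity)
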