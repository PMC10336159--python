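"""Spectrum containers and CSV input/output for point-measurement Raman data.

A point measurement produces a set of single spectra (nominally 1000) on a
common Raman-shift grid; vendor software exports each measurement as one CSV
file. Two dialects are supported:

* ``wide`` (default): first column is the Raman shift (cm^-1), every further
  column is one single spectrum.
* ``long``: three columns ``spectrum``, ``shift``, ``intensity``.

Grids are re-sorted to strictly increasing shift on read regardless of the
file's row order. Non-integer and non-uniform grids are accepted; downstream
operations interpolate rather than assume a 1 cm^-1 step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "MeasurementSet",
    "ConcentrationTable",
    "SpectraError",
    "ParseError",
    "StructuralError",
    "CardinalityWarning",
    "read_measurement_csv",
    "write_measurement_csv",
    "concentration_from_mass",
]


class SpectraError(ValueError):
    """Base class for spectral-data errors."""


class ParseError(SpectraError):
    """A cell in a spectral CSV could not be parsed as a number."""


class StructuralError(SpectraError):
    """The file's layout is inconsistent (mismatched grids, no spectra...)."""


class CardinalityWarning(UserWarning):
    """A measurement holds an unexpected number of single spectra."""


def _as_grid(shifts, intensities):
    """Validate/sort a (shifts, intensities) pair; intensities may be 1-D or 2-D
    with shifts along the last axis. Returns ascending copies."""
    shifts = np.asarray(shifts, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if shifts.ndim != 1:
        raise StructuralError("shift grid must be one-dimensional")
    if intensities.shape[-1] != shifts.shape[0]:
        raise StructuralError(
            f"length mismatch: {shifts.shape[0]} shifts vs "
            f"{intensities.shape[-1]} intensity points"
        )
    if not np.all(np.isfinite(shifts)) or not np.all(np.isfinite(intensities)):
        raise SpectraError("non-finite value in spectrum")
    d = np.diff(shifts)
    if np.all(d > 0):
        return shifts, intensities
    if np.all(d < 0):  # descending export: reorder both consistently
        return shifts[::-1].copy(), intensities[..., ::-1].copy()
    order = np.argsort(shifts, kind="stable")
    shifts = shifts[order]
    if np.any(np.diff(shifts) <= 0):
        raise StructuralError("shift grid contains duplicate values")
    return shifts, intensities[..., order]


@dataclass
class Spectrum:
    """One Raman spectrum: paired shift grid (cm^-1) and intensities (counts).

    The grid is strictly increasing and all values are finite; a descending
    grid is reordered (with its intensities) on construction.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.shifts, self.intensities = _as_grid(self.shifts, self.intensities)
        if self.intensities.ndim != 1:
            raise StructuralError("Spectrum intensities must be one-dimensional")

    def __len__(self) -> int:
        return len(self.shifts)

    def with_intensities(self, intensities, **meta) -> "Spectrum":
        return Spectrum(self.shifts.copy(), intensities, {**self.meta, **meta})


@dataclass
class MeasurementSet:
    """All single spectra of one point measurement on a shared grid.

    ``intensities`` is (n_spectra, n_points). ``point_id`` identifies the
    sampling point (C0/C1/C2) and ``repeat`` the measurement index m in 1..3.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    point_id: str = "C0"
    repeat: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.shifts, self.intensities = _as_grid(self.shifts, self.intensities)
        if self.intensities.ndim != 2:
            raise StructuralError("MeasurementSet intensities must be 2-D")
        if self.intensities.shape[0] == 0:
            raise StructuralError("measurement contains no spectra")

    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    def spectra(self) -> Iterator[Spectrum]:
        for i, row in enumerate(self.intensities):
            yield Spectrum(self.shifts, row, {"index": i, **self.meta})

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum], point_id="C0", repeat=1):
        if not spectra:
            raise StructuralError("measurement contains no spectra")
        grid = spectra[0].shifts
        for s in spectra[1:]:
            if len(s) != len(grid) or not np.allclose(s.shifts, grid):
                raise StructuralError("member spectra are on different grids")
        return cls(grid, np.vstack([s.intensities for s in spectra]),
                   point_id=point_id, repeat=repeat)


def read_measurement_csv(
    path,
    dialect: str = "wide",
    point_id: str = "C0",
    repeat: int = 1,
    expected_spectra: int | None = 1000,
) -> MeasurementSet:
    """Read one exported measurement file into a :class:`MeasurementSet`.

    ``expected_spectra`` triggers a :class:`CardinalityWarning` (not an error)
    when the file holds a different number of single spectra; pass ``None`` to
    disable the check.
    """
    path = Path(path)
    if dialect == "wide":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(f"{path}: {exc}") from exc
        if df.shape[1] < 2:
            raise StructuralError(f"{path}: wide file needs a shift column plus "
                                  "at least one spectrum column")
        _check_numeric(df, path)
        shifts = df.iloc[:, 0].to_numpy(float)
        intensities = df.iloc[:, 1:].to_numpy(float).T
    elif dialect == "long":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover
            raise ParseError(f"{path}: {exc}") from exc
        cols = {c.lower(): c for c in df.columns}
        try:
            sp, sh, it = (cols[k] for k in ("spectrum", "shift", "intensity"))
        except KeyError as exc:
            raise StructuralError(
                f"{path}: long dialect needs columns spectrum/shift/intensity"
            ) from exc
        _check_numeric(df[[sh, it]], path)
        wide = df.pivot(index=sh, columns=sp, values=it)
        if wide.isna().any().any():
            raise StructuralError(f"{path}: spectra cover inconsistent grids")
        shifts = wide.index.to_numpy(float)
        intensities = wide.to_numpy(float).T
    else:
        raise ValueError(f"unknown CSV dialect {dialect!r}")
    if expected_spectra is not None and intensities.shape[0] != expected_spectra:
        warnings.warn(
            f"{path}: {intensities.shape[0]} spectra found, "
            f"{expected_spectra} expected",
            CardinalityWarning,
            stacklevel=2,
        )
    return MeasurementSet(shifts, intensities, point_id=point_id, repeat=repeat)


def _check_numeric(df: pd.DataFrame, path):
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        col = bad.any().idxmax()
        row = int(bad[col].idxmax())
        raise ParseError(
            f"{path}: non-numeric value {df.loc[row, col]!r} at row {row}, "
            f"column {col!r}"
        )
    if df.isna().any().any():
        col = df.isna().any().idxmax()
        row = int(df[col].isna().idxmax())
        raise ParseError(f"{path}: missing value at row {row}, column {col!r}")


def write_measurement_csv(ms: MeasurementSet, path, float_format=None) -> Path:
    """Write a wide-format CSV readable by :func:`read_measurement_csv`.

    The default ``float_format=None`` writes full-precision decimal text, so a
    write/read round trip is lossless.
    """
    path = Path(path)
    cols = {"shift": ms.shifts}
    for i, row in enumerate(ms.intensities):
        cols[f"s{i + 1:04d}"] = row
    pd.DataFrame(cols).to_csv(path, index=False, float_format=float_format)
    return path


@dataclass
class ConcentrationTable:
    """Known sample concentrations: (sample_id, mass_mg, volume_ml, mg/ml)."""

    data: pd.DataFrame

    REQUIRED = ("sample_id", "mass_mg", "volume_ml", "concentration_mg_per_ml")

    def __post_init__(self):
        df = pd.DataFrame(self.data)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise StructuralError(f"concentration table missing columns {missing}")
        if (df["volume_ml"] <= 0).any():
            raise SpectraError("volume must be positive")
        if (df["mass_mg"] < 0).any():
            raise SpectraError("mass must be nonnegative")
        expected = df["mass_mg"] / df["volume_ml"]
        # concentrations are typically reported to 2 decimals
        if not np.allclose(df["concentration_mg_per_ml"], expected, atol=0.005):
            raise SpectraError("concentration column inconsistent with mass/volume")
        self.data = df

    @classmethod
    def from_masses(cls, masses_mg: Sequence[float], volume_ml: float,
                    ids: Sequence[str] | None = None) -> "ConcentrationTable":
        masses = np.asarray(masses_mg, float)
        if ids is None:
            ids = [f"S{i + 1:02d}" for i in range(len(masses))]
        return cls(pd.DataFrame({
            "sample_id": list(ids),
            "mass_mg": masses,
            "volume_ml": volume_ml,
            "concentration_mg_per_ml": masses / volume_ml,
        }))

    @property
    def concentrations(self) -> np.ndarray:
        return self.data["concentration_mg_per_ml"].to_numpy(float)


def concentration_from_mass(mass_mg: float, volume_ml: float) -> float:
    """Concentration in mg/ml of ``mass_mg`` particles in ``volume_ml`` water.

    Rounding to the customary 2 decimals is left to the presentation layer.
    """
    if volume_ml <= 0:
        raise ValueError("volume must be positive")
    if mass_mg < 0:
        raise ValueError("mass must be nonnegative")
    return mass_mg / volume_ml
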