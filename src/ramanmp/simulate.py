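"""Synthetic micro-Raman data: reference spectra, water backgrounds, and full
measurement sets with surface-coverage particle-hit statistics.

The simulator abstracts the physical measurement as follows. Polyethylene
particles float and collect on the water surface; as the stirred water
carries particle clusters under the laser spot, any single 0.1 s exposure
either catches a particle ("hit") or sees only water. The hit probability
follows a Langmuir surface-coverage curve in concentration,

    theta(C) = theta_max * K * C / (1 + K * C),

so the fraction of hit spectra — and with it the average spectrum's
resemblance to the polymer standard — saturates with concentration exactly
the way the calibration model assumes. Hit spectra are water background plus
a fixed fraction of the reference polymer spectrum; all spectra get additive
Gaussian detector noise (optional shot-noise scaling).

Everything is driven by one master seed expanded into independent
per-measurement substreams through ``numpy.random.SeedSequence`` spawn keys,
so any subset of an experiment is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import ReferenceSpectrum
from .spectra_io import MeasurementSet, write_measurement_csv

__all__ = [
    "SimConfig",
    "SimTruth",
    "ExperimentData",
    "PAPER_MASSES_MG",
    "PAPER_VOLUME_ML",
    "paper_concentrations",
    "make_reference",
    "water_background",
    "hit_probability",
    "simulate_measurement",
    "simulate_experiment",
]

#: Particle masses (mg) of the 13-level validation design and the working
#: water volume (ml) they are dispersed in — concentrations 0 to 0.94 mg/ml.
PAPER_MASSES_MG = tuple(0.5 * i for i in range(13))
PAPER_VOLUME_ML = 6.37


def paper_concentrations() -> np.ndarray:
    """The 13 standard concentrations (mg/ml) of the validation design."""
    return np.asarray(PAPER_MASSES_MG, float) / PAPER_VOLUME_ML


# (center cm^-1, sigma cm^-1, amplitude counts); the 2844/2878 C-H stretch
# doublet dominates, the fingerprint bands are weaker.
_DEFAULT_PE_PEAKS = (
    (1059.0, 6.0, 180.0),
    (1128.0, 6.0, 230.0),
    (1239.0, 8.0, 90.0),
    (1415.0, 7.0, 120.0),
    (1438.0, 7.0, 320.0),
    (2844.0, 12.0, 1000.0),
    (2878.0, 12.0, 750.0),
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic instrument and sampling process.

    Amplitudes and backgrounds are in detector counts on a 400-4000 cm^-1
    grid. ``theta_max`` and ``K`` (ml/mg) shape the Langmuir hit-probability
    curve; ``signal_fraction`` is the share of the reference spectrum a hit
    contributes; ``noise_sigma`` is the additive Gaussian noise per point.
    """

    grid_start: float = 400.0
    grid_stop: float = 4000.0
    grid_step: float = 1.0
    pe_peaks: tuple = _DEFAULT_PE_PEAKS
    ref_floor: float = 5.0
    # water: broad fluorescence hump + O-H stretch band near 3400 cm^-1
    fluor_amplitude: float = 600.0
    fluor_center: float = 1300.0
    fluor_sigma: float = 900.0
    fluor_offset: float = 200.0
    oh_amplitude: float = 800.0
    oh_center: float = 3420.0
    oh_sigma: float = 160.0
    theta_max: float = 0.9
    K: float = 8.0
    signal_fraction: float = 0.6
    noise_sigma: float = 20.0
    shot_noise: bool = False
    n_spectra: int = 1000

    def __post_init__(self):
        if not (0.0 <= self.theta_max <= 1.0) or self.K < 0:
            raise ValueError("coverage parameters must give theta in [0,1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if any(a < 0 for _, _, a in self.pe_peaks):
            raise ValueError("peak amplitudes must be nonnegative")
        if self.n_spectra < 1:
            raise ValueError("need at least one spectrum per measurement")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


@dataclass
class SimTruth:
    """Ground truth of one simulated measurement (test/oracle channel)."""

    concentration: float
    n_hits: int
    n_spectra: int
    point_id: str = "C0"
    repeat: int = 1
    seed_key: tuple = ()


def _gaussians(grid, peaks):
    out = np.zeros_like(grid)
    for center, sigma, amp in peaks:
        out += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return out


def make_reference(cfg: SimConfig = SimConfig()) -> ReferenceSpectrum:
    """Standard polymer spectrum: Gaussian peaks on a near-zero baseline."""
    grid = cfg.grid()
    intens = _gaussians(grid, cfg.pe_peaks) + cfg.ref_floor
    return ReferenceSpectrum(grid, intens, {"source": "synthetic"},
                             polymer="PE")


def water_background(cfg: SimConfig = SimConfig()) -> np.ndarray:
    """Deterministic water spectrum: broad fluorescence plus the O-H band."""
    grid = cfg.grid()
    fluor = (cfg.fluor_offset + cfg.fluor_amplitude
             * np.exp(-0.5 * ((grid - cfg.fluor_center) / cfg.fluor_sigma) ** 2))
    oh = cfg.oh_amplitude * np.exp(
        -0.5 * ((grid - cfg.oh_center) / cfg.oh_sigma) ** 2)
    return fluor + oh


def hit_probability(C: float, cfg: SimConfig = SimConfig()) -> float:
    """Langmuir surface-coverage probability that one exposure hits a
    particle."""
    if C < 0:
        raise ValueError("concentration must be nonnegative")
    return cfg.theta_max * cfg.K * C / (1.0 + cfg.K * C)


def _rng(seed: int, key: tuple) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_measurement(
    C: float,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
    point_id: str = "C0",
    repeat: int = 1,
    seed_key: tuple = (0,),
) -> tuple[MeasurementSet, SimTruth]:
    """Draw one point measurement of ``cfg.n_spectra`` single spectra.

    Each exposure is an independent Bernoulli(theta(C)) hit decision; hit
    spectra add ``signal_fraction`` of the reference to the water background.
    Reproducible given (seed, seed_key).
    """
    rng = _rng(seed, seed_key)
    grid = cfg.grid()
    bg = water_background(cfg)
    ref = make_reference(cfg).intensities
    hits = rng.random(cfg.n_spectra) < hit_probability(C, cfg)
    clean = bg[None, :] + np.where(hits[:, None], cfg.signal_fraction, 0.0) * ref
    if cfg.shot_noise:
        sigma = cfg.noise_sigma * np.sqrt(np.maximum(clean, 1.0)
                                          / np.maximum(bg.mean(), 1.0))
        noise = rng.standard_normal(clean.shape) * sigma
    else:
        noise = rng.standard_normal(clean.shape) * cfg.noise_sigma
    ms = MeasurementSet(grid, clean + noise, point_id=point_id, repeat=repeat,
                        meta={"concentration": C})
    truth = SimTruth(C, int(hits.sum()), cfg.n_spectra, point_id, repeat,
                     seed_key)
    return ms, truth


@dataclass
class ExperimentData:
    """A simulated multi-concentration experiment held in memory."""

    measurements: list[MeasurementSet]
    truths: list[SimTruth]
    truth_table: pd.DataFrame
    config: SimConfig = field(default_factory=SimConfig)


POINT_IDS = ("C0", "C1", "C2")
REPEATS = (1, 2, 3)


def simulate_experiment(
    concentrations: Sequence[float] | None = None,
    cfg: SimConfig = SimConfig(),
    seed: int = 0,
    out_dir: str | Path | None = None,
    points: Sequence[str] = POINT_IDS,
    repeats: Sequence[int] = REPEATS,
) -> ExperimentData:
    """Simulate the full validation design: every concentration measured at
    each sampling point (C0, C1, C2) with three repeats — 9 measurements per
    concentration by default.

    When ``out_dir`` is given, every measurement is written as a wide CSV
    (``meas_<k>_<point>_m<repeat>.csv``) along with ``truth.csv``, producing
    a directory the processing pipeline consumes end to end. Outputs are
    deterministic per seed.
    """
    if concentrations is None:
        concentrations = paper_concentrations()
    concentrations = np.asarray(concentrations, float)
    measurements, truths, rows = [], [], []
    idx = 0
    for k, C in enumerate(concentrations):
        for point in points:
            for m in repeats:
                ms, truth = simulate_measurement(
                    float(C), cfg, seed, point_id=point, repeat=m,
                    seed_key=(idx,))
                ms.meta.update({"sample_index": k})
                measurements.append(ms)
                truths.append(truth)
                rows.append({
                    "file": f"meas_{k:02d}_{point}_m{m}.csv",
                    "sample_index": k, "point_id": point, "repeat": m,
                    "concentration": float(C), "n_hits": truth.n_hits,
                    "n_spectra": truth.n_spectra,
                })
                idx += 1
    truth_table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for row, ms in zip(rows, measurements):
            write_measurement_csv(ms, out_dir / row["file"],
                                  float_format="%.4f")
        truth_table.to_csv(out_dir / "truth.csv", index=False)
    return ExperimentData(measurements, truths, truth_table, cfg)
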