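"""Adsorption-isotherm calibration of R_b against particle concentration.

Floating microplastic particles accumulate on the water surface, so the
response variable R_b (correlation of the baseline-corrected average spectrum
with the polymer standard) saturates with concentration like a surface
coverage. Seven empirical isotherm forms are fitted to (C_PE, R_b) pairs by
bounded nonlinear least squares with multi-start, ranked by information
criteria, and the selected curve (Langmuir by default) is inverted in closed
form to estimate concentration from a measured R_b with a 95% prediction
interval.

Model forms (C = concentration in mg/ml; all but the linear model carry an
additive offset c, the R_b value at zero concentration):

======================  ==========================================  =========
name                    R_b =                                       params
======================  ==========================================  =========
linear                  b1*C + b2                                   2
freundlich              b1*C**(1/b2) + c                            3
redlich_peterson        b1*C/(1 + b2*C**b3) + c                     4
sips                    b1*C**b3/(1 + b2*C**b3) + c                 4
temkin                  b1*ln(b2*C + b3) + c                        4 (3 eff.)
dubinin_radushkevich    b1*exp(-b2*ln(1 + 1/C)) + c                 3
langmuir                b1*b2*C/(1 + b2*C) + c                      3
======================  ==========================================  =========

In the Langmuir form b1 is the limiting correlation as C -> infinity, b2 the
affinity (ml/mg). b1 may exceed 1: at high concentration multilayer chunks
violate the monolayer assumption, so the fit is an empirical description of
the tested range rather than a bounded correlation.

Goodness-of-fit statistics: MSE = RSS/(n-p); RMSE = sqrt(MSE);
R2 = 1 - RSS/TSS; adjusted R2 = 1 - (1-R2)(n-1)/(n-p); AIC = 2p - 2lnL and
BIC = p*ln(n) - 2lnL with the Gaussian log-likelihood at sigma^2 = RSS/n.
The Temkin b3 and c are nearly collinear, so it is counted with 3 effective
parameters by default (configurable to 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IsothermModel",
    "IsothermFit",
    "CalibrationCurve",
    "InverseEstimate",
    "SensitivityReport",
    "FitError",
    "SaturationError",
    "MODELS",
    "get_model",
    "fit",
    "goodness",
    "adjusted_r2",
    "invert_with_interval",
    "compare_models",
    "invert",
    "prediction_interval",
    "sensitivity_c0",
]


class FitError(RuntimeError):
    """No optimizer start converged to a usable solution."""


class SaturationError(ValueError):
    """Measured R_b at or above the fitted saturation level b1 + c."""


@dataclass(frozen=True)
class IsothermModel:
    """One isotherm form: prediction function, bounds and start values."""

    name: str
    param_names: tuple[str, ...]
    predict: Callable[[np.ndarray, np.ndarray], np.ndarray]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    n_effective: int | None = None  # information-criterion count, if != len

    @property
    def p(self) -> int:
        return len(self.param_names)

    @property
    def p_eff(self) -> int:
        return self.n_effective if self.n_effective is not None else self.p

    def __call__(self, params, C):
        return self.predict(np.asarray(params, float), np.asarray(C, float))


def _linear(b, C):
    return b[0] * C + b[1]


def _freundlich(b, C):
    return b[0] * np.power(C, 1.0 / b[1]) + b[2]


def _redlich_peterson(b, C):
    return b[0] * C / (1.0 + b[1] * np.power(C, b[2])) + b[3]


def _sips(b, C):
    Cb = np.power(C, b[2])
    return b[0] * Cb / (1.0 + b[1] * Cb) + b[3]


def _temkin(b, C):
    return b[0] * np.log(b[1] * C + b[2]) + b[3]


def _dubinin_radushkevich(b, C):
    # exp(-b2*ln(1+1/C)) = (1+1/C)^(-b2); continuous limit c at C=0
    C = np.asarray(C, float)
    out = np.full(C.shape, 0.0)
    pos = C > 0
    out[pos] = np.power(1.0 + 1.0 / C[pos], -b[1])
    return b[0] * out + b[2]


def _langmuir(b, C):
    return b[0] * b[1] * C / (1.0 + b[1] * C) + b[2]


_INF = math.inf

MODELS: dict[str, IsothermModel] = {m.name: m for m in [
    IsothermModel("linear", ("b1", "b2"), _linear,
                  (0.0, -_INF), (_INF, _INF)),
    IsothermModel("freundlich", ("b1", "b2", "c"), _freundlich,
                  (0.0, 0.1, -_INF), (_INF, _INF, _INF)),
    IsothermModel("redlich_peterson", ("b1", "b2", "b3", "c"),
                  _redlich_peterson, (0.0, 0.0, 0.1, -_INF),
                  (_INF, _INF, 10.0, _INF)),
    IsothermModel("sips", ("b1", "b2", "b3", "c"), _sips,
                  (0.0, 0.0, 0.1, -_INF), (_INF, _INF, 10.0, _INF)),
    IsothermModel("temkin", ("b1", "b2", "b3", "c"), _temkin,
                  (0.0, 0.0, 0.1, -_INF), (_INF, _INF, 10.0, _INF),
                  n_effective=3),
    IsothermModel("dubinin_radushkevich", ("b1", "b2", "c"),
                  _dubinin_radushkevich, (0.0, 0.0, -_INF),
                  (_INF, _INF, _INF)),
    IsothermModel("langmuir", ("b1", "b2", "c"), _langmuir,
                  (0.0, 0.0, -_INF), (_INF, _INF, _INF)),
]}


def get_model(name: str) -> IsothermModel:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown isotherm model {name!r}; "
                       f"available: {sorted(MODELS)}") from None


@dataclass
class IsothermFit:
    """A fitted isotherm with residual statistics and information criteria."""

    model: IsothermModel
    params: np.ndarray
    se: np.ndarray
    cov: np.ndarray | None
    C: np.ndarray
    y: np.ndarray
    residuals: np.ndarray
    rss: float
    mse: float
    rmse: float
    r2: float
    r2_adj: float
    aic: float
    bic: float
    n: int = 0
    p: int = 0
    se_valid: bool = True

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, self.params))

    def predict(self, C):
        return self.model(self.params, C)


def _starts(model: IsothermModel, C, y) -> list[np.ndarray]:
    """Multi-start initial values: log-spaced affinity grid crossed with two
    amplitude guesses; offset initialised at the response at the lowest C."""
    c0 = float(y[np.argmin(C)])
    if model.name == "linear":
        slope = (y[-1] - y[0]) / max(C[-1] - C[0], 1e-12)
        return [np.array([max(slope, 1e-3), c0]), np.array([1.0, 0.0])]
    starts = []
    for b2 in (0.1, 1.0, 10.0, 100.0):
        for b1 in (0.5, 1.0):
            if model.p == 3:
                starts.append(np.array([b1, b2, c0]))
            else:
                starts.append(np.array([b1, b2, 1.0, c0]))
    return starts


def _clip_to_bounds(x, lo, hi):
    eps = 1e-9
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    return np.clip(x, np.where(np.isfinite(lo), lo + 0 * eps, lo),
                   np.where(np.isfinite(hi), hi - 0 * eps, hi))


def fit(model: IsothermModel | str, C, y, init=None,
        weights=None, temkin_p4: bool = False,
        multistart: bool = True) -> IsothermFit:
    """Bounded least-squares fit of one isotherm model to (C, y) pairs.

    Runs every start in a small multi-start grid (affinity is the multi-modal
    direction) and keeps the lowest-cost converged solution; pass ``init``
    with ``multistart=False`` for a single warm start (useful in Monte-Carlo
    replications). ``weights`` (optional, same length as the data) multiply
    the residuals.
    """
    if isinstance(model, str):
        model = get_model(model)
    C = np.asarray(C, float)
    y = np.asarray(y, float)
    if C.ndim != 1 or C.shape != y.shape:
        raise ValueError("C and y must be matching 1-D arrays")
    if np.any(C < 0):
        raise ValueError("concentrations must be nonnegative")
    if np.allclose(C, C[0]):
        raise ValueError("concentrations are all equal; nothing to fit")
    n = len(C)
    p_eff = 4 if (model.name == "temkin" and temkin_p4) else model.p_eff
    if n <= model.p:
        raise ValueError(f"need more data points ({n}) than parameters "
                         f"({model.p})")
    w = np.ones(n) if weights is None else np.asarray(weights, float)

    def resid(b):
        with np.errstate(all="ignore"):
            r = (model(b, C) - y) * w
        return np.where(np.isfinite(r), r, 1e6)

    starts = [np.asarray(init, float)] if init is not None else []
    if init is None or multistart:
        starts += _starts(model, C, y)
    best = None
    for x0 in starts:
        x0 = _clip_to_bounds(x0, model.lower, model.upper)
        try:
            sol = optimize.least_squares(
                resid, x0, bounds=(model.lower, model.upper),
                method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost - 1e-14:
            best = sol
    if best is None:
        raise FitError(f"{model.name}: no optimizer start converged")

    params = best.x
    residuals = model(params, C) - y
    rss = float(residuals @ residuals)
    stats_ = goodness(rss, y, n, p_eff)
    # parameter covariance from the unweighted Jacobian at the optimum
    J = best.jac
    se_valid = True
    cov = None
    se = np.full(model.p, math.nan)
    try:
        JtJ = J.T @ J
        cov = np.linalg.inv(JtJ) * stats_["mse"]
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if not np.all(np.isfinite(se)):
            se_valid = False
    except np.linalg.LinAlgError:
        se_valid = False
    return IsothermFit(
        model=model, params=params, se=se, cov=cov, C=C, y=y,
        residuals=residuals, rss=rss, n=n, p=p_eff, se_valid=se_valid,
        **stats_,
    )


def goodness(rss: float, y, n: int, p: int) -> dict[str, float]:
    """Residual statistics and information criteria for a fitted model.

    Degenerate perfect fits (RSS ~ 0) get ``-inf`` information criteria as an
    explicit sentinel rather than a numeric error.
    """
    y = np.asarray(y, float)
    if n <= p:
        raise ValueError("n must exceed the parameter count")
    tss = float(((y - y.mean()) ** 2).sum())
    mse = rss / (n - p)
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    if rss <= 0.0:
        aic = bic = -math.inf
    else:
        sigma2 = rss / n
        loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        aic = 2 * p - 2 * loglik
        bic = p * math.log(n) - 2 * loglik
    return {"mse": mse, "rmse": math.sqrt(mse), "r2": r2, "r2_adj": r2_adj,
            "aic": aic, "bic": bic}


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 from plain R^2 with n observations and p parameters."""
    if n <= p:
        raise ValueError("n must exceed the parameter count")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def compare_models(C, y, models: Sequence[str] | None = None,
                   **fit_kwargs) -> pd.DataFrame:
    """Fit a set of isotherm models and rank them.

    Returns one row per successfully fitted model with the full statistics
    bundle, sorted by AIC ascending (ties broken by BIC, then parameter
    count). The fitted objects are attached in the ``fit`` column.
    """
    names = list(models) if models is not None else list(MODELS)
    rows = []
    for name in names:
        try:
            f = fit(name, C, y, **fit_kwargs)
        except (FitError, ValueError):
            continue
        rows.append({"model": name, "p": f.p, "rss": f.rss, "mse": f.mse,
                     "rmse": f.rmse, "r2": f.r2, "r2_adj": f.r2_adj,
                     "aic": f.aic, "bic": f.bic, "fit": f})
    if not rows:
        raise FitError("all model fits failed")
    df = pd.DataFrame(rows).sort_values(
        ["aic", "bic", "p"], kind="stable").reset_index(drop=True)
    return df


@dataclass
class InverseEstimate:
    """Concentration recovered from a measured R_b."""

    concentration: float
    below_floor: bool = False
    interval: tuple[float, float] | None = None


@dataclass
class CalibrationCurve:
    """A selected isotherm fit with inverse-prediction machinery.

    Only the Langmuir form has the closed-form inverse used by
    :meth:`invert`; other selected models fall back to numeric inversion.
    """

    fit: IsothermFit
    level: float = 0.95

    @property
    def params(self) -> dict[str, float]:
        return self.fit.param_dict

    def predict(self, C):
        return self.fit.predict(C)

    def invert(self, r_b: float) -> InverseEstimate:
        return invert(self, r_b)


def invert(curve: CalibrationCurve, r_b: float) -> InverseEstimate:
    """Map a measured R_b back to a concentration.

    For the Langmuir curve ``C = (R_b - c) / (b2 * (b1 - (R_b - c)))``.
    Values at or below the calibration floor c return concentration 0 with
    the ``below_floor`` flag; values at or above saturation b1 + c raise
    :class:`SaturationError`.
    """
    f = curve.fit
    if f.model.name == "langmuir":
        b1, b2, c = f.params
        u = r_b - c
        if u <= 0:
            return InverseEstimate(0.0, below_floor=True)
        if u >= b1:
            raise SaturationError(
                f"R_b={r_b} at or above fitted saturation b1+c={b1 + c}")
        return InverseEstimate(float(u / (b2 * (b1 - u))))
    # generic monotone inversion by bracketing on the fitted curve
    c_hi = max(f.C.max(), 1e-6)
    y0 = float(f.predict(0.0))
    if r_b <= y0:
        return InverseEstimate(0.0, below_floor=True)
    while f.predict(c_hi) < r_b:
        c_hi *= 2
        if c_hi > 1e9:
            raise SaturationError(f"R_b={r_b} above the fitted curve's range")
    root = optimize.brentq(lambda C: float(f.predict(C)) - r_b, 0.0, c_hi)
    return InverseEstimate(float(root))


def _param_gradient(f: IsothermFit, C: np.ndarray) -> np.ndarray:
    """d predict / d params at each C, by central differences (rows: C)."""
    C = np.atleast_1d(np.asarray(C, float))
    g = np.empty((len(C), f.model.p))
    for j in range(f.model.p):
        h = 1e-6 * max(abs(f.params[j]), 1.0)
        up = f.params.copy()
        dn = f.params.copy()
        up[j] += h
        dn[j] -= h
        g[:, j] = (f.model(up, C) - f.model(dn, C)) / (2 * h)
    return g


def prediction_interval(curve: CalibrationCurve, C_grid,
                        level: float = 0.95) -> pd.DataFrame:
    """Delta-method prediction band for a *new observation* at each C.

    half-width = t_{n-p,1-a/2} * sqrt(MSE * (1 + g' (J'J)^-1 g)) with g the
    parameter gradient of the curve at C.
    """
    f = curve.fit
    if f.cov is None or not f.se_valid:
        raise FitError("singular parameter covariance; no interval available")
    C_grid = np.atleast_1d(np.asarray(C_grid, float))
    J = _param_gradient(f, f.C)
    JtJ_inv = np.linalg.inv(J.T @ J)
    g = _param_gradient(f, C_grid)
    lever = np.einsum("ij,jk,ik->i", g, JtJ_inv, g)
    tq = stats.t.ppf(0.5 + level / 2, f.n - f.p)
    half = tq * np.sqrt(f.mse * (1.0 + lever))
    yhat = f.predict(C_grid)
    return pd.DataFrame({"C": C_grid, "fit": yhat,
                         "lower": yhat - half, "upper": yhat + half})


def invert_with_interval(curve: CalibrationCurve, r_b: float,
                         level: float = 0.95) -> InverseEstimate:
    """Inverse estimate plus a concentration interval obtained by inverting
    the prediction band edges (0 when the lower edge never reaches r_b;
    +inf when the upper edge saturates below it)."""
    est = invert(curve, r_b)
    f = curve.fit
    c_max = float(f.C.max()) * 10 + 1.0

    def edge(which):
        def fn(C):
            row = prediction_interval(curve, [C], level)
            return float(row[which].iloc[0]) - r_b
        return fn

    lo_fn, hi_fn = edge("upper"), edge("lower")
    # upper band crosses r_b at the smallest concentration consistent with it
    lo = 0.0
    if lo_fn(0.0) < 0:
        lo = optimize.brentq(lo_fn, 0.0, c_max) if lo_fn(c_max) > 0 else c_max
    hi = math.inf
    if hi_fn(0.0) < 0 and hi_fn(c_max) > 0:
        hi = optimize.brentq(hi_fn, 0.0, c_max)
    elif hi_fn(0.0) >= 0:
        hi = 0.0
    est.interval = (float(lo), float(hi))
    return est


@dataclass
class SensitivityReport:
    """Comparison of all-points calibration vs center-point-only calibration."""

    mean_rb_all: pd.Series
    mean_rb_c0: pd.Series
    correlation: float
    fit_all: IsothermFit
    fit_c0: IsothermFit
    within_1se: dict[str, bool]
    all_within_1se: bool


def sensitivity_c0(features_all: pd.DataFrame, features_c0: pd.DataFrame,
                   concentration_col: str = "concentration",
                   rb_col: str = "R_b") -> SensitivityReport:
    """Quantify how much calibration depends on the off-center points.

    Both tables need a concentration column and an R_b column; rows of
    ``features_all`` cover all sampling points (9 per concentration in the
    standard design) and ``features_c0`` only the beaker center (3 per
    concentration). Reports per-concentration mean R_b for both designs,
    their Pearson correlation, both Langmuir fits, and whether every
    center-only parameter lies within one standard error of the all-points
    estimate.
    """
    mean_all = features_all.groupby(concentration_col)[rb_col].mean()
    mean_c0 = features_c0.groupby(concentration_col)[rb_col].mean()
    if not mean_all.index.equals(mean_c0.index):
        raise ValueError("the two designs cover different concentration sets")
    r = float(stats.pearsonr(mean_all.to_numpy(), mean_c0.to_numpy())[0])
    fit_all = fit("langmuir", mean_all.index.to_numpy(float),
                  mean_all.to_numpy())
    fit_c0 = fit("langmuir", mean_c0.index.to_numpy(float),
                 mean_c0.to_numpy())
    within = {}
    for i, name in enumerate(fit_all.model.param_names):
        se = fit_all.se[i]
        within[name] = bool(abs(fit_c0.params[i] - fit_all.params[i])
                            <= (se if np.isfinite(se) else math.inf))
    return SensitivityReport(mean_all, mean_c0, r, fit_all, fit_c0,
                             within, all(within.values()))
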