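"""Isotherm model fitting, model selection, and inverse calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from ramanmp import isotherm as iso
from ramanmp.simulate import paper_concentrations

C13 = paper_concentrations()
TRUE = dict(b1=0.85, b2=8.0, c=0.05)


def langmuir_y(C, b1=TRUE["b1"], b2=TRUE["b2"], c=TRUE["c"]):
    C = np.asarray(C, float)
    return b1 * b2 * C / (1 + b2 * C) + c


class TestPredict:
    def test_langmuir_half_coverage(self):
        m = iso.get_model("langmuir")
        assert m([1.0, 1.0, 0.0], 1.0) == pytest.approx(0.5)

    def test_all_models_return_offset_at_zero(self):
        at_zero = {
            "langmuir": [0.7, 5.0, 0.11],
            "freundlich": [0.7, 2.0, 0.11],
            "sips": [0.7, 5.0, 1.3, 0.11],
            "redlich_peterson": [0.7, 5.0, 1.3, 0.11],
            "dubinin_radushkevich": [0.7, 5.0, 0.11],
        }
        for name, params in at_zero.items():
            val = iso.get_model(name)(params, 0.0)
            assert val == pytest.approx(0.11), name

    def test_langmuir_saturates_at_b1_plus_c(self):
        m = iso.get_model("langmuir")
        assert m([0.85, 8.0, 0.05], 1e9) == pytest.approx(0.90, abs=1e-6)

    def test_langmuir_strictly_increasing_and_bounded(self):
        m = iso.get_model("langmuir")
        C = np.linspace(0, 5, 200)
        y = m([0.85, 8.0, 0.05], C)
        assert (np.diff(y) > 0).all()
        assert (y <= 0.90).all()

    def test_dr_finite_everywhere(self):
        m = iso.get_model("dubinin_radushkevich")
        y = m([0.8, 1.5, 0.05], np.array([0.0, 1e-9, 0.1, 1.0, 1e6]))
        assert np.all(np.isfinite(y))


class TestFit:
    def test_exact_linear_recovery(self):
        y = 0.5 * C13 + 0.1
        f = iso.fit("linear", C13, y)
        assert f.params == pytest.approx([0.5, 0.1], abs=1e-8)
        assert f.rss < 1e-12

    def test_noiseless_langmuir_recovery(self):
        f = iso.fit("langmuir", C13, langmuir_y(C13))
        assert f.params == pytest.approx([0.85, 8.0, 0.05], abs=1e-4)

    def test_optimum_confirmed_by_grid_search(self):
        """Coarse grid search around the optimum finds no lower RSS."""
        y = langmuir_y(C13)
        f = iso.fit("langmuir", C13, y)
        m = iso.get_model("langmuir")

        def rss(p):
            r = m(p, C13) - y
            return float(r @ r)

        best = rss(f.params)
        for b1 in np.linspace(0.5, 1.2, 8):
            for b2 in np.geomspace(1, 60, 8):
                for c in np.linspace(-0.1, 0.2, 7):
                    assert rss([b1, b2, c]) >= best - 1e-12

    def test_noisy_recovery_is_unbiased_enough(self):
        """Monte-Carlo: median |b1 error| stays small at sigma=0.1."""
        rng = np.random.default_rng(77)
        errs = []
        for _ in range(60):
            y = langmuir_y(C13) + rng.normal(0, 0.1, size=len(C13))
            f = iso.fit("langmuir", C13, y)
            errs.append(abs(f.params[0] - TRUE["b1"]))
        assert np.median(errs) < 0.15

    def test_rejects_degenerate_data(self):
        with pytest.raises(ValueError):
            iso.fit("langmuir", np.full(5, 0.3), np.ones(5))
        with pytest.raises(ValueError):
            iso.fit("langmuir", C13[:3], langmuir_y(C13[:3]))
        with pytest.raises(ValueError):
            iso.fit("langmuir", -C13, langmuir_y(C13))


class TestGoodness:
    @pytest.mark.parametrize("r2,p,expected", [
        (0.787, 2, 0.768),   # linear
        (0.886, 3, 0.863),   # langmuir
        (0.889, 4, 0.852),   # sips
        (0.888, 4, 0.851),   # redlich-peterson
        (0.880, 3, 0.856),   # dubinin-radushkevich
    ])
    def test_adjusted_r2_consistency(self, r2, p, expected):
        assert round(iso.adjusted_r2(r2, 13, p), 3) == expected

    def test_rmse_is_sqrt_mse(self):
        y = langmuir_y(C13) + np.sin(C13 * 20) * 0.01
        f = iso.fit("langmuir", C13, y)
        assert f.rmse == pytest.approx(math.sqrt(f.mse))
        assert f.r2_adj <= f.r2

    def test_perfect_fit_sentinel(self):
        g = iso.goodness(0.0, langmuir_y(C13), 13, 3)
        assert g["r2"] == pytest.approx(1.0)
        assert g["aic"] == -math.inf and g["bic"] == -math.inf


class TestCompareModels:
    def test_langmuir_data_beats_linear(self):
        table = iso.compare_models(C13, langmuir_y(C13),
                                   ["linear", "langmuir"])
        assert table.iloc[0]["model"] == "langmuir"

    def test_linear_data_keeps_linear_competitive(self):
        rng = np.random.default_rng(3)
        y = 0.5 * C13 + 0.1 + rng.normal(0, 0.02, len(C13))
        table = iso.compare_models(C13, y)
        aic_lin = float(table.set_index("model").loc["linear", "aic"])
        assert aic_lin <= table["aic"].min() + 2.0

    def test_all_seven_models_fit(self):
        rng = np.random.default_rng(8)
        y = langmuir_y(C13) + rng.normal(0, 0.05, len(C13))
        table = iso.compare_models(C13, y)
        assert set(table["model"]) == set(iso.MODELS)
        assert (table["aic"].diff().dropna() >= 0).all()  # sorted ascending

    def test_sips_nests_langmuir(self):
        rng = np.random.default_rng(15)
        y = langmuir_y(C13) + rng.normal(0, 0.05, len(C13))
        f_lang = iso.fit("langmuir", C13, y)
        f_sips = iso.fit("sips", C13, y)
        assert f_sips.rss <= f_lang.rss + 1e-6


def make_curve(noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    y = langmuir_y(C13) + (rng.normal(0, noise, len(C13)) if noise else 0.0)
    return iso.CalibrationCurve(iso.fit("langmuir", C13, y))


class TestInversion:
    def test_round_trip(self):
        curve = make_curve()
        rb = float(curve.predict(0.47))
        assert curve.invert(rb).concentration == pytest.approx(0.47, abs=1e-10)

    def test_at_floor_returns_zero_with_flag(self):
        curve = make_curve()
        c = curve.params["c"]
        est = curve.invert(c)
        assert est.concentration == 0.0 and est.below_floor

    def test_saturation_raises(self):
        curve = make_curve()
        with pytest.raises(iso.SaturationError):
            curve.invert(curve.params["b1"] + curve.params["c"] + 0.01)

    def test_matches_root_finder(self):
        curve = make_curve()
        b1, b2, c = (curve.params[k] for k in ("b1", "b2", "c"))
        target = 0.475
        root = optimize.brentq(
            lambda C: b1 * b2 * C / (1 + b2 * C) + c - target, 0, 100)
        est = curve.invert(target)
        assert est.concentration == pytest.approx(root, abs=1e-9)
        assert est.concentration == pytest.approx(0.125, abs=1e-6)

    @settings(max_examples=60, deadline=None)
    @given(b1=st.floats(0.2, 2.0), b2=st.floats(0.5, 50.0),
           c=st.floats(-0.2, 0.2), frac=st.floats(0.01, 0.99))
    def test_invert_predict_identity_property(self, b1, b2, c, frac):
        m = iso.get_model("langmuir")
        C_true = frac * 0.94
        rb = float(m([b1, b2, c], C_true))
        u = rb - c
        if not (1e-9 < u < b1 - 1e-9):
            return
        C_back = u / (b2 * (b1 - u))
        assert C_back == pytest.approx(C_true, abs=1e-8, rel=1e-8)


class TestPredictionInterval:
    def test_band_contains_fitted_curve(self):
        curve = make_curve(noise=0.05, seed=4)
        band = iso.prediction_interval(curve, np.linspace(0, 0.94, 40))
        assert (band["lower"] < band["fit"]).all()
        assert (band["upper"] > band["fit"]).all()

    def test_band_narrowest_near_data_center(self):
        curve = make_curve(noise=0.05, seed=4)
        band = iso.prediction_interval(curve, np.linspace(0.0, 0.94, 95))
        width = band["upper"] - band["lower"]
        narrowest = band["C"].iloc[int(np.argmin(width))]
        assert 0.05 < narrowest < 0.9  # interior, not at the extremes

    def test_agrees_with_parametric_bootstrap(self):
        """Delta-method band edges track a parametric-bootstrap band."""
        curve = make_curve(noise=0.05, seed=4)
        f = curve.fit
        sigma = math.sqrt(f.mse)
        rng = np.random.default_rng(99)
        grid = np.linspace(0.05, 0.9, 9)
        sims = []
        for _ in range(400):
            yb = f.predict(f.C) + rng.normal(0, sigma, f.n)
            fb = iso.fit("langmuir", f.C, yb, init=f.params)
            sims.append(fb.predict(grid) + rng.normal(0, sigma, len(grid)))
        sims = np.array(sims)
        boot_lo = np.quantile(sims, 0.025, axis=0)
        boot_hi = np.quantile(sims, 0.975, axis=0)
        band = iso.prediction_interval(curve, grid)
        width = (band["upper"] - band["lower"]).to_numpy()
        disc = (np.abs(band["lower"] - boot_lo) + np.abs(band["upper"] - boot_hi)) / 2
        assert (disc / width).mean() < 0.10

    def test_inverse_interval_brackets_estimate(self):
        curve = make_curve(noise=0.05, seed=4)
        est = iso.invert_with_interval(curve, 0.5)
        lo, hi = est.interval
        assert lo <= est.concentration <= hi


class TestSensitivity:
    def _table(self, rng, points, noise):
        import pandas as pd
        rows = []
        for C in C13:
            for p in points:
                for m in (1, 2, 3):
                    rows.append({"concentration": C, "point_id": p,
                                 "repeat": m,
                                 "R_b": float(langmuir_y(C))
                                 + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_identical_tables_agree_perfectly(self, rng):
        tab = self._table(rng, ["C0"], 0.0)
        rep = iso.sensitivity_c0(tab, tab)
        assert rep.correlation == pytest.approx(1.0)
        assert rep.fit_all.params == pytest.approx(rep.fit_c0.params)
        assert rep.all_within_1se

    def test_center_only_estimates_track_full_design(self, rng):
        full = self._table(rng, ["C0", "C1", "C2"], 0.02)
        rep = iso.sensitivity_c0(full, full[full["point_id"] == "C0"])
        assert rep.correlation > 0.9

    def test_mismatched_designs_rejected(self, rng):
        full = self._table(rng, ["C0"], 0.01)
        other = full[full["concentration"] > 0.1]
        with pytest.raises(ValueError):
            iso.sensitivity_c0(full, other)
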