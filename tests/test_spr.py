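"""Steady-state SPR fitting: isotherm models, recovery, bias, constraints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from dimerfit import (
    DataError,
    FitError,
    SPRAffinityEstimator,
    TitrationSeries,
    apparent_kd_naive,
    fit_affinity,
    predict_response,
    r_squared,
)


def make_series(conc, resp, name="x"):
    return TitrationSeries(ligand=name, analyte=name, concentrations=conc, responses=resp)


def clean_series(model, kd, rmax, conc):
    return make_series(np.asarray(conc, float), predict_response(model, kd, rmax, conc))


class TestPredictResponse:
    @pytest.mark.parametrize("kd", [0.37, 14.0, 100.0])
    def test_halfway_landmarks(self, kd):
        assert predict_response("langmuir_1to1", kd, 100.0, kd) == pytest.approx(50.0)
        # a self-dimerizing analyte at C = K_D only reaches 1/3 occupancy
        assert predict_response("selfdimer_corrected", kd, 100.0, kd) == pytest.approx(
            100.0 / 3.0, rel=1e-12
        )

    def test_frozen_selfdimer_value(self):
        assert predict_response("selfdimer_corrected", 14.0, 100.0, 100.0) == pytest.approx(
            62.35345979031388, rel=1e-9
        )

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            predict_response("kinetic", 1.0, 100.0, 1.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        kd=st.floats(min_value=1e-2, max_value=1e3),
        rmax=st.floats(min_value=1.0, max_value=1e4),
        c=st.floats(min_value=1e-3, max_value=1e4),
        bump=st.floats(min_value=1.1, max_value=10.0),
        model=st.sampled_from(["langmuir_1to1", "selfdimer_corrected"]),
    )
    def test_monotone_in_conc_and_homogeneous_in_rmax(self, kd, rmax, c, bump, model):
        r = predict_response(model, kd, rmax, c)
        assert 0 <= r < rmax
        assert predict_response(model, kd, rmax, c * bump) > r
        assert predict_response(model, kd, rmax * bump, c) == pytest.approx(
            r * bump, rel=1e-12
        )


class TestRSquared:
    def test_landmarks(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert r_squared(obs, obs) == 1.0
        assert r_squared(obs, np.full(3, obs.mean())) == 0.0
        assert r_squared(obs, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            r_squared(np.ones(4), np.ones(4))


class TestFitAffinity:
    @pytest.mark.parametrize("model", ["langmuir_1to1", "selfdimer_corrected"])
    @pytest.mark.parametrize("kd,rmax", [(0.37, 100.0), (14.0, 80.0), (150.0, 500.0)])
    def test_noiseless_roundtrip(self, model, kd, rmax):
        conc = kd * 3.0 ** (np.arange(8) - 3.5)
        fit = fit_affinity(clean_series(model, kd, rmax, conc), model, n_boot=0)
        assert fit.kd_hat == pytest.approx(kd, rel=1e-6)
        assert fit.rmax_hat == pytest.approx(rmax, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_selfdimer_recovery(self):
        """Seeded self-dimer-corrected titration at the homodimer K_D: within 15%."""
        from dimerfit import gen_spr_titration, get_scenario

        spec = get_scenario("dip_eta_spr_selfdimer", seed=1)
        series = gen_spr_titration(spec)
        fit = fit_affinity(series, "selfdimer_corrected", n_boot=200, random_state=1)
        assert fit.kd_hat == pytest.approx(14.0, rel=0.15)
        assert fit.ci_low <= fit.kd_hat <= fit.ci_high

    def test_noisy_langmuir_recovery_strong_binder(self):
        """Seeded Langmuir titration at the strong heterodimer K_D: within 15%."""
        from dimerfit import gen_spr_titration, get_scenario

        spec = get_scenario("dpr6_dipa_langmuir", seed=1)
        fit = fit_affinity(gen_spr_titration(spec), "langmuir_1to1", n_boot=0)
        assert fit.kd_hat == pytest.approx(0.37, rel=0.15)

    def test_weak_binder_without_constraint_advises_rmax(self):
        conc = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        series = clean_series("langmuir_1to1", 5000.0, 400.0, conc)
        with pytest.raises(FitError, match="[Cc]onstrain"):
            fit_affinity(series, "langmuir_1to1", n_boot=0)

    def test_constrained_rmax_is_exact_and_enables_weak_fit(self):
        conc = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        series = clean_series("langmuir_1to1", 5000.0, 400.0, conc)
        fit = fit_affinity(series, "langmuir_1to1", rmax_constraint=400.0, n_boot=0)
        assert fit.rmax_hat == 400.0
        assert fit.rmax_constrained
        assert fit.kd_hat == pytest.approx(5000.0, rel=1e-6)

    def test_unreasonably_low_constraint_rejected(self):
        conc = np.array([1.0, 3.0, 10.0, 30.0])
        series = clean_series("langmuir_1to1", 1.0, 100.0, conc)
        with pytest.raises(DataError, match="rmax_constraint"):
            fit_affinity(series, rmax_constraint=10.0, n_boot=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            fit_affinity(
                make_series(np.array([1.0, 2, 4]), np.array([1.0, 2, 3])), n_boot=0
            )

    def test_constraint_reduces_kd_variance(self):
        """With the true Rmax supplied, K_D estimates scatter less (100 replicates)."""
        kd, rmax = 50.0, 100.0
        conc = 100.0 / 3.0 ** np.arange(8)
        clean = predict_response("langmuir_1to1", kd, rmax, conc)
        free, constrained = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            resp = clean * (1 + 0.02 * rng.standard_normal(8)) + 0.5 * rng.standard_normal(8)
            s = make_series(conc, resp)
            free.append(fit_affinity(s, n_boot=0).kd_hat)
            constrained.append(fit_affinity(s, rmax_constraint=rmax, n_boot=0).kd_hat)
        assert np.var(constrained) < np.var(free)


class TestNaiveLangmuirBias:
    def test_inflation_direction_noiseless(self):
        """Fitting plain Langmuir to self-dimer-corrected truth inflates K_D."""
        kd = 14.0
        conc = np.array([1.0, 3, 10, 30, 60, 100, 150, 200])
        series = clean_series("selfdimer_corrected", kd, 100.0, conc)
        naive = apparent_kd_naive(series)
        assert naive.model == "langmuir_1to1"
        assert naive.kd_hat > kd

    def test_inflation_ratio_matches_grid_search(self):
        """Cross-check the naive fit against profiled-Rmax grid minimisation."""
        kd = 14.0
        conc = np.array([1.0, 3, 10, 30, 60, 100, 150, 200])
        resp = predict_response("selfdimer_corrected", kd, 100.0, conc)
        naive = apparent_kd_naive(clean_series("selfdimer_corrected", kd, 100.0, conc))

        grid = np.geomspace(1.0, 500.0, 4000)
        sses = []
        for k in grid:
            shape = conc / (k + conc)
            rmax = float(resp @ shape / (shape @ shape))  # profiled optimum
            sses.append(float(np.sum((resp - rmax * shape) ** 2)))
        kd_grid = grid[int(np.argmin(sses))]
        assert naive.kd_hat == pytest.approx(kd_grid, rel=0.01)
        assert naive.kd_hat / kd > 1.0

    def test_saturating_limit_bounds_inflation(self):
        """When all concentrations are far above K_D the inflation stays bounded."""
        kd = 0.01
        conc = np.array([1.0, 3, 10, 30, 100, 300, 1000, 3000])
        naive = apparent_kd_naive(clean_series("selfdimer_corrected", kd, 100.0, conc))
        assert naive.kd_hat / kd < 50


class TestEstimatorInterface:
    def test_sklearn_params_and_clone(self):
        est = SPRAffinityEstimator(model="selfdimer_corrected", n_boot=0)
        assert est.get_params()["model"] == "selfdimer_corrected"
        est2 = clone(est).set_params(rmax_constraint=50.0)
        assert est2.rmax_constraint == 50.0

    def test_fit_predict_shapes(self):
        conc = 14.0 * 3.0 ** (np.arange(8) - 3.5)
        y = predict_response("langmuir_1to1", 14.0, 100.0, conc)
        est = SPRAffinityEstimator(n_boot=0).fit(conc.reshape(-1, 1), y)
        pred = est.predict(conc.reshape(-1, 1))
        assert pred.shape == (8,)
        assert np.allclose(pred, y, rtol=1e-6)
        assert est.kd_ == pytest.approx(14.0, rel=1e-6)

    def test_predict_before_fit_raises(self):
        with pytest.raises(FitError):
            SPRAffinityEstimator().predict(np.array([1.0]))
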