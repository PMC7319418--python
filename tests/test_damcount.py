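import numpy as np
import pandas as pd
import pytest

from damcap.damcount import (
    ZINBFit,
    cross_validate,
    dispersion_test,
    fit_zinb,
    predict_catchment_dams,
)
from damcap.synthetic import simulate_reach_table


def _fit_data(n=1500, seed=0):
    return simulate_reach_table(n, seed=seed)


class TestDispersionTest:
    def test_constant_counts_defined_and_not_rejected(self):
        rng = np.random.default_rng(0)
        counts = np.full(200, 2.0)
        res = dispersion_test(counts, rng.uniform(0, 1, 200))
        assert not np.isnan(res.statistic)
        assert res.pvalue > 0.05

    def test_overdispersed_counts_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 2, 2000)
        mu = np.exp(-0.5 + 0.5 * x)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))  # alpha = 1
        res = dispersion_test(y, x)
        assert res.pvalue < 0.05
        assert res.alpha_hat > 0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            dispersion_test(np.zeros(100), np.ones(100))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            dispersion_test(np.ones(10), np.ones(10))


class TestZINBFit:
    def test_recovers_signs_and_significance(self):
        fit = fit_zinb(_fit_data(4000, seed=3))
        assert fit.count_params[1] > 0  # more capacity, more dams
        assert fit.infl_params[1] < 0  # more capacity, fewer structural zeros
        assert fit.count_pvalues[1] < 0.05
        assert fit.alpha > 0

    def test_comparison_table_has_all_models(self):
        fit = fit_zinb(_fit_data(800, seed=4))
        assert set(fit.comparison["model"]) == {"Poisson", "NB", "ZIP", "ZINB"}

    def test_zinb_likelihood_dominates_nb(self):
        fit = fit_zinb(_fit_data(2000, seed=5))
        nb_llf = float(fit.comparison.set_index("model").loc["NB", "llf"])
        assert fit.llf >= nb_llf - 1e-3  # NB is nested in the ZINB

    def test_too_few_reaches_rejected(self):
        with pytest.raises(ValueError):
            fit_zinb(_fit_data(30))

    def test_constant_covariate_rejected(self):
        df = _fit_data(200)
        df["max_dams"] = 1.0
        with pytest.raises(ValueError, match="vary"):
            fit_zinb(df)


class TestPrediction:
    def _manual_fit(self, count, infl, alpha=0.5):
        p = np.array(count, float)
        g = np.array(infl, float)
        return ZINBFit(
            count_params=p, infl_params=g, alpha=alpha, llf=0.0, aic=0.0,
            count_pvalues=np.zeros(2), infl_pvalues=np.zeros(2),
            conf_int=np.zeros((5, 2)), converged=True,
        )

    def test_closed_form_expectation_no_inflation(self):
        # pi == 0, mu == 0.5 for every reach -> 100 reaches expect 50 dams
        fit = self._manual_fit(count=[np.log(0.5), 0.0], infl=[-50.0, 0.0])
        reaches = pd.DataFrame(
            {"max_dams": np.ones(100), "category": "Rare", "length_m": 100.0}
        )
        res = predict_catchment_dams(fit, reaches, active_data=None, bootstrap_reps=0)
        assert res.total == pytest.approx(50.0, rel=1e-6)

    def test_saturating_zero_component_kills_predictions(self):
        fit = self._manual_fit(count=[0.0, 0.3], infl=[50.0, 0.0])
        reaches = pd.DataFrame(
            {"max_dams": np.zeros(50), "category": "None", "length_m": 100.0}
        )
        res = predict_catchment_dams(fit, reaches, active_data=None, bootstrap_reps=0)
        assert res.total == pytest.approx(0.0, abs=1e-9)

    def test_bootstrap_ci_brackets_point_estimate(self):
        data = _fit_data(600, seed=6)
        fit = fit_zinb(data, compare=False)
        reaches = data.assign(category="Occasional", length_m=120.0)
        res = predict_catchment_dams(
            fit, reaches, active_data=data, bootstrap_reps=30, seed=1
        )
        assert res.ci_low <= res.total <= res.ci_high
        assert res.density_per_km == pytest.approx(res.total / (600 * 0.12), rel=1e-6)

    def test_category_sums_equal_total(self):
        data = _fit_data(400, seed=7)
        fit = fit_zinb(data, compare=False)
        cats = np.where(data["max_dams"] > 1.5, "Frequent", "Occasional")
        reaches = data.assign(category=cats, length_m=100.0)
        res = predict_catchment_dams(fit, reaches, active_data=None, bootstrap_reps=0)
        assert res.by_category["expected_dams"].sum() == pytest.approx(res.total)


class TestCrossValidation:
    def test_deterministic_under_fixed_seed(self):
        data = _fit_data(400, seed=8)
        a = cross_validate(data, n_splits=1, n_percentile_subsets=20, seed=5)
        b = cross_validate(data, n_splits=1, n_percentile_subsets=20, seed=5)
        assert a.slope == b.slope and a.rmse == b.rmse and a.mae == b.mae

    def test_rmse_at_least_mae(self):
        data = _fit_data(500, seed=9)
        res = cross_validate(data, n_splits=3, n_percentile_subsets=25, seed=2)
        assert res.rmse >= res.mae >= 0

    def test_well_specified_model_slope_near_one(self):
        data = _fit_data(3000, seed=10)
        res = cross_validate(data, n_splits=8, n_percentile_subsets=40, seed=3)
        assert 0.9 <= res.slope <= 1.1

    def test_shuffled_covariate_loses_per_reach_signal(self):
        # random-subset *sums* track subset size, so even a no-signal model
        # predicts them; the discriminating negative control is per-reach
        # correlation between predictions and observations
        data = _fit_data(1500, seed=11)
        signal_fit = fit_zinb(data, compare=False)
        y = data["observed_dams"].to_numpy(float)
        rho_signal = np.corrcoef(signal_fit.predict_mean(data["max_dams"]), y)[0, 1]
        noise = data.copy()
        noise["max_dams"] = (
            noise["max_dams"].sample(frac=1.0, random_state=0).to_numpy()
        )
        null_fit = fit_zinb(noise, compare=False)
        rho_null = np.corrcoef(null_fit.predict_mean(noise["max_dams"]), y)[0, 1]
        assert rho_signal > 0.2
        assert abs(rho_null) < rho_signal / 2

    def test_too_few_reaches_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(_fit_data(60), n_splits=1)
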