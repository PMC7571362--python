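"""Ensemble cause-of-death machinery: enumeration, fitting, holdouts,
predictive validity and ensemble weighting."""

import numpy as np
import pandas as pd
import pytest

from microgbd import codem
from microgbd.errors import FitError, ValidationError


def _toy_observations(beta=(-5.0, 0.3), noise_sd=0.0, seed=0, n_years=12,
                      countries=("SR0_R0_C0", "SR0_R0_C1", "SR0_R1_C0", "SR1_R0_C0")):
    """Noise-free (or noisy) single-age observations from ln(rate)=b0+b1*x."""
    rng = np.random.default_rng(seed)
    rows = []
    for loc in countries:
        base = rng.normal()
        for t in range(n_years):
            rows.append((loc, 2000 + t, base + 0.1 * t + rng.normal(0, 0.2)))
    covs = pd.DataFrame(rows, columns=["location_id", "year", "x"])
    obs = covs[["location_id", "year"]].copy()
    obs["age_group_id"] = "all"
    obs["sex"] = "male"
    obs["cause_id"] = "toy"
    pop = 1e6
    rate = np.exp(beta[0] + beta[1] * covs["x"] + rng.normal(0, noise_sd, len(covs)))
    obs["deaths"] = rate * pop
    obs["sample_size"] = pop
    obs["source_type"] = "VR"
    return obs, covs


META = pd.DataFrame({
    "location_id": ["SR0_R0_C0", "SR0_R0_C1", "SR0_R1_C0", "SR1_R0_C0"],
    "region_id": ["SR0_R0", "SR0_R0", "SR0_R1", "SR1_R0"],
    "super_region_id": ["SR0", "SR0", "SR0", "SR1"],
})


class TestEnumeration:
    def test_two_covariates_both_families(self):
        specs = codem.enumerate_submodels(["a", "b"])
        assert len(specs) == 6          # (2^2 - 1) subsets x 2 families

    def test_single_covariate_single_family(self):
        specs = codem.enumerate_submodels(["a"], families=("ln_rate",))
        assert len(specs) == 1

    def test_cap_and_reproducible_order(self):
        covs = [f"c{i}" for i in range(10)]
        specs = codem.enumerate_submodels(covs, max_submodels=100)
        again = codem.enumerate_submodels(covs, max_submodels=100)
        assert len(specs) == 100
        assert specs == again

    def test_empty_covariates_rejected(self):
        with pytest.raises(ValidationError):
            codem.enumerate_submodels([])


class TestFitSubmodel:
    def test_noiseless_recovery(self):
        """With data generated exactly from the model, coefficients are
        recovered to numerical precision."""
        obs, covs = _toy_observations(beta=(-5.0, 0.3))
        spec = codem.SubmodelSpec("ln_rate", ("x",))
        fit = codem.fit_submodel(obs, covs, spec, META)
        assert fit.beta["x"] == pytest.approx(0.3, abs=1e-6)
        assert fit.beta["intercept"] == pytest.approx(-5.0, abs=1e-6)
        yhat = fit.predict_transform(obs)
        y = codem.transform_observations(obs, "ln_rate")
        assert np.abs(y - yhat).max() < 1e-6

    def test_constant_response_fits_its_mean(self):
        obs, covs = _toy_observations(beta=(-5.0, 0.0))
        spec = codem.SubmodelSpec("ln_rate", ("x",))
        fit = codem.fit_submodel(obs, covs, spec, META)
        assert fit.predict_transform(obs) == pytest.approx(-5.0, abs=1e-8)

    def test_duplicate_covariate_columns_raise(self):
        obs, covs = _toy_observations()
        covs = covs.copy()
        covs["x2"] = covs["x"]
        spec = codem.SubmodelSpec("ln_rate", ("x", "x2"))
        with pytest.raises(FitError, match="collinear"):
            codem.fit_submodel(obs, covs, spec, META)

    def test_all_zero_deaths_degenerate(self):
        obs, covs = _toy_observations()
        obs["deaths"] = 0.0
        spec = codem.SubmodelSpec("ln_rate", ("x",))
        with pytest.raises(codem.DegenerateDataError):
            codem.fit_submodel(obs, covs, spec, META)

    def test_cause_fraction_family_uses_envelope(self):
        obs, covs = _toy_observations()
        obs["envelope_deaths"] = obs["deaths"] * 4.0
        y = codem.transform_observations(obs, "logit_cause_fraction")
        cf = 1 / (1 + np.exp(-y))
        assert np.allclose(cf, 0.25)


class TestHoldouts:
    def test_holdout_sizes(self):
        obs, _ = _toy_observations(n_years=25)     # 100 obs, 1 per stratum
        plan = codem.make_holdouts(obs, fraction=0.2, repeats=3, seed=0)
        for mask in plan.masks:
            assert mask.sum() == 20

    def test_determinism(self):
        obs, _ = _toy_observations()
        a = codem.make_holdouts(obs, 0.2, 5, seed=7)
        b = codem.make_holdouts(obs, 0.2, 5, seed=7)
        assert all((x == y).all() for x, y in zip(a.masks, b.masks))

    def test_union_coverage(self):
        obs, _ = _toy_observations(n_years=25)
        plan = codem.make_holdouts(obs, 0.2, repeats=5, seed=3)
        assert plan.coverage() >= 0.60   # random 5x20% draws
        plan = codem.make_holdouts(obs, 0.2, repeats=30, seed=3)
        assert plan.coverage() >= 0.95

    @pytest.mark.parametrize("fraction", [0.0, 0.6, -0.1])
    def test_fraction_bounds(self, fraction):
        obs, _ = _toy_observations()
        with pytest.raises(ValidationError):
            codem.make_holdouts(obs, fraction, 1, 0)


class TestPredictiveValidity:
    def test_perfect_fit_has_zero_rmse_full_coverage(self):
        obs, covs = _toy_observations()
        spec = codem.SubmodelSpec("ln_rate", ("x",))
        fit = codem.fit_submodel(obs, covs, spec, META)
        plan = codem.make_holdouts(obs, 0.2, 3, seed=0)
        pv = codem.evaluate_predictive_validity(fit, plan)
        assert pv.rmse_out < 1e-6
        assert pv.coverage_out == 1.0

    def test_monotone_trend_fully_recovered(self):
        y = np.arange(10, dtype=float)
        obs = pd.DataFrame({
            "location_id": "L", "age_group_id": "all", "sex": "male",
            "cause_id": "toy", "year": np.arange(2000, 2010),
        })
        frac = codem._trend_fraction(obs, y, 2 * y + 1)
        assert frac == 1.0

    def test_trend_undefined_without_adjacent_years(self):
        obs = pd.DataFrame({
            "location_id": "L", "age_group_id": "all", "sex": "male",
            "cause_id": "toy", "year": [2000, 2005, 2010],
        })
        assert codem._trend_fraction(obs, np.ones(3), np.ones(3)) is None

    def test_in_sample_rmse_beats_out_of_sample_on_average(self):
        """Noise makes training error optimistic relative to held-out error."""
        diffs = []
        for rep in range(10):
            obs, covs = _toy_observations(noise_sd=0.3, seed=rep)
            spec = codem.SubmodelSpec("ln_rate", ("x",))
            fit = codem.fit_submodel(obs, covs, spec, META)
            plan = codem.make_holdouts(obs, 0.25, 4, seed=rep)
            pv = codem.evaluate_predictive_validity(fit, plan)
            diffs.append(pv.rmse_out - pv.rmse_in)
        assert np.mean(diffs) > 0


class TestEnsemble:
    def _fit(self):
        obs, covs = _toy_observations()
        return codem.fit_submodel(obs, covs, codem.SubmodelSpec("ln_rate", ("x",)), META)

    def _metrics(self, rmse_out, coverage_out=0.95):
        return codem.PVMetrics(rmse_in=rmse_out / 2, rmse_out=rmse_out,
                               trend_in=None, trend_out=None,
                               coverage_in=coverage_out, coverage_out=coverage_out)

    def test_single_submodel_weight_one(self):
        ens = codem.build_ensemble([self._fit()], [self._metrics(0.1)], psi=2.5)
        assert ens.weights == pytest.approx([1.0])

    def test_two_submodels_psi_two(self):
        fits = [self._fit(), self._fit()]
        metrics = [self._metrics(0.1), self._metrics(0.2)]
        ens = codem.build_ensemble(fits, metrics, psi=2.0)
        assert ens.weights == pytest.approx([2 / 3, 1 / 3])

    def test_psi_near_one_approaches_uniform(self):
        fits = [self._fit() for _ in range(3)]
        metrics = [self._metrics(r) for r in (0.1, 0.2, 0.3)]
        ens = codem.build_ensemble(fits, metrics, psi=1.0001)
        assert np.allclose(ens.weights, 1 / 3, atol=1e-4)

    def test_weight_order_matches_rmse_order(self):
        fits = [self._fit() for _ in range(3)]
        metrics = [self._metrics(r) for r in (0.3, 0.1, 0.2)]
        ens = codem.build_ensemble(fits, metrics, psi=2.5)
        assert ens.weights[1] > ens.weights[2] > ens.weights[0]

    def test_trimming_drops_clearly_worse_submodels(self):
        fits = [self._fit(), self._fit()]
        metrics = [self._metrics(0.01), self._metrics(0.5)]
        ens = codem.build_ensemble(fits, metrics, psi=2.0, trim_ratio=2.0)
        assert ens.weights == pytest.approx([1.0, 0.0])

    def test_missing_metrics_error(self):
        with pytest.raises(ValidationError):
            codem.build_ensemble([self._fit()], [], psi=2.0)


class TestPredictDraws:
    def test_zero_variance_draws_equal_point_prediction(self):
        obs, covs = _toy_observations()
        fit = codem.fit_submodel(obs, covs, codem.SubmodelSpec("ln_rate", ("x",)), META)
        assert fit.sigma2 < 1e-10
        ens = codem.EnsembleModel([fit], [None], np.array([1.0]), 2.5)
        draws = codem.predict_draws(ens, obs[["location_id", "year",
                                              "age_group_id", "sex"]], 5, seed=0)
        vals = draws[[c for c in draws.columns if c.startswith("draw_")]].to_numpy()
        point = np.exp(fit.predict_transform(obs))
        assert np.allclose(vals, point[:, None], rtol=1e-5)

    def test_same_seed_bit_identical(self):
        obs, covs = _toy_observations(noise_sd=0.2)
        fit = codem.fit_submodel(obs, covs, codem.SubmodelSpec("ln_rate", ("x",)), META)
        ens = codem.EnsembleModel([fit], [None], np.array([1.0]), 2.5)
        cells = obs[["location_id", "year", "age_group_id", "sex"]]
        a = codem.predict_draws(ens, cells, 10, seed=42)
        b = codem.predict_draws(ens, cells, 10, seed=42)
        assert a.equals(b)

    def test_draw_mean_near_point_prediction(self):
        obs, covs = _toy_observations(noise_sd=0.3, seed=5)
        fit = codem.fit_submodel(obs, covs, codem.SubmodelSpec("ln_rate", ("x",)), META)
        ens = codem.EnsembleModel([fit], [None], np.array([1.0]), 2.5)
        cells = obs[["location_id", "year", "age_group_id", "sex"]]
        draws = codem.predict_draws(ens, cells, 1000, seed=1)
        vals = draws[[c for c in draws.columns if c.startswith("draw_")]].to_numpy()
        # lognormal draw mean = point * exp(sigma2/2)
        expected = np.exp(fit.predict_transform(cells) + fit.sigma2 / 2)
        assert np.abs(vals.mean(axis=1) / expected - 1).max() < 0.1

    def test_minimum_two_draws(self):
        obs, covs = _toy_observations()
        fit = codem.fit_submodel(obs, covs, codem.SubmodelSpec("ln_rate", ("x",)), META)
        ens = codem.EnsembleModel([fit], [None], np.array([1.0]), 2.5)
        with pytest.raises(ValidationError):
            codem.predict_draws(ens, obs, 1, seed=0)
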