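"""Daily nest survival model: likelihood arithmetic, closed-form cumulative
survival, oracle equivalence and the imputation machinery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import turkeydem as td
from turkeydem.data import ValidationError
from turkeydem.nest import NestModelSpec
from turkeydem.priors import PriorSpec


def _nest(nest_id="n1", fate="depredated", n_days=4, **kw):
    y = np.ones(n_days, dtype=np.int8)
    if fate != "hatched":
        y[-1] = 0
    defaults = dict(
        nest_id=nest_id, hen_id="h1", year=2017, attempt=1, start_date=120,
        survival=y, fate=fate, cover_type="grassland", vor_mean=4.0,
        total_cover_mean=0.8, dist_road_m=100.0, x_m=0.0, y_m=0.0,
        precip_mm=np.zeros(n_days), temp_c=np.full(n_days, 15.0),
    )
    defaults.update(kw)
    return td.NestHistory(**defaults)


def _intercept_model(histories):
    return td.NestSurvivalModel(
        histories, covariates=["intercept"], random_effects="none"
    )


class TestDailyProbability:
    def test_reference_profile(self):
        x = np.zeros(11)
        x[0] = 1.0
        b = np.zeros(11)
        b[0] = 3.2
        assert td.nest_daily_probability(x, b) == pytest.approx(0.9608, abs=5e-4)

    def test_zero_coefficients_give_half(self):
        assert td.nest_daily_probability(np.ones(3), np.zeros(3)) == 0.5

    def test_adult_contrast(self):
        x = np.array([1.0, 1.0])
        b = np.array([3.2, 0.3])
        assert td.nest_daily_probability(x, b) == pytest.approx(0.9707, abs=5e-4)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            td.nest_daily_probability(np.ones(3), np.ones(2))


class TestLogLikelihood:
    def test_two_day_survivor_at_half(self):
        model = _intercept_model([_nest(fate="hatched", n_days=2)])
        assert model.log_likelihood(np.array([0.0])) == pytest.approx(np.log(0.25))

    def test_first_day_failure(self):
        model = _intercept_model([_nest(n_days=1)])
        b = np.array([logit(0.8)])
        assert model.log_likelihood(b) == pytest.approx(np.log(0.2))

    def test_additivity_over_nests(self):
        one = _intercept_model([_nest("a", n_days=5)])
        two = _intercept_model([_nest("a", n_days=5), _nest("b", n_days=5)])
        b = np.array([1.3])
        assert two.log_likelihood(b) == pytest.approx(2 * one.log_likelihood(b))

    def test_degenerate_probability_returns_neg_inf(self):
        # daily survival exactly 1 contradicting an observed failure: the
        # likelihood is -inf, never an exception
        model = _intercept_model([_nest(n_days=3)])  # ends in failure
        assert model.log_likelihood(np.array([np.inf])) == -np.inf

    def test_spec_state_with_imputed_values(self):
        h = _nest("m1", fate="hayed", vor_mean=None, total_cover_mean=None)
        model = td.NestSurvivalModel(
            [_nest("o1"), h],
            age_lookup={("h1", 2017): "yearling"},
        )
        J = len(model.coef_names)
        spec = NestModelSpec(
            coef_names=model.coef_names,
            mu=np.zeros(J), tau=np.ones(J),
            beta=np.zeros((2, J)),
            imputed={"vor": np.array([0.0]), "total_cover": np.array([0.0])},
        )
        spec.beta[:, 0] = 1.0
        ll = model.log_likelihood(spec)
        # 8 exposure days total: 3 survived + failure for each of two 4-day nests
        expected = 6 * np.log(expit(1.0)) + 2 * np.log(1 - expit(1.0))
        assert ll == pytest.approx(expected)


class TestCumulativeSurvival:
    def _results_with_constant_daily(self, p):
        model = _intercept_model([_nest(fate="hatched", n_days=28)])
        chains = np.full((2, 40, 1), logit(p) if 0 < p < 1 else 50.0)
        return td.NestSurvivalResults(
            model, td.PosteriorSummary(["intercept"], chains)
        )

    def test_certain_daily_survival(self):
        res = self._results_with_constant_daily(1.0)
        mean, lo, hi = res.cumulative_survival(horizon=28)
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_power_closed_form(self):
        res = self._results_with_constant_daily(0.97)
        mean, _, _ = res.cumulative_survival(horizon=28)
        assert mean == pytest.approx(0.97**28, abs=1e-9)
        assert 0.97**28 == pytest.approx(0.4262, abs=5e-5)

    def test_horizon_one_is_daily(self):
        res = self._results_with_constant_daily(0.9)
        mean, _, _ = res.cumulative_survival(horizon=1)
        daily, _, _ = res.daily_survival()
        assert mean == pytest.approx(daily)

    def test_monotone_in_horizon(self):
        res = self._results_with_constant_daily(0.93)
        vals = [res.cumulative_survival(horizon=h)[0] for h in (1, 7, 14, 28)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_bad_horizon(self):
        res = self._results_with_constant_daily(0.9)
        with pytest.raises(ValidationError):
            res.cumulative_survival(horizon=0)


class TestValidationRules:
    def test_censored_history_rejected(self):
        h = _nest(fate="censored_access")
        h.survival = np.ones(3, dtype=np.int8)
        with pytest.raises(ValidationError, match="censored"):
            td.NestSurvivalModel([h], covariates=["intercept"])

    def test_missing_distance_to_road_rejected(self):
        h = _nest()
        h.dist_road_m = np.nan
        with pytest.raises(ValidationError):
            td.NestSurvivalModel(
                [h], age_lookup={("h1", 2017): "adult"}
            )

    def test_adult_covariate_requires_age_lookup(self):
        with pytest.raises(ValidationError, match="age"):
            td.NestSurvivalModel([_nest()])


class TestOracleEquivalence:
    def test_intercept_only_matches_grid(self):
        # 100 exposure days with 95 survivals: 5 nests of 20 days each
        # ending in failure
        histories = [_nest(f"n{i}", n_days=20) for i in range(5)]
        model = _intercept_model(histories)
        prior = td.default_priors()[("nest_survival", "intercept")]
        res = model.fit(
            td.McmcConfig(n_chains=3, n_warmup=1500, n_samples=2500, seed=3)
        )

        def ll(b0):
            return 95.0 * b0 - 100.0 * np.logaddexp(0.0, b0)

        oracle = td.grid_posterior_oracle(ll, prior, np.linspace(-2, 8, 4001))
        mcse = res.posterior.mcse("intercept")
        assert abs(res.posterior.mean("intercept") - oracle["mean"]) < 3 * max(
            mcse, 0.01
        )

    def test_no_data_posterior_equals_prior(self):
        res = td.NestSurvivalModel([]).fit(
            td.McmcConfig(n_chains=2, n_warmup=200, n_samples=1500, seed=8,
                          max_doublings=0)
        )
        d = res.posterior.draws("intercept")
        assert stats.kstest(d, stats.norm(3.2, 0.3).cdf).statistic < 0.05
        t = res.posterior.draws("tau_intercept")
        assert stats.kstest(t, stats.gamma(1, scale=1).cdf).statistic < 0.05


class TestImputation:
    def test_imputed_values_track_truth_when_identified(self):
        # strong, homogeneous VOR effect and a fixed-effects fit: the
        # posterior means of imputed values must correlate with the deleted
        # measurements
        cfg = td.studylike_config(seed=42)
        cfg = dataclasses.replace(
            cfg, n_hens_per_year={2017: 400, 2018: 400},
            missing_vor_prob_hayed=0.0, missing_vor_prob_failed=0.0,
        )
        cfg.nest_coefs["vor"] = 1.0
        cfg.nest_random_sd = {k: 0.0 for k in cfg.nest_random_sd}
        study, _ = td.simulate_study(cfg)
        rng = np.random.default_rng(0)
        retained = td.build_nest_histories(study.nests)
        failed = [h for h in retained if h.failed]
        sel = rng.choice(len(failed), size=150, replace=False)
        true_vor = {}
        for k in sel:
            h = failed[k]
            true_vor[h.nest_id] = h.vor_mean
            h.vor_mean = None
            h.total_cover_mean = None
        ages = {(h.hen_id, h.year): h.age_class for h in study.hens}
        model = td.NestSurvivalModel(retained, age_lookup=ages, random_effects="none")
        res = model.fit(
            td.McmcConfig(n_chains=2, n_warmup=400, n_samples=400, seed=1,
                          max_doublings=0)
        )
        df = res.imputed_means("vor")
        truth_c = np.array(
            [true_vor[nid] - model.centers["vor"] for nid in df["nest_id"]]
        )
        r = np.corrcoef(truth_c, df["posterior_mean"].to_numpy())[0, 1]
        assert r > 0.2

    def test_missingness_restricted_to_failed_nests(self):
        h = _nest(fate="hatched", n_days=6, vor_mean=None)
        with pytest.raises(ValidationError):
            td.NestSurvivalModel([h], covariates=["intercept"])
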