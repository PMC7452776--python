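"""Poult survival: binomial-thinning marginalization, latent-state
enumeration equivalence, closed forms and directional recovery."""

import dataclasses
import itertools
from math import comb, log

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import turkeydem as td
from turkeydem.data import ValidationError
from turkeydem.poult import interval_count_logpmf


def _brood(brood_id="b1", n_initial=8, counts=None, death=None, year=2017,
           age="yearling"):
    return td.BroodSeries(
        brood_id=brood_id, hen_id="h1", year=year, hen_age_class=age,
        hatch_date=160, n_initial=n_initial,
        counts=counts if counts is not None else {8: 6, 15: 5, 29: 4},
        hen_death_day=death,
    )


class TestIntervalSurvival:
    def test_product(self):
        assert td.interval_survival([0.5, 0.5]) == 0.25
        assert td.interval_survival([0.9, 0.8, 0.7]) == pytest.approx(0.504)

    def test_empty_interval_is_identity(self):
        assert td.interval_survival([]) == 1.0

    def test_inserting_certain_day_leaves_survival_unchanged(self):
        phis = [0.9, 0.85, 0.7]
        assert td.interval_survival(phis + [1.0]) == pytest.approx(
            td.interval_survival(phis)
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            td.interval_survival([1.2])


class TestIntervalCountLogpmf:
    def test_two_day_half_survival_one_of_two(self):
        # q = 0.25; P(1 of 2) = 2 * 0.25 * 0.75 = 0.375
        assert np.exp(interval_count_logpmf(1, 2, [0.5, 0.5])) == pytest.approx(0.375)

    def test_two_day_half_survival_zero_of_two(self):
        assert np.exp(interval_count_logpmf(0, 2, [0.5, 0.5])) == pytest.approx(0.5625)

    def test_certain_interval(self):
        assert interval_count_logpmf(3, 3, [1.0, 1.0]) == 0.0
        assert interval_count_logpmf(2, 3, [1.0]) == -np.inf


class TestMarginalLikelihood:
    def test_matches_bruteforce_trajectory_sum(self):
        # single census at t = 8; enumerate every latent trajectory
        b = _brood(n_initial=3, counts={8: 1})
        model = td.PoultSurvivalModel([b], covariates=["intercept", "brood_age"])
        theta = np.array([1.2, 0.05])
        ages = np.arange(1, 29)
        phis = expit(1.2 + 0.05 * (ages - model.centers["brood_age"]))

        def pmf(k, n, p):
            return comb(n, k) * p**k * (1 - p) ** (n - k) if k <= n else 0.0

        total = 0.0
        for traj in itertools.product(range(4), repeat=6):
            seq = (3,) + traj + (1,)
            prob = 1.0
            for t in range(1, 8):
                if seq[t] > seq[t - 1]:
                    prob = 0.0
                    break
                prob *= pmf(seq[t], seq[t - 1], phis[t - 1])
            total += prob
        assert model.log_likelihood(theta) == pytest.approx(log(total), abs=1e-12)
        assert model.log_likelihood(theta, method="enumerate") == pytest.approx(
            log(total), abs=1e-12
        )

    def test_marginal_equals_enumeration_on_simulated_broods(self, medium_study):
        study, truth, _ = medium_study
        small = [b for b in study.broods if b.n_initial <= 5][:8]
        assert small, "fixture should contain small broods"
        model = td.PoultSurvivalModel(small)
        theta = np.array(
            [truth.coefficients["poult"][c] for c in model.coef_names]
        )
        a = model.log_likelihood(theta)
        b = model.log_likelihood(theta, method="enumerate")
        assert a == pytest.approx(b, abs=1e-10)

    def test_census_exceeding_previous_count_rejected(self):
        with pytest.raises(ValidationError):
            td.PoultSurvivalModel(
                [_brood(counts={8: 6, 15: 7, 29: 2})],
                covariates=["intercept"],
            )

    def test_hen_death_censuses_are_structural_zeros(self):
        # death on day 10: the t=15 and t=29 censuses carry no binomial term
        full = _brood("a", counts={8: 6})
        dead = _brood("b", counts={8: 6, 15: 0, 29: 0}, death=10)
        ma = td.PoultSurvivalModel([full], covariates=["intercept"])
        mb = td.PoultSurvivalModel([dead], covariates=["intercept"])
        theta = np.array([1.0])
        assert mb.log_likelihood(theta) == pytest.approx(ma.log_likelihood(theta))

    def test_module_level_wrapper(self):
        b = _brood(n_initial=2, counts={8: 1})
        val = td.poult_marginal_log_likelihood(
            [b], {"intercept": 2.0, "brood_age": 0.0}, covariates=["intercept", "brood_age"]
        )
        q = expit(2.0) ** 7
        assert val == pytest.approx(log(2 * q * (1 - q)))


class TestCumulativeSurvival:
    def _results_with_constant(self, theta_by_name):
        model = td.PoultSurvivalModel([_brood()], covariates=list(theta_by_name))
        chains = np.zeros((2, 30, len(theta_by_name)))
        for j, v in enumerate(theta_by_name.values()):
            chains[:, :, j] = v
        return td.PoultSurvivalResults(
            model, td.PosteriorSummary(list(theta_by_name), chains)
        )

    def test_zero_coefficients_power_of_half(self):
        res = self._results_with_constant({"intercept": 0.0})
        mean, _, _ = res.cumulative_survival()
        assert mean == pytest.approx(0.5**28, rel=1e-9)

    def test_certain_survival_limit(self):
        res = self._results_with_constant({"intercept": 20.0})
        mean, _, _ = res.cumulative_survival()
        assert mean == pytest.approx(1.0, abs=1e-6)

    def test_positive_age_slope_gives_increasing_daily_curve(self):
        res = self._results_with_constant({"intercept": 2.0, "brood_age": 0.1})
        curve = res.daily_survival_curve()
        assert curve["daily_survival"].is_monotonic_increasing


class TestFitting:
    def test_empty_data_posterior_equals_printed_prior(self):
        res = td.PoultSurvivalModel([]).fit(
            td.McmcConfig(n_chains=2, n_warmup=400, n_samples=1500, seed=9,
                          max_doublings=0)
        )
        d = res.posterior.draws("intercept")
        assert stats.kstest(d, stats.norm(3.4, 0.1).cdf).statistic < 0.05

    def test_intercept_only_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        phi = 0.93
        broods = []
        for i in range(12):
            n0 = 10
            n7 = rng.binomial(n0, phi**7)
            n14 = rng.binomial(n7, phi**7)
            n28 = rng.binomial(n14, phi**14)
            broods.append(_brood(f"b{i}", n_initial=n0, counts={8: n7, 15: n14, 29: n28}))
        prior = td.priors.PriorSpec("gaussian", (2.0, 2.0), "logit")
        priors = td.default_priors()
        priors[("poult", "intercept")] = prior
        model = td.PoultSurvivalModel(broods, priors=priors, covariates=["intercept"])
        res = model.fit(
            td.McmcConfig(n_chains=3, n_warmup=1500, n_samples=2500, seed=6)
        )
        oracle = td.grid_posterior_oracle(
            lambda b: model.log_likelihood(np.array([b])),
            prior,
            np.linspace(0.5, 5.0, 2001),
        )
        mcse = res.posterior.mcse("intercept")
        assert abs(res.posterior.mean("intercept") - oracle["mean"]) < 3 * max(
            mcse, 0.01
        )

    def test_all_zero_censuses_flagged_degenerate(self):
        broods = [_brood(f"b{i}", counts={8: 0, 15: 0, 29: 0}) for i in range(3)]
        res = td.PoultSurvivalModel(broods, covariates=["intercept"]).fit(
            td.McmcConfig(n_chains=2, n_warmup=200, n_samples=200, seed=1,
                          max_doublings=0)
        )
        assert res.notes and "degenerate" in res.notes[0]

    def test_positive_brood_age_effect_recovered_directionally(self):
        # generator has a positive age slope: posterior mass above zero
        hits = 0
        for seed in range(3):
            cfg = td.studylike_config(seed=60 + seed)
            cfg = dataclasses.replace(cfg, n_hens_per_year={2017: 120, 2018: 120})
            study, _ = td.simulate_study(cfg)
            res = td.PoultSurvivalModel.from_study(study).fit(
                td.McmcConfig(n_chains=2, n_warmup=400, n_samples=400, seed=seed,
                              max_doublings=0)
            )
            if np.mean(res.posterior.draws("brood_age") > 0) > 0.9:
                hits += 1
        assert hits >= 2
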