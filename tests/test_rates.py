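"""Scalar-rate GLMs: dataset eligibility, likelihoods against conjugate
oracles, no-data prior limits and parameter recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import turkeydem as td
from turkeydem.data import ValidationError
from turkeydem.priors import PriorSpec
from turkeydem.rates import RateDataset


def _empty_dataset(model, cols):
    return RateDataset(
        model, np.empty(0), pd.DataFrame(columns=cols),
        trials=np.empty(0) if model == "hatchability" else None,
    )


class TestEligibility:
    def test_hen_killed_on_first_nest_excluded_from_renesting(self, medium_study):
        study, _, _ = medium_study
        ds = td.build_rate_datasets(study)
        killed = {
            (n.hen_id, n.year)
            for n in study.nests
            if n.attempt == 1 and n.fate == "hen_died"
        }
        assert killed, "fixture should contain first-attempt hen deaths"
        # every renesting unit corresponds to a surviving first-attempt failure
        first_fail_surviving = [
            n for n in study.nests
            if n.attempt == 1 and n.failed and n.fate != "hen_died"
        ]
        assert ds["renesting"].n == len(first_fail_surviving)

    def test_unknown_clutch_excluded(self, medium_study):
        study, _, _ = medium_study
        ds = td.build_rate_datasets(study)
        known = [
            n for n in study.nests if not n.censored and n.clutch_size is not None
        ]
        assert ds["clutch"].n == len(known)
        assert len(known) < sum(1 for n in study.nests if not n.censored)

    def test_unavailable_hen_excluded_from_nesting(self, small_study):
        study, _, _ = small_study
        hens = [dataclasses.replace(h) for h in study.hens]
        hens[0].available_april1 = False
        study2 = td.StudyData(hens, study.nests, study.broods, study.stations)
        ds = td.build_rate_datasets(study2)
        assert ds["nesting"].n == len(hens) - 1

    def test_hatchability_units_are_hatched_nests(self, medium_study):
        study, _, _ = medium_study
        ds = td.build_rate_datasets(study)
        hatched = [
            n for n in study.nests
            if n.fate == "hatched" and n.clutch_size and n.eggs_hatched is not None
        ]
        assert ds["hatchability"].n == len(hatched)
        assert np.all(ds["hatchability"].response <= ds["hatchability"].trials)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValidationError):
            RateDataset(
                "hatchability", np.array([5.0]),
                pd.DataFrame({"adult": [0.0], "year": [0.0], "weight": [5.0]}),
                trials=np.array([3.0]),
            ).validate()


class TestOracleEquivalence:
    def test_bernoulli_seven_of_ten_matches_grid(self):
        near_flat = PriorSpec("gaussian", (0.0, 50.0), "logit")
        priors = td.default_priors()
        priors[("nesting", "intercept")] = near_flat
        ds = RateDataset(
            "nesting",
            np.array([1.0] * 7 + [0.0] * 3),
            pd.DataFrame({"adult": 0.0, "year": 0.0, "weight": [5.0] * 10}),
        )
        model = td.NestingRateModel(ds, priors=priors)
        # drop the other columns by fixing them at zero via the design:
        res = model.fit(td.McmcConfig(n_chains=3, n_warmup=1500, n_samples=2500, seed=4))
        grid = np.linspace(-6, 6, 3001)

        def ll(b0):
            return 7 * b0 - 10 * np.logaddexp(0.0, b0)

        oracle = td.grid_posterior_oracle(ll, near_flat, grid)
        mcse = res.posterior.mcse("intercept")
        assert abs(res.posterior.mean("intercept") - oracle["mean"]) < 3 * max(
            mcse, 0.01
        )

    def test_hatchability_beta_oracle(self):
        # one nest, 9 of 10 hatched, near-flat prior: Beta(10, 2) posterior
        near_flat = PriorSpec("gaussian", (0.0, 50.0), "logit")
        priors = td.default_priors()
        priors[("hatchability", "intercept")] = near_flat
        ds = RateDataset(
            "hatchability", np.array([9.0]),
            pd.DataFrame({"adult": [0.0], "year": [0.0], "weight": [5.0]}),
            trials=np.array([10.0]),
        )
        res = td.HatchabilityModel(ds, priors=priors).fit(
            td.McmcConfig(n_chains=3, n_warmup=1500, n_samples=2500, seed=5)
        )
        p = 1.0 / (1.0 + np.exp(-res.posterior.draws("intercept")))
        # Beta(10, 2) mean with the Jacobian-free flat-on-logit prior is the
        # grid oracle's mean of expit(b0)
        grid = np.linspace(-6, 8, 3001)

        def ll(b0):
            return 9 * b0 - 10 * np.logaddexp(0.0, b0)

        oracle = td.grid_posterior_oracle(ll, near_flat, grid)
        from scipy.special import expit

        oracle_p = np.trapezoid(expit(oracle["grid"]) * oracle["density"], oracle["grid"])
        assert np.mean(p) == pytest.approx(oracle_p, abs=0.02)


class TestNoDataPriorLimits:
    @pytest.mark.parametrize(
        "cls, model, cols, prior_params",
        [
            (td.NestingRateModel, "nesting", ["adult", "year", "weight"], (0.9, 0.2)),
            (td.RenestingRateModel, "renesting",
             ["adult", "year", "failure_date", "prev_duration", "weight"], (-0.7, 0.6)),
            (td.ClutchSizeModel, "clutch",
             ["adult", "year", "weight", "attempt_second"], (2.4, 0.4)),
            (td.HatchabilityModel, "hatchability", ["adult", "year", "weight"],
             (1.3, 0.9)),
        ],
    )
    def test_posterior_equals_prior(self, cls, model, cols, prior_params):
        ds = _empty_dataset(model, cols)
        res = cls(ds).fit(
            td.McmcConfig(n_chains=2, n_warmup=400, n_samples=1500, seed=6,
                          max_doublings=0)
        )
        draws = res.posterior.draws("intercept")
        ks = stats.kstest(draws, stats.norm(*prior_params).cdf).statistic
        assert ks < 0.05


class TestDerivedQuantities:
    def test_clutch_intercept_mean_identity(self):
        # intercept 2.4 and zero slopes: implied mean clutch e^2.4
        ds = _empty_dataset("clutch", ["adult", "year", "weight", "attempt_second"])
        model = td.ClutchSizeModel(ds)
        chains = np.zeros((2, 50, 5))
        chains[:, :, 0] = 2.4
        res = td.rates.RateResults(model, td.PosteriorSummary(model.coef_names, chains))
        mean, lo, hi = res.mean_clutch(adult=False)
        assert mean == pytest.approx(np.exp(2.4), abs=1e-9)
        assert np.exp(2.4) == pytest.approx(11.02, abs=0.01)

    def test_derived_rates_are_deterministic_transforms(self, small_study, quick_mcmc):
        study, _, _ = small_study
        ds = td.build_rate_datasets(study)
        res = td.NestingRateModel(ds["nesting"]).fit(quick_mcmc)
        a = res.rate_by_age()
        b = res.rate_by_age()
        pd.testing.assert_frame_equal(a, b)

    def test_effect_curve_monotone_in_positive_slope(self):
        ds = _empty_dataset("nesting", ["adult", "year", "weight"])
        model = td.NestingRateModel(ds)
        chains = np.zeros((2, 50, 4))
        chains[:, :, 0] = 0.9
        chains[:, :, 3] = 0.8  # weight slope
        res = td.rates.RateResults(model, td.PosteriorSummary(model.coef_names, chains))
        curve = res.effect_curve("weight", [4.0, 5.0, 6.0], adult=False)
        assert curve["estimate"].is_monotonic_increasing


class TestRecovery:
    def test_clutch_and_hatchability_recover_truth(self):
        cfg = td.studylike_config(seed=31)
        cfg = dataclasses.replace(cfg, n_hens_per_year={2017: 1400, 2018: 1400})
        study, truth = td.simulate_study(cfg)
        ds = td.build_rate_datasets(study)
        mc = td.McmcConfig(n_chains=2, n_warmup=500, n_samples=500, seed=1,
                           max_doublings=1)
        clutch = td.ClutchSizeModel(ds["clutch"]).fit(mc)
        mean, _, _ = clutch.mean_clutch(adult=False)
        assert mean == pytest.approx(10.5, abs=0.2)

        hatch = td.HatchabilityModel(ds["hatchability"]).fit(mc)
        rates = hatch.rate_by_age().set_index("age_class")["estimate"]
        assert rates["adult"] == pytest.approx(0.88, abs=0.02)
        assert rates["yearling"] == pytest.approx(0.87, abs=0.02)

    def test_renesting_coefficients_covered(self):
        cfg = td.studylike_config(seed=37)
        cfg = dataclasses.replace(cfg, n_hens_per_year={2017: 700, 2018: 700})
        study, truth = td.simulate_study(cfg)
        ds = td.build_rate_datasets(study)
        model = td.RenestingRateModel(ds["renesting"])
        res = model.fit(
            td.McmcConfig(n_chains=2, n_warmup=500, n_samples=500, seed=2,
                          max_doublings=1)
        )
        bt = dict(truth.coefficients["renesting"])
        bt["intercept"] = truth.intercept_at("renesting", model.centers)
        missed = []
        for name in model.coef_names:
            lo, hi = res.posterior.ci(name)
            if not lo <= bt[name] <= hi:
                missed.append(name)
        assert len(missed) <= 1, f"renesting CIs missed truth for {missed}"
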