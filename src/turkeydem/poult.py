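"""Poult survival: latent binomial-thinning count chain over 28 days.

The number of poults alive in brood *i* at day index *t* (hatch day is
t = 1) follows ``N_it ~ Binomial(N_i,t-1, phi_it)`` with a logit-linear
daily survival probability ``phi_it`` in brood age (days posthatch,
centered), hen age class, study year, precipitation, temperature and their
interaction.  Counts are observed only at the census indices t = 8, 15, 29
(7, 14 and 28 days posthatch); counts on other days are latent.

Because a composition of binomial thinnings is again a binomial thinning
with the product probability, the latent days marginalize exactly: each
census-to-census interval contributes a single binomial term with success
probability equal to the product of its daily survival probabilities.  The
fitter uses this marginal likelihood (identical to the data-augmented
latent-count formulation but with far better mixing); a forward-summation
evaluation over the latent counts is retained via ``method="enumerate"``
for cross-validation of the marginalization.

If the brood-rearing hen died on day *a* posthatch, every census at or
after *a* records a structural zero: those censuses carry no information
about poult survival and are excluded from the binomial product.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .data import CENSUS_INDICES, BroodSeries, StudyData, ValidationError
from .mcmc import McmcConfig, PosteriorSummary, credible_interval, run_mcmc
from .priors import MODEL_COEFFICIENTS, PriorSet, default_priors

__all__ = [
    "interval_survival",
    "interval_count_logpmf",
    "PoultSurvivalModel",
    "PoultSurvivalResults",
    "poult_marginal_log_likelihood",
    "fit_poult_survival",
    "cumulative_poult_survival",
]

_BROOD_DAYS = 28


def interval_survival(daily_phi: Sequence[float]) -> float:
    """Survival probability over an interval: the product of daily values.

    A composition of binomial thinnings with probabilities ``phi_t`` is a
    binomial thinning with probability ``prod(phi_t)``; the empty interval
    is the identity (probability 1).
    """
    phi = np.asarray(list(daily_phi), dtype=float)
    if phi.size == 0:
        return 1.0
    if np.any((phi < 0.0) | (phi > 1.0)):
        raise ValidationError("daily survival probabilities must lie in [0, 1]")
    return float(np.prod(phi))


def _log_binom_coef(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def interval_count_logpmf(k: int, n: int, daily_phi: Sequence[float]) -> float:
    """Log-probability of observing ``k`` of ``n`` poults after an interval.

    The census-to-census building block of the marginal likelihood:
    ``Binomial(k | n, q)`` with ``q = interval_survival(daily_phi)``.
    """
    if not 0 <= k <= n:
        raise ValidationError("count must lie in 0..n")
    q = interval_survival(daily_phi)
    if q == 1.0:
        return 0.0 if k == n else -np.inf
    if q == 0.0:
        return 0.0 if k == 0 else -np.inf
    return float(
        _log_binom_coef(np.float64(n), np.float64(k))
        + k * np.log(q)
        + (n - k) * np.log1p(-q)
    )


class PoultSurvivalModel:
    """Marginalized state-space model for brood counts.

    Parameters
    ----------
    broods : sequence of BroodSeries
        With daily weather attached when weather covariates are used.
    priors : PriorSet, optional
    covariates : sequence of str, optional
        Subset of the coefficient list, ``intercept`` first (default: all).
    """

    model_name = "poult"

    def __init__(
        self,
        broods: Sequence[BroodSeries],
        priors: PriorSet | None = None,
        covariates: Sequence[str] | None = None,
    ):
        self.priors = priors if priors is not None else default_priors()
        all_names = list(MODEL_COEFFICIENTS[self.model_name])
        covariates = list(covariates) if covariates is not None else all_names
        if not covariates or covariates[0] != "intercept":
            raise ValidationError("covariate list must start with 'intercept'")
        for name in covariates:
            if name not in all_names:
                raise ValidationError(f"unknown poult-survival covariate {name!r}")
        self.coef_names = covariates
        self.broods = list(broods)
        for b in self.broods:
            b.validate()
        self.centers: dict[str, float] = {}
        self._build_design()

    @classmethod
    def from_study(
        cls, study: StudyData, priors: PriorSet | None = None,
        covariates: Sequence[str] | None = None,
    ) -> "PoultSurvivalModel":
        return cls(study.broods, priors=priors, covariates=covariates)

    # ------------------------------------------------------------------
    def _build_design(self) -> None:
        names = self.coef_names
        needs_weather = any(n in names for n in ("precip", "temp", "precip_x_temp"))
        B = len(self.broods)
        # day-level rows: brood b, transition to day index t for t = 2..29,
        # i.e. brood ages a = t - 1 in 1..28
        ages = np.arange(1, _BROOD_DAYS + 1, dtype=float)
        precip_all, temp_all = [], []
        for b in self.broods:
            if needs_weather:
                if b.precip_mm is None or b.temp_c is None:
                    raise ValidationError(
                        f"brood {b.brood_id}: daily weather missing; attach station data"
                    )
                precip_all.append(np.asarray(b.precip_mm, dtype=float)[:_BROOD_DAYS])
                temp_all.append(np.asarray(b.temp_c, dtype=float)[:_BROOD_DAYS])
        D = B * _BROOD_DAYS
        precip_c = temp_c = np.empty(0)
        if needs_weather and B:
            precip = np.concatenate(precip_all)
            temp = np.concatenate(temp_all)
            self.centers["precip"] = float(np.mean(precip))
            self.centers["temp"] = float(np.mean(temp))
            precip_c = precip - self.centers["precip"]
            temp_c = temp - self.centers["temp"]
        if "brood_age" in names:
            self.centers["brood_age"] = float(np.mean(ages))
        years = sorted({b.year for b in self.broods})
        first_year = years[0] if years else 0

        X = np.zeros((D, len(names)))
        age_col = np.tile(ages - self.centers.get("brood_age", 0.0), B)
        for j, name in enumerate(names):
            if name == "intercept":
                X[:, j] = 1.0
            elif name == "brood_age":
                X[:, j] = age_col
            elif name == "adult":
                vals = np.array(
                    [float(b.hen_age_class == "adult") for b in self.broods]
                )
                X[:, j] = np.repeat(vals, _BROOD_DAYS)
            elif name == "year":
                vals = np.array([float(b.year != first_year) for b in self.broods])
                X[:, j] = np.repeat(vals, _BROOD_DAYS)
            elif name == "precip":
                X[:, j] = precip_c
            elif name == "temp":
                X[:, j] = temp_c
            elif name == "precip_x_temp":
                X[:, j] = precip_c * temp_c
        self.X = X

        # census intervals: for each brood, consecutive (t_prev, t_next,
        # n_prev, k_next) pairs with the closing census observed before any
        # hen death
        day_interval = np.full(D, -1, dtype=np.intp)  # interval id per day row
        n_prev, k_next, log_coef = [], [], []
        degenerate = True
        iid = 0
        for bi, b in enumerate(self.broods):
            t_prev, count_prev = 1, b.n_initial
            for t in CENSUS_INDICES:
                if t not in b.counts:
                    continue
                if b.hen_death_day is not None and (t - 1) >= b.hen_death_day:
                    continue  # structural zero: no binomial term
                k = b.counts[t]
                if k > count_prev:
                    raise ValidationError(
                        f"brood {b.brood_id}: census count exceeds previous count"
                    )
                # day rows for ages a = t_prev .. t-1 (transitions t_prev+1..t)
                row0 = bi * _BROOD_DAYS
                day_interval[row0 + (t_prev - 1): row0 + (t - 1)] = iid
                n_prev.append(count_prev)
                k_next.append(k)
                iid += 1
                if k > 0:
                    degenerate = False
                t_prev, count_prev = t, k
        self.day_interval = day_interval
        self.n_prev = np.asarray(n_prev, dtype=float)
        self.k_next = np.asarray(k_next, dtype=float)
        self.log_coef = _log_binom_coef(self.n_prev, self.k_next)
        self.n_intervals = iid
        self.degenerate_data = bool(self.broods) and degenerate
        self._active = day_interval >= 0

    # ------------------------------------------------------------------
    def log_likelihood(self, params: np.ndarray, method: str = "marginal") -> float:
        """Log-likelihood of the observed censuses.

        ``method="marginal"`` uses the exact binomial-thinning
        marginalization; ``method="enumerate"`` sums over the latent daily
        counts by forward recursion (identical value, kept for
        cross-validation).
        """
        if method == "enumerate":
            return self._log_likelihood_enumerate(params)
        if self.n_intervals == 0:
            return 0.0
        params = np.asarray(params, dtype=float)
        eta = self.X @ params
        with np.errstate(over="ignore"):
            log_phi = -np.logaddexp(0.0, -eta)
        log_q = np.bincount(
            self.day_interval[self._active],
            weights=log_phi[self._active],
            minlength=self.n_intervals,
        )
        q = np.exp(log_q)
        n, k = self.n_prev, self.k_next
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = self.log_coef + k * log_q + (n - k) * np.log1p(-q)
        # q == 1 with k == n is a point mass (term 0); q == 1 with k < n is
        # impossible (-inf)
        exact = q >= 1.0
        ll = np.where(exact & (k == n), self.log_coef, ll)
        ll = np.where(exact & (k < n), -np.inf, ll)
        return float(np.sum(ll))

    def _log_likelihood_enumerate(self, params: np.ndarray) -> float:
        """Forward summation over latent daily counts (data-augmented form
        with the latents integrated numerically)."""
        params = np.asarray(params, dtype=float)
        eta = self.X @ params
        phi = expit(eta)
        total = 0.0
        for bi, b in enumerate(self.broods):
            row0 = bi * _BROOD_DAYS
            # forward distribution over N_t, conditioning on censuses
            dist = np.zeros(b.n_initial + 1)
            dist[b.n_initial] = 1.0
            t = 1
            for t_census in CENSUS_INDICES:
                if t_census not in b.counts:
                    continue
                if b.hen_death_day is not None and (t_census - 1) >= b.hen_death_day:
                    continue
                while t < t_census:
                    p = phi[row0 + (t - 1)]
                    new = np.zeros_like(dist)
                    for n_now in range(dist.size):
                        if dist[n_now] == 0.0:
                            continue
                        for n_next in range(n_now + 1):
                            new[n_next] += dist[n_now] * _binom_pmf(n_next, n_now, p)
                    dist = new
                    t += 1
                k = b.counts[t_census]
                prob = dist[k] if k < dist.size else 0.0
                if prob <= 0.0:
                    return -np.inf
                total += float(np.log(prob))
                dist = np.zeros(b.n_initial + 1)
                dist[k] = 1.0
        return total

    # ------------------------------------------------------------------
    def _prior_specs(self):
        return [self.priors[(self.model_name, c)] for c in self.coef_names]

    def log_posterior(self, params: np.ndarray) -> float:
        lp = self.log_likelihood(params)
        for spec, val in zip(self._prior_specs(), params):
            lp += float(spec.logpdf(val))
        return lp

    def fit(self, mcmc: McmcConfig | None = None) -> "PoultSurvivalResults":
        """Sample the posterior over the regression coefficients (latent
        counts are marginalized exactly)."""
        mcmc = mcmc or McmcConfig()
        specs = self._prior_specs()

        def init_sampler(rng):
            return np.array([s.sample(rng) for s in specs])

        scales = np.array(
            [min(s.params[1], 1.0) if s.family in ("gaussian", "logistic") else 1.0
             for s in specs]
        )
        summary = run_mcmc(
            self.log_posterior, init_sampler, mcmc, self.coef_names,
            init_scales=scales,
        )
        return PoultSurvivalResults(self, summary)


def _binom_pmf(k: int, n: int, p: float) -> float:
    if k > n:
        return 0.0
    from math import comb

    return comb(n, k) * p**k * (1.0 - p) ** (n - k)


def poult_marginal_log_likelihood(
    broods: Sequence[BroodSeries],
    coefficients: np.ndarray | Mapping[str, float],
    covariates: Sequence[str] | None = None,
) -> float:
    """Marginal log-likelihood of brood censuses given coefficient values."""
    model = PoultSurvivalModel(broods, covariates=covariates)
    if isinstance(coefficients, Mapping):
        coefficients = np.array([coefficients[c] for c in model.coef_names])
    return model.log_likelihood(coefficients)


def fit_poult_survival(
    broods: Sequence[BroodSeries],
    priors: PriorSet | None = None,
    mcmc: McmcConfig | None = None,
    covariates: Sequence[str] | None = None,
) -> "PoultSurvivalResults":
    return PoultSurvivalModel(broods, priors=priors, covariates=covariates).fit(mcmc)


class PoultSurvivalResults:
    """Posterior results for the poult survival model."""

    def __init__(self, model: PoultSurvivalModel, posterior: PosteriorSummary):
        self.model = model
        self.posterior = posterior
        if model.degenerate_data:
            self.notes = ["all observed censuses were zero; data are degenerate"]
        else:
            self.notes = []

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    def summary(self) -> pd.DataFrame:
        return self.posterior.summary()

    def _trajectory_eta(self, profile: Mapping[str, object]) -> np.ndarray:
        names = self.model.coef_names
        draws = self.posterior.draws()
        ages = np.arange(1, _BROOD_DAYS + 1, dtype=float)
        x = np.zeros((_BROOD_DAYS, len(names)))
        age = profile.get("age_class", "yearling")
        for j, name in enumerate(names):
            if name == "intercept":
                x[:, j] = 1.0
            elif name == "brood_age":
                x[:, j] = ages - self.model.centers.get("brood_age", 0.0)
            elif name == "adult":
                x[:, j] = float(age == "adult")
            elif name == "year":
                x[:, j] = float(profile.get("year_contrast", 0.0))
            elif name in self.model.centers and name in profile:
                x[:, j] = float(profile[name]) - self.model.centers[name]
        return draws @ x.T  # (n_draws, 28)

    def daily_survival_curve(self, profile: Mapping[str, object] | None = None) -> pd.DataFrame:
        """Daily survival probability versus brood age (tabular analogue of
        the published age-effect figure)."""
        phi = expit(self._trajectory_eta(profile or {}))
        rows = []
        for a in range(_BROOD_DAYS):
            lo, hi = credible_interval(phi[:, a])
            rows.append(
                {"brood_age": a + 1, "daily_survival": float(np.mean(phi[:, a])),
                 "lower95": lo, "upper95": hi}
            )
        return pd.DataFrame(rows)

    def cumulative_survival(self, profile: Mapping[str, object] | None = None):
        """28-day posthatch survival: per draw, the product of daily
        survival along the brood-age trajectory, weather at sample means."""
        phi = expit(self._trajectory_eta(profile or {}))
        cum = np.prod(phi, axis=1)
        lo, hi = credible_interval(cum)
        return float(np.mean(cum)), lo, hi

    def survival_by_age(self) -> pd.DataFrame:
        rows = []
        for age in ("yearling", "adult"):
            mean, lo, hi = self.cumulative_survival({"age_class": age})
            rows.append(
                {"age_class": age, "estimate": mean, "lower95": lo, "upper95": hi}
            )
        return pd.DataFrame(rows)


def cumulative_poult_survival(
    results: PoultSurvivalResults, profile: Mapping[str, object] | None = None
):
    """Functional wrapper for :meth:`PoultSurvivalResults.cumulative_survival`."""
    return results.cumulative_survival(profile)
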