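"""Bayesian GLMs for the four scalar reproductive rates.

Nesting rate (hen-years available on 1 April; Bernoulli/logit), renesting
rate (first-attempt failures with surviving hens; Bernoulli/logit), clutch
size (nests with a known egg count; Poisson/log) and hatchability (successful
nests; Binomial/logit with clutch size as the denominator).  Each model is a
statsmodels-style class: construct from a :class:`~turkeydem.data.StudyData`
via ``from_study`` (or directly from a :class:`RateDataset`), call ``fit``
to obtain a :class:`RateResults` carrying posterior draws, summaries and the
derived age-class rates.

Continuous covariates (weight, failure date, previous incubation duration)
are mean-centered before fitting so the informative intercept priors —
elicited from overall published rates — apply at average covariate values.
Hen-years are treated as independent units, following the study design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .data import StudyData, ValidationError
from .mcmc import McmcConfig, PosteriorSummary, credible_interval, run_mcmc
from .priors import MODEL_COEFFICIENTS, PriorSet, default_priors

__all__ = [
    "RateDataset",
    "build_rate_datasets",
    "NestingRateModel",
    "RenestingRateModel",
    "ClutchSizeModel",
    "HatchabilityModel",
    "RateResults",
    "fit_bernoulli_rate",
    "fit_clutch_size",
    "fit_hatchability",
]

logger = logging.getLogger(__name__)

#: continuous covariates (centered at sample means) per model
_CONTINUOUS = {
    "nesting": ("weight",),
    "renesting": ("failure_date", "prev_duration", "weight"),
    "clutch": ("weight",),
    "hatchability": ("weight",),
}


@dataclass
class RateDataset:
    """Observational units for one scalar-rate model.

    ``response`` is the binary indicator (nesting/renesting), the clutch
    count (clutch) or the hatched-egg count (hatchability); ``trials`` is
    the clutch size for hatchability and None otherwise.  ``covariates``
    holds raw, uncentered values, one row per unit.
    """

    model: str
    response: np.ndarray
    covariates: pd.DataFrame
    trials: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.response.size)

    def validate(self) -> None:
        if self.model == "clutch" and self.n and np.any(self.response < 1):
            raise ValidationError("clutch counts must be >= 1")
        if self.model == "hatchability" and self.n:
            if np.any(self.trials <= 0):
                raise ValidationError("hatchability denominators must be > 0")
            if np.any(self.response > self.trials):
                raise ValidationError("hatched count exceeds clutch size")


def _hen_lookup(study: StudyData) -> dict[tuple[str, int], "object"]:
    return {(h.hen_id, h.year): h for h in study.hens}


def build_rate_datasets(study: StudyData) -> dict[str, RateDataset]:
    """Derive the four model datasets from the study tables.

    Eligibility rules: nesting units are hen-years available on 1 April with
    a known nesting outcome; renesting units are hens whose first attempt
    failed from a cause other than her own death (only first-to-second
    transitions); clutch units are non-censored attempts with a known egg
    count; hatchability units are hatched nests with known clutch and
    hatched-egg counts.
    """
    hens = _hen_lookup(study)
    years = sorted({h.year for h in study.hens} | {n.year for n in study.nests})
    first_year = years[0] if years else 0

    # nesting
    rows, resp = [], []
    for h in study.hens:
        if not h.available_april1 or h.nested is None:
            continue
        rows.append(
            {
                "adult": float(h.age_class == "adult"),
                "year": float(h.year != first_year),
                "weight": h.weight_kg,
            }
        )
        resp.append(float(h.nested))
    nesting = RateDataset(
        "nesting", np.asarray(resp), pd.DataFrame(rows, columns=["adult", "year", "weight"])
    )

    # group non-censored attempts by hen-year
    by_hen_year: dict[tuple[str, int], list] = {}
    for n in study.nests:
        if not n.censored:
            by_hen_year.setdefault((n.hen_id, n.year), []).append(n)

    rows, resp = [], []
    for (hen_id, year), attempts in sorted(by_hen_year.items()):
        attempts = sorted(attempts, key=lambda n: n.attempt)
        first = attempts[0]
        if first.attempt != 1 or not first.failed or first.fate == "hen_died":
            continue
        hen = hens.get((hen_id, year))
        if hen is None:
            continue
        renested = any(n.attempt == 2 for n in attempts)
        # a censored second attempt still proves renesting
        renested = renested or any(
            n.attempt == 2 and n.hen_id == hen_id and n.year == year
            for n in study.nests
        )
        rows.append(
            {
                "adult": float(hen.age_class == "adult"),
                "year": float(year != first_year),
                "failure_date": float(first.end_date),
                "prev_duration": float(first.n_days),
                "weight": hen.weight_kg,
            }
        )
        resp.append(float(renested))
    renesting = RateDataset(
        "renesting",
        np.asarray(resp),
        pd.DataFrame(
            rows, columns=["adult", "year", "failure_date", "prev_duration", "weight"]
        ),
    )

    # clutch
    rows, resp = [], []
    for n in study.nests:
        if n.censored or n.clutch_size is None:
            continue
        hen = hens.get((n.hen_id, n.year))
        if hen is None:
            continue
        rows.append(
            {
                "adult": float(hen.age_class == "adult"),
                "year": float(n.year != first_year),
                "weight": hen.weight_kg,
                "attempt_second": float(n.attempt >= 2),
            }
        )
        resp.append(float(n.clutch_size))
    clutch = RateDataset(
        "clutch",
        np.asarray(resp),
        pd.DataFrame(rows, columns=["adult", "year", "weight", "attempt_second"]),
    )

    # hatchability
    rows, resp, trials = [], [], []
    for n in study.nests:
        if n.fate != "hatched" or n.clutch_size is None or n.eggs_hatched is None:
            continue
        hen = hens.get((n.hen_id, n.year))
        if hen is None:
            continue
        rows.append(
            {
                "adult": float(hen.age_class == "adult"),
                "year": float(n.year != first_year),
                "weight": hen.weight_kg,
            }
        )
        resp.append(float(n.eggs_hatched))
        trials.append(float(n.clutch_size))
    hatchability = RateDataset(
        "hatchability",
        np.asarray(resp),
        pd.DataFrame(rows, columns=["adult", "year", "weight"]),
        trials=np.asarray(trials),
    )

    out = {
        "nesting": nesting,
        "renesting": renesting,
        "clutch": clutch,
        "hatchability": hatchability,
    }
    for ds in out.values():
        ds.validate()
    return out


class _ScalarRateModel:
    """Shared machinery for the four scalar-rate GLMs."""

    model_name: str = ""
    family: str = "bernoulli"  # bernoulli | binomial | poisson

    def __init__(self, dataset: RateDataset, priors: PriorSet | None = None):
        if dataset.model != self.model_name:
            raise ValidationError(
                f"dataset is for model {dataset.model!r}, expected {self.model_name!r}"
            )
        dataset.validate()
        self.dataset = dataset
        self.priors = priors if priors is not None else default_priors()
        self.coef_names = list(MODEL_COEFFICIENTS[self.model_name])
        self.centers: dict[str, float] = {}
        self._build_design()

    @classmethod
    def from_study(cls, study: StudyData, priors: PriorSet | None = None):
        return cls(build_rate_datasets(study)[cls.model_name], priors=priors)

    def _build_design(self) -> None:
        ds = self.dataset
        n = ds.n
        X = np.zeros((n, len(self.coef_names)))
        X[:, 0] = 1.0
        for j, name in enumerate(self.coef_names[1:], start=1):
            col = ds.covariates[name].to_numpy(dtype=float) if n else np.empty(0)
            if name in _CONTINUOUS.get(self.model_name, ()):
                mu = float(np.mean(col)) if n else 0.0
                self.centers[name] = mu
                col = col - mu
            X[:, j] = col
        self.exog = X
        self.endog = ds.response.astype(float)
        self.trials = None if ds.trials is None else ds.trials.astype(float)
        if self.family in ("bernoulli", "binomial") and n:
            frac = self.endog.sum() / (
                self.trials.sum() if self.trials is not None else n
            )
            if frac in (0.0, 1.0):
                logger.warning(
                    "%s: single response level observed; the prior dominates",
                    self.model_name,
                )

    # -- likelihood --------------------------------------------------------
    def log_likelihood(self, params: np.ndarray) -> float:
        if self.dataset.n == 0:
            return 0.0
        eta = self.exog @ params
        y = self.endog
        if self.family == "bernoulli":
            ll = y * eta - np.logaddexp(0.0, eta)
        elif self.family == "binomial":
            ntr = self.trials
            ll = (
                y * eta
                - ntr * np.logaddexp(0.0, eta)
                + gammaln(ntr + 1)
                - gammaln(y + 1)
                - gammaln(ntr - y + 1)
            )
        else:  # poisson
            ll = y * eta - np.exp(eta) - gammaln(y + 1)
        return float(np.sum(ll))

    def _prior_specs(self):
        return [self.priors[(self.model_name, c)] for c in self.coef_names]

    def log_posterior(self, params: np.ndarray) -> float:
        lp = self.log_likelihood(params)
        for spec, val in zip(self._prior_specs(), params):
            lp += float(spec.logpdf(val))
        return lp

    def fit(self, mcmc: McmcConfig | None = None) -> "RateResults":
        """Sample the posterior and return a results object."""
        mcmc = mcmc or McmcConfig()
        specs = self._prior_specs()

        def init_sampler(rng):
            return np.array([s.sample(rng) for s in specs])

        scales = np.array(
            [s.params[1] if s.family in ("gaussian", "logistic") else 1.0 for s in specs]
        )
        summary = run_mcmc(
            self.log_posterior, init_sampler, mcmc, self.coef_names,
            init_scales=np.minimum(scales, 1.0),
        )
        return RateResults(self, summary)


class NestingRateModel(_ScalarRateModel):
    """Probability a hen alive on 1 April initiates a nest (logit link)."""

    model_name = "nesting"
    family = "bernoulli"


class RenestingRateModel(_ScalarRateModel):
    """Probability of a second attempt given first-attempt failure."""

    model_name = "renesting"
    family = "bernoulli"


class ClutchSizeModel(_ScalarRateModel):
    """Poisson regression for eggs laid per nest (log link)."""

    model_name = "clutch"
    family = "poisson"


class HatchabilityModel(_ScalarRateModel):
    """Binomial logistic regression for eggs hatched of eggs laid."""

    model_name = "hatchability"
    family = "binomial"


class RateResults:
    """Posterior results for a scalar-rate model.

    Wraps the :class:`PosteriorSummary` and adds the derived quantities the
    study reports: age-class rates (probability or mean count) computed per
    draw at reference covariate values (centered covariates at zero, i.e.
    sample averages; first study year; first attempt), and effect-curve
    tables on natural covariate scales.
    """

    def __init__(self, model: _ScalarRateModel, posterior: PosteriorSummary):
        self.model = model
        self.posterior = posterior

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    def summary(self) -> pd.DataFrame:
        return self.posterior.summary()

    def _draw_matrix(self) -> np.ndarray:
        return self.posterior.draws()

    def _reference_eta(self, adult: bool, **indicators) -> np.ndarray:
        draws = self._draw_matrix()
        eta = draws[:, 0].copy()
        for j, name in enumerate(self.model.coef_names):
            if name == "adult" and adult:
                eta += draws[:, j]
            elif indicators.get(name):
                eta += draws[:, j]
        return eta

    def rate_by_age(self, level: float = 0.95) -> pd.DataFrame:
        """Derived rate for yearling and adult hens at reference covariates."""
        rows = []
        for age, adult in (("yearling", False), ("adult", True)):
            eta = self._reference_eta(adult)
            val = np.exp(eta) if self.model.family == "poisson" else expit(eta)
            lo, hi = credible_interval(val, level)
            rows.append(
                {"age_class": age, "estimate": float(np.mean(val)),
                 "lower95": lo, "upper95": hi}
            )
        return pd.DataFrame(rows)

    def mean_clutch(self, adult: bool = False, second_attempt: bool = False):
        """Posterior mean clutch size (Poisson mean) with 95% CI."""
        eta = self._reference_eta(adult, attempt_second=second_attempt)
        mu = np.exp(eta)
        lo, hi = credible_interval(mu)
        return float(np.mean(mu)), lo, hi

    def effect_curve(
        self, covariate: str, grid: Sequence[float], adult: bool = True
    ) -> pd.DataFrame:
        """Predicted rate over a natural-scale covariate grid, other
        covariates at reference.  Mirrors the published weight- and
        failure-date effect figures as a tidy table."""
        j = self.model.coef_names.index(covariate)
        center = self.model.centers.get(covariate, 0.0)
        draws = self._draw_matrix()
        base = self._reference_eta(adult)
        rows = []
        for value in grid:
            eta = base + draws[:, j] * (float(value) - center)
            val = np.exp(eta) if self.model.family == "poisson" else expit(eta)
            lo, hi = credible_interval(val)
            rows.append(
                {covariate: float(value), "estimate": float(np.mean(val)),
                 "lower95": lo, "upper95": hi}
            )
        return pd.DataFrame(rows)


# -- functional wrappers (spec operation names) -----------------------------

def fit_bernoulli_rate(
    dataset: RateDataset,
    model: str,
    priors: PriorSet | None = None,
    mcmc: McmcConfig | None = None,
) -> RateResults:
    """Fit the nesting or renesting logistic model."""
    cls = {"nesting": NestingRateModel, "renesting": RenestingRateModel}[model]
    return cls(dataset, priors=priors).fit(mcmc)


def fit_clutch_size(
    dataset: RateDataset,
    priors: PriorSet | None = None,
    mcmc: McmcConfig | None = None,
) -> RateResults:
    return ClutchSizeModel(dataset, priors=priors).fit(mcmc)


def fit_hatchability(
    dataset: RateDataset,
    priors: PriorSet | None = None,
    mcmc: McmcConfig | None = None,
) -> RateResults:
    return HatchabilityModel(dataset, priors=priors).fit(mcmc)
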