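"""Prior distributions for the six reproductive-rate models.

All regression models in this package are fitted with informative Gaussian
priors on the intercept and the adult log-odds-ratio (elicited from previously
published wild-turkey demographic rates) and weakly informative priors on
every other coefficient: logistic(0, 1) on logit-link coefficients,
Gaussian(0, 1) on log-link coefficients, and gamma(shape=1, rate=1) on the
precision hyperparameters of the nest-survival random-coefficients model.
:func:`default_priors` returns the canonical set; :func:`elicit_gaussian_prior`
implements the pooling procedure used to construct informative priors from
published point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy import stats

__all__ = ["PriorSpec", "PriorSet", "default_priors", "elicit_gaussian_prior"]

_FAMILIES = ("gaussian", "logistic", "gamma")
_LINKS = ("logit", "log", "identity")


@dataclass(frozen=True)
class PriorSpec:
    """One prior: a distribution family bound to a coefficient on a link scale.

    Parameters
    ----------
    family : {"gaussian", "logistic", "gamma"}
        ``gaussian(mean, sd)``, ``logistic(location, scale)`` or
        ``gamma(shape, rate)``.  Gamma priors bind precision parameters only.
    params : tuple of float
        The two family parameters, in the order above.
    link : {"logit", "log", "identity"}
        Scale on which the coefficient lives.
    role : str
        Which coefficient this prior binds (free-form label).
    """

    family: str
    params: tuple[float, float]
    link: str = "identity"
    role: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if self.params[1] <= 0:
            raise ValueError(
                f"{self.family} prior scale/rate must be > 0, got {self.params[1]}"
            )
        if self.family == "gamma" and self.params[0] <= 0:
            raise ValueError("gamma shape must be > 0")

    # -- distribution interface -------------------------------------------
    @property
    def _dist(self):
        a, b = self.params
        if self.family == "gaussian":
            return stats.norm(loc=a, scale=b)
        if self.family == "logistic":
            return stats.logistic(loc=a, scale=b)
        # gamma(shape, rate): scipy parameterizes by scale = 1/rate
        return stats.gamma(a, scale=1.0 / b)

    def logpdf(self, x):
        # direct formulas: cheap enough to sit inside MCMC inner loops
        x = np.asarray(x, dtype=float)
        a, b = self.params
        if self.family == "gaussian":
            out = -0.5 * ((x - a) / b) ** 2 - np.log(b) - 0.5 * np.log(2 * np.pi)
        elif self.family == "logistic":
            z = (x - a) / b
            out = -z - 2.0 * np.logaddexp(0.0, -z) - np.log(b)
        else:  # gamma(shape, rate)
            from scipy.special import gammaln

            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(
                    x > 0,
                    (a - 1.0) * np.log(np.where(x > 0, x, 1.0))
                    - b * x
                    + a * np.log(b)
                    - gammaln(a),
                    -np.inf,
                )
        return out if out.ndim else float(out)

    def cdf(self, x):
        return self._dist.cdf(x)

    def sample(self, rng: np.random.Generator, size=None):
        a, b = self.params
        if self.family == "gaussian":
            return rng.normal(a, b, size=size)
        if self.family == "logistic":
            u = rng.uniform(size=size)
            return a + b * np.log(u / (1.0 - u))
        return rng.gamma(a, scale=1.0 / b, size=size)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": [float(p) for p in self.params],
            "link": self.link,
            "role": self.role,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PriorSpec":
        return cls(
            family=d["family"],
            params=tuple(float(p) for p in d["params"]),
            link=d.get("link", "identity"),
            role=d.get("role", ""),
        )


def gaussian(mean: float, sd: float, link: str = "identity", role: str = "") -> PriorSpec:
    return PriorSpec("gaussian", (mean, sd), link, role)


def logistic(loc: float = 0.0, scale: float = 1.0, link: str = "logit", role: str = "") -> PriorSpec:
    return PriorSpec("logistic", (loc, scale), link, role)


def gamma(shape: float = 1.0, rate: float = 1.0, role: str = "") -> PriorSpec:
    return PriorSpec("gamma", (shape, rate), "identity", role)


class PriorSet:
    """Mapping from ``(model_name, coefficient_name)`` to :class:`PriorSpec`.

    Every coefficient of every model has exactly one prior; lookups of
    unknown keys raise ``KeyError`` naming the model and coefficient.
    """

    def __init__(self, priors: Mapping[tuple[str, str], PriorSpec] | None = None):
        self._priors: dict[tuple[str, str], PriorSpec] = dict(priors or {})

    def __getitem__(self, key: tuple[str, str]) -> PriorSpec:
        try:
            return self._priors[key]
        except KeyError:
            raise KeyError(
                f"no prior registered for model {key[0]!r}, coefficient {key[1]!r}"
            ) from None

    def __setitem__(self, key: tuple[str, str], spec: PriorSpec) -> None:
        self._priors[key] = spec

    def __contains__(self, key) -> bool:
        return key in self._priors

    def __iter__(self):
        return iter(self._priors)

    def __len__(self) -> int:
        return len(self._priors)

    def items(self):
        return self._priors.items()

    def for_model(self, model: str) -> dict[str, PriorSpec]:
        return {c: s for (m, c), s in self._priors.items() if m == model}

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path=None) -> str | None:
        payload = {
            f"{m}.{c}": spec.to_dict() for (m, c), spec in sorted(self._priors.items())
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "PriorSet":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        priors = {}
        for key, d in payload.items():
            model, coef = key.split(".", 1)
            priors[(model, coef)] = PriorSpec.from_dict(d)
        return cls(priors)

    def updated(self, other: "PriorSet") -> "PriorSet":
        merged = dict(self._priors)
        merged.update(other._priors)
        return PriorSet(merged)


#: Coefficient lists, in design-matrix order, for each model.
MODEL_COEFFICIENTS: dict[str, tuple[str, ...]] = {
    "nesting": ("intercept", "adult", "year", "weight"),
    "nest_survival": (
        "intercept",
        "adult",
        "precip",
        "temp",
        "precip_x_temp",
        "cover_forest",
        "cover_pasture",
        "cover_agriculture",
        "vor",
        "total_cover",
        "dist_road",
    ),
    "renesting": (
        "intercept",
        "adult",
        "year",
        "failure_date",
        "prev_duration",
        "weight",
    ),
    "clutch": ("intercept", "adult", "year", "weight", "attempt_second"),
    "hatchability": ("intercept", "adult", "year", "weight"),
    "poult": (
        "intercept",
        "brood_age",
        "adult",
        "year",
        "precip",
        "temp",
        "precip_x_temp",
    ),
}


def default_priors() -> PriorSet:
    """Canonical prior set for all six models.

    Informative Gaussian priors (elicited from published turkey demographic
    rates) bind the intercepts and most adult-contrast coefficients; the
    poult-survival adult contrast gets the weakly informative logistic(0, 1)
    because published poult-survival estimates rarely distinguish hen age.
    Nest-survival priors bind the population-level means of the random
    coefficients; their precisions get gamma(shape=1, rate=1).
    """
    ps = PriorSet()

    def fill_logistic(model: str, skip: Iterable[str]) -> None:
        for coef in MODEL_COEFFICIENTS[model]:
            if coef not in skip:
                ps[(model, coef)] = logistic(0.0, 1.0, "logit", coef)

    # nesting rate: logistic regression on hen-years available on 1 April
    ps[("nesting", "intercept")] = gaussian(0.9, 0.2, "logit", "intercept")
    ps[("nesting", "adult")] = gaussian(1.6, 0.8, "logit", "adult LOR")
    fill_logistic("nesting", {"intercept", "adult"})

    # daily nest survival: priors on population-level means mu_j
    ps[("nest_survival", "intercept")] = gaussian(3.2, 0.3, "logit", "intercept mean")
    ps[("nest_survival", "adult")] = gaussian(0.3, 0.4, "logit", "adult LOR mean")
    fill_logistic("nest_survival", {"intercept", "adult"})
    for coef in MODEL_COEFFICIENTS["nest_survival"]:
        ps[("nest_survival", f"tau_{coef}")] = gamma(1.0, 1.0, f"precision of {coef}")

    # renesting rate
    ps[("renesting", "intercept")] = gaussian(-0.7, 0.6, "logit", "intercept")
    ps[("renesting", "adult")] = gaussian(0.6, 0.7, "logit", "adult LOR")
    fill_logistic("renesting", {"intercept", "adult"})

    # clutch size: Poisson regression, log link
    ps[("clutch", "intercept")] = gaussian(2.4, 0.4, "log", "intercept")
    ps[("clutch", "adult")] = gaussian(0.0, 0.6, "log", "adult contrast")
    for coef in MODEL_COEFFICIENTS["clutch"]:
        if coef not in ("intercept", "adult"):
            ps[("clutch", coef)] = gaussian(0.0, 1.0, "log", coef)

    # hatchability: binomial logistic with clutch size as denominator
    ps[("hatchability", "intercept")] = gaussian(1.3, 0.9, "logit", "intercept")
    ps[("hatchability", "adult")] = gaussian(-0.2, 1.1, "logit", "adult LOR")
    fill_logistic("hatchability", {"intercept", "adult"})

    # daily poult survival
    ps[("poult", "intercept")] = gaussian(3.4, 0.1, "logit", "intercept")
    fill_logistic("poult", {"intercept"})

    return ps


def elicit_gaussian_prior(
    estimates: Iterable[float],
    link: str,
    sd_floor: float = 1.0,
    role: str = "",
) -> PriorSpec:
    """Pool published point estimates into a Gaussian prior on a link scale.

    Each estimate is transformed to the link scale (logit for probabilities,
    log for positive count means); the prior mean is the unweighted mean of
    the transformed values and the prior sd is their sample standard
    deviation (``ddof=1``).  With a single estimate the sd falls back to
    ``sd_floor``.

    Parameters
    ----------
    estimates : iterable of float
        Probabilities strictly in (0, 1) for ``link="logit"``, strictly
        positive means for ``link="log"``.
    link : {"logit", "log"}
    sd_floor : float
        Standard deviation used when only one estimate is supplied.
    """
    values = np.asarray(list(estimates), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one estimate")
    if link == "logit":
        if np.any((values <= 0.0) | (values >= 1.0)):
            raise ValueError("logit-link estimates must lie strictly in (0, 1)")
        z = np.log(values / (1.0 - values))
    elif link == "log":
        if np.any(values <= 0.0):
            raise ValueError("log-link estimates must be strictly positive")
        z = np.log(values)
    else:
        raise ValueError(f"elicitation supports logit or log links, got {link!r}")
    mean = float(np.mean(z))
    if values.size == 1:
        sd = float(sd_floor)
    else:
        sd = float(np.std(z, ddof=1))
        if sd < 1e-12:  # numerically identical estimates
            sd = float(sd_floor)
    return gaussian(mean, sd, link, role)
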