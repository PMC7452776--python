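"""Daily nest survival: hierarchical Bernoulli hazard model.

Survival of nest *i* on exposure day *t* is Bernoulli with daily probability
``p_it = logit^-1(x_it' beta_i)``; the survival vector is absorbing, so days
after the failure day contribute nothing.  Each coefficient ``beta_ji`` is a
Gaussian random variable with population mean ``mu_j`` and precision
``tau_j`` (precision = 1/variance), giving every nest its own coefficient
vector.  Covariates: hen age class, daily precipitation, daily temperature,
their interaction, land-cover contrasts versus grassland, mean visual
obstruction (VOR), mean total cover, and distance to the nearest road.
Continuous covariates are mean-centered; reference levels are yearling hens
and grassland cover.

Vegetation covariates (VOR, total cover) missing for nests hayed before
measurement are imputed inside the sampler: each such covariate gets a
Gaussian population model on the centered scale (mean ~ N(0, 10),
sd ~ Uniform(0, 10)) and the missing values are latent draws updated jointly
with the regression parameters.  Missingness is treated as ignorable given
fate.

The sampler is a blocked Metropolis-within-Gibbs scheme: per-nest
coefficients are updated column-wise with vectorized Metropolis steps across
nests (valid because nests are conditionally independent), population means
with conjugate Gaussian draws (or near-independence proposals under logistic
priors), and precisions with exact conjugate gamma draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import NestHistory, StudyData, ValidationError, build_nest_histories
from .mcmc import McmcConfig, PosteriorSummary, credible_interval, rhat
from .priors import MODEL_COEFFICIENTS, PriorSet, default_priors

__all__ = [
    "NestModelSpec",
    "NestSurvivalModel",
    "NestSurvivalResults",
    "nest_daily_probability",
    "nest_log_likelihood",
    "fit_nest_survival",
    "cumulative_nest_survival",
]

_IMPUTABLE = ("vor", "total_cover")
# imputation hyperpriors: mean ~ N(0, 10), sd ~ Uniform(0, 10) on the
# centered covariate scale
_IMP_MEAN_SD = 10.0
_IMP_SD_UPPER = 10.0


@dataclass
class NestModelSpec:
    """A full parameter state of the nest survival model.

    ``beta`` has one row per nest (coefficient order = ``coef_names``);
    ``mu``/``tau`` are the population-level means and precisions;
    ``imputed`` maps covariate name to the centered latent values filled in
    for nests with missing measurements.
    """

    coef_names: list[str]
    mu: np.ndarray
    tau: np.ndarray
    beta: np.ndarray
    imputed: dict[str, np.ndarray] = field(default_factory=dict)
    imputation_hyper: dict[str, tuple[float, float]] = field(default_factory=dict)


def nest_daily_probability(covariate_row: np.ndarray, coefficients: np.ndarray) -> float:
    """Daily survival probability ``logit^-1(x' beta)`` for one exposure day."""
    x = np.asarray(covariate_row, dtype=float)
    b = np.asarray(coefficients, dtype=float)
    if x.shape != b.shape:
        raise ValidationError(
            f"covariate row has {x.size} entries but coefficients {b.size}"
        )
    return float(expit(x @ b))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class NestSurvivalModel:
    """Hierarchical daily-survival model over retained nest histories.

    Parameters
    ----------
    histories : sequence of NestHistory
        Non-censored attempts with daily weather attached.  Censored
        attempts are rejected; use :func:`~turkeydem.data.build_nest_histories`
        first.
    age_lookup : mapping, optional
        ``(hen_id, year) -> age_class``; required when the ``adult``
        covariate is included.
    priors : PriorSet, optional
    covariates : sequence of str, optional
        Subset of the full covariate list (default: all).  Must include
        ``intercept`` first.
    random_effects : {"all", "intercept", "none"}
        Which coefficients vary by nest.  ``"all"`` follows the study's
        model statement; ``"intercept"`` restricts nest-level variation to
        the intercept; ``"none"`` is a fixed-effects logistic model.
    """

    model_name = "nest_survival"

    def __init__(
        self,
        histories: Sequence[NestHistory],
        age_lookup: Mapping[tuple[str, int], str] | None = None,
        priors: PriorSet | None = None,
        covariates: Sequence[str] | None = None,
        random_effects: str = "all",
    ):
        if random_effects not in ("all", "intercept", "none"):
            raise ValueError("random_effects must be 'all', 'intercept' or 'none'")
        self.random_effects = random_effects
        self.priors = priors if priors is not None else default_priors()
        all_names = list(MODEL_COEFFICIENTS[self.model_name])
        if covariates is None:
            covariates = all_names
        covariates = list(covariates)
        if covariates[0] != "intercept":
            raise ValidationError("covariate list must start with 'intercept'")
        for name in covariates:
            if name not in all_names:
                raise ValidationError(f"unknown nest-survival covariate {name!r}")
        self.coef_names = covariates
        self.histories = [h for h in histories]
        for h in self.histories:
            if h.censored:
                raise ValidationError(
                    f"nest {h.nest_id}: censored attempts must be excluded before fitting"
                )
            h.validate()
        self.age_lookup = dict(age_lookup or {})
        self.centers: dict[str, float] = {}
        self._build_design()

    @classmethod
    def from_study(
        cls,
        study: StudyData,
        priors: PriorSet | None = None,
        covariates: Sequence[str] | None = None,
        random_effects: str = "all",
    ) -> "NestSurvivalModel":
        retained = build_nest_histories(study.nests)
        ages = {(h.hen_id, h.year): h.age_class for h in study.hens}
        return cls(
            retained, age_lookup=ages, priors=priors, covariates=covariates,
            random_effects=random_effects,
        )

    # ------------------------------------------------------------------
    def _build_design(self) -> None:
        names = self.coef_names
        self.n_nests = len(self.histories)
        J = len(names)
        day_rows: list[np.ndarray] = []
        nest_idx: list[int] = []
        y_all: list[np.ndarray] = []

        needs_weather = any(n in names for n in ("precip", "temp", "precip_x_temp"))
        # nest-level covariate values (raw); NaN marks missing
        raw = {name: np.full(self.n_nests, np.nan) for name in ("vor", "total_cover", "dist_road")}
        adult = np.zeros(self.n_nests)
        for i, h in enumerate(self.histories):
            if "adult" in names:
                age = self.age_lookup.get((h.hen_id, h.year))
                if age is None:
                    raise ValidationError(
                        f"nest {h.nest_id}: hen age class unknown; supply age_lookup"
                    )
                adult[i] = float(age == "adult")
            if h.vor_mean is not None and not np.isnan(h.vor_mean):
                raw["vor"][i] = h.vor_mean
            if h.total_cover_mean is not None and not np.isnan(h.total_cover_mean):
                raw["total_cover"][i] = h.total_cover_mean
            raw["dist_road"][i] = h.dist_road_m
            if needs_weather and (h.precip_mm is None or h.temp_c is None):
                raise ValidationError(
                    f"nest {h.nest_id}: daily weather missing; attach station data"
                )

        if "dist_road" in names and np.any(np.isnan(raw["dist_road"])):
            raise ValidationError(
                "distance to road may not be missing for any nest"
            )

        # centers for nest-level continuous covariates (observed values only)
        for name in ("vor", "total_cover", "dist_road"):
            if name in names:
                obs = raw[name][~np.isnan(raw[name])]
                if obs.size == 0 and self.n_nests:
                    raise ValidationError(f"covariate {name!r} entirely missing")
                self.centers[name] = float(np.mean(obs)) if obs.size else 0.0

        # day-level rows
        precip_all, temp_all = [], []
        for i, h in enumerate(self.histories):
            d = h.n_days
            nest_idx.extend([i] * d)
            y_all.append(np.asarray(h.survival, dtype=float))
            if needs_weather:
                precip_all.append(np.asarray(h.precip_mm, dtype=float))
                temp_all.append(np.asarray(h.temp_c, dtype=float))
        self.nest_idx = np.asarray(nest_idx, dtype=np.intp)
        self.y = np.concatenate(y_all) if y_all else np.empty(0)
        D = self.y.size
        precip_c = temp_c = np.empty(0)
        if needs_weather and D:
            precip = np.concatenate(precip_all)
            temp = np.concatenate(temp_all)
            self.centers["precip"] = float(np.mean(precip))
            self.centers["temp"] = float(np.mean(temp))
            precip_c = precip - self.centers["precip"]
            temp_c = temp - self.centers["temp"]

        X = np.zeros((D, J))
        self._nest_level_col: dict[str, int] = {}
        for j, name in enumerate(names):
            if name == "intercept":
                X[:, j] = 1.0
            elif name == "adult":
                X[:, j] = adult[self.nest_idx]
            elif name == "precip":
                X[:, j] = precip_c
            elif name == "temp":
                X[:, j] = temp_c
            elif name == "precip_x_temp":
                X[:, j] = precip_c * temp_c
            elif name in ("cover_forest", "cover_pasture", "cover_agriculture"):
                level = name.split("_", 1)[1]
                vals = np.array(
                    [float(h.cover_type == level) for h in self.histories]
                )
                X[:, j] = vals[self.nest_idx]
            elif name in ("vor", "total_cover", "dist_road"):
                centered = raw[name] - self.centers[name]
                col = np.where(np.isnan(centered), 0.0, centered)
                X[:, j] = col[self.nest_idx]
                self._nest_level_col[name] = j

        self.X = X
        self._centered_nest_values = {
            name: raw[name] - self.centers[name]
            for name in ("vor", "total_cover")
            if name in names
        }
        self.missing: dict[str, np.ndarray] = {}
        for name in _IMPUTABLE:
            if name in names:
                idx = np.flatnonzero(np.isnan(raw[name]))
                if idx.size:
                    self.missing[name] = idx
        self._y_sign = 1.0 - 2.0 * self.y  # +1 for failure days, -1 for survivals

    # ------------------------------------------------------------------
    def log_likelihood(self, spec: NestModelSpec | np.ndarray) -> float:
        """Bernoulli log-likelihood over all nests and exposure days.

        ``spec`` may be a :class:`NestModelSpec` (per-nest coefficients,
        missing covariates replaced by the imputed values) or a single
        coefficient vector shared by every nest.  Degenerate probabilities
        contradicting an observation yield ``-inf``, never an exception.
        """
        if isinstance(spec, NestModelSpec):
            beta = np.asarray(spec.beta, dtype=float)
            X = self.X.copy()
            for name, values in spec.imputed.items():
                j = self._nest_level_col[name]
                col = X[:, j].copy()
                vals = np.asarray(values, dtype=float)
                for k, i in enumerate(self.missing.get(name, [])):
                    col[self.nest_idx == i] = vals[k]
                X[:, j] = col
        else:
            b = np.atleast_1d(np.asarray(spec, dtype=float))
            if b.ndim == 1:
                beta = np.broadcast_to(b, (max(self.n_nests, 1), b.size))
            else:
                beta = b
            X = self.X
        if self.y.size == 0:
            return 0.0
        eta = np.einsum("dj,dj->d", X, beta[self.nest_idx])
        with np.errstate(over="ignore"):
            ll = -_softplus(self._y_sign * eta)
        return float(np.sum(ll))

    # ------------------------------------------------------------------
    def fit(self, mcmc: McmcConfig | None = None) -> "NestSurvivalResults":
        """Run the blocked sampler and return results.

        Monitored parameters: population means (named by coefficient),
        precisions (``tau_<coef>``) for coefficients with nest-level
        variation, imputation hyperparameters, and the imputed covariate
        values themselves (``<cov>_missing_<nest_id>``).  Convergence
        (R-hat <= threshold after automatic doubling) is assessed on the
        population-level parameters.
        """
        mcmc = mcmc or McmcConfig()
        J = len(self.coef_names)
        if self.random_effects == "all":
            random_j = list(range(J))
        elif self.random_effects == "intercept":
            random_j = [0]
        else:
            random_j = []

        mon_names = list(self.coef_names)
        mon_names += [f"tau_{self.coef_names[j]}" for j in random_j]
        n_pop = len(mon_names)
        for name, idx in self.missing.items():
            mon_names += [f"{name}_pop_mean", f"{name}_pop_sd"]
            n_pop += 2
        for name, idx in self.missing.items():
            mon_names += [
                f"{name}_missing_{self.histories[i].nest_id}" for i in idx
            ]

        n_warmup, n_samples = mcmc.n_warmup, mcmc.n_samples
        root = np.random.SeedSequence(mcmc.seed)
        for attempt in range(mcmc.max_doublings + 1):
            ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(attempt,))
            seeds = ss.spawn(mcmc.n_chains)
            chains = np.empty((mcmc.n_chains, n_samples, len(mon_names)))
            for ci in range(mcmc.n_chains):
                chains[ci] = self._run_chain(
                    np.random.default_rng(seeds[ci]), random_j, n_warmup, n_samples
                )
            worst = max(rhat(chains[:, :, j]) for j in range(n_pop))
            if worst <= mcmc.rhat_threshold:
                return NestSurvivalResults(self, PosteriorSummary(mon_names, chains, True))
            n_warmup *= 2
            n_samples *= 2
        return NestSurvivalResults(self, PosteriorSummary(mon_names, chains, False))

    # ------------------------------------------------------------------
    def _prior(self, coef: str):
        return self.priors[(self.model_name, coef)]

    def _run_chain(self, rng, random_j, n_warmup, n_samples):
        J = len(self.coef_names)
        N = self.n_nests
        D = self.y.size
        X = self.X.copy()
        nest_idx = self.nest_idx
        y_sign = self._y_sign
        specs = [self._prior(c) for c in self.coef_names]
        tau_specs = {j: self._prior(f"tau_{self.coef_names[j]}") for j in random_j}

        # --- initial state: draws from the priors ---
        mu = np.array([s.sample(rng) for s in specs])
        tau = np.ones(J)
        for j in random_j:
            tau[j] = tau_specs[j].sample(rng)
        if N:
            beta = np.tile(mu, (N, 1))
            for j in random_j:
                sd = 1.0 / np.sqrt(tau[j])
                beta[:, j] = mu[j] + sd * rng.normal(size=N)
        else:
            beta = np.zeros((0, J))
        imp_vals = {}
        imp_hyper = {}
        for name, idx in self.missing.items():
            imp_vals[name] = rng.normal(0.0, 1.0, size=idx.size)
            imp_hyper[name] = [0.0, 1.0]
            j = self._nest_level_col[name]
            col_vals = np.zeros(N)
            col_vals[idx] = imp_vals[name]
            obs_mask = ~np.isnan(self._centered_nest_values[name])
            col_vals[obs_mask] = self._centered_nest_values[name][obs_mask]
            X[:, j] = col_vals[nest_idx]

        def nest_ll_from_eta(eta):
            with np.errstate(over="ignore"):
                ll_day = -_softplus(y_sign * eta)
            return np.bincount(nest_idx, weights=ll_day, minlength=N)

        if D:
            eta = np.einsum("dj,dj->d", X, beta[nest_idx])
            ll_nest = nest_ll_from_eta(eta)
        else:
            eta = np.empty(0)
            ll_nest = np.zeros(N)

        # proposal scales, adapted in warmup
        s_beta = np.full(J, 0.3)
        s_fixed = np.full(J, 0.2)
        s_shift = np.full(J, 0.2)
        acc_shift = np.zeros(J)
        s_miss = {name: 0.5 for name in self.missing}
        s_logsd = {name: 0.5 for name in self.missing}
        acc_beta = np.zeros(J)
        acc_fixed = np.zeros(J)
        acc_miss = {name: 0.0 for name in self.missing}
        acc_logsd = {name: 0.0 for name in self.missing}
        batch = 50

        fixed_j = [j for j in range(J) if j not in random_j]
        # which nests have any nonzero design entry per column
        informed_nests = {}
        for j in random_j:
            if D:
                nz = np.bincount(
                    nest_idx, weights=(X[:, j] != 0.0).astype(float), minlength=N
                )
                informed_nests[j] = nz > 0
            else:
                informed_nests[j] = np.zeros(N, dtype=bool)
        records = []

        total = n_warmup + n_samples
        for it in range(total):
            # -- per-nest coefficients, column-wise vectorized Metropolis --
            if N and D:
                for j in random_j:
                    informed = informed_nests[j]
                    # nests whose rows are all zero in this column carry no
                    # likelihood information: exact conjugate draw
                    n_uninf = N - informed.sum()
                    if n_uninf:
                        beta[~informed, j] = mu[j] + rng.normal(
                            size=n_uninf
                        ) / np.sqrt(tau[j])
                    if not informed.any():
                        continue
                    prop_sd = s_beta[j] / np.sqrt(tau[j])
                    delta = np.where(informed, rng.normal(0.0, prop_sd, size=N), 0.0)
                    eta_prop = eta + X[:, j] * delta[nest_idx]
                    ll_prop = nest_ll_from_eta(eta_prop)
                    b_old = beta[:, j]
                    b_new = b_old + delta
                    logr = (
                        ll_prop - ll_nest
                        - 0.5 * tau[j] * ((b_new - mu[j]) ** 2 - (b_old - mu[j]) ** 2)
                    )
                    acc = informed & (np.log(rng.uniform(size=N)) < logr)
                    if np.any(acc):
                        beta[acc, j] = b_new[acc]
                        eta = eta + X[:, j] * np.where(acc, delta, 0.0)[nest_idx]
                        ll_nest = np.where(acc, ll_prop, ll_nest)
                    acc_beta[j] += acc[informed].mean()

            # -- joint translation: shift mu_j and the whole beta column
            # together (breaks the slow tandem walk of the centered
            # parameterization under strong shrinkage) --
            if N and D:
                for j in random_j:
                    delta = rng.normal(0.0, s_shift[j])
                    eta_prop = eta + X[:, j] * delta
                    ll_prop = nest_ll_from_eta(eta_prop)
                    spec = specs[j]
                    logr = float(np.sum(ll_prop - ll_nest)) + float(
                        spec.logpdf(mu[j] + delta) - spec.logpdf(mu[j])
                    )
                    if np.log(rng.uniform()) < logr:
                        mu[j] += delta
                        beta[:, j] += delta
                        eta = eta_prop
                        ll_nest = ll_prop
                        acc_shift[j] += 1.0

            # -- population means --
            for j in random_j:
                spec = specs[j]
                if N == 0:
                    mu[j] = spec.sample(rng)
                    continue
                mean_l = beta[:, j].mean()
                prec_l = N * tau[j]
                if spec.family == "gaussian":
                    m0, s0 = spec.params
                    prec = prec_l + 1.0 / s0**2
                    mean = (prec_l * mean_l + m0 / s0**2) / prec
                    mu[j] = mean + rng.normal() / np.sqrt(prec)
                else:  # logistic prior: independence proposal from the
                    # Gaussian conditional of the hierarchy, prior-corrected
                    prop = mean_l + rng.normal() / np.sqrt(prec_l)
                    logr = float(spec.logpdf(prop) - spec.logpdf(mu[j]))
                    if np.log(rng.uniform()) < logr:
                        mu[j] = prop

            # -- fixed coefficients (shared across nests) --
            for j in fixed_j:
                spec = specs[j]
                if D == 0:
                    mu[j] = spec.sample(rng)
                    beta[:, j] = mu[j]
                    continue
                delta = rng.normal(0.0, s_fixed[j])
                eta_prop = eta + X[:, j] * delta
                ll_prop = nest_ll_from_eta(eta_prop)
                logr = (
                    float(np.sum(ll_prop - ll_nest))
                    + float(spec.logpdf(mu[j] + delta) - spec.logpdf(mu[j]))
                )
                if np.log(rng.uniform()) < logr:
                    mu[j] += delta
                    beta[:, j] = mu[j]
                    eta = eta_prop
                    ll_nest = ll_prop
                    acc_fixed[j] += 1.0

            # -- precisions: conjugate gamma --
            for j in random_j:
                shape0, rate0 = tau_specs[j].params
                resid = beta[:, j] - mu[j] if N else np.empty(0)
                shape = shape0 + 0.5 * N
                rate = rate0 + 0.5 * float(resid @ resid)
                tau[j] = rng.gamma(shape, 1.0 / rate)

            # -- missing covariates and their population models --
            for name, idx in self.missing.items():
                j = self._nest_level_col[name]
                hyp_m, hyp_s = imp_hyper[name]
                vals = imp_vals[name]
                if D:
                    delta = rng.normal(0.0, s_miss[name], size=idx.size)
                    dv_full = np.zeros(N)
                    dv_full[idx] = delta
                    coef_col = beta[:, j]
                    eta_prop = eta + coef_col[nest_idx] * dv_full[nest_idx]
                    ll_prop = nest_ll_from_eta(eta_prop)
                    new_vals = vals + delta
                    logr = (
                        (ll_prop - ll_nest)[idx]
                        - 0.5 * ((new_vals - hyp_m) ** 2 - (vals - hyp_m) ** 2) / hyp_s**2
                    )
                    acc = np.log(rng.uniform(size=idx.size)) < logr
                    if np.any(acc):
                        vals = np.where(acc, new_vals, vals)
                        imp_vals[name] = vals
                        dv_acc = np.zeros(N)
                        dv_acc[idx] = np.where(acc, delta, 0.0)
                        eta = eta + coef_col[nest_idx] * dv_acc[nest_idx]
                        X[:, j] = X[:, j] + dv_acc[nest_idx]
                        acc_idx = idx[acc]
                        ll_new = nest_ll_from_eta(eta)
                        ll_nest[acc_idx] = ll_new[acc_idx]
                    acc_miss[name] += acc.mean()
                # population model over observed + imputed centered values
                obs = self._centered_nest_values[name]
                z = obs.copy()
                z[idx] = imp_vals[name]
                z = z[~np.isnan(z)]
                n_z = z.size
                prec = n_z / hyp_s**2 + 1.0 / _IMP_MEAN_SD**2
                mean = (z.sum() / hyp_s**2) / prec
                hyp_m = mean + rng.normal() / np.sqrt(prec)
                # sd: random-walk on log scale, Uniform(0, upper) prior
                log_s = np.log(hyp_s)
                prop = log_s + rng.normal(0.0, s_logsd[name])
                sd_prop = np.exp(prop)
                if sd_prop < _IMP_SD_UPPER:
                    ssq = float(np.sum((z - hyp_m) ** 2))
                    logr = (
                        -n_z * (prop - log_s)
                        - 0.5 * ssq * (1.0 / sd_prop**2 - 1.0 / hyp_s**2)
                        + (prop - log_s)  # Jacobian of the log transform
                    )
                    if np.log(rng.uniform()) < logr:
                        hyp_s = sd_prop
                        acc_logsd[name] += 1.0
                imp_hyper[name] = [hyp_m, hyp_s]

            # -- warmup adaptation --
            if it < n_warmup and (it + 1) % batch == 0:
                s_beta *= np.exp(np.clip(acc_beta / batch - 0.44, -0.3, 0.3))
                s_fixed *= np.exp(np.clip(acc_fixed / batch - 0.44, -0.3, 0.3))
                s_shift *= np.exp(np.clip(acc_shift / batch - 0.44, -0.3, 0.3))
                acc_beta[:] = 0.0
                acc_fixed[:] = 0.0
                acc_shift[:] = 0.0
                for name in self.missing:
                    s_miss[name] *= np.exp(
                        np.clip(acc_miss[name] / batch - 0.44, -0.3, 0.3)
                    )
                    s_logsd[name] *= np.exp(
                        np.clip(acc_logsd[name] / batch - 0.44, -0.3, 0.3)
                    )
                    acc_miss[name] = 0.0
                    acc_logsd[name] = 0.0

            if it >= n_warmup:
                row = list(mu)
                row += [tau[j] for j in random_j]
                for name in self.missing:
                    row += list(imp_hyper[name])
                for name in self.missing:
                    row += list(imp_vals[name])
                records.append(row)

        return np.asarray(records)


def nest_log_likelihood(
    histories: Sequence[NestHistory],
    spec: NestModelSpec,
    age_lookup: Mapping[tuple[str, int], str] | None = None,
) -> float:
    """Module-level convenience wrapper around
    :meth:`NestSurvivalModel.log_likelihood`."""
    model = NestSurvivalModel(
        histories, age_lookup=age_lookup, covariates=spec.coef_names,
        random_effects="all",
    )
    return model.log_likelihood(spec)


def fit_nest_survival(
    histories: Sequence[NestHistory],
    priors: PriorSet | None = None,
    mcmc: McmcConfig | None = None,
    age_lookup: Mapping[tuple[str, int], str] | None = None,
    random_effects: str = "all",
) -> "NestSurvivalResults":
    model = NestSurvivalModel(
        histories, age_lookup=age_lookup, priors=priors, random_effects=random_effects
    )
    return model.fit(mcmc)


class NestSurvivalResults:
    """Posterior results for the nest survival model."""

    def __init__(self, model: NestSurvivalModel, posterior: PosteriorSummary):
        self.model = model
        self.posterior = posterior

    @property
    def converged(self) -> bool:
        return self.posterior.converged

    def summary(self) -> pd.DataFrame:
        return self.posterior.summary()

    def _profile_eta(self, profile: Mapping[str, object]) -> np.ndarray:
        """Linear predictor draws for a covariate profile, at the
        population-mean coefficients (a typical new nest: random effects at
        their logit-scale mean)."""
        names = self.model.coef_names
        draws = self.posterior.draws()[:, : len(names)]
        x = np.zeros(len(names))
        x[0] = 1.0
        cover = profile.get("cover_type", "grassland")
        age = profile.get("age_class", "yearling")
        for j, name in enumerate(names):
            if name == "adult":
                x[j] = float(age == "adult")
            elif name.startswith("cover_"):
                x[j] = float(cover == name.split("_", 1)[1])
            elif name in self.model.centers and name in profile:
                x[j] = float(profile[name]) - self.model.centers[name]
        return draws @ x

    def daily_survival(self, profile: Mapping[str, object] | None = None):
        """Posterior daily survival probability at a covariate profile."""
        p = expit(self._profile_eta(profile or {}))
        lo, hi = credible_interval(p)
        return float(np.mean(p)), lo, hi

    def cumulative_survival(
        self, profile: Mapping[str, object] | None = None, horizon: int = 28
    ):
        """Survival over ``horizon`` days (product of constant daily
        survival at the profile), with an equal-tailed 95% CI.

        Weather covariates default to their sample means; continuous
        covariates may be overridden with natural-scale values in
        ``profile``.
        """
        if horizon < 1:
            raise ValidationError("horizon must be >= 1")
        p = expit(self._profile_eta(profile or {}))
        cum = p**horizon
        lo, hi = credible_interval(cum)
        return float(np.mean(cum)), lo, hi

    def effect_curve(
        self,
        covariate: str,
        grid: Sequence[float],
        profile: Mapping[str, object] | None = None,
    ) -> pd.DataFrame:
        """Daily-survival effect curve over a natural-scale covariate grid
        (tabular analogue of the published effect figures)."""
        profile = dict(profile or {})
        rows = []
        for value in grid:
            profile[covariate] = float(value)
            mean, lo, hi = self.daily_survival(profile)
            rows.append(
                {covariate: float(value), "daily_survival": mean,
                 "lower95": lo, "upper95": hi}
            )
        return pd.DataFrame(rows)

    def imputed_means(self, covariate: str) -> pd.DataFrame:
        """Posterior means of imputed (centered) covariate values."""
        rows = []
        for i in self.model.missing.get(covariate, []):
            nest_id = self.model.histories[i].nest_id
            name = f"{covariate}_missing_{nest_id}"
            rows.append({"nest_id": nest_id, "posterior_mean": self.posterior.mean(name)})
        return pd.DataFrame(rows)


def cumulative_nest_survival(
    results: NestSurvivalResults,
    profile: Mapping[str, object] | None = None,
    horizon: int = 28,
):
    """Functional wrapper for :meth:`NestSurvivalResults.cumulative_survival`."""
    return results.cumulative_survival(profile, horizon)
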