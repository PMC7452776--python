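"""Model-agnostic posterior computation.

The sampler is a component-wise adaptive random-walk Metropolis algorithm:
each scalar parameter gets its own proposal scale, tuned during warmup to a
~0.44 acceptance rate (Robbins–Monro on the log scale in batches), then
frozen for the sampling phase.  Several independent chains are run from
independent prior draws; convergence is assessed with the split-chain
potential scale reduction factor (R-hat).  If any monitored R-hat exceeds the
threshold, warmup and sampling lengths are doubled and the run repeated, up
to ``max_doublings`` times; persistent non-convergence sets a flag on the
returned summary rather than passing silently.

A trapezoid-rule grid-integration oracle over one- or two-parameter models is
provided as an independent check on the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .priors import PriorSpec

__all__ = [
    "McmcConfig",
    "PosteriorSummary",
    "run_mcmc",
    "rhat",
    "credible_interval",
    "grid_posterior_oracle",
]


@dataclass(frozen=True)
class McmcConfig:
    """Settings for one MCMC run.

    ``n_chains`` must be at least 2 (R-hat needs between-chain information);
    ``max_doublings`` bounds the automatic continuation triggered by
    R-hat > ``rhat_threshold``.
    """

    n_chains: int = 3
    n_warmup: int = 2000
    n_samples: int = 2000
    seed: int = 0
    rhat_threshold: float = 1.1
    max_doublings: int = 2

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.rhat_threshold <= 1.0:
            raise ValueError("rhat_threshold must be > 1")
        if self.n_warmup < 1 or self.n_samples < 1:
            raise ValueError("n_warmup and n_samples must be positive")


class PosteriorSummary:
    """Posterior draws plus per-parameter summaries and diagnostics.

    Attributes
    ----------
    names : list of str
    chains : ndarray, shape (n_chains, n_draws, n_params)
        Post-warmup draws.
    converged : bool
        False when any monitored R-hat still exceeded the threshold after
        all automatic doublings.
    """

    def __init__(self, names: Sequence[str], chains: np.ndarray, converged: bool = True):
        chains = np.asarray(chains, dtype=float)
        if chains.ndim != 3:
            raise ValueError("chains must have shape (n_chains, n_draws, n_params)")
        if chains.shape[2] != len(names):
            raise ValueError("parameter-name count does not match chains")
        self.names = list(names)
        self.chains = chains
        self.converged = bool(converged)

    @property
    def n_params(self) -> int:
        return len(self.names)

    def draws(self, name: str | None = None) -> np.ndarray:
        """Pooled post-warmup draws: all chains concatenated."""
        flat = self.chains.reshape(-1, self.n_params)
        if name is None:
            return flat
        return flat[:, self.names.index(name)]

    def mean(self, name: str) -> float:
        return float(np.mean(self.draws(name)))

    def sd(self, name: str) -> float:
        return float(np.std(self.draws(name), ddof=1))

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        return credible_interval(self.draws(name), level)

    def rhat(self, name: str) -> float:
        return rhat(self.chains[:, :, self.names.index(name)])

    def mcse(self, name: str) -> float:
        """Crude Monte-Carlo standard error: sd / sqrt(ESS) with ESS from
        lag-autocorrelation of the pooled per-chain means (conservative:
        uses n_eff >= n_chains * n / (1 + 2 * sum of positive autocorr))."""
        x = self.chains[:, :, self.names.index(name)]
        n = x.shape[1]
        # initial positive sequence estimator on each chain, averaged
        ess_total = 0.0
        for c in range(x.shape[0]):
            xc = x[c] - x[c].mean()
            var = np.mean(xc * xc)
            if var == 0:
                ess_total += n
                continue
            rho_sum = 0.0
            for lag in range(1, min(n - 1, 200)):
                rho = np.mean(xc[:-lag] * xc[lag:]) / var
                if rho < 0.05:
                    break
                rho_sum += rho
            ess_total += n / (1.0 + 2.0 * rho_sum)
        return self.sd(name) / np.sqrt(max(ess_total, 1.0))

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            lo, hi = self.ci(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.mean(name),
                    "sd": self.sd(name),
                    "lower95": lo,
                    "upper95": hi,
                    "rhat": self.rhat(name),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary().to_csv(path, index=False)

    def to_json(self, path=None, include_draws: bool = False):
        import json

        payload = {
            "converged": self.converged,
            "parameters": self.summary().to_dict(orient="records"),
        }
        if include_draws:
            payload["draws"] = {
                name: self.chains[:, :, i].tolist() for i, name in enumerate(self.names)
            }
        text = json.dumps(payload)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman–Rubin).

    Each chain is split in half; R-hat compares between- and within-chain
    variance across the split halves.  Degenerate (zero-variance) draws
    return exactly 1 by convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("rhat requires >= 2 chains of equal length")
    if chains.shape[1] < 4:
        raise ValueError("chains must hold at least 4 draws each")
    n_half = chains.shape[1] // 2
    halves = np.concatenate(
        [chains[:, :n_half], chains[:, n_half : 2 * n_half]], axis=0
    )
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    scale = max(1.0, float(np.mean(chain_means) ** 2))
    if w <= 1e-12 * scale:  # degenerate draws
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(max(1.0, np.sqrt(var_hat / w)))


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from empirical quantiles.

    Uses the linear-interpolation quantile definition (numpy default).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValueError("need at least 2 draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _run_chain(
    log_posterior: Callable[[np.ndarray], float],
    init: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    init_scales: np.ndarray,
) -> np.ndarray:
    d = init.size
    x = init.astype(float).copy()
    lp = float(log_posterior(x))
    log_s = np.log(init_scales.astype(float))
    batch = 50
    accept = np.zeros(d)
    out = np.empty((n_samples, d))
    total = n_warmup + n_samples
    for it in range(total):
        # one sweep of component-wise Metropolis
        z = rng.normal(size=d)
        u = np.log(rng.uniform(size=d))
        for j in range(d):
            prop = x[j] + np.exp(log_s[j]) * z[j]
            old = x[j]
            x[j] = prop
            lp_prop = float(log_posterior(x))
            if lp_prop - lp > u[j]:
                lp = lp_prop
                accept[j] += 1
            else:
                x[j] = old
        if it < n_warmup and (it + 1) % batch == 0:
            rate = accept / batch
            log_s += np.clip(rate - 0.44, -0.3, 0.3)
            accept[:] = 0.0
        if it >= n_warmup:
            out[it - n_warmup] = x
    return out


def run_mcmc(
    log_posterior: Callable[[np.ndarray], float],
    init_sampler: Callable[[np.random.Generator], np.ndarray],
    config: McmcConfig,
    param_names: Sequence[str],
    init_scales: np.ndarray | None = None,
) -> PosteriorSummary:
    """Sample a posterior with multiple adaptive Metropolis chains.

    Parameters
    ----------
    log_posterior : callable
        Maps a parameter vector (ordered as ``param_names``) to an
        unnormalized log posterior density; may return ``-inf``.
    init_sampler : callable
        Maps an ``np.random.Generator`` to an initial parameter vector;
        chains start from independent draws (typically from the priors).
    config : McmcConfig
    param_names : sequence of str
        Names of the monitored parameters, in vector order.
    init_scales : ndarray, optional
        Initial per-parameter proposal standard deviations (default 1).

    Returns
    -------
    PosteriorSummary
        At least ``config.n_samples`` post-warmup draws per chain; the
        ``converged`` flag records whether every monitored R-hat reached
        the threshold, after automatic doubling of chain lengths up to
        ``config.max_doublings`` times.
    """
    d = len(param_names)
    if init_scales is None:
        init_scales = np.ones(d)
    n_warmup, n_samples = config.n_warmup, config.n_samples
    root_ss = np.random.SeedSequence(config.seed)
    for attempt in range(config.max_doublings + 1):
        attempt_ss = np.random.SeedSequence(
            entropy=root_ss.entropy, spawn_key=(attempt,)
        )
        chain_seeds = attempt_ss.spawn(config.n_chains)
        chains = np.empty((config.n_chains, n_samples, d))
        for c in range(config.n_chains):
            rng = np.random.default_rng(chain_seeds[c])
            init = None
            for _ in range(100):
                cand = np.atleast_1d(np.asarray(init_sampler(rng), dtype=float))
                if np.isfinite(log_posterior(cand)):
                    init = cand
                    break
            if init is None:
                raise RuntimeError(
                    "log posterior non-finite at every initialization drawn"
                )
            chains[c] = _run_chain(
                log_posterior, init, n_warmup, n_samples, rng, np.asarray(init_scales, float)
            )
        worst = max(rhat(chains[:, :, j]) for j in range(d))
        if worst <= config.rhat_threshold:
            return PosteriorSummary(param_names, chains, converged=True)
        n_warmup *= 2
        n_samples *= 2
    return PosteriorSummary(param_names, chains, converged=False)


def grid_posterior_oracle(
    log_likelihood: Callable,
    priors: PriorSpec | Sequence[PriorSpec],
    grids: np.ndarray | Sequence[np.ndarray],
):
    """Normalized posterior on a 1-D or 2-D grid by trapezoid integration.

    An independent oracle for small models: the posterior density is
    evaluated pointwise as ``exp(log_likelihood + log_prior)``, normalized by
    the trapezoid rule, and summarized by the posterior mean and equal-tailed
    95% interval of each parameter (from the interpolated marginal CDF).

    Returns a dict with keys ``grid``, ``density``, ``mean``, ``ci95``
    (scalars for 1-D, tuples/lists for 2-D marginals).
    """
    if isinstance(priors, PriorSpec):
        priors = [priors]
        grids = [np.asarray(grids, dtype=float)]
    else:
        priors = list(priors)
        grids = [np.asarray(g, dtype=float) for g in grids]
    if len(priors) not in (1, 2) or len(priors) != len(grids):
        raise ValueError("oracle supports 1 or 2 parameters with matching grids")

    if len(priors) == 1:
        (g,) = grids
        logpost = np.array(
            [log_likelihood(x) for x in g], dtype=float
        ) + priors[0].logpdf(g)
        if not np.any(np.isfinite(logpost)):
            raise ValueError("likelihood non-finite across the entire grid")
        if g.size == 1:
            return {"grid": g, "density": np.array([1.0]), "mean": float(g[0]),
                    "ci95": (float(g[0]), float(g[0]))}
        dens = np.exp(logpost - np.max(logpost[np.isfinite(logpost)]))
        dens[~np.isfinite(dens)] = 0.0
        z = np.trapezoid(dens, g)
        dens /= z
        mean = float(np.trapezoid(g * dens, g))
        lo, hi = _grid_interval(g, dens)
        return {"grid": g, "density": dens, "mean": mean, "ci95": (lo, hi)}

    g0, g1 = grids
    lp = np.empty((g0.size, g1.size))
    for i, a in enumerate(g0):
        for j, b in enumerate(g1):
            lp[i, j] = log_likelihood(a, b)
    lp += priors[0].logpdf(g0)[:, None] + priors[1].logpdf(g1)[None, :]
    if not np.any(np.isfinite(lp)):
        raise ValueError("likelihood non-finite across the entire grid")
    dens = np.exp(lp - np.max(lp[np.isfinite(lp)]))
    dens[~np.isfinite(dens)] = 0.0
    z = np.trapezoid(np.trapezoid(dens, g1, axis=1), g0)
    dens /= z
    marg0 = np.trapezoid(dens, g1, axis=1)
    marg1 = np.trapezoid(dens, g0, axis=0)
    means = [float(np.trapezoid(g0 * marg0, g0)), float(np.trapezoid(g1 * marg1, g1))]
    cis = [_grid_interval(g0, marg0), _grid_interval(g1, marg1)]
    return {"grid": grids, "density": dens, "mean": means, "ci95": cis}


def _grid_interval(g: np.ndarray, dens: np.ndarray, level: float = 0.95):
    """Equal-tailed interval from a gridded density via the trapezoid CDF."""
    if g.size == 1:
        return float(g[0]), float(g[0])
    cdf = np.concatenate(
        [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(g))]
    )
    cdf /= cdf[-1]
    alpha = (1.0 - level) / 2.0
    lo = float(np.interp(alpha, cdf, g))
    hi = float(np.interp(1.0 - alpha, cdf, g))
    return lo, hi
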