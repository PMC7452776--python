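"""Synthetic reproductive-demography studies with known ground truth.

The generator emulates a two-season VHF-telemetry study of wild turkey hens:
hen-years with an age/weight mixture, a station network recording daily
precipitation and temperature, Bernoulli nesting decisions, absorbing daily
Bernoulli nest survival with per-nest Gaussian random coefficients and
nearest-station weather, multinomial failure causes, renesting conditional on
first-attempt failure, Poisson clutches, binomial hatching, and a latent
binomial-thinning poult chain observed only at the 7/14/28-day censuses.

Every stochastic choice flows from a single seed, so a configuration fully
determines the output tables and the :class:`TruthRecord` that scores
parameter recovery downstream.

Weather model: daily temperature is a seasonal sinusoid plus AR(1) noise;
precipitation is an independent Bernoulli wet-day indicator times an
exponential amount.  Covariate effects in all six true models act on
centered scales, with the centering constants stored in the config (and
echoed in the TruthRecord) so fitted coefficients can be compared to truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .data import (
    CENSUS_INDICES,
    COVER_TYPES,
    FAILURE_FATES,
    BroodSeries,
    HenYear,
    NestHistory,
    StudyData,
    ValidationError,
    WeatherStation,
    attach_weather,
)

__all__ = ["GeneratorConfig", "TruthRecord", "simulate_study", "studylike_config"]

_INCUBATION_DAYS = 28
_BROOD_DAYS = 28


@dataclass
class GeneratorConfig:
    """Full parameterization of a simulated study.

    Coefficient dictionaries are on link scales (logit except the log-link
    clutch model) and act on covariates centered at the ``centers`` values.
    ``nest_random_sd`` holds the nest-level random-coefficient standard
    deviations of the daily nest survival model.
    """

    seed: int = 0
    years: tuple[int, ...] = (2017, 2018)
    n_hens_per_year: dict = field(default_factory=lambda: {2017: 76, 2018: 79})
    prop_adult: float = 0.5
    weight_mean_kg: dict = field(
        default_factory=lambda: {"yearling": 4.3, "adult": 5.1}
    )
    weight_sd_kg: float = 0.45

    # station network / weather model
    n_stations: int = 10
    extent_m: float = 60000.0
    season_start: int = 85
    season_end: int = 245
    temp_mean_c: float = 15.0
    temp_amplitude_c: float = 10.0
    temp_peak_doy: int = 200
    temp_ar1: float = 0.6
    temp_noise_sd: float = 3.0
    precip_wet_prob: float = 0.35
    precip_wet_mean_mm: float = 5.0

    # nesting phenology
    first_nest_mean_doy: float = 135.0
    first_nest_sd_days: float = 10.0
    renest_delay_mean_days: float = 9.0
    renest_delay_sd_days: float = 3.0
    max_attempts: int = 3

    # nest-site covariates
    cover_probs: dict = field(
        default_factory=lambda: {
            "grassland": 0.40,
            "pasture": 0.28,
            "agriculture": 0.22,
            "forest": 0.10,
        }
    )
    vor_mean: float = 4.0
    vor_sd: float = 1.5
    total_cover_mean: float = 0.75
    total_cover_sd: float = 0.15
    dist_road_mean_m: float = 250.0

    # true coefficient vectors (link scale, centered covariates)
    nesting_coefs: dict = field(default_factory=dict)
    nest_coefs: dict = field(default_factory=dict)
    nest_random_sd: dict = field(default_factory=dict)
    renesting_coefs: dict = field(default_factory=dict)
    clutch_coefs: dict = field(default_factory=dict)
    hatchability_coefs: dict = field(default_factory=dict)
    poult_coefs: dict = field(default_factory=dict)

    # failure-cause mix conditional on failure
    failure_cause_probs: dict = field(
        default_factory=lambda: {
            "abandoned": 0.09,
            "hen_died": 0.12,
            "hayed": 0.16,
            "depredated": 0.58,
            "trampled": 0.05,
        }
    )
    missing_vor_prob_hayed: float = 0.9
    missing_vor_prob_failed: float = 0.05
    censor_interference_prob: float = 0.034
    censor_access_prob: float = 0.034
    brood_hen_daily_death_prob: float = 0.003
    census_days_posthatch: tuple[int, ...] = (7, 14, 28)

    # centering constants the true linear predictors act on
    centers: dict = field(default_factory=dict)

    def validate(self) -> None:
        probs = [
            self.prop_adult,
            self.precip_wet_prob,
            self.missing_vor_prob_hayed,
            self.missing_vor_prob_failed,
            self.censor_interference_prob,
            self.censor_access_prob,
            self.brood_hen_daily_death_prob,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        cause_total = sum(self.failure_cause_probs.values())
        if abs(cause_total - 1.0) > 1e-9:
            raise ValidationError("failure-cause probabilities must sum to 1")
        if set(self.failure_cause_probs) != set(FAILURE_FATES):
            raise ValidationError("failure-cause probabilities must cover all causes")
        if abs(sum(self.cover_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("cover-type probabilities must sum to 1")
        if set(self.cover_probs) != set(COVER_TYPES):
            raise ValidationError("cover probabilities must cover all cover types")
        if self.n_stations < 1:
            raise ValidationError("need at least one weather station")
        if not -1.0 < self.temp_ar1 < 1.0:
            raise ValidationError("temp_ar1 must lie in (-1, 1)")
        if tuple(self.census_days_posthatch) != (7, 14, 28):
            raise ValidationError("censuses are fixed at 7, 14 and 28 days posthatch")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path=None):
        payload = asdict(self)
        payload["years"] = list(self.years)
        payload["census_days_posthatch"] = list(self.census_days_posthatch)
        payload["n_hens_per_year"] = {int(k): int(v) for k, v in self.n_hens_per_year.items()}
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_yaml(cls, source) -> "GeneratorConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            try:
                with open(source, "r", encoding="utf-8") as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        payload["years"] = tuple(payload.get("years", (2017, 2018)))
        payload["census_days_posthatch"] = tuple(
            payload.get("census_days_posthatch", (7, 14, 28))
        )
        payload["n_hens_per_year"] = {
            int(k): int(v) for k, v in payload.get("n_hens_per_year", {}).items()
        }
        return cls(**payload)


@dataclass
class TruthRecord:
    """Everything needed to score parameter recovery against the generator.

    ``nest_betas`` maps nest_id to the realized per-nest coefficient dict;
    ``brood_latent_counts`` maps brood_id to the full latent daily count
    trajectory (day indices t = 1..29).
    """

    coefficients: dict  # model -> {coef: value}
    nest_random_sd: dict
    centers: dict
    nest_betas: dict = field(default_factory=dict)
    brood_latent_counts: dict = field(default_factory=dict)

    def intercept_at(self, model: str, sample_centers: Mapping[str, float]) -> float:
        """True intercept re-expressed at a fitter's centering constants.

        Fitters center continuous covariates at sample means; the generator
        centers at fixed constants.  The true intercept in the fitter's
        parameterization is the true linear predictor evaluated where all
        fitter-centered covariates are zero:
        ``b0 + sum_j b_j * (sample_center_j - generator_center_j)``.
        """
        coefs = self.coefficients[model]
        b0 = coefs["intercept"]
        for name, center in sample_centers.items():
            if name in coefs and name in self.centers:
                b0 += coefs[name] * (center - self.centers[name])
        return float(b0)

    def to_json(self, path=None):
        payload = {
            "coefficients": self.coefficients,
            "nest_random_sd": self.nest_random_sd,
            "centers": self.centers,
            "nest_betas": self.nest_betas,
            "brood_latent_counts": self.brood_latent_counts,
        }
        text = json.dumps(payload)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
        return None


def _poult_implied_survival(b0: float, b_age: float, extra: float, age_center: float) -> float:
    ages = np.arange(1, _BROOD_DAYS + 1)
    phi = expit(b0 + extra + b_age * (ages - age_center))
    return float(np.prod(phi))


def studylike_config(seed: int = 0) -> GeneratorConfig:
    """Defaults whose implied demographic rates match the study estimates.

    Implied rates at reference covariates: nesting 0.70 yearling / 0.80
    adult; 28-day nest survival ~0.40 (daily logit 3.4); renesting 0.26
    yearling / 0.59 adult; mean clutch exp(log 10.5) = 10.5; hatchability
    0.87 yearling / 0.88 adult; 28-day poult survival 0.16 yearling-reared /
    0.33 adult-reared (brood-age slope 0.08/day, intercept solved
    numerically); failure causes in the observed 9/12/16/58/5 proportions.
    """
    cfg = GeneratorConfig(seed=seed)
    logit = lambda p: float(np.log(p / (1.0 - p)))

    cfg.nesting_coefs = {
        "intercept": logit(0.70),
        "adult": logit(0.80) - logit(0.70),
        "year": 0.0,
        "weight": 0.8,
    }
    cfg.nest_coefs = {
        "intercept": 3.4,
        "adult": 0.15,
        "precip": 0.03,
        "temp": -0.02,
        "precip_x_temp": -0.004,
        "cover_forest": 0.10,
        "cover_pasture": 0.10,
        "cover_agriculture": -1.30,
        "vor": 0.15,
        "total_cover": 0.0,
        "dist_road": 0.001,
    }
    cfg.nest_random_sd = {name: 0.1 for name in cfg.nest_coefs}
    cfg.renesting_coefs = {
        "intercept": logit(0.26),
        "adult": logit(0.59) - logit(0.26),
        "year": 0.0,
        "failure_date": -0.04,
        "prev_duration": 0.0,
        "weight": 0.0,
    }
    cfg.clutch_coefs = {
        "intercept": float(np.log(10.5)),
        "adult": float(np.log(10.6 / 10.0)),
        "year": 0.0,
        "weight": 0.0,
        "attempt_second": -0.05,
    }
    cfg.hatchability_coefs = {
        "intercept": logit(0.87),
        "adult": logit(0.88) - logit(0.87),
        "year": 0.0,
        "weight": 0.0,
    }

    age_center = (1 + _BROOD_DAYS) / 2.0
    b_age = 0.08
    b0 = brentq(
        lambda b: _poult_implied_survival(b, b_age, 0.0, age_center) - 0.16,
        0.0, 6.0,
    )
    b_adult = brentq(
        lambda b: _poult_implied_survival(b0, b_age, b, age_center) - 0.33,
        0.0, 4.0,
    )
    cfg.poult_coefs = {
        "intercept": float(b0),
        "brood_age": b_age,
        "adult": float(b_adult),
        "year": 0.0,
        "precip": -0.02,
        "temp": 0.01,
        "precip_x_temp": 0.0,
    }

    w_mean = (
        cfg.prop_adult * cfg.weight_mean_kg["adult"]
        + (1 - cfg.prop_adult) * cfg.weight_mean_kg["yearling"]
    )
    cfg.centers = {
        "weight": w_mean,
        "precip": cfg.precip_wet_prob * cfg.precip_wet_mean_mm,
        "temp": cfg.temp_mean_c,
        "vor": cfg.vor_mean,
        "total_cover": cfg.total_cover_mean,
        "dist_road": cfg.dist_road_mean_m,
        "failure_date": 160.0,
        "prev_duration": 14.0,
        "brood_age": age_center,
    }
    return cfg


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _simulate_stations(cfg: GeneratorConfig, rng: np.random.Generator) -> list[WeatherStation]:
    n = cfg.n_stations
    side = int(np.ceil(np.sqrt(n)))
    xs, ys = [], []
    for k in range(n):
        i, j = divmod(k, side)
        xs.append((j + 0.5) / side * cfg.extent_m)
        ys.append((i + 0.5) / side * cfg.extent_m)
    dates = np.arange(cfg.season_start, cfg.season_end + 1)
    stations = []
    for k in range(n):
        seasonal = cfg.temp_mean_c + cfg.temp_amplitude_c * np.cos(
            2 * np.pi * (dates - cfg.temp_peak_doy) / 365.0
        )
        noise = np.empty(dates.size)
        e = rng.normal(0.0, cfg.temp_noise_sd)
        for t in range(dates.size):
            e = cfg.temp_ar1 * e + rng.normal(0.0, cfg.temp_noise_sd) * np.sqrt(
                1 - cfg.temp_ar1**2
            )
            noise[t] = e
        temp = seasonal + noise
        wet = rng.uniform(size=dates.size) < cfg.precip_wet_prob
        amount = rng.exponential(cfg.precip_wet_mean_mm, size=dates.size)
        precip = np.where(wet, amount, 0.0)
        stations.append(
            WeatherStation(
                station_id=f"S{k:02d}",
                x_m=xs[k],
                y_m=ys[k],
                dates=dates,
                precip_mm=precip,
                temp_c=temp,
            )
        )
    return stations


def _nearest_station(stations, x, y):
    return min(
        stations,
        key=lambda s: ((s.x_m - x) ** 2 + (s.y_m - y) ** 2, str(s.station_id)),
    )


def simulate_study(config: GeneratorConfig) -> tuple[StudyData, TruthRecord]:
    """Simulate a complete study; the seed fully determines the output."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    c = cfg.centers
    if not c:
        raise ValidationError(
            "config.centers must be set (studylike_config provides defaults)"
        )

    stations = _simulate_stations(cfg, rng)
    truth = TruthRecord(
        coefficients={
            "nesting": dict(cfg.nesting_coefs),
            "nest_survival": dict(cfg.nest_coefs),
            "renesting": dict(cfg.renesting_coefs),
            "clutch": dict(cfg.clutch_coefs),
            "hatchability": dict(cfg.hatchability_coefs),
            "poult": dict(cfg.poult_coefs),
        },
        nest_random_sd=dict(cfg.nest_random_sd),
        centers=dict(c),
    )

    hens: list[HenYear] = []
    nests: list[NestHistory] = []
    broods: list[BroodSeries] = []
    cover_names = list(COVER_TYPES)
    cover_p = np.array([cfg.cover_probs[k] for k in cover_names])
    cause_names = list(FAILURE_FATES)
    cause_p = np.array([cfg.failure_cause_probs[k] for k in cause_names])
    nest_coef_names = list(cfg.nest_coefs)

    nest_counter = 0
    for year_idx, year in enumerate(cfg.years):
        n_hens = int(cfg.n_hens_per_year[year])
        year_contrast = float(year_idx > 0)
        for h in range(n_hens):
            hen_id = f"H{year}-{h:04d}"
            adult = rng.uniform() < cfg.prop_adult
            age = "adult" if adult else "yearling"
            weight = rng.normal(cfg.weight_mean_kg[age], cfg.weight_sd_kg)
            weight = float(max(weight, 2.5))

            lp_nest = (
                cfg.nesting_coefs["intercept"]
                + cfg.nesting_coefs["adult"] * adult
                + cfg.nesting_coefs["year"] * year_contrast
                + cfg.nesting_coefs["weight"] * (weight - c["weight"])
            )
            nested = rng.uniform() < expit(lp_nest)
            hens.append(
                HenYear(
                    hen_id=hen_id,
                    year=year,
                    age_class=age,
                    weight_kg=weight,
                    available_april1=True,
                    nested=bool(nested),
                )
            )
            if not nested:
                continue

            start = int(
                np.clip(
                    round(rng.normal(cfg.first_nest_mean_doy, cfg.first_nest_sd_days)),
                    cfg.season_start + 5,
                    cfg.season_end - _INCUBATION_DAYS - _BROOD_DAYS - 10,
                )
            )
            hen_alive = True
            for attempt in range(1, cfg.max_attempts + 1):
                nest_counter += 1
                nest_id = f"N{nest_counter:05d}"
                x = rng.uniform(0.0, cfg.extent_m)
                y = rng.uniform(0.0, cfg.extent_m)
                cover = cover_names[rng.choice(len(cover_names), p=cover_p)]
                vor = float(max(rng.normal(cfg.vor_mean, cfg.vor_sd), 0.25))
                tot = float(
                    np.clip(rng.normal(cfg.total_cover_mean, cfg.total_cover_sd), 0.0, 1.0)
                )
                dist = float(rng.exponential(cfg.dist_road_mean_m))

                beta = {
                    name: cfg.nest_coefs[name]
                    + cfg.nest_random_sd.get(name, 0.0) * rng.normal()
                    for name in nest_coef_names
                }
                truth.nest_betas[nest_id] = dict(beta)

                station = _nearest_station(stations, x, y)
                dates = start + np.arange(_INCUBATION_DAYS)
                precip, temp = station.series(dates)
                pc = precip - c["precip"]
                tc = temp - c["temp"]
                eta = (
                    beta["intercept"]
                    + beta["adult"] * adult
                    + beta["precip"] * pc
                    + beta["temp"] * tc
                    + beta["precip_x_temp"] * pc * tc
                    + beta["cover_forest"] * (cover == "forest")
                    + beta["cover_pasture"] * (cover == "pasture")
                    + beta["cover_agriculture"] * (cover == "agriculture")
                    + beta["vor"] * (vor - c["vor"])
                    + beta["total_cover"] * (tot - c["total_cover"])
                    + beta["dist_road"] * (dist - c["dist_road"])
                )
                p_daily = expit(eta)
                fail_day = None
                for t in range(_INCUBATION_DAYS):
                    if rng.uniform() >= p_daily[t]:
                        fail_day = t + 1
                        break

                u_cens = rng.uniform()
                censored_fate = None
                if u_cens < cfg.censor_interference_prob:
                    censored_fate = "censored_interference"
                elif u_cens < cfg.censor_interference_prob + cfg.censor_access_prob:
                    censored_fate = "censored_access"

                lp_clutch = (
                    cfg.clutch_coefs["intercept"]
                    + cfg.clutch_coefs["adult"] * adult
                    + cfg.clutch_coefs["year"] * year_contrast
                    + cfg.clutch_coefs["weight"] * (weight - c["weight"])
                    + cfg.clutch_coefs["attempt_second"] * (attempt >= 2)
                )
                clutch = int(max(rng.poisson(np.exp(lp_clutch)), 1))

                if censored_fate is not None:
                    # truncated observation; excluded from all analyses
                    last = fail_day - 1 if fail_day is not None else _INCUBATION_DAYS
                    n_obs = int(max(1, min(last, rng.integers(1, _INCUBATION_DAYS + 1))))
                    nests.append(
                        NestHistory(
                            nest_id=nest_id,
                            hen_id=hen_id,
                            year=year,
                            attempt=attempt,
                            start_date=start,
                            survival=np.ones(n_obs, dtype=np.int8),
                            fate=censored_fate,
                            cover_type=cover,
                            vor_mean=vor,
                            total_cover_mean=tot,
                            dist_road_m=dist,
                            x_m=x,
                            y_m=y,
                            clutch_size=None,
                            eggs_hatched=None,
                        )
                    )
                    break  # hen's season ends unobserved

                if fail_day is None:
                    # hatched: binomial hatching, then a brood if any hatch
                    lp_hatch = (
                        cfg.hatchability_coefs["intercept"]
                        + cfg.hatchability_coefs["adult"] * adult
                        + cfg.hatchability_coefs["year"] * year_contrast
                        + cfg.hatchability_coefs["weight"] * (weight - c["weight"])
                    )
                    hatched_eggs = int(rng.binomial(clutch, expit(lp_hatch)))
                    nests.append(
                        NestHistory(
                            nest_id=nest_id,
                            hen_id=hen_id,
                            year=year,
                            attempt=attempt,
                            start_date=start,
                            survival=np.ones(_INCUBATION_DAYS, dtype=np.int8),
                            fate="hatched",
                            cover_type=cover,
                            vor_mean=vor,
                            total_cover_mean=tot,
                            dist_road_m=dist,
                            x_m=x,
                            y_m=y,
                            clutch_size=clutch,
                            eggs_hatched=hatched_eggs,
                        )
                    )
                    if hatched_eggs >= 1:
                        broods.append(
                            _simulate_brood(
                                cfg, rng, truth, hen_id, year, age, adult,
                                year_contrast, start + _INCUBATION_DAYS,
                                hatched_eggs, station, c,
                            )
                        )
                    break

                cause = cause_names[rng.choice(len(cause_names), p=cause_p)]
                miss_p = (
                    cfg.missing_vor_prob_hayed
                    if cause == "hayed"
                    else cfg.missing_vor_prob_failed
                )
                missing = rng.uniform() < miss_p
                known_clutch = rng.uniform() < (0.6 if cause == "depredated" else 0.9)
                y_vec = np.ones(fail_day, dtype=np.int8)
                y_vec[-1] = 0
                nests.append(
                    NestHistory(
                        nest_id=nest_id,
                        hen_id=hen_id,
                        year=year,
                        attempt=attempt,
                        start_date=start,
                        survival=y_vec,
                        fate=cause,
                        cover_type=cover,
                        vor_mean=None if missing else vor,
                        total_cover_mean=None if missing else tot,
                        dist_road_m=dist,
                        x_m=x,
                        y_m=y,
                        clutch_size=clutch if known_clutch else None,
                        eggs_hatched=None,
                    )
                )
                if cause == "hen_died":
                    hen_alive = False
                    break
                if attempt >= cfg.max_attempts:
                    break
                failure_date = start + fail_day
                lp_renest = (
                    cfg.renesting_coefs["intercept"]
                    + cfg.renesting_coefs["adult"] * adult
                    + cfg.renesting_coefs["year"] * year_contrast
                    + cfg.renesting_coefs["failure_date"]
                    * (failure_date - c["failure_date"])
                    + cfg.renesting_coefs["prev_duration"]
                    * (fail_day - c["prev_duration"])
                    + cfg.renesting_coefs["weight"] * (weight - c["weight"])
                )
                if rng.uniform() >= expit(lp_renest):
                    break
                delay = max(
                    3,
                    int(round(rng.normal(cfg.renest_delay_mean_days, cfg.renest_delay_sd_days))),
                )
                start = failure_date + delay
                # leave room for incubation plus the brood window
                if start > cfg.season_end - _INCUBATION_DAYS - _BROOD_DAYS - 1:
                    break

    study = StudyData(hens=hens, nests=nests, broods=broods, stations=stations)
    study.validate()
    attach_weather(study)
    return study, truth


def _simulate_brood(
    cfg, rng, truth, hen_id, year, age, adult, year_contrast, hatch_date,
    n_initial, station, c,
) -> BroodSeries:
    dates = hatch_date + np.arange(_BROOD_DAYS)
    precip, temp = station.series(dates)
    pc = precip - c["precip"]
    tc = temp - c["temp"]
    ages = np.arange(1, _BROOD_DAYS + 1)
    eta = (
        cfg.poult_coefs["intercept"]
        + cfg.poult_coefs["brood_age"] * (ages - c["brood_age"])
        + cfg.poult_coefs["adult"] * adult
        + cfg.poult_coefs["year"] * year_contrast
        + cfg.poult_coefs["precip"] * pc
        + cfg.poult_coefs["temp"] * tc
        + cfg.poult_coefs["precip_x_temp"] * pc * tc
    )
    phi = expit(eta)

    hen_death_day = None
    latent = [int(n_initial)]  # N_1
    n = int(n_initial)
    for a in range(1, _BROOD_DAYS + 1):  # transition to day index t = a + 1
        if hen_death_day is None and rng.uniform() < cfg.brood_hen_daily_death_prob:
            hen_death_day = a
        n = int(rng.binomial(n, phi[a - 1]))
        latent.append(n)
    brood_id = f"B-{hen_id}-{year}"
    truth.brood_latent_counts[brood_id] = list(latent)

    counts = {}
    for day, t_idx in zip(cfg.census_days_posthatch, CENSUS_INDICES):
        if hen_death_day is not None and day >= hen_death_day:
            counts[t_idx] = 0
        else:
            counts[t_idx] = latent[day]  # latent[day] = N at t = day + 1
    return BroodSeries(
        brood_id=brood_id,
        hen_id=hen_id,
        year=year,
        hen_age_class=age,
        hatch_date=hatch_date,
        n_initial=int(n_initial),
        counts=counts,
        hen_death_day=hen_death_day,
    )
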