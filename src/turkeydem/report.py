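"""Pipeline driver and report assembly.

:func:`run_pipeline` executes the full analysis — data loading (or
simulation), encounter-history construction, all six model fits, derived
demographic rates, effect-curve tables and a convergence panel — and writes
every product as a diffable CSV/JSON bundle.  :func:`compare_to_published`
places this run's estimates beside previously published wild-turkey
reproductive rates and flags estimates falling outside the published range.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    StudyData,
    build_nest_histories,
    load_study_tables,
    summarize_failure_causes,
)
from .mcmc import McmcConfig
from .nest import NestSurvivalModel
from .poult import PoultSurvivalModel
from .priors import PriorSet, default_priors
from .rates import (
    ClutchSizeModel,
    HatchabilityModel,
    NestingRateModel,
    RenestingRateModel,
    build_rate_datasets,
)
from .simulate import GeneratorConfig, simulate_study

__all__ = ["StudyReport", "run_pipeline", "compare_to_published", "load_published_estimates"]

logger = logging.getLogger(__name__)


@dataclass
class StudyReport:
    """All data products of one pipeline run."""

    failure_table: pd.DataFrame
    coefficients: dict[str, pd.DataFrame]
    derived_rates: pd.DataFrame
    curves: dict[str, pd.DataFrame]
    convergence: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "failure_table": self.failure_table.to_dict(orient="records"),
            "derived_rates": self.derived_rates.to_dict(orient="records"),
            "convergence": self.convergence.to_dict(orient="records"),
            "coefficients": {
                k: v.to_dict(orient="records") for k, v in self.coefficients.items()
            },
        }
        return json.dumps(payload, sort_keys=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.failure_table.to_csv(out / "failure_causes.csv", index=False)
        for name, df in self.coefficients.items():
            df.to_csv(out / f"{name}_coefficients.csv", index=False)
        self.derived_rates.to_csv(out / "derived_rates.csv", index=False)
        for name, df in self.curves.items():
            df.to_csv(out / f"curve_{name}.csv", index=False)
        self.convergence.to_csv(out / "convergence.csv", index=False)
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    def validate(self) -> None:
        required = {"parameter", "age_class", "estimate", "lower95", "upper95"}
        if not required.issubset(self.derived_rates.columns):
            raise ValueError("derived_rates is missing required columns")
        if not {"model", "parameter", "rhat"}.issubset(self.convergence.columns):
            raise ValueError("convergence panel is missing required columns")


def _config_hash(config: GeneratorConfig | None) -> str:
    if config is None:
        return ""
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(
    data_dir=None,
    config: GeneratorConfig | None = None,
    priors: PriorSet | None = None,
    mcmc: McmcConfig | None = None,
    out_dir=None,
) -> StudyReport:
    """Run the full analysis on a data directory or a simulated study.

    Exactly one of ``data_dir`` and ``config`` must be given.  Each stage
    failure aborts with the stage name attached.
    """
    if (data_dir is None) == (config is None):
        raise ValueError("supply exactly one of data_dir or config")
    priors = priors if priors is not None else default_priors()
    mcmc = mcmc or McmcConfig()

    stage = "load"
    try:
        if config is not None:
            study, _truth = simulate_study(config)
        else:
            study = load_study_tables(data_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return analyze_study(
        study, priors=priors, mcmc=mcmc, out_dir=out_dir,
        provenance={
            "seed": mcmc.seed,
            "config_hash": _config_hash(config),
            "package_version": __version__,
        },
    )


def analyze_study(
    study: StudyData,
    priors: PriorSet | None = None,
    mcmc: McmcConfig | None = None,
    out_dir=None,
    provenance: dict | None = None,
) -> StudyReport:
    """Fit every model to an in-memory study and assemble the report."""
    priors = priors if priors is not None else default_priors()
    mcmc = mcmc or McmcConfig()
    coefficients: dict[str, pd.DataFrame] = {}
    convergence_rows = []
    rate_rows = []
    curves: dict[str, pd.DataFrame] = {}

    def record(model_name, results):
        df = results.summary()
        coefficients[model_name] = df
        for _, row in df.iterrows():
            convergence_rows.append(
                {"model": model_name, "parameter": row["parameter"], "rhat": row["rhat"]}
            )

    stage = "encounter-histories"
    try:
        retained = build_nest_histories(study.nests)
        failure = summarize_failure_causes(retained).to_frame()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "scalar-rates"
    try:
        logger.info("fitting scalar-rate models")
        datasets = build_rate_datasets(study)
        for name, cls in (
            ("nesting", NestingRateModel),
            ("renesting", RenestingRateModel),
            ("clutch", ClutchSizeModel),
            ("hatchability", HatchabilityModel),
        ):
            res = cls(datasets[name], priors=priors).fit(mcmc)
            record(name, res)
            if name == "clutch":
                for age, adult in (("yearling", False), ("adult", True)):
                    m, lo, hi = res.mean_clutch(adult=adult, second_attempt=False)
                    rate_rows.append(
                        {"parameter": "clutch", "age_class": age,
                         "estimate": m, "lower95": lo, "upper95": hi}
                    )
            else:
                for _, row in res.rate_by_age().iterrows():
                    rate_rows.append(
                        {"parameter": name if name != "nesting" else "nesting",
                         "age_class": row["age_class"], "estimate": row["estimate"],
                         "lower95": row["lower95"], "upper95": row["upper95"]}
                    )
            if name == "nesting" and datasets[name].n:
                w = datasets[name].covariates["weight"]
                grid = np.linspace(float(w.min()), float(w.max()), 25)
                curves["nesting_vs_weight"] = res.effect_curve("weight", grid)
            if name == "renesting" and datasets[name].n:
                d = datasets[name].covariates["failure_date"]
                grid = np.linspace(float(d.min()), float(d.max()), 25)
                curves["renesting_vs_failure_date"] = res.effect_curve(
                    "failure_date", grid
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "nest-survival"
    try:
        logger.info("fitting nest survival model")
        nest_model = NestSurvivalModel.from_study(study, priors=priors)
        nest_res = nest_model.fit(mcmc)
        record("nest_survival", nest_res)
        for age in ("yearling", "adult"):
            m, lo, hi = nest_res.cumulative_survival({"age_class": age})
            rate_rows.append(
                {"parameter": "nest_survival", "age_class": age,
                 "estimate": m, "lower95": lo, "upper95": hi}
            )
        cover_rows = []
        for cover in ("grassland", "pasture", "agriculture", "forest"):
            m, lo, hi = nest_res.daily_survival(
                {"age_class": "adult", "cover_type": cover}
            )
            cover_rows.append(
                {"cover_type": cover, "daily_survival": m, "lower95": lo, "upper95": hi}
            )
        curves["nest_daily_by_cover"] = pd.DataFrame(cover_rows)
        if "vor" in nest_model.centers:
            c = nest_model.centers["vor"]
            curves["nest_daily_vs_vor"] = nest_res.effect_curve(
                "vor", np.linspace(max(c - 3, 0.1), c + 3, 25), {"age_class": "adult"}
            )
        if "dist_road" in nest_model.centers:
            c = nest_model.centers["dist_road"]
            curves["nest_daily_vs_dist_road"] = nest_res.effect_curve(
                "dist_road", np.linspace(0.0, c + 600, 25), {"age_class": "adult"}
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "poult-survival"
    try:
        logger.info("fitting poult survival model")
        poult_model = PoultSurvivalModel.from_study(study, priors=priors)
        poult_res = poult_model.fit(mcmc)
        record("poult", poult_res)
        for _, row in poult_res.survival_by_age().iterrows():
            rate_rows.append(
                {"parameter": "poult_survival", "age_class": row["age_class"],
                 "estimate": row["estimate"], "lower95": row["lower95"],
                 "upper95": row["upper95"]}
            )
        curves["poult_daily_vs_age"] = poult_res.daily_survival_curve()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = StudyReport(
        failure_table=failure,
        coefficients=coefficients,
        derived_rates=pd.DataFrame(rate_rows),
        curves=curves,
        convergence=pd.DataFrame(convergence_rows),
        provenance=provenance or {},
    )
    report.validate()
    if out_dir is not None:
        report.write(out_dir)
    return report


def render_curve(curve: pd.DataFrame, x: str, y: str, out_path) -> None:
    """Render one effect-curve table to an image (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve[x], curve[y], color="black")
    if {"lower95", "upper95"}.issubset(curve.columns):
        ax.fill_between(curve[x], curve["lower95"], curve["upper95"],
                        alpha=0.25, color="gray")
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def load_published_estimates() -> pd.DataFrame:
    """Bundled table of previously published turkey reproductive rates."""
    with resources.files("turkeydem").joinpath("published_estimates.csv").open() as fh:
        return pd.read_csv(fh)


def compare_to_published(
    report: StudyReport, published: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flag this run's derived rates against published ranges.

    For each (parameter, age_class) the published range is the min-max of
    the age-specific estimates where available, pooled with "combined"
    estimates.  Flags: within range / below range / above range.
    """
    if published is None:
        published = load_published_estimates()
    if published.empty:
        return pd.DataFrame(
            columns=["parameter", "age_class", "estimate", "published_min",
                     "published_max", "flag"]
        )
    known = set(published["parameter"].unique())
    rows = []
    for _, row in report.derived_rates.iterrows():
        param, age = row["parameter"], row["age_class"]
        if param not in known:
            raise KeyError(f"parameter {param!r} not present in the published table")
        sub = published[published["parameter"] == param]
        vals = pd.concat([sub[age].dropna(), sub["combined"].dropna()])
        if vals.empty:
            flag = "no published estimates"
            lo = hi = np.nan
        else:
            lo, hi = float(vals.min()), float(vals.max())
            if row["estimate"] < lo:
                flag = "below range"
            elif row["estimate"] > hi:
                flag = "above range"
            else:
                flag = "within range"
        rows.append(
            {"parameter": param, "age_class": age, "estimate": row["estimate"],
             "published_min": lo, "published_max": hi, "flag": flag}
        )
    return pd.DataFrame(rows)
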