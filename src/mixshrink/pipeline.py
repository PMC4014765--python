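"""End-to-end orchestration: simulate (or read) -> preprocess -> first stage
-> shrink -> sensitivity/interaction, with every output written as CSV and a
manifest recording the seed, tau^2 and the chemical accounting at each filter
step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemicals import CLASSES, default_panel, full_measurement_panel
from .cohort import Cohort, CohortConfig, generate_cohort
from .first_stage import FirstStageFit, fit_repeated_model
from .preprocess import ProcessedPanel, preprocess_panel
from .semibayes import ShrinkageResult, build_exchangeability, shrink, tau2_from_range
from .sensitivity import SCENARIOS, SensitivityReport, run_sensitivity_suite, sex_interaction

CLASS_RANK = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class RunConfig:
    seed: int
    n_subjects: int = 175
    panel: str = "default"  # "default" (52 chemicals) or "full" (all 70 measured)
    prior_range: float = 20.0
    coverage: float = 0.95
    small_prior_range: float = 10.0
    r_threshold: float = 0.95
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIOS))
    sex_interaction_chemicals: list[str] = field(default_factory=list)
    p_both_visits: float = 135.0 / 175.0
    true_betas: dict[str, float] = field(default_factory=dict)
    dropout_model: dict[str, float] = field(default_factory=lambda: {"intercept": 20.0})
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.prior_range > 0:
            raise ValueError("prior_range must be positive")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        if self.panel == "default":
            chemicals, extra = default_panel(), []
        elif self.panel == "full":
            chemicals, extra = full_measurement_panel()
        else:
            raise ValueError(f"unknown panel {self.panel!r}")
        return CohortConfig(
            n_subjects=self.n_subjects,
            chemicals=chemicals,
            extra_correlations=extra,
            true_betas=dict(self.true_betas),
            p_both_visits=self.p_both_visits,
            dropout_model=dict(self.dropout_model),
            seed=self.seed,
        )


@dataclass
class RunResult:
    config: RunConfig
    cohort: Cohort
    processed: ProcessedPanel
    fit: FirstStageFit
    shrinkage: ShrinkageResult
    results: pd.DataFrame
    manifest: dict
    sensitivity: SensitivityReport | None = None
    interactions: pd.DataFrame | None = None


def _results_table(
    processed: ProcessedPanel, fit: FirstStageFit, shrinkage: ShrinkageResult
) -> pd.DataFrame:
    rows = []
    for rec in processed.chemicals:
        name = rec.name
        rows.append(
            {
                "chemical": name,
                "chem_class": rec.chem_class,
                "coding": processed.coding[name],
                "beta_raw": float(fit.beta[name]),
                "se_raw": float(fit.se[name]),
                "beta_star": float(shrinkage.beta_star[name]),
                "se_star": float(shrinkage.se_star[name]),
                "ci_low": float(shrinkage.ci95.loc[name, "ci_low"]),
                "ci_high": float(shrinkage.ci95.loc[name, "ci_high"]),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline on one synthetic cohort."""
    try:
        cohort = generate_cohort(config.cohort_config())
    except Exception as exc:
        raise RuntimeError(f"simulation stage failed: {exc}") from exc
    try:
        processed = preprocess_panel(cohort.panel, r_threshold=config.r_threshold)
    except Exception as exc:
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc
    try:
        fit = fit_repeated_model(cohort.outcomes, processed.data, cohort.covariates)
    except Exception as exc:
        raise RuntimeError(f"first-stage fit failed: {exc}") from exc
    try:
        zspec = build_exchangeability(processed.chemicals)
        tau2 = tau2_from_range(config.prior_range, config.coverage)
        shrinkage = shrink(fit, zspec, tau2)
    except Exception as exc:
        raise RuntimeError(f"second-stage shrinkage failed: {exc}") from exc

    results = _results_table(processed, fit, shrinkage)
    counts = processed.counts()
    manifest = {
        "seed": config.seed,
        "n_subjects": int(config.n_subjects),
        "n_children_analyzed": int(fit.n_children),
        "n_obs": int(fit.n_obs),
        "tau2": round(float(shrinkage.tau2_used), 6),
        "prior_range": float(config.prior_range),
        "coverage": float(config.coverage),
        "chemicals": counts,
        "icc": round(float(fit.icc), 6),
    }
    assert counts["analyzed"] == (
        counts["measured"] - counts["low_detection"] - counts["correlation_excluded"]
    )

    sens = None
    if set(config.scenarios) - {"main"}:
        try:
            sens = run_sensitivity_suite(
                cohort.outcomes,
                processed,
                cohort.covariates,
                completed=cohort.completed,
                prior_range=config.prior_range,
                small_prior_range=config.small_prior_range,
                coverage=config.coverage,
                zspec=zspec,
                scenarios=tuple(config.scenarios),
            )
        except Exception as exc:
            raise RuntimeError(f"sensitivity stage failed: {exc}") from exc

    interactions = None
    if config.sex_interaction_chemicals:
        try:
            recs = []
            for chem in config.sex_interaction_chemicals:
                r = sex_interaction(cohort.outcomes, processed.data, cohort.covariates, chem)
                recs.append(
                    {
                        "chemical": r.chemical,
                        "beta_girls": r.beta_girls,
                        "ci_girls_low": r.ci_girls[0],
                        "ci_girls_high": r.ci_girls[1],
                        "beta_boys": r.beta_boys,
                        "ci_boys_low": r.ci_boys[0],
                        "ci_boys_high": r.ci_boys[1],
                        "interaction_p": r.interaction_p,
                        "display": r.display,
                    }
                )
            interactions = pd.DataFrame(recs)
        except Exception as exc:
            raise RuntimeError(f"sex-interaction stage failed: {exc}") from exc

    result = RunResult(
        config=config,
        cohort=cohort,
        processed=processed,
        fit=fit,
        shrinkage=shrinkage,
        results=results,
        manifest=manifest,
        sensitivity=sens,
        interactions=interactions,
    )
    if config.out_dir is not None:
        write_outputs(result, Path(config.out_dir))
    return result


def summarize_run(results: pd.DataFrame) -> pd.DataFrame:
    """Figure-style ordered effect table: rows grouped by chemical class in
    panel order, dichotomous chemicals annotated, and strong-but-precise
    associations (|beta*| >= 1.5 and SE < 2.0) flagged."""
    if results.empty:
        return pd.DataFrame(
            columns=[
                "chemical", "chem_class", "annotation",
                "beta_star", "se_star", "ci_low", "ci_high", "highlight",
            ]
        )
    df = results.copy()
    df["_rank"] = df["chem_class"].map(CLASS_RANK)
    df = df.sort_values(["_rank"], kind="stable").drop(columns="_rank")
    df["annotation"] = np.where(
        df["coding"] == "dichotomous", "detected vs. nondetectable", ""
    )
    df["highlight"] = (df["beta_star"].abs() >= 1.5) & (df["se_star"] < 2.0)
    cols = [
        "chemical", "chem_class", "annotation",
        "beta_star", "se_star", "ci_low", "ci_high", "highlight",
    ]
    return df[cols].reset_index(drop=True)


def write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = result.cohort
    cohort.panel.to_long().to_csv(out_dir / "exposures.csv", index=False)
    cohort.covariates.to_csv(out_dir / "covariates.csv")
    cohort.outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    if cohort.completed is not None:
        cohort.completed.astype(int).to_csv(out_dir / "completed.csv")
    result.processed.report.to_csv(out_dir / "preprocess_report.csv", index=False)
    result.processed.data.to_csv(out_dir / "coded_exposures.csv")

    fs = pd.DataFrame(
        {"chemical": result.fit.labels, "beta": result.fit.beta.to_numpy(), "se": result.fit.se.to_numpy()}
    )
    fs.to_csv(out_dir / "first_stage.csv", index=False)
    result.fit.V.to_csv(out_dir / "first_stage_cov.csv")

    zspec = build_exchangeability(result.processed.chemicals)
    zspec.Z.astype(int).to_csv(out_dir / "exchangeability.csv")

    result.results.to_csv(out_dir / "results.csv", index=False)
    summarize_run(result.results).to_csv(out_dir / "summary.csv", index=False)
    if result.sensitivity is not None:
        result.sensitivity.table.to_csv(out_dir / "sensitivity.csv", index=False)
    if result.interactions is not None:
        result.interactions.to_csv(out_dir / "interactions.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
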