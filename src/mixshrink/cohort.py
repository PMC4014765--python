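"""Synthetic cohort generator.

Produces cohorts with the statistical structure the downstream analysis
assumes: lognormal exposure biomarkers with class-blocked correlation and
quantile-derived limits of detection, a covariate table with realistic
marginal frequencies, repeated outcome scores with a child-level random
intercept, and covariate-dependent loss to follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chemicals import ChemicalSpec, default_panel
from .panel import ExposurePanel
from .preprocess import preprocess_panel

# Default within-class exposure correlations (log scale); chosen to mimic the
# qualitative collinearity of the source mixture while keeping the implied
# correlation matrix positive definite. All configurable.
DEFAULT_WITHIN_CLASS = {
    "phthalate": 0.5,
    "phenol": 0.0,
    "PCB": 0.6,
    "OC_pesticide": 0.4,
    "BFR": 0.5,
    "PFAS": 0.4,
}
DEFAULT_CROSS_CLASS = 0.1

# Covariate marginal structure: category lists (first = reference level) and
# sampling probabilities approximating the cohort's demographic table.
CATEGORICAL_COVARIATES: dict[str, tuple[list[str], list[float]]] = {
    "race": (["White", "Black", "Other"], [0.67, 0.29, 0.04]),
    "maternal_age": (["25_to_34", "under_25", "35_plus"], [0.66, 0.21, 0.13]),
    "education": (
        ["graduate", "some_college", "high_school", "less_than_high_school"],
        [0.53, 0.27, 0.12, 0.08],
    ),
    "marital_status": (["married", "living_together", "living_alone"], [0.70, 0.09, 0.21]),
    "income": (["over_80k", "40_to_80k", "20_to_40k", "under_20k"], [0.26, 0.38, 0.15, 0.21]),
    "parity": (["nulliparous", "one_to_two", "three_plus"], [0.46, 0.47, 0.07]),
    "insurance": (["private", "public_or_none"], [0.74, 0.26]),
    "employment": (["any", "none"], [0.83, 0.17]),
    "prenatal_vitamins": (["daily", "weekly", "rarely"], [0.75, 0.10, 0.15]),
    "child_sex": (["boy", "girl"], [0.46, 0.54]),
}

CONTINUOUS_COVARIATES: dict[str, tuple[float, float]] = {
    "depression": (8.0, 6.0),
    "maternal_iq": (107.0, 12.0),
    "home_score": (39.0, 6.0),
    "log10_cotinine": (-1.3, 1.0),
}

# Modest default confounder -> outcome effects (design-column keyed), mirroring
# the socioeconomic gradients of the demographic table.
DEFAULT_CONFOUNDER_EFFECTS = {
    "race_Black": 8.0,
    "education_less_than_high_school": 5.0,
    "income_under_20k": 5.0,
    "insurance_public_or_none": 3.0,
    "depression": 0.3,
    "maternal_iq": -0.1,
    "home_score": -0.3,
    "log10_cotinine": 1.5,
}


@dataclass
class TruthRecord:
    """Ground truth retained for parameter-recovery tests."""

    true_betas: pd.Series
    true_tau2: float
    true_pi: pd.Series

    def __post_init__(self) -> None:
        if self.true_betas.isna().any():
            raise ValueError("true_betas must be fully specified")


@dataclass
class CohortConfig:
    n_subjects: int = 175
    chemicals: list[ChemicalSpec] = field(default_factory=default_panel)
    within_class_correlation: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_WITHIN_CLASS)
    )
    cross_class_correlation: float = DEFAULT_CROSS_CLASS
    extra_correlations: list[tuple[str, str, float]] = field(default_factory=list)
    true_betas: Mapping[str, float] = field(default_factory=dict)
    confounder_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS)
    )
    icc_target: float = 0.74
    outcome_mean: float = 50.0
    outcome_sd: float = 10.0
    # logistic model for completing follow-up; keys are covariate/exposure
    # columns of the baseline frame plus "intercept"
    dropout_model: Mapping[str, float] = field(
        default_factory=lambda: {"intercept": 20.0}
    )
    p_both_visits: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory when simulating")
        if not 0.0 < self.icc_target < 1.0:
            raise ValueError("icc_target must lie in (0, 1)")
        if not 0.0 <= self.p_both_visits <= 1.0:
            raise ValueError("p_both_visits must lie in [0, 1]")

    def within_class(self, chem_class: str) -> float:
        if isinstance(self.within_class_correlation, Mapping):
            return float(
                self.within_class_correlation.get(
                    chem_class, DEFAULT_WITHIN_CLASS.get(chem_class, 0.3)
                )
            )
        return float(self.within_class_correlation)

    def stage_rngs(self) -> dict[str, np.random.Generator]:
        """One independent, named random stream per generation stage."""
        names = ("exposures", "covariates", "outcomes", "dropout")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class Cohort:
    panel: ExposurePanel
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: TruthRecord
    completed: pd.Series | None = None


def build_correlation_matrix(config: CohortConfig) -> np.ndarray:
    """Block correlation by chemical class with a constant cross-class floor
    plus any explicit pairwise overrides. Fails if not positive definite."""
    chems = config.chemicals
    p = len(chems)
    classes = [c.chem_class for c in chems]
    R = np.full((p, p), config.cross_class_correlation)
    for i in range(p):
        for j in range(p):
            if i != j and classes[i] == classes[j]:
                R[i, j] = config.within_class(classes[i])
    np.fill_diagonal(R, 1.0)
    name_idx = {c.name: k for k, c in enumerate(chems)}
    for a, b, r in config.extra_correlations:
        if a not in name_idx or b not in name_idx:
            raise ValueError(f"extra correlation names unknown: ({a}, {b})")
        i, j = name_idx[a], name_idx[b]
        R[i, j] = R[j, i] = float(r)
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        bad = []
        for cls in dict.fromkeys(classes):
            idx = [k for k, c in enumerate(classes) if c == cls]
            sub = R[np.ix_(idx, idx)]
            if np.linalg.eigvalsh(sub).min() <= 0:
                bad.append(cls)
        detail = f" (offending class blocks: {', '.join(bad)})" if bad else ""
        raise ValueError(
            "implied exposure correlation matrix is not positive definite" + detail
        ) from None
    return R


def generate_exposures(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> ExposurePanel:
    """Draw log10 concentrations from a block-correlated multivariate normal.

    Each chemical's LOD is the (1 - detection_target) quantile of its marginal,
    so the realized detection frequency matches the target in expectation.
    Censored cells keep the raw draw; substitution happens in preprocessing.
    """
    if rng is None:
        rng = config.stage_rngs()["exposures"]
    chems = config.chemicals
    R = build_correlation_matrix(config)
    L = np.linalg.cholesky(R)
    mu = np.array([math.log10(c.geometric_mean) for c in chems])
    sigma = np.array([math.log10(c.geometric_sd) for c in chems])

    z = rng.standard_normal((config.n_subjects, len(chems)))
    logx = mu + sigma * (z @ L.T)
    values = 10.0 ** logx

    det = np.array([c.detection_target for c in chems])
    with np.errstate(divide="ignore"):
        q = stats.norm.ppf(1.0 - det)  # -inf when detection_target == 1
    log_lod = mu + sigma * q
    lods = np.where(np.isneginf(log_lod), 0.0, 10.0 ** log_lod)
    censored = values < lods[np.newaxis, :]

    subjects = pd.RangeIndex(config.n_subjects, name="subject_id")
    names = [c.name for c in chems]
    records = [c.to_record(lod=float(l)) for c, l in zip(chems, lods)]
    return ExposurePanel(
        chemicals=records,
        values=pd.DataFrame(values, index=subjects, columns=names),
        censored=pd.DataFrame(censored, index=subjects, columns=names),
    )


def generate_covariates(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    if rng is None:
        rng = config.stage_rngs()["covariates"]
    n = config.n_subjects
    cols: dict[str, object] = {}
    for name, (levels, probs) in CATEGORICAL_COVARIATES.items():
        probs = np.asarray(probs, dtype=float)
        probs = probs / probs.sum()
        draws = rng.choice(len(levels), size=n, p=probs)
        cols[name] = pd.Categorical.from_codes(draws, categories=levels)
    for name, (mean, sd) in CONTINUOUS_COVARIATES.items():
        cols[name] = rng.normal(mean, sd, size=n)
    return pd.DataFrame(cols, index=pd.RangeIndex(n, name="subject_id"))


def covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Reference-coded design for the covariate table: dummies (first level
    dropped) for categoricals, identity for continuous columns."""
    pieces = []
    for col in covariates.columns:
        s = covariates[col]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            d = pd.get_dummies(s, prefix=col, prefix_sep="_", drop_first=True)
            pieces.append(d.astype(float))
        else:
            pieces.append(s.astype(float).to_frame())
    return pd.concat(pieces, axis=1)


def _linear_predictor(design: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    lp = np.zeros(len(design))
    for col, eff in effects.items():
        if col == "intercept":
            lp += float(eff)
        elif col in design.columns:
            lp += float(eff) * design[col].to_numpy(dtype=float)
        else:
            raise KeyError(f"effect refers to unknown design column {col!r}")
    return lp


def generate_outcomes(
    coded_exposures: pd.DataFrame,
    covariates: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    ages: Sequence[int] = (4, 5),
) -> pd.DataFrame:
    """Repeated outcome scores: one row per attended visit.

    score = outcome_mean + sum(beta * coded exposure) + confounder effects
            + child random intercept + residual,
    with the random-intercept share of the residual variance equal to
    ``icc_target`` and the total outcome SD approximately ``outcome_sd``.
    A fraction ``p_both_visits`` of children (exact count) attend both ages;
    the rest attend one age chosen at random.
    """
    if rng is None:
        rng = config.stage_rngs()["outcomes"]
    if not 0.0 < config.icc_target < 1.0:
        raise ValueError("icc_target must lie in (0, 1)")
    n = len(coded_exposures)
    subjects = coded_exposures.index

    betas = pd.Series(0.0, index=coded_exposures.columns)
    for name, b in config.true_betas.items():
        if name in betas.index:
            betas[name] = float(b)
    lp = config.outcome_mean + coded_exposures.to_numpy(dtype=float) @ betas.to_numpy()
    if config.confounder_effects:
        design = covariate_design(covariates.loc[subjects])
        lp = lp + _linear_predictor(design, config.confounder_effects)

    var_fixed = float(np.var(lp)) if n > 1 else 0.0
    resid_total = max(config.outcome_sd**2 - var_fixed, 1e-12)
    sd_b = math.sqrt(config.icc_target * resid_total)
    sd_e = math.sqrt((1.0 - config.icc_target) * resid_total)

    b = rng.normal(0.0, sd_b, size=n)

    n_both = int(round(config.p_both_visits * n))
    both = np.zeros(n, dtype=bool)
    both[rng.permutation(n)[:n_both]] = True
    single_age = rng.choice(len(ages), size=n)

    rows = []
    for k, age in enumerate(ages):
        attend = both | (single_age == k)
        e = rng.normal(0.0, sd_e, size=n)
        score = lp + b + e
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": np.asarray(subjects)[attend],
                    "age": age,
                    "score": score[attend],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["subject_id", "age"], ignore_index=True)


def apply_dropout(cohort: Cohort, config: CohortConfig, rng: np.random.Generator | None = None) -> Cohort:
    """Draw a completion indicator from a logistic model on baseline columns
    (covariate design columns and/or chemical names) and drop outcome rows of
    non-completers. Generation covariates are retained for IPW testing."""
    if rng is None:
        rng = config.stage_rngs()["dropout"]
    design = covariate_design(cohort.covariates)
    baseline = pd.concat([design, cohort.panel.values], axis=1)
    logit = _linear_predictor(baseline, config.dropout_model)
    p_complete = 1.0 / (1.0 + np.exp(-logit))
    completed = rng.random(len(baseline)) < p_complete
    completed = pd.Series(completed, index=cohort.covariates.index, name="completed")
    outcomes = cohort.outcomes[
        cohort.outcomes["subject_id"].map(completed).to_numpy(dtype=bool)
    ].reset_index(drop=True)
    return Cohort(
        panel=cohort.panel,
        covariates=cohort.covariates,
        outcomes=outcomes,
        truth=cohort.truth,
        completed=completed,
    )


def completion_summary(completed: pd.Series | np.ndarray) -> dict[str, float]:
    """Follow-up bookkeeping: enrolled, completed, and rounded percentage."""
    arr = np.asarray(completed, dtype=bool)
    n = int(arr.size)
    k = int(arr.sum())
    pct = int(round(100.0 * k / n)) if n else 0
    return {"n_enrolled": n, "n_completed": k, "pct_completed": pct}


def count_observations(outcomes: pd.DataFrame) -> int:
    return int(len(outcomes))


def generate_cohort(config: CohortConfig) -> Cohort:
    """Full generation pipeline: exposures -> analysis coding -> covariates ->
    repeated outcomes -> dropout."""
    rngs = config.stage_rngs()
    panel = generate_exposures(config, rngs["exposures"])
    processed = preprocess_panel(panel)
    covariates = generate_covariates(config, rngs["covariates"])
    outcomes = generate_outcomes(processed.data, covariates, config, rngs["outcomes"])

    betas = pd.Series(0.0, index=pd.Index([c.name for c in config.chemicals], name="chemical"))
    for name, b in config.true_betas.items():
        if name in betas.index:
            betas[name] = float(b)
    truth = TruthRecord(true_betas=betas, true_tau2=float("nan"), true_pi=pd.Series(dtype=float))
    cohort = Cohort(panel=panel, covariates=covariates, outcomes=outcomes, truth=truth)
    return apply_dropout(cohort, config, rngs["dropout"])
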