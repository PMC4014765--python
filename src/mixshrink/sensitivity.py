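"""Sensitivity suite and the sex-interaction exploratory analysis.

Scenarios: inverse-probability weighting for loss to follow-up, a smaller
prior coefficient range (stronger shrinkage), empirical-Bayes estimation of
the second-stage residual variance, and unrestricted single-pollutant models.
The exploratory analysis fits single-pollutant models with a chemical-by-sex
product term to obtain sex-specific slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import covariate_design
from .first_stage import FirstStageFit, fit_repeated_model
from .preprocess import ProcessedPanel
from .semibayes import (
    ExchangeabilitySpec,
    Tau2Spec,
    build_exchangeability,
    empirical_bayes_tau2,
    shrink,
    tau2_from_range,
)

SCENARIOS = ("main", "tau2_small", "empirical_bayes", "ipw", "single_pollutant")


def ipw_weights(
    baseline: pd.DataFrame,
    completed: pd.Series,
    probability_floor: float = 1e-6,
) -> pd.Series:
    """Stabilized inverse-probability-of-completion weights.

    Fits a logistic model of completion on the baseline design, then returns
    ``P(complete) / p_hat_i`` for completers (mean ~ 1). Raises if any fitted
    probability falls below ``probability_floor`` (separation)."""
    X = sm.add_constant(baseline.astype(float), has_constant="add")
    y = completed.loc[baseline.index].astype(float)
    if y.min() == y.max():
        # degenerate: everyone (or no one) completed
        if y.min() == 1.0:
            return pd.Series(1.0, index=baseline.index, name="ipw")
        raise ValueError("no completers: cannot construct IPW weights")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fitted = model.fit()
    p_hat = pd.Series(np.asarray(fitted.predict(X)), index=baseline.index)
    completers = y.astype(bool)
    if (p_hat[completers] < probability_floor).any():
        raise ValueError(
            "fitted completion probability below floor; near-separation in the dropout model"
        )
    marginal = float(y.mean())
    w = marginal / p_hat[completers]
    w.name = "ipw"
    return w


@dataclass
class SensitivityReport:
    """Per-chemical estimates under each scenario (long format)."""

    table: pd.DataFrame  # columns: scenario, chemical, beta, se, tau2, n_obs

    def scenario(self, label: str) -> pd.DataFrame:
        return self.table[self.table["scenario"] == label].set_index("chemical")


def single_pollutant_fits(
    outcomes: pd.DataFrame,
    coded: pd.DataFrame,
    covariates: pd.DataFrame,
    weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Confounder-adjusted single-pollutant repeated-measures models, one per
    chemical, each on the maximal sample with that chemical observed."""
    rows = []
    for name in coded.columns:
        col = coded[[name]].dropna()
        fit = fit_repeated_model(outcomes, col, covariates, weights=weights)
        rows.append(
            {
                "chemical": name,
                "beta": float(fit.beta.iloc[0]),
                "se": float(fit.se.iloc[0]),
                "n_obs": fit.n_obs,
            }
        )
    return pd.DataFrame(rows)


def run_sensitivity_suite(
    outcomes: pd.DataFrame,
    processed: ProcessedPanel,
    covariates: pd.DataFrame,
    completed: pd.Series | None = None,
    prior_range: float = 20.0,
    small_prior_range: float = 10.0,
    coverage: float = 0.95,
    zspec: ExchangeabilitySpec | None = None,
    scenarios: tuple[str, ...] = SCENARIOS,
) -> SensitivityReport:
    """Run the main model plus the sensitivity scenarios on one cohort."""
    if zspec is None:
        zspec = build_exchangeability(processed.chemicals)
    coded = processed.data
    rows: list[dict] = []

    def add(scenario: str, fit: FirstStageFit, tau2: Tau2Spec | float | None):
        if tau2 is None:
            beta, se = fit.beta, fit.se
            tau2_val = np.nan
        else:
            result = shrink(fit, zspec, tau2)
            beta, se = result.beta_star, result.se_star
            tau2_val = result.tau2_used
        for name in beta.index:
            rows.append(
                {
                    "scenario": scenario,
                    "chemical": name,
                    "beta": float(beta[name]),
                    "se": float(se[name]),
                    "tau2": tau2_val,
                    "n_obs": fit.n_obs,
                }
            )

    main_fit = fit_repeated_model(outcomes, coded, covariates)
    if "main" in scenarios:
        add("main", main_fit, tau2_from_range(prior_range, coverage))
    if "tau2_small" in scenarios:
        add("tau2_small", main_fit, tau2_from_range(small_prior_range, coverage))
    if "empirical_bayes" in scenarios:
        tau2_hat = empirical_bayes_tau2(
            main_fit.beta.to_numpy(), main_fit.V.to_numpy(), zspec.Z.loc[main_fit.labels].to_numpy()
        )
        add("empirical_bayes", main_fit, tau2_hat)
    if "ipw" in scenarios:
        if completed is None or bool(completed.all()):
            w = None
        else:
            w = ipw_weights(covariate_design(covariates), completed)
        ipw_fit = fit_repeated_model(outcomes, coded, covariates, weights=w)
        add("ipw", ipw_fit, tau2_from_range(prior_range, coverage))
    if "single_pollutant" in scenarios:
        sp = single_pollutant_fits(outcomes, coded, covariates)
        for _, r in sp.iterrows():
            rows.append(
                {
                    "scenario": "single_pollutant",
                    "chemical": r["chemical"],
                    "beta": r["beta"],
                    "se": r["se"],
                    "tau2": np.nan,
                    "n_obs": r["n_obs"],
                }
            )

    table = pd.DataFrame(rows)
    # every scenario must cover the identical chemical list
    by_scenario = table.groupby("scenario")["chemical"].apply(set)
    if len(by_scenario) and any(s != set(coded.columns) for s in by_scenario):
        raise AssertionError("scenarios cover different chemical lists")
    return SensitivityReport(table=table)


@dataclass
class SexInteractionResult:
    chemical: str
    beta_girls: float
    ci_girls: tuple[float, float]
    beta_boys: float
    ci_boys: tuple[float, float]
    interaction_p: float

    @property
    def display(self) -> bool:
        # display rule for the stratified figure
        return self.interaction_p < 0.10


def sex_interaction(
    outcomes: pd.DataFrame,
    coded: pd.DataFrame,
    covariates: pd.DataFrame,
    chemical: str,
    sex_column: str = "child_sex",
    girl_level: str = "girl",
) -> SexInteractionResult:
    """Single-pollutant repeated-measures model with a chemical x sex product
    term; returns sex-specific slopes and the Wald interaction p-value."""
    sex_raw = covariates[sex_column]
    levels = sorted(set(sex_raw.astype(str)))
    if len(levels) < 2:
        raise ValueError("sex interaction requires both sexes in the cohort")
    girl = (sex_raw.astype(str) == girl_level).astype(float)

    x = coded[chemical]
    ex = pd.DataFrame(
        {
            chemical: x,
            "girl": girl,
            f"{chemical}:girl": x * girl,
        },
        index=coded.index,
    )
    other_cov = covariates.drop(columns=[sex_column])
    fit = fit_repeated_model(outcomes, ex, other_cov)

    b = fit.beta
    V = fit.V
    beta_boys = float(b[chemical])
    se_boys = float(np.sqrt(V.loc[chemical, chemical]))
    inter = f"{chemical}:girl"
    beta_girls = float(b[chemical] + b[inter])
    var_girls = float(
        V.loc[chemical, chemical] + V.loc[inter, inter] + 2.0 * V.loc[chemical, inter]
    )
    se_girls = float(np.sqrt(var_girls))
    z_int = float(b[inter] / np.sqrt(V.loc[inter, inter]))
    p_int = float(2.0 * stats.norm.sf(abs(z_int)))
    z = float(stats.norm.ppf(0.975))
    return SexInteractionResult(
        chemical=chemical,
        beta_girls=beta_girls,
        ci_girls=(beta_girls - z * se_girls, beta_girls + z * se_girls),
        beta_boys=beta_boys,
        ci_boys=(beta_boys - z * se_boys, beta_boys + z * se_boys),
        interaction_p=p_int,
    )
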