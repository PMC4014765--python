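"""Stage-one repeated-measures linear model.

Outcome scores are regressed on every coded exposure plus confounders in a
single linear model with a child-level random intercept (compound symmetry),
estimated by restricted maximum likelihood. Optional per-subject weights scale
each subject's contribution to the likelihood, which is what the
inverse-probability-weighted sensitivity analysis needs; with all weights
equal to one the fit is the ordinary REML fit.

The compound-symmetry structure makes every per-subject covariance
R_i(rho) = (1 - rho) I + rho J, whose inverse and determinant are analytic,
so the REML criterion reduces to a one-dimensional profile over rho.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cohort import covariate_design


@dataclass
class FirstStageFit:
    """Exposure coefficient vector and its joint covariance."""

    beta: pd.Series
    V: pd.DataFrame
    labels: list[str]
    confounder_estimates: pd.Series
    n_obs: int
    n_children: int
    icc: float
    sigma2: float
    params: pd.Series  # all fixed effects
    cov_params: pd.DataFrame

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.V.to_numpy())), index=self.beta.index, name="se")


class SingularDesignError(ValueError):
    pass


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps * 1e3
    bad = [names[i] for i in np.where(diag < tol)[0]]
    if bad:
        raise SingularDesignError(
            "design matrix is rank deficient; dependent columns: " + ", ".join(bad)
        )


def _reml_profile(
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    w_row: np.ndarray,
    w_grp: np.ndarray,
    n_i: np.ndarray,
):
    """Return f(rho) -> (criterion, beta, A, sigma2) for the profiled REML."""
    p = X.shape[1]
    N = X.shape[0]
    Xw = X * w_row[:, None]
    XtWX = X.T @ Xw
    XtWy = Xw.T @ y

    def group_sum_mat(M: np.ndarray) -> np.ndarray:
        out = np.zeros((n_groups, M.shape[1]))
        np.add.at(out, group_idx, M)
        return out

    S = group_sum_mat(X)  # group sums of rows of X
    t = np.zeros(n_groups)
    np.add.at(t, group_idx, y)

    logdet_R_base = n_i - 1.0  # coefficient of log(1-rho)

    def evaluate(rho: float):
        c = rho / (1.0 + (n_i - 1.0) * rho)  # per group
        wc = w_grp * c
        A = (XtWX - S.T @ (S * wc[:, None])) / (1.0 - rho)
        b = (XtWy - S.T @ (t * wc)) / (1.0 - rho)
        beta = np.linalg.solve(A, b)
        r = y - X @ beta
        rg = np.zeros(n_groups)
        np.add.at(rg, group_idx, r)
        Q = (float(r @ (w_row * r)) - float(wc @ (rg**2))) / (1.0 - rho)
        sigma2 = Q / (N - p)
        logdet_R = float(logdet_R_base.sum()) * np.log1p(-rho) + float(
            np.sum(np.log(1.0 + (n_i - 1.0) * rho))
        )
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0 or sigma2 <= 0:
            return np.inf, beta, A, sigma2
        crit = (N - p) * np.log(sigma2) + logdet_R + logdet_A
        return crit, beta, A, sigma2

    return evaluate


def _fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    subject_weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """REML fit of the random-intercept model; returns (beta, cov, rho, sigma2)."""
    n_i = np.bincount(group_idx, minlength=n_groups).astype(float)
    w_grp = np.asarray(subject_weights, dtype=float)
    w_row = w_grp[group_idx]
    evaluate = _reml_profile(y, X, group_idx, n_groups, w_row, w_grp, n_i)

    if np.all(n_i <= 1):
        rho = 0.0
    else:
        res = minimize_scalar(
            lambda r: evaluate(r)[0], bounds=(0.0, 1.0 - 1e-6), method="bounded",
            options={"xatol": 1e-8},
        )
        rho = float(res.x)
        if evaluate(0.0)[0] < evaluate(rho)[0]:
            rho = 0.0
    _, beta, A, sigma2 = evaluate(rho)
    cov = sigma2 * np.linalg.inv(A)
    cov = 0.5 * (cov + cov.T)
    return beta, cov, rho, sigma2


def fit_repeated_model(
    outcomes: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    weights: pd.Series | None = None,
    include_age_term: bool = True,
) -> FirstStageFit:
    """Fit the repeated-measures model of scores on all coded exposures.

    Parameters
    ----------
    outcomes : rows (subject_id, age, score), one or two rows per child.
    exposures : coded exposure matrix indexed by subject_id.
    covariates : optional raw covariate table (categoricals are expanded to
        reference-coded indicators, continuous columns pass through).
    weights : optional per-subject weights (e.g. stabilized IPW), indexed by
        subject_id; subjects missing from the index get weight 1.
    include_age_term : add a visit-age indicator (age 5 vs 4).
    """
    df = outcomes.reset_index(drop=True)
    subj = df["subject_id"].to_numpy()
    keep = pd.Index(subj).isin(exposures.index)
    if not keep.all():
        df = df.loc[keep].reset_index(drop=True)
        subj = df["subject_id"].to_numpy()

    exposure_cols = list(exposures.columns)
    blocks = [pd.DataFrame({"intercept": np.ones(len(df))})]
    blocks.append(exposures.loc[subj].reset_index(drop=True))
    if covariates is not None and len(covariates.columns):
        design = covariate_design(covariates)
        blocks.append(design.loc[subj].reset_index(drop=True))
    if include_age_term:
        ages = sorted(df["age"].unique())
        if len(ages) > 1:
            blocks.append(
                pd.DataFrame({"age_late": (df["age"] == ages[-1]).to_numpy(dtype=float)})
            )
    Xdf = pd.concat(blocks, axis=1)
    names = list(Xdf.columns)
    X = Xdf.to_numpy(dtype=float)
    y = df["score"].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"more parameters ({X.shape[1]}) than observations ({X.shape[0]})"
        )
    _check_rank(X, names)

    groups, group_idx = np.unique(subj, return_inverse=True)
    if weights is None:
        w = np.ones(len(groups))
    else:
        w = np.array([float(weights.get(g, 1.0)) for g in groups])
        if np.any(w <= 0):
            raise ValueError("subject weights must be positive")

    beta_all, cov_all, rho, sigma2 = _fit_reml(y, X, group_idx, len(groups), w)
    if np.linalg.eigvalsh(cov_all).min() < -1e-8 * max(1.0, np.abs(cov_all).max()):
        raise ValueError("fitted coefficient covariance is not positive semidefinite")

    params = pd.Series(beta_all, index=names, name="estimate")
    cov_params = pd.DataFrame(cov_all, index=names, columns=names)
    beta = params.loc[exposure_cols]
    V = cov_params.loc[exposure_cols, exposure_cols]
    other = [n for n in names if n not in exposure_cols]
    return FirstStageFit(
        beta=beta,
        V=V,
        labels=exposure_cols,
        confounder_estimates=params.loc[other],
        n_obs=len(df),
        n_children=len(groups),
        icc=rho,
        sigma2=sigma2,
        params=params,
        cov_params=cov_params,
    )


def icc(outcomes: pd.DataFrame) -> float:
    """Intraclass correlation of repeated scores from an intercept-only
    variance-components (random-intercept REML) fit."""
    counts = outcomes.groupby("subject_id").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("ICC requires at least two subjects with repeated records")
    subj = outcomes["subject_id"].to_numpy()
    groups, group_idx = np.unique(subj, return_inverse=True)
    y = outcomes["score"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    _, _, rho, _ = _fit_reml(y, X, group_idx, len(groups), np.ones(len(groups)))
    return float(rho)
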