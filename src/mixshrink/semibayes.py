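"""Second-stage semi-Bayesian shrinkage.

First-stage exposure coefficients are regressed on an exchangeability design
of chemical-group indicators by generalized least squares with weight matrix
W = (V + tau^2 I)^(-1), and each coefficient is pulled toward its fitted group
mean in proportion to its (im)precision. tau^2 is either prespecified from an
assumed coefficient range or estimated from the data (empirical Bayes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .chemicals import ChemicalRecord
from .first_stage import FirstStageFit

#: Fixed second-stage column order: intercept, metabolite groups, classes,
#: persistence.
EXCHANGEABILITY_COLUMNS = (
    "intercept",
    "DBP_metabolites",
    "DEHP_metabolites",
    "BFR",
    "PFAS",
    "PCB",
    "OC_pesticide",
    "persistent",
)

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class Tau2Spec:
    """tau^2 derived from an assumed range of plausible coefficients."""

    prior_range: float
    coverage: float
    value: float


@dataclass
class ExchangeabilitySpec:
    Z: pd.DataFrame  # chemicals x columns, 0/1 with leading intercept
    column_labels: list[str]

    def __post_init__(self) -> None:
        arr = self.Z.to_numpy(dtype=float)
        if not np.all(arr[:, 0] == 1.0):
            raise ValueError("first exchangeability column must be the intercept")
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("exchangeability entries must be 0/1")


@dataclass
class ShrinkageResult:
    beta_star: pd.Series
    se_star: pd.Series
    ci95: pd.DataFrame  # columns: ci_low, ci_high
    pi_hat: pd.Series
    tau2_used: float
    cov_star: pd.DataFrame
    prior_mean: pd.Series  # fitted second-stage mean Z @ pi_hat per chemical


def tau2_from_range(prior_range: float, coverage: float = 0.95) -> Tau2Spec:
    """tau^2 such that a Normal(0, tau^2) coefficient falls inside an interval
    of width ``prior_range`` with probability ``coverage``:
    tau^2 = (range / (2 z))^2 with z the standard-normal quantile at
    (1 + coverage)/2."""
    if not prior_range > 0:
        raise ValueError("prior_range must be positive")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must lie in (0, 1)")
    z = float(stats.norm.ppf((1.0 + coverage) / 2.0))
    return Tau2Spec(prior_range=prior_range, coverage=coverage, value=(prior_range / (2.0 * z)) ** 2)


def build_exchangeability(chemicals: list[ChemicalRecord]) -> ExchangeabilitySpec:
    """Indicator design: DBP/DEHP metabolite groups, BFR/PFAS/PCB/OC classes,
    and persistence (serum-measured), plus an intercept."""
    rows = []
    for c in chemicals:
        row = dict.fromkeys(EXCHANGEABILITY_COLUMNS, 0.0)
        row["intercept"] = 1.0
        if c.metabolite_group == "DBP":
            row["DBP_metabolites"] = 1.0
        elif c.metabolite_group == "DEHP":
            row["DEHP_metabolites"] = 1.0
        if c.chem_class in ("BFR", "PFAS", "PCB", "OC_pesticide"):
            row[c.chem_class] = 1.0
        row["persistent"] = 1.0 if c.persistent else 0.0
        rows.append(row)
    Z = pd.DataFrame(rows, index=pd.Index([c.name for c in chemicals], name="chemical"))
    Z = Z[list(EXCHANGEABILITY_COLUMNS)]
    return ExchangeabilitySpec(Z=Z, column_labels=list(EXCHANGEABILITY_COLUMNS))


def _as_matrix(V, p: int) -> np.ndarray:
    V = np.asarray(V, dtype=float)
    if V.ndim == 1:
        V = np.diag(V)
    if V.shape != (p, p):
        raise ValueError(f"V must be {p}x{p}")
    return V


def second_stage_gls(
    beta: np.ndarray,
    V: np.ndarray,
    Z: np.ndarray,
    tau2: float,
    allow_rank_deficient: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """GLS of beta on Z with weight W = (V + tau^2 I)^(-1):
    pi_hat = (Z'WZ)^(-1) Z'W beta, cov_pi = (Z'WZ)^(-1).

    With ``allow_rank_deficient=True`` a rank-deficient Z is handled by the
    Moore-Penrose pseudoinverse (pi_hat is then the minimum-norm solution;
    the fitted group means Z @ pi_hat are unique either way). Note the full
    indicator design is exactly collinear whenever the persistence column
    equals the sum of the serum-class columns, which shrink() tolerates.
    """
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    V = _as_matrix(V, p)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    M = V + tau2 * np.eye(p)
    W = np.linalg.inv(M)
    W = 0.5 * (W + W.T)
    evals, evecs = np.linalg.eigh(W)
    Whalf = (evecs * np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T

    from scipy.linalg import qr as _qr

    _, R, piv = _qr(Whalf @ Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = (diag[0] if diag.size else 0.0) * max(Z.shape) * np.finfo(float).eps * 1e3
    rank = int((diag > tol).sum())
    ZtWZ = Z.T @ W @ Z
    if rank < Z.shape[1]:
        if not allow_rank_deficient:
            bad = sorted(int(j) for j in piv[rank:])
            raise ValueError(
                f"exchangeability design is rank deficient (collinear columns {bad})"
            )
        cov_pi = np.linalg.pinv(ZtWZ)
    else:
        cov_pi = np.linalg.inv(ZtWZ)
    pi_hat = cov_pi @ (Z.T @ W @ beta)
    return pi_hat, cov_pi


def shrink(fit: FirstStageFit, zspec: ExchangeabilitySpec, tau2: Tau2Spec | float) -> ShrinkageResult:
    """Semi-Bayes posterior coefficients.

    beta* = beta - V W (beta - Z pi_hat), W = (V + tau^2 I)^(-1)
    Cov(beta*) = V - V W V + V W Z (Z'WZ)^(-1) Z' W V
    """
    tau2_value = tau2.value if isinstance(tau2, Tau2Spec) else float(tau2)
    names = list(fit.beta.index)
    Zdf = zspec.Z.loc[names]
    beta = fit.beta.to_numpy(dtype=float)
    V = fit.V.to_numpy(dtype=float)
    Z = Zdf.to_numpy(dtype=float)
    p = beta.shape[0]

    pi_hat, cov_pi = second_stage_gls(beta, V, Z, tau2_value, allow_rank_deficient=True)
    W = np.linalg.inv(V + tau2_value * np.eye(p))
    prior_mean = Z @ pi_hat
    beta_star = beta - V @ W @ (beta - prior_mean)
    VW = V @ W
    cov_star = V - VW @ V + VW @ Z @ cov_pi @ Z.T @ W @ V
    cov_star = 0.5 * (cov_star + cov_star.T)
    se_star = np.sqrt(np.clip(np.diag(cov_star), 0.0, None))

    idx = pd.Index(names, name="chemical")
    ci = pd.DataFrame(
        {"ci_low": beta_star - Z975 * se_star, "ci_high": beta_star + Z975 * se_star},
        index=idx,
    )
    return ShrinkageResult(
        beta_star=pd.Series(beta_star, index=idx, name="beta_star"),
        se_star=pd.Series(se_star, index=idx, name="se_star"),
        ci95=ci,
        pi_hat=pd.Series(pi_hat, index=zspec.column_labels, name="pi_hat"),
        tau2_used=tau2_value,
        cov_star=pd.DataFrame(cov_star, index=idx, columns=idx),
        prior_mean=pd.Series(prior_mean, index=idx, name="prior_mean"),
    )


def empirical_bayes_tau2(beta: np.ndarray, V: np.ndarray, Z: np.ndarray) -> float:
    """Estimate tau^2 by restricted maximum likelihood of
    beta ~ Normal(Z pi, V + tau^2 I), profiling over pi; returns 0 at the
    boundary."""
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    V = _as_matrix(V, p)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    q = int(np.linalg.matrix_rank(Z))
    if p <= q:
        raise ValueError("need more coefficients than independent exchangeability columns")

    def neg2_reml(tau2: float) -> float:
        M = V + tau2 * np.eye(p)
        try:
            cF = np.linalg.cholesky(M)
        except np.linalg.LinAlgError:
            return np.inf
        logdetM = 2.0 * float(np.sum(np.log(np.diag(cF))))
        W = np.linalg.inv(M)
        ZtWZ = Z.T @ W @ Z
        # pseudo-log-determinant: tolerates an exactly collinear indicator set
        ev = np.linalg.eigvalsh(ZtWZ)
        tol = ev.max() * Z.shape[1] * np.finfo(float).eps * 1e3
        keep = ev > tol
        if not keep.any():
            return np.inf
        logdetZ = float(np.sum(np.log(ev[keep])))
        pi_hat = np.linalg.pinv(ZtWZ) @ (Z.T @ W @ beta)
        r = beta - Z @ pi_hat
        return logdetM + logdetZ + float(r @ W @ r)

    spread = float(np.var(beta, ddof=1)) + float(np.mean(np.diag(V)))
    upper = max(10.0 * spread, 1e-6)
    res = minimize_scalar(neg2_reml, bounds=(0.0, upper), method="bounded", options={"xatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"empirical-Bayes tau2 optimization failed: {res.message}")
    tau2_hat = float(res.x)
    if neg2_reml(0.0) <= res.fun:
        return 0.0
    if upper - tau2_hat < 1e-3 * upper:
        # optimum stuck at the search boundary: widen once, then fail
        res2 = minimize_scalar(
            neg2_reml, bounds=(0.0, 100.0 * upper), method="bounded", options={"xatol": 1e-10}
        )
        if not res2.success or 100.0 * upper - res2.x < 1e-3 * upper:
            raise RuntimeError("empirical-Bayes tau2 did not converge (unbounded estimate)")
        tau2_hat = float(res2.x)
    return tau2_hat
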