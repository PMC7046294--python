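"""Covariate-adjusted association statistics shared across the pipeline.

Every group comparison in the pipeline controls for the two clinical
covariates that differ between ancestry groups — age at diagnosis and tumor
grade — through a single propensity score: the fitted probability of
belonging to the group of interest given age and (integer-coded ordinal)
grade. The score enters downstream logistic and linear models as one
covariate rather than through matching or weighting.

Also provided here: inverse-normal rank transformation (Blom offset),
Fisher's exact test on 2x2 tables, and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClinicalTable",
    "PropensityModel",
    "AssociationResult",
    "fit_propensity",
    "adjusted_logistic",
    "adjusted_linear_ranknorm",
    "fisher_2x2",
    "bh_fdr",
    "rank_inverse_normal",
]


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    group is the binary indicator of the group of interest (1 = group of
    interest); grade is an ordinal category drawn from ``grade_levels``
    (low to high).
    """

    sample_ids: list[str]
    group: np.ndarray
    age: np.ndarray
    grade: list
    grade_levels: tuple = (6, 7, 8, 9, 10)

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=int)
        self.age = np.asarray(self.age, dtype=float)
        if set(np.unique(self.group)) - {0, 1}:
            raise ValueError("group indicator must be binary 0/1")
        unknown = set(self.grade) - set(self.grade_levels)
        if unknown:
            raise ValueError(f"grades outside declared ordered set: {sorted(unknown)}")

    def grade_numeric(self) -> np.ndarray:
        """Integer rank of each grade within the declared ordered set."""
        lookup = {g: i for i, g in enumerate(self.grade_levels)}
        return np.array([lookup[g] for g in self.grade], dtype=float)

    @classmethod
    def from_tsv(cls, path, **kw) -> "ClinicalTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sample_ids=df["sample"].astype(str).tolist(),
            group=df["group"].to_numpy(),
            age=df["age"].to_numpy(),
            grade=df["grade"].tolist(),
            **kw,
        )


@dataclass
class PropensityModel:
    coef: np.ndarray
    scores: np.ndarray  # fitted P(group=1 | age, grade), in (0,1)
    penalized: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if np.any((s <= 0) | (s >= 1)):
            # numerical guard: clip into the open interval
            self.scores = np.clip(s, 1e-12, 1 - 1e-12)


@dataclass
class AssociationResult:
    unit: str
    effect: float  # OR for logistic/Fisher, coefficient for linear
    ci_low: float
    ci_high: float
    p: float
    q: float = np.nan
    method: str = ""
    flags: str = ""
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "unit": self.unit,
            "effect": self.effect,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "q": self.q,
            "method": self.method,
            "flags": self.flags,
        }


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy TSV-ready frame; q filled by BH across the listed results."""
    df = pd.DataFrame([r.to_row() for r in results])
    ok = df["p"].notna().to_numpy()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok] = bh_fdr(df.loc[ok, "p"].to_numpy())
    df["q"] = q
    for r, qi in zip(results, q):
        r.q = qi
    return df


# ---------------------------------------------------------------------------
# propensity score
# ---------------------------------------------------------------------------

def fit_propensity(clinical: ClinicalTable) -> PropensityModel:
    """Logistic regression of group on age + integer-coded ordinal grade.

    Perfect separation triggers a ridge-penalized fallback (flagged); the
    scores are then the penalized fitted probabilities.
    """
    y = clinical.group
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be present to fit a propensity score")
    X = sm.add_constant(
        np.column_stack([clinical.age, clinical.grade_numeric()]), has_constant="add"
    )
    penalized = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 30):
            raise ValueError("unstable fit")
    except Exception:
        fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0)
        penalized = True
    scores = np.clip(fit.predict(X), 1e-12, 1 - 1e-12)
    return PropensityModel(coef=np.asarray(fit.params), scores=scores, penalized=penalized)


# ---------------------------------------------------------------------------
# adjusted models
# ---------------------------------------------------------------------------

def _ridge_logistic(y, X, alpha=0.5):
    """Newton solver for an L2-penalized logistic fit (intercept unpenalized).

    Used only as a fallback under separation; Wald statistics come from the
    penalized information matrix and are flagged as approximate.
    """
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0
    beta = np.zeros(p)
    for _ in range(100):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * W) @ X + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = (X.T * (mu * (1 - mu))) @ X + np.diag(pen)
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


def adjusted_logistic(
    outcome: np.ndarray,
    exposure: np.ndarray,
    propensity: PropensityModel | np.ndarray | None,
    unit: str = "",
) -> AssociationResult:
    """Wald OR/CI/p for the exposure term, with the propensity score as covariate."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome needs at least one event and one non-event")
    cols = [np.ones_like(y), x]
    if propensity is not None:
        ps = propensity.scores if isinstance(propensity, PropensityModel) else np.asarray(propensity)
        if np.ptp(ps) > 1e-12:  # constant covariate contributes nothing
            cols.append(ps)
    X = np.column_stack(cols)
    flags = ""
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        beta, se = np.asarray(fit.params), np.asarray(fit.bse)
        if not np.all(np.isfinite(se)) or np.abs(beta[1]) > 30:
            raise ValueError("separation")
        method = "logistic"
    except Exception:
        beta, se = _ridge_logistic(y, X)
        method = "ridge_logistic"
        flags = "penalized"
    z = beta[1] / se[1]
    p = 2 * st.norm.sf(abs(z))
    return AssociationResult(
        unit=unit,
        effect=float(np.exp(beta[1])),
        ci_low=float(np.exp(beta[1] - 1.959963984540054 * se[1])),
        ci_high=float(np.exp(beta[1] + 1.959963984540054 * se[1])),
        p=float(p),
        method=method,
        flags=flags,
        extra={"z": float(z), "log_or": float(beta[1]), "se": float(se[1])},
    )


def rank_inverse_normal(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom inverse-normal transform of ranks; ties get average ranks."""
    x = np.asarray(x, dtype=float)
    r = st.rankdata(x, method="average")
    n = len(x)
    return st.norm.ppf((r - offset) / (n - 2 * offset + 1))


def adjusted_linear_ranknorm(
    outcome: np.ndarray,
    exposure: np.ndarray,
    propensity: PropensityModel | np.ndarray | None,
    unit: str = "",
) -> AssociationResult:
    """OLS of the rank-normalized outcome on exposure + propensity score."""
    y = np.asarray(outcome, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(y) == 0:
        return AssociationResult(unit=unit, effect=np.nan, ci_low=np.nan,
                                 ci_high=np.nan, p=np.nan,
                                 method="ranknorm_ols", flags="constant_outcome")
    z = rank_inverse_normal(y)
    cols = [np.asarray(exposure, dtype=float)]
    if propensity is not None:
        ps = propensity.scores if isinstance(propensity, PropensityModel) else np.asarray(propensity)
        if np.ptp(ps) > 1e-12:
            cols.append(ps)
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    fit = sm.OLS(z, X).fit()
    ci = fit.conf_int()[1]
    return AssociationResult(
        unit=unit,
        effect=float(fit.params[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(fit.pvalues[1]),
        method="ranknorm_ols",
        extra={"t": float(fit.tvalues[1])},
    )


def adjusted_linear(
    outcome: np.ndarray,
    exposure: np.ndarray,
    propensity: PropensityModel | np.ndarray | None,
    unit: str = "",
) -> AssociationResult:
    """Plain OLS of outcome on exposure + propensity score (no rank transform)."""
    y = np.asarray(outcome, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(y) == 0:
        return AssociationResult(unit=unit, effect=np.nan, ci_low=np.nan,
                                 ci_high=np.nan, p=np.nan, method="ols",
                                 flags="constant_outcome")
    cols = [np.asarray(exposure, dtype=float)]
    if propensity is not None:
        ps = propensity.scores if isinstance(propensity, PropensityModel) else np.asarray(propensity)
        if np.ptp(ps) > 1e-12:
            cols.append(ps)
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()[1]
    return AssociationResult(
        unit=unit, effect=float(fit.params[1]), ci_low=float(ci[0]),
        ci_high=float(ci[1]), p=float(fit.pvalues[1]), method="ols",
        extra={"t": float(fit.tvalues[1])},
    )


# ---------------------------------------------------------------------------
# Fisher's exact test and BH FDR
# ---------------------------------------------------------------------------

def fisher_2x2(table, unit: str = "") -> AssociationResult:
    """Two-sided Fisher's exact test on a 2x2 table of non-negative integers.

    The p-value is exact (sum of hypergeometric table probabilities no
    larger than the observed one). The reported OR is the sample odds ratio
    (ad/bc) with the Haldane 0.5 correction applied only when a cell is
    zero; the correction affects the display OR/CI, never the p-value.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    _, p = st.fisher_exact(t, alternative="two-sided")
    flags = ""
    tc = t.copy()
    if np.any(t == 0):
        tc = t + 0.5
        flags = "haldane"
    a, b, c, d = tc.ravel()
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = np.exp(np.log(orr) - 1.959963984540054 * se)
    hi = np.exp(np.log(orr) + 1.959963984540054 * se)
    return AssociationResult(
        unit=unit, effect=float(orr), ci_low=float(lo), ci_high=float(hi),
        p=float(p), method="fisher_exact", flags=flags,
        extra={"table": t.astype(int).tolist()},
    )


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
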