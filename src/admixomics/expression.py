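"""Differential expression between ancestry groups.

The DE stage is a deliberately simplified negative-binomial Wald test:
median-of-ratios size factors, per-gene method-of-moments dispersion on
normalized counts, an NB log-linear model (group + optional propensity
covariate) fit by IRLS vectorized across genes, and a Wald test on the
group coefficient. There is no dispersion shrinkage, no fold-change
shrinkage, and no independent filtering; a pluggable reader lets an
externally computed DE table be substituted where those refinements
matter. Sign convention: positive log2 fold change = higher expression in
the group coded 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from . import costats

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "DEResult",
    "size_factors_median_ratio",
    "nb_wald_de",
    "direction_concordance",
    "fold_change_screen",
]


@dataclass
class CountMatrix:
    """Genes x samples raw counts, optionally with per-gene biotypes."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_genes, n_samples) non-negative integers
    biotypes: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count shape does not match id lists")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @classmethod
    def from_tsv(cls, path, biotype_path=None) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        biotypes = None
        if biotype_path is not None:
            bt = pd.read_csv(biotype_path, sep="\t", index_col=0)
            biotypes = bt.reindex(df.index).iloc[:, 0].fillna("other").tolist()
        return cls(df.index.astype(str).tolist(), df.columns.astype(str).tolist(),
                   df.to_numpy(), biotypes)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.gene_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")


@dataclass
class DEResult:
    df: pd.DataFrame  # gene, log2fc, se, wald, p, q, base_mean, filtered

    @classmethod
    def from_tsv(cls, path) -> "DEResult":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def ranked_by_wald(self) -> pd.DataFrame:
        ok = self.df[~self.df["filtered"]].copy()
        # stable order by gene id among exact ties
        return ok.sort_values(["wald", "gene"], ascending=[False, True])


def size_factors_median_ratio(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes nonzero in every sample."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x samples")
    if counts.shape[1] == 1:
        return np.ones(1)
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with nonzero counts in all samples; "
                         "consider a pseudo-reference normalization")
    sub = counts[allpos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    return np.exp(np.median(np.log(sub) - log_geo, axis=0))


def _mom_dispersion(counts: np.ndarray, sf: np.ndarray, groups: list[np.ndarray],
                    floor: float = 1e-8) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion from normalized counts.

    Uses within-group residual moments (so planted group effects do not
    inflate the estimate): alpha = sum((q-mu)^2 - mu/w) / sum(mu^2) with q
    the normalized counts, mu the group mean and w the size-factor weight
    approximated by 1/sf.
    """
    q = counts / sf[None, :]
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for sel in groups:
        ng = int(sel.sum())
        if ng < 2:
            continue
        qs = q[:, sel]
        mu = qs.mean(axis=1, keepdims=True)
        # unbiased within-group variance; Var(q) = mu/sf + alpha mu^2
        var = ((qs - mu) ** 2).sum(axis=1) / (ng - 1)
        inv_sf = np.mean(1.0 / sf[sel])
        num += (var - mu[:, 0] * inv_sf)
        den += mu[:, 0] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = num / den
    return np.clip(np.where(np.isfinite(alpha), alpha, floor), floor, 10.0)


def nb_wald_de(counts: CountMatrix, group: np.ndarray, propensity=None,
               size_factors: np.ndarray | None = None,
               max_iter: int = 50, tol: float = 1e-8) -> DEResult:
    """Simplified NB Wald differential-expression test.

    Per gene: log mu = log(sf) + b0 + b1*group (+ b2*propensity); the Wald
    statistic b1/se(b1) is referred to the standard normal. All-zero genes
    are flagged ``filtered`` and excluded from testing and from the BH
    denominator.
    """
    y = np.asarray(counts.counts, dtype=float)
    g = np.asarray(group, dtype=float)
    if (g == 1).sum() < 3 or (g == 0).sum() < 3:
        raise ValueError("need >=3 samples per group")
    sf = size_factors_median_ratio(y) if size_factors is None else np.asarray(size_factors)
    ps = None
    if propensity is not None:
        ps = propensity.scores if isinstance(propensity, costats.PropensityModel) else np.asarray(propensity)
        if np.ptp(ps) <= 1e-12:
            ps = None

    G, n = y.shape
    nonzero = y.sum(axis=1) > 0
    cols = [np.ones(n), g] + ([ps] if ps is not None else [])
    X = np.column_stack(cols)          # (n, p), shared across genes
    p_dim = X.shape[1]

    alpha = _mom_dispersion(y, sf, [g == 0, g == 1])
    off = np.log(sf)

    # vectorized IRLS across genes
    idx = np.where(nonzero)[0]
    yk = y[idx]                        # (K, n)
    ak = alpha[idx][:, None]
    # init: intercept at log mean normalized count
    beta = np.zeros((len(idx), p_dim))
    beta[:, 0] = np.log(np.maximum((yk / sf[None, :]).mean(axis=1), 1e-8))
    for _ in range(max_iter):
        eta = off[None, :] + beta @ X.T           # (K, n)
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + ak * mu)                  # NB working weights, log link
        z = (yk - mu) / mu
        # normal equations per gene: (X^T W X) d = X^T W z
        XtWX = np.einsum("kn,np,nq->kpq", W, X, X)
        XtWz = np.einsum("kn,np,kn->kp", W, X, z)
        try:
            step = np.linalg.solve(XtWX + 1e-10 * np.eye(p_dim)[None], XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(
                XtWX.reshape(-1, p_dim, p_dim)[0], XtWz.T, rcond=None)[0].T
        step = np.clip(step, -5, 5)
        beta += step
        if np.max(np.abs(step)) < tol:
            break

    eta = off[None, :] + beta @ X.T
    mu = np.exp(np.clip(eta, -30, 30))
    W = mu / (1.0 + ak * mu)
    XtWX = np.einsum("kn,np,nq->kpq", W, X, X)
    with np.errstate(all="ignore"):
        cov = np.linalg.pinv(XtWX + 1e-10 * np.eye(p_dim)[None])
        se = np.sqrt(cov[:, 1, 1])
        wald = beta[:, 1] / se
        pvals = 2 * st.norm.sf(np.abs(wald))

    log2fc = np.full(G, np.nan)
    se_full = np.full(G, np.nan)
    wald_full = np.full(G, np.nan)
    p_full = np.full(G, np.nan)
    log2fc[idx] = beta[:, 1] / np.log(2.0)
    se_full[idx] = se / np.log(2.0)
    wald_full[idx] = wald
    p_full[idx] = pvals

    bad = ~np.isfinite(p_full) & nonzero
    if bad.any():
        logger.warning("nb_wald_de: %d genes had unstable fits (flagged NA)", int(bad.sum()))
    q_full = np.full(G, np.nan)
    testable = np.isfinite(p_full)
    if testable.any():
        q_full[testable] = costats.bh_fdr(p_full[testable])

    df = pd.DataFrame({
        "gene": counts.gene_ids,
        "log2fc": log2fc,
        "se": se_full,
        "wald": wald_full,
        "p": p_full,
        "q": q_full,
        "base_mean": (y / sf[None, :]).mean(axis=1),
        "filtered": ~nonzero,
    })
    if counts.biotypes is not None:
        df["biotype"] = counts.biotypes
    return DEResult(df)


def direction_concordance(primary: DEResult, secondary: DEResult,
                          deg_mask: np.ndarray | None = None,
                          q_cut: float = 0.1) -> costats.AssociationResult:
    """Fisher test of sign agreement between two cohorts' fold changes.

    Builds the 2x2 table {DEG, non-DEG} x {sign agreement, disagreement}
    over the shared gene universe; DEG status comes from the primary
    cohort (q < ``q_cut``) unless a mask is supplied.
    """
    a = primary.df.set_index("gene")
    b = secondary.df.set_index("gene")
    shared = a.index.intersection(b.index)
    shared = [g for g in shared
              if np.isfinite(a.loc[g, "log2fc"]) and np.isfinite(b.loc[g, "log2fc"])]
    if len(shared) == 0:
        raise ValueError("no shared genes between cohorts")
    a, b = a.loc[shared], b.loc[shared]
    agree = (np.sign(a["log2fc"].to_numpy()) == np.sign(b["log2fc"].to_numpy()))
    if deg_mask is None:
        deg = (a["q"].to_numpy() < q_cut)
    else:
        deg = np.asarray(deg_mask, dtype=bool)
    t = np.array([[int((deg & agree).sum()), int((deg & ~agree).sum())],
                  [int((~deg & agree).sum()), int((~deg & ~agree).sum())]])
    res = costats.fisher_2x2(t, unit="direction_concordance")
    res.extra["agreement_deg"] = float(agree[deg].mean()) if deg.any() else np.nan
    return res


def fold_change_screen(results: DEResult, min_fold: float = 2.0,
                       q_cut: float = 0.1) -> list[str]:
    """Genes with q < q_cut and |log2FC| >= log2(min_fold)."""
    df = results.df
    sel = (df["q"] < q_cut) & (np.abs(df["log2fc"]) >= np.log2(min_fold))
    return df.loc[sel.fillna(False), "gene"].tolist()
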