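"""Set-based enrichment: pre-ranked GSEA, SSEA lineage specificity, and
category (eGene/GWAS/TWAS-style) Fisher enrichment.

Pre-ranked GSEA follows the classical running-sum construction: walking
down the ranked list, hits increment the sum proportionally to
|metric|^weight (normalized so hits total +1) and misses decrement it
uniformly (total -1); the enrichment score (ES) is the extremum of the
walk. The null is random member-set permutation of the universe; NES
normalizes ES by the mean |null ES| of matching sign, and the permutation
p-value is one-sided within the matching sign (reported two-sided-style
against the sign-matched null).

SSEA applies the same machinery to samples ranked by one gene's
expression, with the sample sets defined by cancer type; fractional ranks
convert per-type NES values into within-type percentiles (1 = most
enriched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from . import costats

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "GeneSet",
    "ESResult",
    "SSEAResult",
    "enrichment_score",
    "preranked_gsea",
    "gsea_many",
    "ssea",
    "fractional_ranks",
    "category_enrichment",
    "gwas_proximity_genes",
    "read_gmt",
]


@dataclass
class RankedList:
    """Items ordered by a ranking metric (descending); ties broken by id."""

    ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked list ids must be unique")
        self.metric = np.asarray(self.metric, dtype=float)
        order = sorted(range(len(self.ids)),
                       key=lambda i: (-self.metric[i], self.ids[i]))
        self.ids = [self.ids[i] for i in order]
        self.metric = self.metric[order]


@dataclass
class GeneSet:
    name: str
    members: set

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if len(self.members) < 2:
            raise ValueError("a set needs at least 2 members")


@dataclass
class ESResult:
    name: str
    es: float
    nes: float
    p: float
    q: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    n_members: int = 0


@dataclass
class SSEAResult:
    """Per (gene, cancer type) ES/NES plus per-type fractional ranks."""

    table: pd.DataFrame  # gene, cancer_type, es, nes, fractional_rank


def read_gmt(path) -> list:
    """GMT gene sets: one set per line, name TAB description TAB members."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 4:  # name, description, >=2 members
                sets.append(GeneSet(parts[0], set(parts[2:])))
    return sets


def _walk(hit: np.ndarray, metric: np.ndarray, weight: float) -> np.ndarray:
    """Running-sum values of the enrichment walk (length N)."""
    w = np.abs(metric) ** weight
    w = np.where(hit, w, 0.0)
    tot = w.sum()
    if tot == 0:  # all hit metrics zero: fall back to unweighted hits
        w = hit.astype(float)
        tot = w.sum()
    inc = w / tot
    n_miss = (~hit).sum()
    dec = np.where(hit, 0.0, 1.0 / n_miss) if n_miss else np.zeros_like(inc)
    return np.cumsum(inc - dec)


def enrichment_score(ranking: RankedList, members: set, weight: float = 1.0):
    """ES (signed extremum of the walk) and the walk itself."""
    hit = np.array([i in members for i in ranking.ids])
    if hit.sum() == 0:
        raise ValueError("empty intersection between set and ranked universe")
    walk = _walk(hit, ranking.metric, weight)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i]), walk, hit, i


def _null_es(metric: np.ndarray, n_hit: int, weight: float, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES values from random member sets of the same size (vectorized)."""
    N = len(metric)
    w_all = np.abs(metric) ** weight
    out = np.empty(n_perm)
    # vectorized over permutations in manageable blocks
    block = max(1, min(n_perm, int(4e6 / max(N, 1))))
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        # random hit masks: choose n_hit positions per row
        U = rng.random((b, N))
        part = np.argpartition(U, n_hit - 1, axis=1)[:, :n_hit]
        hit = np.zeros((b, N), dtype=bool)
        np.put_along_axis(hit, part, True, axis=1)
        w = np.where(hit, w_all[None, :], 0.0)
        tot = w.sum(axis=1, keepdims=True)
        zero = tot[:, 0] == 0
        if zero.any():
            w[zero] = hit[zero].astype(float)
            tot = w.sum(axis=1, keepdims=True)
        inc = w / tot
        n_miss = N - n_hit
        dec = np.where(hit, 0.0, 1.0 / n_miss) if n_miss else np.zeros_like(inc)
        walks = np.cumsum(inc - dec, axis=1)
        idx = np.argmax(np.abs(walks), axis=1)
        out[done:done + b] = walks[np.arange(b), idx]
        done += b
    return out


def preranked_gsea(ranking: RankedList, gene_set: GeneSet, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0) -> ESResult:
    """Pre-ranked GSEA for one set; null by random member-set permutation."""
    members = gene_set.members & set(ranking.ids)
    if len(members) < 2:
        return ESResult(name=gene_set.name, es=np.nan, nes=np.nan, p=np.nan,
                        n_members=len(members))
    es, walk, hit, i_ext = enrichment_score(ranking, members, weight)
    rng = np.random.default_rng(seed)
    null = _null_es(ranking.metric, len(members), weight, n_perm, rng)
    same = null * np.sign(es) > 0
    if same.sum() == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / np.mean(np.abs(null[same]))
        p = (1.0 + np.sum(np.abs(null[same]) >= abs(es))) / (same.sum() + 1.0)
    if es >= 0:
        le = [g for g, h in zip(ranking.ids[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        le = [g for g, h in zip(ranking.ids[i_ext:], hit[i_ext:]) if h]
    return ESResult(name=gene_set.name, es=es, nes=float(nes), p=float(p),
                    leading_edge=le, n_members=len(members))


def gsea_many(ranking: RankedList, sets: list[GeneSet], weight: float = 1.0,
              n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """GSEA over a collection of sets with BH adjustment across sets."""
    rng = np.random.default_rng(seed)
    results = [preranked_gsea(ranking, s, weight, n_perm,
                              seed=int(rng.integers(0, 2**31 - 1))) for s in sets]
    df = pd.DataFrame([{
        "set": r.name, "es": r.es, "nes": r.nes, "p": r.p,
        "n_members": r.n_members,
        "leading_edge": ";".join(r.leading_edge),
    } for r in results])
    ok = df["p"].notna().to_numpy()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok] = costats.bh_fdr(df.loc[ok, "p"].to_numpy())
    df["q"] = q
    return df


# ---------------------------------------------------------------------------
# SSEA
# ---------------------------------------------------------------------------

def ssea(expression: pd.DataFrame, sample_types: pd.Series,
         weight: float = 1.0, n_perm: int = 200, seed: int = 0) -> SSEAResult:
    """Lineage specificity of each gene by sample set enrichment.

    ``expression`` is genes x samples; ``sample_types`` maps sample ->
    cancer type (every sample exactly one type). For each gene, samples
    are ranked by expression (descending) and each cancer type's sample
    set is scored exactly as in pre-ranked GSEA. Fractional ranks are then
    assigned within each type across genes.
    """
    sample_types = sample_types.reindex(expression.columns)
    if sample_types.isna().any():
        raise ValueError("every sample must be assigned to exactly one cancer type")
    types = sample_types.unique().tolist()
    counts = sample_types.value_counts()
    usable = [t for t in types if counts[t] >= 2]
    for t in set(types) - set(usable):
        logger.warning("ssea: cancer type %r has < 2 samples; skipped", t)
    rng = np.random.default_rng(seed)
    rows = []
    for gene, row in expression.iterrows():
        ranking = RankedList(expression.columns.tolist(), row.to_numpy(dtype=float))
        for t in usable:
            members = set(sample_types[sample_types == t].index)
            res = preranked_gsea(ranking, GeneSet(t, members), weight, n_perm,
                                 seed=int(rng.integers(0, 2**31 - 1)))
            rows.append({"gene": gene, "cancer_type": t, "es": res.es, "nes": res.nes})
    df = pd.DataFrame(rows)
    df["fractional_rank"] = np.nan
    for t in usable:
        sel = df["cancer_type"] == t
        df.loc[sel, "fractional_rank"] = fractional_ranks(df.loc[sel, "nes"].to_numpy())
    return SSEAResult(df)


def fractional_ranks(nes: np.ndarray) -> np.ndarray:
    """Percentile ranks on (0, 1]; 1 = highest value, ties averaged."""
    nes = np.asarray(nes, dtype=float)
    if nes.size == 0:
        raise ValueError("need at least one value")
    r = st.rankdata(nes, method="average")  # ascending, ties averaged
    return r / len(nes)


# ---------------------------------------------------------------------------
# category enrichment and GWAS proximity
# ---------------------------------------------------------------------------

def category_enrichment(q_values: np.ndarray, category: np.ndarray,
                        fdr_levels: tuple = (0.1, 0.01, 0.001)) -> pd.DataFrame:
    """Fisher enrichment of a gene category among DEGs at several FDR levels."""
    q = np.asarray(q_values, dtype=float)
    cat = np.asarray(category, dtype=bool)
    if len(q) != len(cat):
        raise ValueError("q-values and category indicator must align")
    results = []
    for level in fdr_levels:
        deg = q < level
        t = np.array([[int((deg & cat).sum()), int((deg & ~cat).sum())],
                      [int((~deg & cat).sum()), int((~deg & ~cat).sum())]])
        if t[0].sum() == 0 or t[1].sum() == 0:
            results.append(costats.AssociationResult(
                unit=f"fdr<{level}", effect=np.nan, ci_low=np.nan,
                ci_high=np.nan, p=np.nan, method="fisher_exact",
                flags="empty_stratum"))
            continue
        r = costats.fisher_2x2(t, unit=f"fdr<{level}")
        if (np.asarray(r.extra["table"]) == 0).any():
            r.flags = (r.flags + ";infinite_or" if r.flags else "haldane;infinite_or") \
                if "haldane" not in r.flags else r.flags + ";infinite_or"
        results.append(r)
    return pd.DataFrame([r.to_row() for r in results])


def gwas_proximity_genes(genes: pd.DataFrame, snps: pd.DataFrame,
                         window: int = 1_000_000) -> pd.Series:
    """Flag genes with any SNP within ``window`` bp of the gene span.

    ``genes``: columns gene, chrom, start, end. ``snps``: chrom, pos.
    A gene is flagged when some SNP lies in [start - window, end + window].
    """
    gene_style = {c.startswith("chr") for c in set(genes["chrom"])}
    snp_style = {c.startswith("chr") for c in set(snps["chrom"])}
    if gene_style and snp_style and gene_style != snp_style:
        offenders = sorted(set(snps["chrom"]) - set(genes["chrom"]))
        raise ValueError(f"chromosome naming mismatch; offenders: {offenders}")
    flags = []
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in snps.groupby("chrom")}
    for rec in genes.itertuples(index=False):
        pos = by_chrom.get(rec.chrom)
        if pos is None:
            flags.append(False)
            continue
        lo, hi = rec.start - window, rec.end + window
        i = np.searchsorted(pos, lo, side="left")
        flags.append(bool(i < len(pos) and pos[i] <= hi))
    return pd.Series(flags, index=genes["gene"].tolist(), name="near_gwas")
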