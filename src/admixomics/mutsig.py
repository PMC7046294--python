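"""96-channel mutational spectra and constrained signature refitting.

Each somatic SNV is assigned to one of 96 trinucleotide channels: 6
pyrimidine-centered substitution classes (C>A, C>G, C>T, T>A, T>C, T>G)
crossed with the 4 possible 5' and 4 possible 3' flanking bases. Mutations
reported with a purine reference are reverse-complemented into the
pyrimidine representation.

Channel ordering (stable across versions): substitution-major, then 5'
base, then 3' base, both alphabetical — i.e. A[C>A]A, A[C>A]C, ...,
T[T>G]T. This is the ordering produced by :data:`CHANNELS`.

Refitting solves a non-negative least-squares problem for each tumor's
normalized spectrum against a fixed signature catalog, then applies two
cleaning rules used in practice by refitting tools: weights below 0.06 are
discarded, and any signature whose removal (followed by a refit) costs no
more than 0.02 of cosine similarity to the observed spectrum is pruned,
greedily, lowest weight first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as spo

from . import costats

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
#: canonical channel order, e.g. "A[C>A]A"
CHANNELS = tuple(f"{f}[{s}]{t}" for s in SUBSTITUTIONS for f in BASES for t in BASES)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = [
    "CHANNELS",
    "MutationCatalog",
    "SignatureMatrix",
    "ExposureFit",
    "build_catalog",
    "refit_signatures",
    "cosine_similarity",
    "signature_contribution_association",
    "burden_association",
    "gene_frequency_association",
    "clonality_fisher",
    "builtin_signatures",
]


@dataclass
class MutationCatalog:
    """Per-sample 96-channel mutation counts."""

    sample_ids: list[str]
    counts: np.ndarray  # (n_samples, 96)
    n_skipped: int = 0  # non-SNV or uninterpretable records

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 96:
            raise ValueError("catalog must have 96 channels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=list(CHANNELS))


@dataclass
class SignatureMatrix:
    """96 x S matrix of channel probabilities; columns sum to 1."""

    names: list[str]
    profiles: np.ndarray  # (96, S)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.shape != (96, len(self.names)):
            raise ValueError("profiles must be 96 x n_signatures")
        if np.any(self.profiles < 0):
            raise ValueError("signature entries must be non-negative")
        sums = self.profiles.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("every signature column must sum to 1")

    @classmethod
    def from_tsv(cls, path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.reindex(list(CHANNELS))
        if df.isna().any().any():
            raise ValueError("signature TSV must cover all 96 canonical channels")
        return cls(df.columns.astype(str).tolist(), df.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.profiles, index=list(CHANNELS), columns=self.names).to_csv(path, sep="\t")


@dataclass
class ExposureFit:
    """Refitting result for one sample."""

    sample_id: str
    signature_names: list[str]
    weights: np.ndarray          # full-length vector, zeros for dropped sigs
    discarded: list[str]         # dropped by the 0.06 rule
    pruned: list[str]            # dropped by the 0.02 cosine rule
    cosine: float
    reconstruction: np.ndarray   # (96,) probability vector
    flagged: bool = False

    @property
    def retained(self) -> dict:
        return {n: float(w) for n, w in zip(self.signature_names, self.weights) if w > 0}

    @property
    def weights_renormalized(self) -> np.ndarray:
        s = self.weights.sum()
        return self.weights / s if s > 0 else self.weights


def exposures_to_frame(fits: list[ExposureFit]) -> pd.DataFrame:
    names = fits[0].signature_names
    df = pd.DataFrame([f.weights for f in fits], columns=names,
                      index=[f.sample_id for f in fits])
    df["cosine"] = [f.cosine for f in fits]
    df["flagged"] = [f.flagged for f in fits]
    df.index.name = "sample"
    return df


# ---------------------------------------------------------------------------
# catalog construction
# ---------------------------------------------------------------------------

def channel_of(ref: str, alt: str, context: str) -> str | None:
    """Canonical channel for an SNV with its trinucleotide context.

    ``context`` is the reference trinucleotide centered on the mutated
    base. Purine references are reverse-complemented. Returns None for
    non-SNVs or contexts containing N.
    """
    ref, alt = ref.upper(), alt.upper()
    context = context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        return None
    if ref not in BASES or alt not in BASES or len(context) != 3:
        return None
    if any(b not in BASES for b in context):
        return None
    if context[1] != ref:
        return None
    if ref in ("G", "A"):  # purine: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = "".join(_COMPLEMENT[b] for b in reversed(context))
    sub = f"{ref}>{alt}"
    if sub not in SUBSTITUTIONS:
        return None
    return f"{context[0]}[{sub}]{context[2]}"


def build_catalog(mutations: pd.DataFrame, context_provider=None,
                  sample_ids: list[str] | None = None) -> MutationCatalog:
    """Build a 96-channel catalog from MAF-lite records.

    ``mutations`` needs columns sample, ref, alt and either a ``context``
    column (reference trinucleotide) or chrom/pos resolved through
    ``context_provider(chrom, pos) -> str``. Non-SNV records and records
    whose context contains N are skipped and counted.
    """
    # accept standard MAF column names as-is
    maf_map = {"Tumor_Sample_Barcode": "sample", "Reference_Allele": "ref",
               "Tumor_Seq_Allele2": "alt", "Chromosome": "chrom",
               "Start_Position": "pos"}
    ren = {c: maf_map[c] for c in mutations.columns
           if c in maf_map and maf_map[c] not in mutations.columns}
    if ren:
        mutations = mutations.rename(columns=ren)
    if sample_ids is None:
        sample_ids = sorted(mutations["sample"].astype(str).unique())
    idx = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), 96))
    skipped = 0
    has_ctx = "context" in mutations.columns
    for rec in mutations.itertuples(index=False):
        if has_ctx and isinstance(rec.context, str):
            ctx = rec.context
        elif context_provider is not None:
            ctx = context_provider(rec.chrom, int(rec.pos))
        else:
            skipped += 1
            continue
        ch = channel_of(str(rec.ref), str(rec.alt), str(ctx))
        if ch is None:
            skipped += 1
            continue
        i = idx.get(str(rec.sample))
        if i is None:
            continue
        counts[i, _CHANNEL_INDEX[ch]] += 1
    if skipped:
        logger.info("build_catalog: skipped %d non-SNV/uninterpretable records", skipped)
    return MutationCatalog(list(sample_ids), counts, n_skipped=skipped)


# ---------------------------------------------------------------------------
# refitting
# ---------------------------------------------------------------------------

def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _nnls_weights(spectrum: np.ndarray, profiles: np.ndarray) -> np.ndarray:
    """Normalized non-negative least-squares weights (sum 1 if any mass)."""
    w, _ = spo.nnls(profiles, spectrum)
    s = w.sum()
    return w / s if s > 0 else w


def refit_signatures(spectrum: np.ndarray, sigs: SignatureMatrix,
                     sample_id: str = "", discard_below: float = 0.06,
                     prune_gain: float = 0.02) -> ExposureFit:
    """Refit one 96-channel spectrum onto a fixed signature catalog.

    Steps: (1) NNLS fit of the normalized spectrum; (2) weights normalized
    to sum 1; (3) weights below ``discard_below`` discarded and the sample
    refit on the survivors; (4) greedy pruning, lowest weight first — a
    signature is removed for good if refitting without it lowers the cosine
    similarity to the observed spectrum by at most ``prune_gain``;
    (5) remaining weights reported on the original normalized scale
    (sum <= 1, renormalized view available on the result).
    """
    v = np.asarray(spectrum, dtype=float)
    if v.sum() <= 0:
        raise ValueError("cannot refit an empty spectrum")
    target = v / v.sum()
    P = sigs.profiles
    S = P.shape[1]

    w = _nnls_weights(target, P)
    discarded = [sigs.names[i] for i in range(S) if 0 < w[i] < discard_below]
    active = [i for i in range(S) if w[i] >= discard_below]
    if not active:
        # nothing survives the discard rule: flag, keep best single signature
        best = int(np.argmax(w))
        active = [best]
        flagged = True
    else:
        flagged = False
    w_act = _nnls_weights(target, P[:, active])

    def cos_with(idx_list, weights):
        recon = P[:, idx_list] @ weights
        return cosine_similarity(target, recon)

    pruned: list[str] = []
    improved = True
    while improved and len(active) > 1:
        improved = False
        cos_full = cos_with(active, w_act)
        # re-evaluate candidates lowest-weight-first
        for j in np.argsort(w_act, kind="stable"):
            trial = [a for i, a in enumerate(active) if i != j]
            w_trial = _nnls_weights(target, P[:, trial])
            if cos_full - cos_with(trial, w_trial) <= prune_gain:
                pruned.append(sigs.names[active[j]])
                active, w_act = trial, w_trial
                improved = True
                break

    # map retained weights back to the original normalized scale:
    # refit NNLS on the retained set without renormalizing
    w_final_raw, _ = spo.nnls(P[:, active], target)
    s = w_final_raw.sum()
    if s > 1.0:  # weights live on [0,1]; normalized spectrum keeps sum near 1
        w_final_raw = w_final_raw / s
    weights = np.zeros(S)
    for i, a in enumerate(active):
        weights[a] = w_final_raw[i]
    recon = P[:, active] @ w_final_raw
    cos = cosine_similarity(target, recon) if recon.sum() > 0 else 0.0
    return ExposureFit(sample_id=sample_id, signature_names=list(sigs.names),
                       weights=weights, discarded=discarded, pruned=pruned,
                       cosine=cos, reconstruction=recon, flagged=flagged)


def refit_catalog(catalog: MutationCatalog, sigs: SignatureMatrix,
                  **kw) -> list[ExposureFit]:
    return [refit_signatures(catalog.counts[i], sigs, sample_id=s, **kw)
            for i, s in enumerate(catalog.sample_ids)]


def builtin_signatures() -> SignatureMatrix:
    """Three synthetic, nearly orthogonal test signatures.

    Deterministic Dirichlet-free construction: each signature concentrates
    80% of its mass on a disjoint block of 32 channels with a flat 20%
    background, so pairwise cosine similarity is low (~0.2). Useful for
    tests and demos; real analyses should load a published catalog TSV.
    """
    P = np.full((96, 3), 0.2 / 96)
    for k in range(3):
        block = slice(32 * k, 32 * (k + 1))
        P[block, k] += 0.8 / 32
    P = P / P.sum(axis=0)
    return SignatureMatrix(["SYN1", "SYN2", "SYN3"], P)


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------

def signature_contribution_association(fits: list[ExposureFit], group: np.ndarray,
                                       propensity) -> pd.DataFrame:
    """Per-signature linear model of contribution on group + propensity."""
    group = np.asarray(group)
    if (group == 1).sum() < 2 or (group == 0).sum() < 2:
        raise ValueError("need >=2 samples per group")
    names = fits[0].signature_names
    W = np.array([f.weights for f in fits])
    results = []
    for j, name in enumerate(names):
        if np.ptp(W[:, j]) < 1e-12:
            results.append(costats.AssociationResult(
                unit=name, effect=np.nan, ci_low=np.nan, ci_high=np.nan,
                p=np.nan, method="ols", flags="constant_weight"))
            continue
        results.append(costats.adjusted_linear(W[:, j], group, propensity, unit=name))
    return costats.results_to_frame(results)


def burden_association(totals: np.ndarray, group: np.ndarray,
                       propensity) -> costats.AssociationResult:
    """Rank-normalized burden regressed on group + propensity."""
    totals = np.asarray(totals, dtype=float)
    if len(totals) < 4:
        raise ValueError("need at least 4 samples")
    return costats.adjusted_linear_ranknorm(totals, group, propensity, unit="burden")


def gene_frequency_association(table: pd.DataFrame, group: np.ndarray,
                               propensity, min_freq: float = 0.01) -> pd.DataFrame:
    """Per-gene adjusted logistic models of mutation status on group.

    ``table`` is a samples x genes binary indicator frame. Genes mutated in
    fewer than ``min_freq`` of samples are excluded before testing.
    Separating tables fall back to Fisher's exact test, flagged.
    """
    vals = table.to_numpy()
    if set(np.unique(vals)) - {0, 1}:
        raise ValueError("gene mutation table must be binary")
    group = np.asarray(group)
    freq = vals.mean(axis=0)
    results = []
    for j, gene in enumerate(table.columns):
        if freq[j] < min_freq:
            continue
        y = vals[:, j]
        try:
            res = costats.adjusted_logistic(y, group, propensity, unit=str(gene))
            if res.flags == "penalized":
                raise ValueError("separation")
        except ValueError:
            t = np.array([[int(((group == 1) & (y == 1)).sum()),
                           int(((group == 1) & (y == 0)).sum())],
                          [int(((group == 0) & (y == 1)).sum()),
                           int(((group == 0) & (y == 0)).sum())]])
            res = costats.fisher_2x2(t, unit=str(gene))
            res.flags = (res.flags + ";fisher_fallback").lstrip(";")
        results.append(res)
    return costats.results_to_frame(results)


def clonality_fisher(table) -> costats.AssociationResult:
    """Fisher's exact test on a 2x2 clonal/subclonal x group count table."""
    return costats.fisher_2x2(table, unit="clonality")
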