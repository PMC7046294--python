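"""Supervised genetic-ancestry inference from genotype dosages.

The workflow mirrors the reference-anchored design used for ancestry
calling in tumor cohorts: principal axes of variation are learned from a
labeled reference panel only (so that study samples cannot distort the
axes), study samples are projected onto those axes, each sample is assigned
the majority ancestry label of its k nearest reference neighbors, and a
quantitative ancestral composition is estimated per sample by maximizing a
binomial likelihood over mixtures of the panel's population allele
frequencies.

SNP standardization follows the EIGENSTRAT convention: dosages are centered
at 2p and scaled by sqrt(2p(1-p)), with p the panel allele frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "ReferencePanel",
    "PCModel",
    "Projection",
    "AncestryAssignment",
    "AdmixtureEstimate",
    "fit_reference_pca",
    "project_samples",
    "classify_knn",
    "estimate_admixture",
    "population_frequencies",
]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-dosage matrix; values 0/1/2, NaN = missing."""

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray  # float array, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage shape does not match id lists")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (set(np.unique(vals)) - {0.0, 1.0, 2.0}):
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.astype(str).tolist(), df.columns.astype(str).tolist(),
                   df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)
        # keep integers readable; missing stays empty
        df.to_csv(path, sep="\t", float_format="%.0f")

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read biallelic sites from a VCF, mapping GT to ALT-allele dosage."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        snp_ids, rows = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types, dtype=float)
            dos = np.where(gt == 3, 2.0, gt)
            dos[gt == 2] = np.nan
            rows.append(dos)
        if not rows:
            raise ValueError("no biallelic sites in VCF")
        return cls(samples, snp_ids, np.column_stack(rows))


@dataclass
class ReferencePanel:
    genotypes: GenotypeMatrix
    labels: list[str]  # population label per panel sample

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.genotypes.sample_ids):
            raise ValueError("every panel sample must carry a population label")
        counts = pd.Series(self.labels).value_counts()
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("panel needs >=2 populations with >=2 samples each")

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.labels))


@dataclass
class PCModel:
    snp_ids: list[str]
    center: np.ndarray        # 2p per SNP
    scale: np.ndarray         # sqrt(2p(1-p)) per SNP
    loadings: np.ndarray      # (n_snps, n_axes), orthonormal columns
    eigenvalues: np.ndarray   # decreasing
    n_axes: int


@dataclass
class Projection:
    sample_ids: list[str]
    coords: np.ndarray  # (n_samples, n_axes)

    def to_tsv(self, path) -> None:
        cols = [f"PC{i+1}" for i in range(self.coords.shape[1])]
        pd.DataFrame(self.coords, index=self.sample_ids, columns=cols).to_csv(path, sep="\t")


@dataclass
class AncestryAssignment:
    sample_ids: list[str]
    labels: list[str]
    votes: list[dict]          # label -> neighbor count, sums to k
    tie_broken: np.ndarray     # bool per sample
    other_called: np.ndarray   # bool per sample (distance-outlier rule)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.sample_ids,
            "ancestry": self.labels,
            "votes": [";".join(f"{k}:{v}" for k, v in sorted(v.items())) for v in self.votes],
            "tie_broken": self.tie_broken,
            "other": self.other_called,
        })


@dataclass
class AdmixtureEstimate:
    sample_ids: list[str]
    populations: list[str]
    fractions: np.ndarray  # (n_samples, n_pops), rows on the simplex
    converged: np.ndarray = field(default=None)
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, index=self.sample_ids, columns=self.populations)
        df.index.name = "sample"
        return df


# ---------------------------------------------------------------------------
# PCA on the reference panel
# ---------------------------------------------------------------------------

def _standardize(dosages: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    Z = (dosages - center) / scale
    return np.where(np.isnan(Z), 0.0, Z)  # mean imputation = zero after centering


def fit_reference_pca(panel: ReferencePanel, n_axes: int = 10,
                      max_missing: float = 0.05) -> PCModel:
    """Principal axes of variation from the reference panel only.

    SNPs that are monomorphic in the panel, or whose missing rate exceeds
    ``max_missing``, are dropped (logged). Loadings have a deterministic
    sign: each axis is flipped so its largest-magnitude entry is positive.
    """
    G = panel.genotypes.dosages
    miss = np.mean(np.isnan(G), axis=0)
    p = np.nanmean(G, axis=0) / 2.0
    keep = (miss <= max_missing) & (p > 0) & (p < 1) & ~np.isnan(p)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d SNPs (monomorphic or missing-rate > %.2f)",
                       n_drop, max_missing)
    if keep.sum() == 0:
        raise ValueError("no SNPs usable for PCA after filtering")
    snp_ids = [s for s, k in zip(panel.genotypes.snp_ids, keep) if k]
    p = p[keep]
    center = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))
    Z = _standardize(G[:, keep], center, scale)
    Zc = Z - Z.mean(axis=0)  # eigenvectors of the sample covariance
    rank = np.linalg.matrix_rank(Zc)
    if n_axes > rank:
        raise ValueError(f"n_axes={n_axes} exceeds rank {rank} of the panel")
    # SVD of the standardized matrix: right singular vectors = loadings
    _, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    loadings = Vt[:n_axes].T
    eigenvalues = (s[:n_axes] ** 2) / (Z.shape[0] - 1)
    # deterministic sign
    for j in range(n_axes):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCModel(snp_ids=snp_ids, center=center, scale=scale,
                   loadings=loadings, eigenvalues=eigenvalues, n_axes=n_axes)


def project_samples(model: PCModel, samples: GenotypeMatrix) -> Projection:
    """Project dosages onto the fitted axes; the model is never refit.

    Missing dosages are imputed to the panel mean (i.e. contribute zero
    after centering). Requires a non-empty SNP overlap with the model.
    """
    idx = {s: i for i, s in enumerate(samples.snp_ids)}
    pos = [idx.get(s, -1) for s in model.snp_ids]
    have = np.array([p >= 0 for p in pos])
    if not have.any():
        raise ValueError("no SNP overlap between samples and PCA model")
    D = np.full((len(samples.sample_ids), len(model.snp_ids)), np.nan)
    src = [p for p in pos if p >= 0]
    D[:, have] = samples.dosages[:, src]
    Z = _standardize(D, model.center, model.scale)
    return Projection(samples.sample_ids, Z @ model.loadings)


# ---------------------------------------------------------------------------
# k-NN ancestry classification
# ---------------------------------------------------------------------------

def classify_knn(targets: Projection, refs: Projection, labels: list[str],
                 k: int = 5, other_quantile: float | None = None) -> AncestryAssignment:
    """Majority-vote k-NN in the retained-axes space (Euclidean distance).

    Ties are broken by the nearest population centroid among the tied
    labels. If ``other_quantile`` is set, a sample whose nearest-neighbor
    distance exceeds that quantile of within-population nearest-neighbor
    distances is called "other".
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(refs.sample_ids):
        raise ValueError("k exceeds the number of reference samples")
    labels = list(labels)
    D = ssd.cdist(targets.coords, refs.coords)
    order = np.argsort(D, axis=1, kind="stable")
    uniq = sorted(set(labels))
    centroids = {u: refs.coords[[i for i, l in enumerate(labels) if l == u]].mean(axis=0)
                 for u in uniq}

    out_labels, out_votes = [], []
    tie_broken = np.zeros(len(targets.sample_ids), dtype=bool)
    other = np.zeros(len(targets.sample_ids), dtype=bool)

    if other_quantile is not None:
        # within-population nearest-neighbor distances in the panel
        Dr = ssd.cdist(refs.coords, refs.coords)
        np.fill_diagonal(Dr, np.inf)
        lab_arr = np.asarray(labels)
        nn = []
        for u in uniq:
            sel = lab_arr == u
            nn.extend(Dr[np.ix_(sel, sel)].min(axis=1))
        cutoff = np.quantile(nn, other_quantile)

    for i in range(len(targets.sample_ids)):
        nbr = order[i, :k]
        votes: dict[str, int] = {}
        for j in nbr:
            votes[labels[j]] = votes.get(labels[j], 0) + 1
        top = max(votes.values())
        winners = [u for u, v in votes.items() if v == top]
        if len(winners) == 1:
            lab = winners[0]
        else:
            tie_broken[i] = True
            cd = {u: np.linalg.norm(targets.coords[i] - centroids[u]) for u in winners}
            lab = min(cd, key=cd.get)
        if other_quantile is not None and D[i, order[i, 0]] > cutoff:
            other[i] = True
            lab = "other"
        out_labels.append(lab)
        out_votes.append(votes)
    return AncestryAssignment(targets.sample_ids, out_labels, out_votes, tie_broken, other)


# ---------------------------------------------------------------------------
# supervised admixture-fraction estimation
# ---------------------------------------------------------------------------

def population_frequencies(panel: ReferencePanel) -> tuple[list[str], np.ndarray]:
    """Per-population allele frequencies (pops x SNPs), clipped to (0,1)."""
    pops = panel.populations
    G = panel.genotypes.dosages
    lab = np.asarray(panel.labels)
    F = np.vstack([np.nanmean(G[lab == u], axis=0) / 2.0 for u in pops])
    return pops, np.clip(F, 1e-6, 1 - 1e-6)


def estimate_admixture(samples: GenotypeMatrix, pop_freqs: np.ndarray,
                       populations: list[str], tol: float = 1e-8,
                       max_iter: int = 5000) -> AdmixtureEstimate:
    """Supervised admixture fractions by EM on the binomial dosage likelihood.

    Each sample's dosage vector g is modeled as Binomial(2, f(q)) per SNP,
    with f(q) = sum_a q_a F_{a,snp} and panel frequencies F held fixed; the
    mixing vector q is the free parameter on the simplex. EM starts from
    the uniform point; convergence when the log-likelihood improves by
    less than ``tol``. Plain EM crawls near the simplex boundary, so each
    cycle takes two EM steps and a safeguarded extrapolation (accepted only
    when it does not lower the likelihood), keeping the per-cycle
    log-likelihood monotone non-decreasing. With panel populations that
    are (numerically) identical the likelihood is flat: the uniform point
    is returned and the estimate flagged degenerate.
    """
    F = np.clip(np.asarray(pop_freqs, dtype=float), 1e-6, 1 - 1e-6)
    A, M = F.shape
    if len(populations) != A:
        raise ValueError("population names do not match frequency rows")
    if samples.dosages.shape[1] != M:
        raise ValueError("SNP dimension mismatch between samples and frequencies")
    n = len(samples.sample_ids)
    if n == 0:
        return AdmixtureEstimate([], list(populations), np.zeros((0, A)),
                                 converged=np.zeros(0, dtype=bool))
    if np.max(np.ptp(F, axis=0)) < 1e-9:
        return AdmixtureEstimate(samples.sample_ids, list(populations),
                                 np.full((n, A), 1.0 / A),
                                 converged=np.ones(n, dtype=bool), degenerate=True)

    G = samples.dosages
    obs_full = ~np.isnan(G)
    Gz_full = np.where(obs_full, G, 0.0)
    Fc = 1.0 - F

    def loglik(Q, Gz, obs):
        mix = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        return np.where(obs, Gz * np.log(mix) + (2 - Gz) * np.log1p(-mix), 0.0).sum(axis=1)

    def em_step(Q, Gz, obs):
        mix = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        # fractional allele-copy counts per population:
        #   derived: g * q_a F_a / mix ; ancestral: (2-g) * q_a (1-F_a) / (1-mix)
        d = np.where(obs, Gz / mix, 0.0)
        a = np.where(obs, (2 - Gz) / (1 - mix), 0.0)
        counts = Q * (d @ F.T + a @ Fc.T)
        return counts / counts.sum(axis=1, keepdims=True)

    Q = np.full((n, A), 1.0 / A)
    prev_ll = loglik(Q, Gz_full, obs_full)
    converged = np.zeros(n, dtype=bool)
    n_cycles = max(1, max_iter // 2)
    for _ in range(n_cycles):
        idx = np.where(~converged)[0]
        if idx.size == 0:
            break
        Qa0 = Q[idx]
        Gz, obs = Gz_full[idx], obs_full[idx]
        Q1 = em_step(Qa0, Gz, obs)
        Q2 = em_step(Q1, Gz, obs)
        R = Q1 - Qa0
        V = Q2 - Q1 - R
        nv = np.linalg.norm(V, axis=1)
        alpha = np.where(nv > 1e-30, -np.linalg.norm(R, axis=1) / np.maximum(nv, 1e-30), -1.0)
        Qx = Qa0 - 2 * alpha[:, None] * R + (alpha ** 2)[:, None] * V
        Qx = np.clip(Qx, 1e-12, None)
        Qx /= Qx.sum(axis=1, keepdims=True)
        lla = loglik(Qx, Gz, obs)
        ll2 = loglik(Q2, Gz, obs)
        use_acc = lla >= ll2
        Qnew = np.where(use_acc[:, None], Qx, Q2)
        ll = np.where(use_acc, lla, ll2)
        Q[idx] = Qnew
        converged[idx] = ll - prev_ll[idx] < tol
        prev_ll[idx] = ll
    if not converged.all():
        logger.warning("admixture EM: %d samples not converged after %d cycles",
                       int((~converged).sum()), n_cycles)
    return AdmixtureEstimate(samples.sample_ids, list(populations), Q,
                             converged=converged, degenerate=False)
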