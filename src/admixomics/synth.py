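"""Synthetic-data generators emulating the statistical structure of a
multi-platform tumor ancestry-disparity study.

Every generator is a pure function of its parameters and a seed, returns
known ground truth alongside the data, and writes the same plain-text
formats the pipeline consumes (genotype/label/count TSV, SEG, MAF-lite,
GTF, BED, truth JSON). The generators model:

* multi-population allele-frequency structure (Balding-Nichols) with
  admixed study samples;
* 96-channel mutation spectra as multinomial draws from signature
  mixtures;
* segmented copy-number profiles tiling each chromosome, with planted
  recurrent focal events whose carrier probability differs by group;
* negative-binomial expression counts with planted fold changes and
  optional confounding of group with age and grade;
* coding/lncRNA gene models with locus-biotype classes planted by
  construction.

None of this reproduces linkage disequilibrium, genome-realistic mutation
placement, or read-level noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ancestry import GenotypeMatrix, ReferencePanel
from .mutsig import MutationCatalog, SignatureMatrix
from .scna import SegmentTable, FocalRegionSet
from .expression import CountMatrix
from .lncrna import GeneModel, Transcript
from .costats import ClinicalTable

__all__ = [
    "PopulationModel",
    "PlantedTruth",
    "SimulatedPanel",
    "simulate_reference_panel",
    "simulate_admixed_cohort",
    "simulate_mutation_catalogs",
    "simulate_segment_tables",
    "simulate_counts",
    "simulate_gene_models",
    "simulate_clinical",
]


@dataclass
class PopulationModel:
    """Balding-Nichols population divergence model."""

    n_pops: int
    n_snps: int
    fst: float
    ancestral_freqs: np.ndarray | None = None  # drawn Uniform(0.05, 0.95) if None

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("need at least 2 populations")
        if not (0 < self.fst < 1):
            raise ValueError("fst must lie in (0, 1)")
        if self.ancestral_freqs is not None:
            f = np.asarray(self.ancestral_freqs, dtype=float)
            if np.any((f <= 0) | (f >= 1)):
                raise ValueError("ancestral frequencies must lie in (0, 1)")
            self.ancestral_freqs = f


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators (whatever was simulated)."""

    admixture: pd.DataFrame | None = None       # sample x population fractions
    signature_weights: pd.DataFrame | None = None
    scna_regions: pd.DataFrame | None = None    # region, chrom, start, end, type, p_group0, p_group1, delta
    scna_carriers: pd.DataFrame | None = None   # sample x region indicator
    de_genes: pd.DataFrame | None = None        # gene, log2fc
    lnc_classes: dict | None = None             # gene -> planted class

    def to_json(self, path) -> None:
        def enc(v):
            if isinstance(v, pd.DataFrame):
                return json.loads(v.to_json(orient="split"))
            return v
        data = {k: enc(getattr(self, k)) for k in self.__dataclass_fields__
                if getattr(self, k) is not None}
        with open(path, "w") as fh:
            json.dump(data, fh, default=str)


@dataclass
class SimulatedPanel:
    """Reference panel plus the true per-population allele frequencies."""

    panel: ReferencePanel
    populations: list
    pop_freqs: np.ndarray  # (n_pops, n_snps)


def _check_seed(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_reference_panel(model: PopulationModel, n_per_pop: int,
                             seed: int = 0) -> SimulatedPanel:
    """Labeled reference panel under the Balding-Nichols model.

    Population-specific frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F)
    around the ancestral frequency p with divergence F; genotypes are
    Binomial(2, freq).
    """
    if n_per_pop < 2:
        raise ValueError("need n_per_pop >= 2")
    rng = _check_seed(seed)
    p = model.ancestral_freqs
    if p is None:
        p = rng.uniform(0.05, 0.95, model.n_snps)
    F = model.fst
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    pops = [f"POP{i+1}" for i in range(model.n_pops)]
    pop_freqs = np.clip(rng.beta(a, b, size=(model.n_pops, model.n_snps)),
                        1e-4, 1 - 1e-4)
    dosages = np.vstack([
        rng.binomial(2, pop_freqs[k], size=(n_per_pop, model.n_snps)).astype(float)
        for k in range(model.n_pops)
    ])
    sample_ids = [f"{pops[k]}_{i:03d}" for k in range(model.n_pops)
                  for i in range(n_per_pop)]
    labels = [pops[k] for k in range(model.n_pops) for _ in range(n_per_pop)]
    snp_ids = [f"snp{j:05d}" for j in range(model.n_snps)]
    gm = GenotypeMatrix(sample_ids, snp_ids, dosages)
    return SimulatedPanel(ReferencePanel(gm, labels), pops, pop_freqs)


def simulate_admixed_cohort(panel: SimulatedPanel, fractions: np.ndarray,
                            seed: int = 0, prefix: str = "S"):
    """Admixed study genotypes: each allele copy picks an ancestral
    population by the sample's fractions, then draws from that
    population's allele frequency. Returns (GenotypeMatrix, PlantedTruth).
    """
    rng = _check_seed(seed)
    Q = np.atleast_2d(np.asarray(fractions, dtype=float))
    if Q.shape[0] == 0:
        gm = GenotypeMatrix([], [f"snp{j:05d}" for j in range(panel.pop_freqs.shape[1])],
                            np.zeros((0, panel.pop_freqs.shape[1])))
        return gm, PlantedTruth(admixture=pd.DataFrame(columns=panel.populations))
    if np.any(np.abs(Q.sum(axis=1) - 1.0) > 1e-9) or np.any(Q < 0):
        raise ValueError("every fractions row must lie on the simplex")
    F = panel.pop_freqs
    A, M = F.shape
    n = Q.shape[0]
    # per allele copy: population ~ Categorical(q), allele ~ Bernoulli(F_pop)
    dosages = np.zeros((n, M))
    for copy in range(2):
        u = rng.random((n, M))
        pop = (u[..., None] > np.cumsum(Q, axis=1)[:, None, :]).sum(axis=2)
        freq = F[pop, np.arange(M)[None, :]]
        dosages += rng.random((n, M)) < freq
    sample_ids = [f"{prefix}{i:04d}" for i in range(n)]
    snp_ids = [f"snp{j:05d}" for j in range(M)]
    gm = GenotypeMatrix(sample_ids, snp_ids, dosages)
    truth = PlantedTruth(admixture=pd.DataFrame(Q, index=sample_ids,
                                                columns=panel.populations))
    return gm, truth


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

def simulate_mutation_catalogs(signatures: SignatureMatrix, weights: np.ndarray,
                               n_mutations, seed: int = 0,
                               sample_ids: list | None = None):
    """Multinomial catalogs from per-sample signature mixtures.

    ``weights`` is samples x signatures on the simplex; ``n_mutations``
    is a scalar or per-sample vector. Row sums equal the requested counts.
    """
    rng = _check_seed(seed)
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[1] != len(signatures.names):
        raise ValueError("weight/signature dimension mismatch")
    if np.any(np.abs(W.sum(axis=1) - 1.0) > 1e-9) or np.any(W < 0):
        raise ValueError("weights rows must lie on the simplex")
    n = W.shape[0]
    nm = np.full(n, n_mutations) if np.isscalar(n_mutations) else np.asarray(n_mutations)
    if sample_ids is None:
        sample_ids = [f"T{i:04d}" for i in range(n)]
    counts = np.zeros((n, 96))
    for i in range(n):
        spectrum = signatures.profiles @ W[i]
        counts[i] = rng.multinomial(int(nm[i]), spectrum / spectrum.sum())
    truth = PlantedTruth(signature_weights=pd.DataFrame(
        W, index=sample_ids, columns=signatures.names))
    return MutationCatalog(list(sample_ids), counts), truth


def catalog_to_maf(catalog: MutationCatalog, path, seed: int = 0) -> None:
    """Write a MAF-lite TSV whose records reproduce the catalog.

    Channel identity is carried in the context column; positions are
    arbitrary. Round trip: build_catalog(read back) == catalog.
    """
    from .mutsig import CHANNELS
    rng = _check_seed(seed)
    rows = []
    for i, s in enumerate(catalog.sample_ids):
        for c in range(96):
            ch = CHANNELS[c]
            ref, alt = ch[2], ch[4]
            ctx = ch[0] + ref + ch[6]
            for _ in range(int(catalog.counts[i, c])):
                rows.append({"sample": s, "gene": "NA",
                             "chrom": "chr1", "pos": int(rng.integers(1, 2**28)),
                             "ref": ref, "alt": alt, "class": "Missense_Mutation",
                             "clonality": "clonal", "context": ctx})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# copy-number segments
# ---------------------------------------------------------------------------

def simulate_segment_tables(genome: dict, planted: pd.DataFrame,
                            groups: np.ndarray, noise_sd: float = 0.05,
                            seed: int = 0, sample_ids: list | None = None,
                            segments_per_chrom: int = 5,
                            max_segments: int | None = None):
    """Log2-ratio segment profiles with planted group-differential focal events.

    ``genome`` maps chromosome -> length (bp). ``planted`` has columns
    region, chrom, start, end, type, p_group0, p_group1, delta (delta is
    the absolute log2 shift, >= 0.5 recommended; deletions subtract it).
    Segments tile every chromosome without gaps or overlaps; values are
    Gaussian noise around 0 plus the planted effect inside carried
    regions. Carrier status is Bernoulli with the group-specific
    probability. Returns (SegmentTable, FocalRegionSet, PlantedTruth).
    """
    rng = _check_seed(seed)
    groups = np.asarray(groups, dtype=int)
    n = len(groups)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    planted = planted.reset_index(drop=True)
    for c, grp in planted.groupby("chrom"):
        s = grp.sort_values("start")
        if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping planted regions on {c}")
        if (s["end"] > genome[c]).any() or (s["start"] < 1).any():
            raise ValueError(f"planted region outside chromosome bounds on {c}")

    carriers = np.zeros((n, len(planted)), dtype=int)
    for j, r in planted.iterrows():
        p = np.where(groups == 1, r["p_group1"], r["p_group0"])
        carriers[:, j] = rng.random(n) < p

    # plain tuples per chromosome; pandas row access is too slow in the loop
    by_chrom: dict = {c: [] for c in genome}
    for j, r in planted.iterrows():
        by_chrom[r["chrom"]].append(
            (int(r["start"]), int(r["end"]),
             float(r["delta"]) if r["type"] == "amplification" else -float(r["delta"]),
             j))
    rows = []
    for i, sid in enumerate(sample_ids):
        for chrom, L in genome.items():
            # breakpoints: random plus planted-region edges on this chromosome
            bp = set([1, L + 1])
            k = max(segments_per_chrom - 1, 0)
            if k:
                bp.update(int(x) for x in rng.integers(2, L, k))
            sub = by_chrom[chrom]
            for start, end, _, _ in sub:
                bp.add(start)
                bp.add(end + 1)
            bp = sorted(bp)
            for a, b in zip(bp[:-1], bp[1:]):
                val = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                for start, end, delta, j in sub:
                    if a >= start and b - 1 <= end and carriers[i, j]:
                        val += delta
                rows.append({"sample": sid, "chrom": chrom, "start": a,
                             "end": b - 1, "value": val})
    seg = SegmentTable(pd.DataFrame(rows))
    if max_segments is not None:
        per = seg.df.groupby("sample").size()
        assert (per <= max_segments).all()
    regions = FocalRegionSet(planted[["region", "chrom", "start", "end", "type"]])
    truth = PlantedTruth(
        scna_regions=planted,
        scna_carriers=pd.DataFrame(carriers, index=sample_ids,
                                   columns=planted["region"].tolist()))
    return seg, regions, truth


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_counts(n_genes: int, group: np.ndarray, planted_lfc: dict | None = None,
                    dispersion: float = 0.05, seed: int = 0,
                    base_mean_range=(20.0, 2000.0),
                    size_factors: np.ndarray | None = None,
                    sample_ids: list | None = None,
                    biotypes: list | None = None):
    """Negative-binomial counts with planted group-associated fold changes.

    Counts are NB(mean = base * sf * 2^(lfc * group), dispersion) via the
    gamma-Poisson mixture. ``planted_lfc`` maps gene index -> true log2
    fold change. Returns (CountMatrix, PlantedTruth).
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = _check_seed(seed)
    group = np.asarray(group, dtype=int)
    n = len(group)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n)]
    if size_factors is None:
        size_factors = np.exp(rng.normal(0.0, 0.15, n))
    gene_ids = [f"G{g:05d}" for g in range(n_genes)]
    base = np.exp(rng.uniform(np.log(base_mean_range[0]),
                              np.log(base_mean_range[1]), n_genes))
    lfc = np.zeros(n_genes)
    for g, v in (planted_lfc or {}).items():
        lfc[int(g)] = float(v)
    mean = base[:, None] * size_factors[None, :] * np.power(2.0, lfc[:, None] * group[None, :])
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam).astype(np.int64)
    truth = PlantedTruth(de_genes=pd.DataFrame({"gene": gene_ids, "log2fc": lfc}))
    return CountMatrix(gene_ids, list(sample_ids), counts, biotypes), truth


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def simulate_gene_models(n_coding: int = 20, n_lnc_per_class: int = 5,
                         seed: int = 0, chrom: str = "chr1"):
    """Coding genes plus lncRNAs planted into the four locus classes.

    Coding genes are multi-exon, evenly spaced and widely separated
    (>= 50 kb) on one strand. For each class the lncRNAs are built by
    construction: exonic overlaps a coding exon same strand; intronic sits
    wholly inside an intron same strand; antisense overlaps the coding
    span on the opposite strand without same-strand coding overlap;
    intergenic lies > 10 kb from every coding gene. Returns
    (lnc_models, coding_models, PlantedTruth).
    """
    if n_coding < 0 or n_lnc_per_class < 0:
        raise ValueError("counts must be non-negative")
    rng = _check_seed(seed)
    spacing = 100_000
    gene_len = 20_000
    exon_len = 1_000
    n_exons = 4
    coding = []
    for i in range(n_coding):
        start = 50_000 + i * spacing
        # 4 exons of 1 kb separated by ~5.3 kb introns
        intron = (gene_len - n_exons * exon_len) // (n_exons - 1)
        exons = [(start + k * (exon_len + intron),
                  start + k * (exon_len + intron) + exon_len) for k in range(n_exons)]
        coding.append(GeneModel(f"PC{i:03d}", "protein_coding", chrom, "+",
                                [Transcript(f"PC{i:03d}.t1", chrom, "+", exons)]))
    lnc = []
    truth: dict = {}

    def add(gid, klass, strand, exons):
        lnc.append(GeneModel(gid, "lncRNA", chrom, strand,
                             [Transcript(f"{gid}.t1", chrom, strand, exons)]))
        truth[gid] = klass

    for k in range(n_lnc_per_class):
        host = coding[k % max(n_coding, 1)] if n_coding else None
        if host is None:
            break
        hx = host.transcripts[0].exons
        # exonic: starts inside the host's second exon, same strand
        e0 = hx[1]
        add(f"LEX{k:03d}", "exonic", "+", [(e0[0] + 100, e0[0] + 600),
                                           (e0[1] + 200, e0[1] + 700)])
        # intronic: wholly inside the intron between exons 2 and 3
        i0, i1 = hx[1][1], hx[2][0]
        add(f"LIN{k:03d}", "intronic", "+", [(i0 + 300, i0 + 800),
                                             (i1 - 900, i1 - 400)])
        # antisense: overlaps the host span, opposite strand
        span = host.span
        add(f"LAS{k:03d}", "antisense", "-", [(span[0] + 2_000, span[0] + 2_500),
                                              (span[0] + 3_500, span[0] + 4_000)])
        # intergenic: in the wide gap between hosts, > 10 kb from any gene
        gap_start = span[1] + 30_000
        add(f"LIG{k:03d}", "intergenic",
            "+" if rng.random() < 0.5 else "-",
            [(gap_start, gap_start + 500), (gap_start + 1_500, gap_start + 2_000)])
    return lnc, coding, PlantedTruth(lnc_classes=truth)


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

def simulate_clinical(group: np.ndarray, seed: int = 0, age_shift: float = -5.0,
                      grade_shift: float = -0.8,
                      grade_levels=(6, 7, 8, 9, 10)) -> ClinicalTable:
    """Age/grade covariates with configurable confounding by group.

    Group 1 receives a Gaussian age shift (years) and an ordinal grade
    shift (latent-normal threshold model), so that group membership is
    predictable from the covariates and any covariate-linked outcome is
    confounded until the propensity score absorbs it.
    """
    rng = _check_seed(seed)
    group = np.asarray(group, dtype=int)
    n = len(group)
    age = rng.normal(62.0, 8.0, n) + age_shift * group
    latent = rng.normal(0.0, 1.0, n) + grade_shift * group
    edges = np.quantile(latent, np.linspace(0, 1, len(grade_levels) + 1)[1:-1])
    idx = np.searchsorted(edges, latent)
    grade = [grade_levels[i] for i in idx]
    return ClinicalTable([f"S{i:04d}" for i in range(n)], group, age, grade,
                         grade_levels=tuple(grade_levels))
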