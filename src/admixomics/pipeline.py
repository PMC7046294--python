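"""End-to-end orchestration: simulate a full synthetic study, then run
every analysis stage from on-disk inputs under one config and seed.

Stage order follows the data dependencies: ancestry calling first (it
defines the comparison groups), then the propensity score, then the three
independent molecular branches (mutational signatures, copy number,
expression), then enrichment and lncRNA annotation on the expression
results. A failure in one branch is recorded and does not abort the
others. Every run writes a manifest with the config snapshot, seeds and
per-file checksums, sufficient to verify byte-identical re-runs of the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, costats, enrichment, expression, lncrna, mutsig, scna, synth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "simulate_all", "run_pipeline"]

DEFAULTS = {
    "seed": 0,
    "n_ref_pops": 3,
    "n_per_pop": 150,
    "n_snps": 5000,
    "fst": 0.1,
    "n_study": 400,
    "n_group1": 60,
    "n_axes": 10,
    "knn_k": 5,
    "n_genes": 2000,
    "n_de_genes": 100,
    "de_lfc": 1.0,
    "dispersion": 0.05,
    "n_regions": 20,
    "n_perm": 2000,
    "scna_threshold": 0.25,
    "wgii_deviation": 0.3,
    "fdr_de": 0.1,
    "fdr_scna_flag": 0.25,
    "n_mutations": 2000,
    "stages": ["ancestry", "propensity", "mutsig", "scna", "expression",
               "enrichment", "lncrna"],
}


@dataclass
class PipelineConfig:
    outdir: Path
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        merged = dict(DEFAULTS)
        merged.update(self.params)
        self.params = merged
        if self.params["n_study"] <= 0 or self.params["n_per_pop"] <= 0:
            raise ValueError("sample counts must be positive")
        unknown = set(self.params) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config parameters: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        outdir = raw.pop("outdir", ".")
        return cls(outdir=outdir, params=raw)

    def validate_inputs(self, datadir: Path) -> None:
        datadir = Path(datadir)
        need = {
            "ancestry": ["panel_genotypes.tsv", "panel_labels.tsv", "study_genotypes.tsv"],
            "propensity": ["clinical.tsv"],
            "mutsig": ["mutations.maf.tsv", "signatures.tsv"],
            "scna": ["segments.seg", "regions.bed"],
            "expression": ["counts.tsv"],
        }
        missing = []
        for stage in self.params["stages"]:
            for f in need.get(stage, []):
                if not (datadir / f).exists():
                    missing.append(f"{stage}: {f}")
        if missing:
            raise FileNotFoundError("missing pipeline inputs: " + "; ".join(missing))


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    started: float
    finished: float = 0.0
    stages: dict = field(default_factory=dict)  # stage -> {status, outputs: {path: sha256}}

    def record(self, stage: str, status: str, outputs: list) -> None:
        sums = {}
        for p in outputs:
            p = Path(p)
            if p.exists():
                sums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages[stage] = {"status": status, "outputs": sums}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "version": self.version, "started": self.started,
                       "finished": self.finished, "stages": self.stages},
                      fh, indent=2, default=str)


def _genome(n_chrom: int = 4, size: int = 100_000_000) -> dict:
    return {f"chr{i+1}": size for i in range(n_chrom)}


def simulate_all(config: PipelineConfig) -> Path:
    """Generate the full synthetic study bundle the demo config consumes."""
    p = config.params
    seed = int(p["seed"])
    rng = np.random.default_rng(seed)
    datadir = config.outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)

    # --- genotypes: reference panel + admixed study cohort -----------------
    model = synth.PopulationModel(n_pops=p["n_ref_pops"], n_snps=p["n_snps"], fst=p["fst"])
    sim_panel = synth.simulate_reference_panel(model, p["n_per_pop"],
                                               seed=int(rng.integers(2**31)))
    n, n1 = p["n_study"], p["n_group1"]
    # group 1 mostly population 1, group 0 mostly population 2, both admixed
    Q = np.zeros((n, p["n_ref_pops"]))
    main = rng.uniform(0.7, 1.0, n)
    group = np.array([1] * n1 + [0] * (n - n1))
    for i in range(n):
        primary = 0 if group[i] == 1 else 1
        Q[i, primary] = main[i]
        rest = rng.dirichlet(np.ones(p["n_ref_pops"] - 1)) * (1 - main[i])
        Q[i, [j for j in range(p["n_ref_pops"]) if j != primary]] = rest
    study, truth_admix = synth.simulate_admixed_cohort(
        sim_panel, Q, seed=int(rng.integers(2**31)))

    sim_panel.panel.genotypes.to_tsv(datadir / "panel_genotypes.tsv")
    pd.DataFrame({"sample": sim_panel.panel.genotypes.sample_ids,
                  "population": sim_panel.panel.labels}).to_csv(
        datadir / "panel_labels.tsv", sep="\t", index=False)
    study.to_tsv(datadir / "study_genotypes.tsv")

    # --- clinical covariates (confounded with group) ----------------------
    clinical = synth.simulate_clinical(group, seed=int(rng.integers(2**31)))
    clinical.sample_ids = study.sample_ids
    pd.DataFrame({"sample": clinical.sample_ids, "group": clinical.group,
                  "age": clinical.age, "grade": clinical.grade}).to_csv(
        datadir / "clinical.tsv", sep="\t", index=False)

    # --- mutation catalogs -------------------------------------------------
    sigs = mutsig.builtin_signatures()
    W = rng.dirichlet(np.ones(3) * 2.0, size=n)
    catalog, truth_sig = synth.simulate_mutation_catalogs(
        sigs, W, p["n_mutations"], seed=int(rng.integers(2**31)),
        sample_ids=study.sample_ids)
    sigs.to_tsv(datadir / "signatures.tsv")
    synth.catalog_to_maf(catalog, datadir / "mutations.maf.tsv",
                         seed=int(rng.integers(2**31)))

    # --- copy-number segments ---------------------------------------------
    genome = _genome()
    chroms = list(genome)
    regions = []
    for j in range(p["n_regions"]):
        c = chroms[j % len(chroms)]
        start = 5_000_000 + (j // len(chroms)) * 20_000_000
        base = 0.15
        p0, p1 = base, base
        if j == 0:  # one planted group-differential deletion
            p0, p1 = 0.10, 0.30
        regions.append({"region": f"R{j:02d}", "chrom": c, "start": start,
                        "end": start + 1_000_000,
                        "type": "amplification" if j % 2 else "deletion",
                        "p_group0": p0, "p_group1": p1, "delta": 0.6})
    seg, region_set, truth_scna = synth.simulate_segment_tables(
        genome, pd.DataFrame(regions), group, noise_sd=0.05,
        seed=int(rng.integers(2**31)), sample_ids=study.sample_ids)
    seg.to_seg(datadir / "segments.seg")
    bed = region_set.df.copy()
    bed["start"] = bed["start"] - 1
    bed[["chrom", "start", "end", "region", "type"]].to_csv(
        datadir / "regions.bed", sep="\t", index=False, header=False)

    # --- expression counts + gene models ----------------------------------
    lnc_models, coding_models, truth_lnc = synth.simulate_gene_models(
        n_coding=20, n_lnc_per_class=5, seed=int(rng.integers(2**31)))
    de_idx = rng.choice(p["n_genes"], p["n_de_genes"], replace=False)
    lfc = {int(g): float(p["de_lfc"] * (1 if rng.random() < 0.5 else -1))
           for g in de_idx}
    n_lnc_genes = int(p["n_genes"] * 0.3)
    biotypes = ["lncRNA" if g < n_lnc_genes else "protein_coding"
                for g in range(p["n_genes"])]
    counts, truth_de = synth.simulate_counts(
        p["n_genes"], group, planted_lfc=lfc, dispersion=p["dispersion"],
        seed=int(rng.integers(2**31)), sample_ids=study.sample_ids,
        biotypes=biotypes)
    counts.to_tsv(datadir / "counts.tsv")
    pd.DataFrame({"gene": counts.gene_ids, "biotype": biotypes}).to_csv(
        datadir / "biotypes.tsv", sep="\t", index=False)
    lncrna.write_gtf(lnc_models + coding_models, datadir / "genes.gtf")

    truth = synth.PlantedTruth(
        admixture=truth_admix.admixture,
        signature_weights=truth_sig.signature_weights,
        scna_regions=truth_scna.scna_regions,
        scna_carriers=truth_scna.scna_carriers,
        de_genes=truth_de.de_genes,
        lnc_classes=truth_lnc.lnc_classes)
    truth.to_json(datadir / "truth.json")
    return datadir


def run_pipeline(config: PipelineConfig, datadir: Path | None = None) -> RunManifest:
    """Run the configured stages from on-disk inputs; write tidy outputs + manifest."""
    from . import __version__

    p = config.params
    datadir = Path(datadir) if datadir is not None else config.outdir / "data"
    outdir = config.outdir / "results"
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate_inputs(datadir)
    manifest = RunManifest(config=dict(p), seed=int(p["seed"]),
                           version=__version__, started=time.time())
    seed = int(p["seed"])
    group = None
    propensity = None
    de_result = None

    def stage(name):
        return name in p["stages"]

    # ancestry -------------------------------------------------------------
    if stage("ancestry"):
        try:
            panel_g = ancestry.GenotypeMatrix.from_tsv(datadir / "panel_genotypes.tsv")
            labels = pd.read_csv(datadir / "panel_labels.tsv", sep="\t")["population"].tolist()
            panel = ancestry.ReferencePanel(panel_g, labels)
            study = ancestry.GenotypeMatrix.from_tsv(datadir / "study_genotypes.tsv")
            model = ancestry.fit_reference_pca(panel, n_axes=min(p["n_axes"],
                                                                 len(panel_g.sample_ids) - 1))
            ref_proj = ancestry.project_samples(model, panel_g)
            stu_proj = ancestry.project_samples(model, study)
            calls = ancestry.classify_knn(stu_proj, ref_proj, labels, k=p["knn_k"])
            pops, freqs = ancestry.population_frequencies(panel)
            # admixture on the model's SNP subset
            study_pos = {s: i for i, s in enumerate(study.snp_ids)}
            panel_pos = {s: i for i, s in enumerate(panel_g.snp_ids)}
            sub = ancestry.GenotypeMatrix(study.sample_ids, model.snp_ids,
                                          study.dosages[:, [study_pos[s] for s in model.snp_ids]])
            fsub = freqs[:, [panel_pos[s] for s in model.snp_ids]]
            admix = ancestry.estimate_admixture(sub, fsub, pops)
            stu_proj.to_tsv(outdir / "projection.tsv")
            calls.to_frame().to_csv(outdir / "ancestry.tsv", sep="\t", index=False)
            admix.to_frame().to_csv(outdir / "admixture.tsv", sep="\t")
            manifest.record("ancestry", "ok", [outdir / f for f in
                                               ("projection.tsv", "ancestry.tsv", "admixture.tsv")])
        except Exception as e:  # stage isolation
            logger.exception("ancestry stage failed")
            manifest.record("ancestry", f"failed: {e}", [])

    # propensity -----------------------------------------------------------
    if stage("propensity"):
        try:
            clinical = costats.ClinicalTable.from_tsv(datadir / "clinical.tsv")
            group = clinical.group
            propensity = costats.fit_propensity(clinical)
            pd.DataFrame({"sample": clinical.sample_ids,
                          "propensity": propensity.scores}).to_csv(
                outdir / "propensity.tsv", sep="\t", index=False)
            manifest.record("propensity", "ok", [outdir / "propensity.tsv"])
        except Exception as e:
            logger.exception("propensity stage failed")
            manifest.record("propensity", f"failed: {e}", [])

    # mutational signatures --------------------------------------------------
    if stage("mutsig") and group is not None:
        try:
            maf = pd.read_csv(datadir / "mutations.maf.tsv", sep="\t")
            sigs = mutsig.SignatureMatrix.from_tsv(datadir / "signatures.tsv")
            sample_ids = pd.read_csv(datadir / "clinical.tsv", sep="\t")["sample"].astype(str).tolist()
            catalog = mutsig.build_catalog(maf, sample_ids=sample_ids)
            fits = mutsig.refit_catalog(catalog, sigs)
            mutsig.exposures_to_frame(fits).to_csv(outdir / "exposures.tsv", sep="\t")
            assoc = mutsig.signature_contribution_association(fits, group, propensity)
            assoc.to_csv(outdir / "signature_assoc.tsv", sep="\t", index=False)
            burden = mutsig.burden_association(catalog.counts.sum(axis=1), group, propensity)
            pd.DataFrame([burden.to_row()]).to_csv(outdir / "burden_assoc.tsv",
                                                   sep="\t", index=False)
            manifest.record("mutsig", "ok", [outdir / f for f in
                                             ("exposures.tsv", "signature_assoc.tsv",
                                              "burden_assoc.tsv")])
        except Exception as e:
            logger.exception("mutsig stage failed")
            manifest.record("mutsig", f"failed: {e}", [])

    # copy number ------------------------------------------------------------
    if stage("scna") and group is not None:
        try:
            seg = scna.SegmentTable.from_seg(datadir / "segments.seg")
            seg = scna.filter_hypersegmented(seg)
            regions = scna.FocalRegionSet.from_bed(datadir / "regions.bed")
            genome_chroms = tuple(sorted(set(seg.df["chrom"]),
                                         key=lambda c: int(c.replace("chr", ""))))
            wgii_df = scna.compute_wgii_all(seg, deviation=p["wgii_deviation"],
                                            autosomes=genome_chroms)
            wgii_df.to_csv(outdir / "wgii.tsv", sep="\t", index=False)
            order = {s: i for i, s in enumerate(seg.samples)}
            galigned = np.asarray(group)[[order[s] for s in seg.samples]] \
                if len(seg.samples) == len(group) else np.asarray(group)
            wres = scna.wgii_association(wgii_df["wgii"].to_numpy(), galigned, propensity)
            pd.DataFrame([wres.to_row()]).to_csv(outdir / "wgii_assoc.tsv",
                                                 sep="\t", index=False)
            alt = scna.build_alteration_matrix(seg, regions,
                                               threshold=p["scna_threshold"])
            alt.to_frame().to_csv(outdir / "alteration_matrix.tsv", sep="\t")
            perm = scna.scna_association_test(alt, galigned, propensity,
                                              n_perm=p["n_perm"], seed=seed,
                                              q_flag=p["fdr_scna_flag"])
            perm.df.to_csv(outdir / "scna_test.tsv", sep="\t", index=False)
            manifest.record("scna", "ok", [outdir / f for f in
                                           ("wgii.tsv", "wgii_assoc.tsv",
                                            "alteration_matrix.tsv", "scna_test.tsv")])
        except Exception as e:
            logger.exception("scna stage failed")
            manifest.record("scna", f"failed: {e}", [])

    # expression -------------------------------------------------------------
    if stage("expression") and group is not None:
        try:
            counts = expression.CountMatrix.from_tsv(datadir / "counts.tsv",
                                                     datadir / "biotypes.tsv"
                                                     if (datadir / "biotypes.tsv").exists()
                                                     else None)
            de_result = expression.nb_wald_de(counts, group, propensity)
            de_result.to_tsv(outdir / "de_results.tsv")
            screen = expression.fold_change_screen(de_result, q_cut=p["fdr_de"])
            pd.Series(screen, name="gene").to_csv(outdir / "de_2fold.tsv",
                                                  sep="\t", index=False)
            manifest.record("expression", "ok", [outdir / "de_results.tsv",
                                                 outdir / "de_2fold.tsv"])
        except Exception as e:
            logger.exception("expression stage failed")
            manifest.record("expression", f"failed: {e}", [])

    # enrichment -------------------------------------------------------------
    if stage("enrichment") and de_result is not None:
        try:
            ranked = de_result.ranked_by_wald()
            ranking = enrichment.RankedList(ranked["gene"].tolist(),
                                           ranked["wald"].to_numpy())
            rng = np.random.default_rng(seed + 1)
            # demo gene sets: top-Wald set (positive control) and random sets
            ids = ranking.ids
            sets = [enrichment.GeneSet("top_wald", set(ids[:50]))]
            for i in range(5):
                sets.append(enrichment.GeneSet(
                    f"random_{i}", set(rng.choice(ids, 50, replace=False))))
            gres = enrichment.gsea_many(ranking, sets, n_perm=500, seed=seed + 2)
            gres.to_csv(outdir / "gsea.tsv", sep="\t", index=False)
            # category enrichment of lncRNA biotype among DEGs
            df = de_result.df
            ok = df["q"].notna()
            if "biotype" in df.columns:
                cat = (df.loc[ok, "biotype"] == "lncRNA").to_numpy()
                ce = enrichment.category_enrichment(df.loc[ok, "q"].to_numpy(), cat)
                ce.to_csv(outdir / "category_enrichment.tsv", sep="\t", index=False)
            manifest.record("enrichment", "ok",
                            [outdir / "gsea.tsv", outdir / "category_enrichment.tsv"])
        except Exception as e:
            logger.exception("enrichment stage failed")
            manifest.record("enrichment", f"failed: {e}", [])

    # lncRNA -----------------------------------------------------------------
    if stage("lncrna") and (datadir / "genes.gtf").exists():
        try:
            models = lncrna.read_gtf(datadir / "genes.gtf")
            lnc = [g for g in models if g.biotype == "lncRNA"]
            coding = [g for g in models if g.biotype == "protein_coding"]
            cls = lncrna.classify_lncrna(lnc, coding)
            cls.to_frame().to_csv(outdir / "lnc_classes.tsv", sep="\t", index=False)
            manifest.record("lncrna", "ok", [outdir / "lnc_classes.tsv"])
        except Exception as e:
            logger.exception("lncrna stage failed")
            manifest.record("lncrna", f"failed: {e}", [])

    manifest.finished = time.time()
    manifest.to_json(outdir / "manifest.json")
    return manifest
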