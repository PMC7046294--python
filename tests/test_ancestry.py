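"""Reference PCA, projection, k-NN ancestry calls, admixture estimation."""

import numpy as np
import pytest

from admixomics import ancestry, synth


def test_loadings_orthonormal_and_eigenvalues_sorted(small_pca):
    L = small_pca.loadings
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
    ev = small_pca.eigenvalues
    assert (ev >= 0).all() and (np.diff(ev) <= 1e-12).all()


def test_duplicated_panel_gives_identical_loadings(small_panel):
    gm = small_panel.panel.genotypes
    dup = ancestry.GenotypeMatrix(
        gm.sample_ids + [s + "_b" for s in gm.sample_ids],
        gm.snp_ids, np.vstack([gm.dosages, gm.dosages]))
    panel2 = ancestry.ReferencePanel(dup, small_panel.panel.labels * 2)
    m1 = ancestry.fit_reference_pca(small_panel.panel, n_axes=3)
    m2 = ancestry.fit_reference_pca(panel2, n_axes=3)
    common = [s for s in m1.snp_ids if s in set(m2.snp_ids)]
    i1 = [m1.snp_ids.index(s) for s in common]
    i2 = [m2.snp_ids.index(s) for s in common]
    assert np.allclose(m1.loadings[i1], m2.loadings[i2], atol=1e-6)


def test_pc1_separates_two_populations():
    model = synth.PopulationModel(n_pops=2, n_snps=1500, fst=0.1)
    sp = synth.simulate_reference_panel(model, 50, seed=21)
    pcm = ancestry.fit_reference_pca(sp.panel, n_axes=2)
    proj = ancestry.project_samples(pcm, sp.panel.genotypes)
    pc1_a = proj.coords[:50, 0]
    pc1_b = proj.coords[50:, 0]
    assert max(pc1_a.min(), pc1_b.min()) > min(pc1_a.max(), pc1_b.max()) \
        or max(pc1_b.min(), pc1_a.min()) > min(pc1_b.max(), pc1_a.max())
    assert (pc1_a.max() < pc1_b.min()) or (pc1_b.max() < pc1_a.min())


def test_projecting_panel_reproduces_fitted_scores(small_panel, small_pca):
    proj1 = ancestry.project_samples(small_pca, small_panel.panel.genotypes)
    proj2 = ancestry.project_samples(small_pca, small_panel.panel.genotypes)
    assert np.allclose(proj1.coords, proj2.coords, atol=1e-8)


def test_sample_at_panel_means_projects_to_origin(small_panel, small_pca):
    # dosages equal to the panel mean are all-missing: imputed to the mean
    gm = ancestry.GenotypeMatrix(["mean"], small_pca.snp_ids,
                                 np.full((1, len(small_pca.snp_ids)), np.nan))
    proj = ancestry.project_samples(small_pca, gm)
    assert np.allclose(proj.coords, 0.0, atol=1e-10)


def test_projection_requires_snp_overlap(small_pca):
    gm = ancestry.GenotypeMatrix(["x"], ["nope1", "nope2"], np.zeros((1, 2)))
    with pytest.raises(ValueError):
        ancestry.project_samples(small_pca, gm)


def test_n_axes_beyond_rank_errors():
    model = synth.PopulationModel(n_pops=2, n_snps=200, fst=0.2)
    sp = synth.simulate_reference_panel(model, 3, seed=2)
    with pytest.raises(ValueError):
        ancestry.fit_reference_pca(sp.panel, n_axes=10)


# ---------------------------------------------------------------------------
# k-NN
# ---------------------------------------------------------------------------

def test_knn_coincident_target_k1(small_panel, small_pca):
    refs = ancestry.project_samples(small_pca, small_panel.panel.genotypes)
    target = ancestry.Projection(["t"], refs.coords[[7]])
    call = ancestry.classify_knn(target, refs, small_panel.panel.labels, k=1)
    assert call.labels[0] == small_panel.panel.labels[7]


def test_knn_simulated_targets_all_correct(small_panel, small_pca):
    refs = ancestry.project_samples(small_pca, small_panel.panel.genotypes)
    Q = np.zeros((30, 3))
    Q[:10, 0] = Q[10:20, 1] = Q[20:, 2] = 1.0
    gm, _ = synth.simulate_admixed_cohort(small_panel, Q, seed=31)
    proj = ancestry.project_samples(small_pca, gm)
    call = ancestry.classify_knn(proj, refs, small_panel.panel.labels, k=5)
    expected = ["POP1"] * 10 + ["POP2"] * 10 + ["POP3"] * 10
    assert call.labels == expected


def test_knn_vote_splits_and_centroid_tiebreak():
    # constructed fixture: 2-2 tie at k=4 resolved by nearest centroid
    refs = ancestry.Projection(
        [f"r{i}" for i in range(4)],
        np.array([[0.0, 0.0], [0.1, 0.0], [2.0, 0.0], [2.1, 0.0]]))
    labels = ["A", "A", "B", "B"]
    target = ancestry.Projection(["t"], np.array([[1.0, 0.0]]))
    call = ancestry.classify_knn(target, refs, labels, k=4)
    assert call.tie_broken[0]
    assert call.votes[0] == {"A": 2, "B": 2}
    # centroid of A (0.05) is nearer to 1.0 than centroid of B (2.05)
    assert call.labels[0] == "A"
    # plurality at k=3: two A's and one B among the 3 nearest
    call3 = ancestry.classify_knn(target, refs, labels, k=3)
    assert not call3.tie_broken[0]
    assert call3.labels[0] == "A" and call3.votes[0] == {"A": 2, "B": 1}


def test_knn_invariant_to_reference_order(small_panel, small_pca, rng):
    refs = ancestry.project_samples(small_pca, small_panel.panel.genotypes)
    perm = rng.permutation(len(refs.sample_ids))
    refs_p = ancestry.Projection([refs.sample_ids[i] for i in perm],
                                 refs.coords[perm])
    labels = small_panel.panel.labels
    labels_p = [labels[i] for i in perm]
    target = ancestry.Projection(["t"], refs.coords[[3]] + 0.01)
    a = ancestry.classify_knn(target, refs, labels, k=5)
    b = ancestry.classify_knn(target, refs_p, labels_p, k=5)
    assert a.labels == b.labels


def test_knn_rejects_bad_k(small_panel, small_pca):
    refs = ancestry.project_samples(small_pca, small_panel.panel.genotypes)
    with pytest.raises(ValueError):
        ancestry.classify_knn(refs, refs, small_panel.panel.labels, k=0)


# ---------------------------------------------------------------------------
# admixture
# ---------------------------------------------------------------------------

def test_admixture_pure_sample_recovered(small_panel):
    Q = np.zeros((5, 3))
    Q[:, 0] = 1.0
    gm, _ = synth.simulate_admixed_cohort(small_panel, Q, seed=41)
    pops = small_panel.populations
    est = ancestry.estimate_admixture(gm, small_panel.pop_freqs, pops)
    assert (est.fractions[:, 0] >= 0.95).all()


def test_admixture_estimates_on_simplex(small_panel, rng):
    Q = rng.dirichlet(np.ones(3), size=10)
    gm, _ = synth.simulate_admixed_cohort(small_panel, Q, seed=42)
    est = ancestry.estimate_admixture(gm, small_panel.pop_freqs,
                                      small_panel.populations)
    assert np.allclose(est.fractions.sum(axis=1), 1.0, atol=1e-6)
    assert (est.fractions >= 0).all()


def test_admixture_identical_populations_degenerate(small_panel):
    F = np.tile(small_panel.pop_freqs[0], (3, 1))
    gm, _ = synth.simulate_admixed_cohort(small_panel, np.array([[1.0, 0, 0]]),
                                          seed=43)
    est = ancestry.estimate_admixture(gm, F, small_panel.populations)
    assert est.degenerate
    assert np.allclose(est.fractions, 1 / 3)


def test_admixture_half_half_recovery(small_panel):
    Q = np.tile([0.5, 0.5, 0.0], (40, 1))
    gm, _ = synth.simulate_admixed_cohort(small_panel, Q, seed=44)
    pops, F = ancestry.population_frequencies(small_panel.panel)
    est = ancestry.estimate_admixture(gm, F, pops)
    assert np.abs(est.fractions - Q).mean(axis=0).max() < 0.05


def test_vcf_reader_maps_gt_to_dosage(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "chr1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n"
        "chr1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\t./.\n"
        "chr1\t300\trs3\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/0\n")
    gm = ancestry.GenotypeMatrix.from_vcf(vcf)
    assert gm.sample_ids == ["s1", "s2"]
    assert gm.snp_ids == ["rs1", "rs2"]  # multiallelic rs3 skipped
    assert gm.dosages[0, 0] == 0 and gm.dosages[1, 0] == 1
    assert gm.dosages[0, 1] == 2 and np.isnan(gm.dosages[1, 1])
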