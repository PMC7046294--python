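"""wGII, alteration matrix, and the fixed-margin permutation machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from admixomics import costats, scna, synth


def enumerate_margin_class(row_sums, col_sums):
    """All binary matrices with the given margins (brute-force oracle)."""
    n, m = len(row_sums), len(col_sums)
    out = []

    def rec(i, remaining):
        if i == n:
            if all(r == 0 for r in remaining):
                out.append(np.array(rows))
            return
        # prune: remaining capacity must cover remaining row sums
        if sum(remaining) != sum(row_sums[i:]):
            return
        for cols in itertools.combinations(range(m), row_sums[i]):
            if all(remaining[c] > 0 for c in cols):
                row = [0] * m
                for c in cols:
                    row[c] = 1
                rows.append(row)
                rec(i + 1, [r - (c in cols) for c, r in enumerate(remaining)])
                rows.pop()

    rows: list = []
    rec(0, list(col_sums))
    return out


def seg_df(rows):
    return scna.SegmentTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# hypersegmentation filter
# ---------------------------------------------------------------------------

def test_filter_hypersegmented_boundary():
    rows = []
    for sid, nseg in [("keep", 2000), ("drop", 2001)]:
        for i in range(nseg):
            rows.append({"sample": sid, "chrom": "chr1", "start": i * 10 + 1,
                         "end": i * 10 + 10, "value": 0.0})
    out = scna.filter_hypersegmented(seg_df(rows))
    assert out.samples == ["keep"]
    empty = scna.filter_hypersegmented(seg_df([
        {"sample": "x", "chrom": "chr1", "start": 1, "end": 10, "value": 0.0}]))
    assert empty.samples == ["x"]


# ---------------------------------------------------------------------------
# wGII
# ---------------------------------------------------------------------------

def toy_two_chrom():
    return pd.DataFrame([
        {"sample": "t", "chrom": "chr1", "start": 1, "end": 60_000_000, "value": 0.0},
        {"sample": "t", "chrom": "chr1", "start": 60_000_001, "end": 100_000_000, "value": 0.58},
        {"sample": "t", "chrom": "chr2", "start": 1, "end": 100_000_000, "value": 0.0},
    ])


def test_wgii_hand_computed_toy():
    res = scna.compute_wgii(toy_two_chrom(), autosomes=("chr1", "chr2"))
    assert res.ploidy == 0.0
    assert res.gii["chr1"] == pytest.approx(0.4)
    assert res.gii["chr2"] == 0.0
    assert res.wgii == pytest.approx(0.2)


def test_wgii_flat_profile_is_zero():
    df = pd.DataFrame([{"sample": "t", "chrom": c, "start": 1,
                        "end": 50_000_000, "value": 0.7}
                       for c in ("chr1", "chr2")])
    res = scna.compute_wgii(df, autosomes=("chr1", "chr2"))
    assert res.wgii == 0.0 and res.ploidy == pytest.approx(0.7)


def test_wgii_refinement_invariance(rng):
    for _ in range(20):
        n_seg = rng.integers(2, 8)
        bounds = np.sort(rng.choice(np.arange(2, 1000), n_seg - 1, replace=False))
        edges = np.concatenate([[1], bounds * 100_000, [100_000_000]])
        vals = rng.normal(0, 0.5, n_seg)
        rows = []
        prev = 0
        for i in range(n_seg):
            start, end = prev + 1, int(edges[i + 1])
            rows.append({"sample": "t", "chrom": "chr1", "start": start,
                         "end": end, "value": vals[i]})
            prev = end
        base = pd.DataFrame(rows)
        # split every segment at its midpoint
        split_rows = []
        for r in rows:
            mid = (r["start"] + r["end"]) // 2
            if mid > r["start"]:
                split_rows.append({**r, "end": mid})
                split_rows.append({**r, "start": mid + 1})
            else:
                split_rows.append(r)
        a = scna.compute_wgii(base, autosomes=("chr1",))
        b = scna.compute_wgii(pd.DataFrame(split_rows), autosomes=("chr1",))
        assert a.wgii == pytest.approx(b.wgii, abs=1e-12)
        assert 0 <= a.wgii <= 1


def test_wgii_missing_autosome_named_in_error():
    with pytest.raises(ValueError, match="chr2"):
        scna.compute_wgii(toy_two_chrom()[lambda d: d.chrom == "chr1"],
                          autosomes=("chr1", "chr2"))


# ---------------------------------------------------------------------------
# region change & alteration matrix
# ---------------------------------------------------------------------------

def test_region_change_cases():
    segs = pd.DataFrame([
        {"sample": "s", "chrom": "chr1", "start": 1, "end": 1000, "value": -0.7},
        {"sample": "s", "chrom": "chr2", "start": 1, "end": 100, "value": 0.0},
        {"sample": "s", "chrom": "chr2", "start": 101, "end": 200, "value": 0.5},
    ])
    assert scna.region_change(segs, "chr1", 100, 200) == pytest.approx(-0.7)
    assert scna.region_change(segs, "chr2", 1, 200) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        scna.region_change(segs, "chr1", 200, 100)
    assert np.isnan(scna.region_change(segs, "chr3", 1, 10))


def test_alteration_matrix_boundary_thresholds():
    rows = [
        {"sample": "a", "chrom": "chr1", "start": 1, "end": 1000, "value": 0.25},
        {"sample": "b", "chrom": "chr1", "start": 1, "end": 1000, "value": -0.25},
        {"sample": "c", "chrom": "chr1", "start": 1, "end": 1000, "value": 0.10},
    ]
    seg = seg_df(rows)
    amp = scna.FocalRegionSet(pd.DataFrame([
        {"region": "r", "chrom": "chr1", "start": 1, "end": 1000,
         "type": "amplification"}]))
    dele = scna.FocalRegionSet(pd.DataFrame([
        {"region": "r", "chrom": "chr1", "start": 1, "end": 1000,
         "type": "deletion"}]))
    Xa = scna.build_alteration_matrix(seg, amp).X[:, 0]
    Xd = scna.build_alteration_matrix(seg, dele).X[:, 0]
    assert list(Xa) == [1, 0, 0]   # c = +0.25 counts for amplification
    assert list(Xd) == [0, 1, 0]   # c = -0.25 counts for deletion


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def test_permutations_preserve_margins_exactly(rng):
    for _ in range(5):
        X = (rng.random((8, 5)) < 0.35).astype(np.int8)
        rs, cs = X.sum(1), X.sum(0)
        for M in scna.permute_fixed_margins(X, n_perm=200, seed=5):
            assert (M.sum(1) == rs).all() and (M.sum(0) == cs).all()


def test_permutation_two_by_two_identity_split():
    X = np.eye(2, dtype=np.int8)
    seen = {0: 0, 1: 0}
    for M in scna.permute_fixed_margins(X, n_perm=10_000, seed=6):
        seen[int(M[0, 0])] += 1
    assert seen[0] / 10_000 == pytest.approx(0.5, abs=0.02)
    assert seen[1] / 10_000 == pytest.approx(0.5, abs=0.02)


def test_permutation_all_ones_degenerate():
    stream = scna.permute_fixed_margins(np.ones((3, 4), dtype=np.int8),
                                        n_perm=10, seed=7)
    mats = list(stream)
    assert stream.degenerate
    assert all((m == 1).all() for m in mats)


def test_permutation_uniform_over_enumerated_class():
    X = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=np.int8)
    cls = enumerate_margin_class(X.sum(1).tolist(), X.sum(0).tolist())
    keys = {m.tobytes(): i for i, m in enumerate(np.array(c, dtype=np.int8)
                                                 for c in cls)}
    counts = np.zeros(len(cls))
    n_emit = 6000
    for M in scna.permute_fixed_margins(X, n_perm=n_emit, seed=8):
        counts[keys[M.tobytes()]] += 1
    from scipy.stats import chisquare
    stat, p = chisquare(counts)
    assert counts.min() > 0
    assert p > 0.01


def test_permutation_respects_type_blocks(rng):
    X = (rng.random((6, 4)) < 0.5).astype(np.int8)
    types = ["amplification", "amplification", "deletion", "deletion"]
    for M in scna.permute_fixed_margins(X, types, n_perm=100, seed=9):
        # within-block row sums are preserved, not just global ones
        assert (M[:, :2].sum(1) == X[:, :2].sum(1)).all()
        assert (M[:, 2:].sum(1) == X[:, 2:].sum(1)).all()


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def _toy_alt(X, types=None):
    n, m = X.shape
    if types is None:
        types = ["deletion"] * m
    return scna.AlterationMatrix([f"s{i}" for i in range(n)],
                                 [f"r{j}" for j in range(m)],
                                 X.astype(np.int8), X.astype(float), types)


def test_group_swap_negates_observed_z(rng):
    X = (rng.random((60, 4)) < 0.3).astype(np.int8)
    group = np.array([1] * 30 + [0] * 30)
    a = scna.scna_association_test(_toy_alt(X), group, None, n_perm=300, seed=1)
    b = scna.scna_association_test(_toy_alt(X), 1 - group, None, n_perm=300, seed=1)
    assert np.allclose(a.df.z_obs, -b.df.z_obs, atol=1e-6)
    assert np.allclose(a.df.p, b.df.p, atol=0.05)


def test_needs_two_per_group(rng):
    X = (rng.random((10, 2)) < 0.5).astype(np.int8)
    with pytest.raises(ValueError):
        scna.scna_association_test(_toy_alt(X), np.array([1] + [0] * 9), None)


def test_wgii_association_requires_n4():
    with pytest.raises(ValueError):
        scna.wgii_association(np.array([0.1, 0.2, 0.3]), np.array([1, 0, 1]), None)


def test_wgii_association_detects_shift(rng):
    group = np.array([1] * 100 + [0] * 100)
    w = np.clip(rng.normal(0.2, 0.1, 200) + 0.1 * group, 0, 1)
    res = scna.wgii_association(w, group, None)
    assert res.p < 1e-6 and res.effect > 0


# ---------------------------------------------------------------------------
# SEG round trip
# ---------------------------------------------------------------------------

def test_seg_round_trip(tmp_path):
    df = toy_two_chrom()
    seg = scna.SegmentTable(df)
    path = tmp_path / "t.seg"
    seg.to_seg(path)
    back = scna.SegmentTable.from_seg(path)
    pd.testing.assert_frame_equal(
        back.df[["sample", "chrom", "start", "end", "value"]],
        df[["sample", "chrom", "start", "end", "value"]])


def test_segment_table_rejects_overlap():
    with pytest.raises(ValueError):
        seg_df([{"sample": "s", "chrom": "chr1", "start": 1, "end": 100, "value": 0},
                {"sample": "s", "chrom": "chr1", "start": 50, "end": 150, "value": 0}])
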