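"""Locus-biotype classification, chromatin proximity, RCI, AR calls, TSS profiles."""

import numpy as np
import pandas as pd
import pytest

from admixomics import lncrna, synth
from admixomics.lncrna import ChromatinStateMap, GeneModel, Transcript


def gene(gid, strand, exons, chrom="chr1", biotype="lncRNA"):
    return GeneModel(gid, biotype, chrom, strand,
                     [Transcript(f"{gid}.t1", chrom, strand, exons)])


CODING = [gene("PC1", "+", [(10_000, 11_000), (15_000, 16_000), (20_000, 21_000)],
               biotype="protein_coding")]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("exons,strand,expected", [
    ([(10_500, 10_800)], "+", "exonic"),          # shares exon bp, same strand
    ([(11_500, 12_000)], "+", "intronic"),        # inside intron 1, same strand
    ([(11_500, 12_000)], "-", "antisense"),       # span overlap, opposite strand
    ([(40_000, 41_000)], "+", "intergenic"),      # no span overlap
    ([(10_999, 11_001)], "+", "exonic"),          # 1 bp of shared exon suffices
])
def test_transcript_classes(exons, strand, expected):
    cls = lncrna.classify_lncrna([gene("L", strand, exons)], CODING)
    assert cls.gene_classes["L"] == expected


def test_gene_class_hierarchy_over_transcripts():
    g = GeneModel("L", "lncRNA", "chr1", "+", [
        Transcript("L.t1", "chr1", "+", [(11_500, 12_000)]),  # intronic
        Transcript("L.t2", "chr1", "+", [(10_500, 10_800)]),  # exonic
    ])
    cls = lncrna.classify_lncrna([g], CODING)
    assert cls.gene_classes["L"] == "exonic"
    assert cls.transcript_classes["L"] == {"L.t1": "intronic", "L.t2": "exonic"}


def test_same_strand_overlap_outranks_antisense():
    # overlaps PC1 on the same strand (intronic) and a second gene antisense
    coding = CODING + [gene("PC2", "-", [(11_400, 12_200)], biotype="protein_coding")]
    cls = lncrna.classify_lncrna([gene("L", "+", [(11_500, 12_000)])], coding)
    assert cls.gene_classes["L"] == "intronic"


def test_classification_round_trip_and_partition():
    lnc, coding, truth = synth.simulate_gene_models(10, 4, seed=9)
    cls = lncrna.classify_lncrna(lnc, coding)
    assert cls.gene_classes == truth.lnc_classes
    assert set(cls.gene_classes) == {g.gene_id for g in lnc}


def test_coordinate_shift_invariance():
    shift = 1_000_000
    lnc, coding, truth = synth.simulate_gene_models(5, 2, seed=10)

    def shifted(g):
        return GeneModel(g.gene_id, g.biotype, g.chrom, g.strand, [
            Transcript(t.transcript_id, t.chrom, t.strand,
                       [(a + shift, b + shift) for a, b in t.exons])
            for t in g.transcripts])

    a = lncrna.classify_lncrna(lnc, coding).gene_classes
    b = lncrna.classify_lncrna([shifted(g) for g in lnc],
                               [shifted(g) for g in coding]).gene_classes
    assert a == b


def test_transcript_without_exons_rejected():
    with pytest.raises(ValueError):
        Transcript("bad", "chr1", "+", [])


def test_empty_lnc_set_gives_empty_classification():
    cls = lncrna.classify_lncrna([], CODING)
    assert cls.gene_classes == {}


# ---------------------------------------------------------------------------
# chromatin-state proximity
# ---------------------------------------------------------------------------

def states_at(start, end, state="active_promoter"):
    return ChromatinStateMap(pd.DataFrame([
        {"chrom": "chr1", "start": start, "end": end, "state": state}]))


@pytest.mark.parametrize("gap,expected", [
    (5_000, True),     # 5 kb away
    (10_000, True),    # exactly 10 kb
    (10_001, False),   # 1 bp beyond
    (15_000, False),
])
def test_chromatin_window_boundaries(gap, expected):
    g = gene("L", "+", [(100_000, 101_000)])
    st = states_at(101_000 + gap, 101_000 + gap + 500)
    flags = lncrna.chromatin_state_annotation([g], st)
    assert bool(flags.loc["L", "active_promoter"]) is expected


def test_chromatin_overlap_distance_zero():
    g = gene("L", "+", [(100_000, 101_000)])
    flags = lncrna.chromatin_state_annotation([g], states_at(100_500, 100_600))
    assert bool(flags.loc["L", "active_promoter"])


def test_unknown_state_label_rejected():
    with pytest.raises(ValueError):
        ChromatinStateMap(pd.DataFrame([
            {"chrom": "chr1", "start": 1, "end": 2, "state": "mystery"}]))


# ---------------------------------------------------------------------------
# RCI comparison
# ---------------------------------------------------------------------------

def test_rci_shift_detected(rng):
    genes = [f"g{i}" for i in range(200)]
    de = pd.Series([True] * 100 + [False] * 100, index=genes)
    rci = pd.Series(np.concatenate([rng.normal(-1, 1, 100),
                                    rng.normal(0, 1, 100)]), index=genes)
    out = lncrna.rci_compare(rci, de)
    assert out["p"] < 1e-6 and out["difference"] < 0


def test_rci_single_gene_stratum_errors(rng):
    genes = ["a", "b", "c"]
    rci = pd.Series([0.0, 1.0, 2.0], index=genes)
    de = pd.Series([True, False, False], index=genes)
    with pytest.raises(ValueError):
        lncrna.rci_compare(rci, de)


# ---------------------------------------------------------------------------
# AR regulation
# ---------------------------------------------------------------------------

def test_arg_cutoff_calibration_hand_case():
    out = lncrna.calibrate_arg_cutoff(np.full(10, 2.0), (1.2, 1.5, 3.0))
    assert out["cutoff"] == 1.5 and out["sensitivity"] == 1.0


def test_arg_cutoff_boundary_and_floor_failure():
    out = lncrna.calibrate_arg_cutoff(np.array([1.5, 1.5]), (1.5,),
                                      sensitivity_floor=1.0)
    assert out["cutoff"] == 1.5 and out["sensitivity"] == 1.0
    out2 = lncrna.calibrate_arg_cutoff(np.array([1.4, 2.0]), (1.5, 2.5),
                                       sensitivity_floor=1.0)
    assert out2["flag"] == "no_cutoff_met_floor" and out2["cutoff"] == 1.5


def test_classify_args_boundaries():
    folds = pd.Series({"up": 1.25, "down": 0.80, "flat": 1.0, "edge": 1.2})
    out = lncrna.classify_args(folds, cutoff=1.2)
    assert out.loc["up", "direction"] == "enhanced"
    assert out.loc["down", "direction"] == "suppressed"  # 0.80 <= 1/1.2
    assert not out.loc["flat", "ar_regulated"]
    assert out.loc["edge", "ar_regulated"]
    with pytest.raises(ValueError):
        lncrna.classify_args(pd.Series({"bad": -1.0}))


# ---------------------------------------------------------------------------
# TSS aggregation
# ---------------------------------------------------------------------------

def test_tss_constant_track_flat_profile():
    track = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 1_000_000,
                           "value": 3.0}])
    tss = pd.DataFrame([{"chrom": "chr1", "pos": 500_000, "strand": "+"},
                        {"chrom": "chr1", "pos": 600_000, "strand": "+"}])
    prof = lncrna.tss_aggregate(track, tss, flank=2000, bin_size=100)
    assert np.allclose(prof.signal, 3.0)
    assert np.allclose(prof.coverage, 1.0)


def test_tss_spike_peaks_at_zero():
    track = pd.DataFrame([{"chrom": "chr1", "start": 499_950, "end": 500_050,
                           "value": 10.0}])
    tss = pd.DataFrame([{"chrom": "chr1", "pos": 500_000, "strand": "+"}])
    prof = lncrna.tss_aggregate(track, tss, flank=1000, bin_size=100)
    peak_pos = prof.loc[prof.signal.idxmax(), "position"]
    assert abs(peak_pos) <= 100


def test_tss_strand_mirror_symmetry():
    track = pd.DataFrame([{"chrom": "chr1", "start": 500_000, "end": 500_300,
                           "value": 5.0}])
    plus = pd.DataFrame([{"chrom": "chr1", "pos": 499_900, "strand": "+"}])
    # mirrored setup: signal upstream of a minus-strand TSS
    track_m = pd.DataFrame([{"chrom": "chr1", "start": 499_500, "end": 499_800,
                             "value": 5.0}])
    minus = pd.DataFrame([{"chrom": "chr1", "pos": 499_900, "strand": "-"}])
    a = lncrna.tss_aggregate(track, plus, flank=1000, bin_size=100)
    b = lncrna.tss_aggregate(track_m, minus, flank=1000, bin_size=100)
    assert np.allclose(a.signal, b.signal)


def test_tss_empty_list_errors():
    with pytest.raises(ValueError):
        lncrna.tss_aggregate(pd.DataFrame(columns=["chrom", "start", "end", "value"]),
                             pd.DataFrame(columns=["chrom", "pos", "strand"]))


# ---------------------------------------------------------------------------
# GTF round trip
# ---------------------------------------------------------------------------

def test_gtf_round_trip(tmp_path):
    lnc, coding, _ = synth.simulate_gene_models(3, 1, seed=12)
    path = tmp_path / "g.gtf"
    lncrna.write_gtf(lnc + coding, path)
    back = lncrna.read_gtf(path)
    assert {g.gene_id for g in back} == {g.gene_id for g in lnc + coding}
    orig = {g.gene_id: g for g in lnc + coding}
    for g in back:
        o = orig[g.gene_id]
        assert g.strand == o.strand and g.biotype == o.biotype
        assert [t.exons for t in g.transcripts] == [t.exons for t in o.transcripts]
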