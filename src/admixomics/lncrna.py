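"""lncRNA locus-biotype classification and regulatory annotation.

Each lncRNA transcript is placed relative to protein-coding gene loci:

* exonic — same-strand overlap sharing at least 1 bp of exonic sequence;
* intronic — same-strand gene-span overlap lying entirely within introns;
* antisense — opposite-strand gene-span overlap only;
* intergenic — no coding-gene span overlap.

A multi-transcript gene takes the highest transcript class under the
hierarchy exonic > intronic > antisense > intergenic.

Also here: chromatin-state proximity flags (within 10 kb of an annotated
state region), cytoplasmic/nuclear RCI comparison between DE and non-DE
lncRNAs, calibration of the fold-change cutoff that defines androgen
receptor (AR)-regulated genes against positive-control AR targets, and
TSS-centered aggregation of signal tracks.

Internally all intervals are 0-based half-open; the GTF reader (1-based
inclusive) and BED reader (already half-open) normalize on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "Transcript",
    "LncClassification",
    "ChromatinStateMap",
    "CHROMATIN_STATES",
    "classify_lncrna",
    "chromatin_state_annotation",
    "rci_compare",
    "calibrate_arg_cutoff",
    "classify_args",
    "tss_aggregate",
    "read_gtf",
    "write_gtf",
]

CLASS_HIERARCHY = ("exonic", "intronic", "antisense", "intergenic")
CHROMATIN_STATES = ("active_promoter", "bivalent_promoter", "active_enhancer",
                    "poised_enhancer", "polycomb", "transcribed", "unmarked")


@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    exons: list  # [(start, end)] 0-based half-open, sorted, non-overlapping

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    chrom: str
    strand: str
    transcripts: list  # of Transcript

    @property
    def span(self) -> tuple:
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return (min(starts), max(ends))


@dataclass
class LncClassification:
    gene_classes: dict       # gene_id -> class
    transcript_classes: dict  # gene_id -> {transcript_id: class}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"gene": g, "locus_class": c} for g, c in self.gene_classes.items()])


@dataclass
class ChromatinStateMap:
    df: pd.DataFrame  # chrom, start, end (half-open), state

    def __post_init__(self) -> None:
        bad = set(self.df["state"]) - set(CHROMATIN_STATES)
        if bad:
            raise ValueError(f"unknown chromatin states: {sorted(bad)}")


def _overlap(a: tuple, b: tuple) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _gap(a: tuple, b: tuple) -> int:
    """Gap between half-open intervals; 0 when they touch or overlap."""
    if _overlap(a, b) > 0:
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _classify_transcript(t: Transcript, coding: list) -> str:
    span = t.span
    same, opposite = [], []
    for g in coding:
        if g.chrom != t.chrom:
            continue
        if _overlap(span, g.span) > 0:
            (same if g.strand == t.strand else opposite).append(g)
    if same:
        for g in same:
            for gt in g.transcripts:
                for ex in gt.exons:
                    if any(_overlap(ex, te) > 0 for te in t.exons):
                        return "exonic"
        return "intronic"
    if opposite:
        return "antisense"
    return "intergenic"


def classify_lncrna(lnc: list, coding: list) -> LncClassification:
    """Locus-biotype class per lncRNA transcript and gene.

    Same-strand gene-span overlap outranks opposite-strand overlap within
    a transcript (exonic/intronic before antisense), and the gene-level
    class is the transcript maximum under the declared hierarchy.
    """
    gene_classes: dict = {}
    transcript_classes: dict = {}
    rank = {c: i for i, c in enumerate(CLASS_HIERARCHY)}
    for gene in lnc:
        tc = {t.transcript_id: _classify_transcript(t, coding) for t in gene.transcripts}
        transcript_classes[gene.gene_id] = tc
        gene_classes[gene.gene_id] = min(tc.values(), key=lambda c: rank[c])
    return LncClassification(gene_classes, transcript_classes)


# ---------------------------------------------------------------------------
# chromatin-state proximity
# ---------------------------------------------------------------------------

def chromatin_state_annotation(genes: list, states: ChromatinStateMap,
                               window: int = 10_000) -> pd.DataFrame:
    """Per-gene flag for each chromatin state within ``window`` bp.

    A gene is related to a state when the gap distance between its span
    and any interval of that state is at most ``window`` (overlap = 0).
    """
    by_state = {s: g for s, g in states.df.groupby("state")}
    rows = []
    for gene in genes:
        span = gene.span
        row = {"gene": gene.gene_id}
        for s in CHROMATIN_STATES:
            sdf = by_state.get(s)
            flag = False
            if sdf is not None:
                sub = sdf[sdf["chrom"] == gene.chrom]
                for rec in sub.itertuples(index=False):
                    if _gap(span, (rec.start, rec.end)) <= window:
                        flag = True
                        break
            row[s] = flag
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# RCI, AR regulation, TSS profiles
# ---------------------------------------------------------------------------

def rci_compare(rci: pd.Series, de_flags: pd.Series):
    """Pooled-variance two-sample t-test of CN-RCI between DE and non-DE genes.

    Lower RCI = nuclear enrichment; a negative difference (DE minus
    non-DE) indicates DE genes sit more in the nucleus.
    """
    common = rci.index.intersection(de_flags.index)
    x = rci.loc[common][de_flags.loc[common].astype(bool)].dropna()
    y = rci.loc[common][~de_flags.loc[common].astype(bool)].dropna()
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >=2 genes per stratum for the t-test")
    t, p = st.ttest_ind(x, y, equal_var=True)
    return {"t": float(t), "p": float(p), "mean_de": float(x.mean()),
            "mean_non_de": float(y.mean()),
            "difference": float(x.mean() - y.mean()),
            "n_de": len(x), "n_non_de": len(y)}


def calibrate_arg_cutoff(control_folds: np.ndarray, candidate_cutoffs,
                         sensitivity_floor: float = 0.85):
    """Choose the largest fold-change cutoff keeping control sensitivity high.

    Sensitivity at a cutoff = fraction of positive-control fold changes
    >= cutoff. Returns the largest candidate with sensitivity >= the
    floor; if none qualifies, the lowest candidate is returned flagged.
    """
    folds = np.asarray(control_folds, dtype=float)
    if folds.size == 0:
        raise ValueError("need at least one positive-control gene")
    cuts = sorted(float(c) for c in candidate_cutoffs)
    curve = {c: float(np.mean(folds >= c)) for c in cuts}
    qualifying = [c for c in cuts if curve[c] >= sensitivity_floor]
    if qualifying:
        chosen = max(qualifying)
        flag = ""
    else:
        chosen = cuts[0]
        flag = "no_cutoff_met_floor"
    return {"cutoff": chosen, "sensitivity": curve[chosen], "curve": curve,
            "flag": flag}


def classify_args(folds: pd.Series, cutoff: float = 1.2) -> pd.DataFrame:
    """AR-regulation calls from stimulation fold changes.

    Regulated iff fold >= cutoff (enhanced) or fold <= 1/cutoff
    (suppressed); boundary values count as regulated.
    """
    f = folds.astype(float)
    if (f <= 0).any():
        raise ValueError("fold changes must be positive")
    enhanced = f >= cutoff
    suppressed = f <= 1.0 / cutoff
    direction = np.where(enhanced, "enhanced",
                         np.where(suppressed, "suppressed", "none"))
    return pd.DataFrame({
        "gene": f.index,
        "fold": f.to_numpy(),
        "ar_regulated": (enhanced | suppressed).to_numpy(),
        "direction": direction,
    }).set_index("gene")


def tss_aggregate(track: pd.DataFrame, tss: pd.DataFrame, flank: int = 5000,
                  bin_size: int = 100):
    """Average signal profile around TSSs, strand-oriented.

    ``track``: chrom, start, end (half-open), value — binned or per-base
    signal. ``tss``: chrom, pos, strand. The profile covers
    [-flank, +flank) in TSS-relative coordinates at ``bin_size``
    resolution; minus-strand profiles are reversed before averaging;
    positions without track coverage contribute 0 and the per-bin coverage
    fraction is reported.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS list")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin size")
    n_bins = 2 * flank // bin_size
    profile = np.zeros(n_bins)
    coverage = np.zeros(n_bins)
    by_chrom = {c: g.sort_values("start") for c, g in track.groupby("chrom")}
    for rec in tss.itertuples(index=False):
        sub = by_chrom.get(rec.chrom)
        vals = np.zeros(n_bins)
        cov = np.zeros(n_bins)
        if sub is not None:
            win_lo = rec.pos - flank
            for seg in sub.itertuples(index=False):
                lo = max(seg.start, win_lo)
                hi = min(seg.end, rec.pos + flank)
                if lo >= hi:
                    continue
                b0 = (lo - win_lo) // bin_size
                b1 = (hi - 1 - win_lo) // bin_size
                for b in range(b0, b1 + 1):
                    bin_lo = win_lo + b * bin_size
                    ov = min(hi, bin_lo + bin_size) - max(lo, bin_lo)
                    vals[b] += seg.value * ov / bin_size
                    cov[b] += ov / bin_size
        if rec.strand == "-":
            vals = vals[::-1]
            cov = cov[::-1]
        profile += vals
        coverage += cov
    profile /= len(tss)
    coverage /= len(tss)
    positions = np.arange(-flank, flank, bin_size) + bin_size // 2
    return pd.DataFrame({"position": positions, "signal": profile,
                         "coverage": coverage})


# ---------------------------------------------------------------------------
# GTF I/O (1-based inclusive on disk, half-open in memory)
# ---------------------------------------------------------------------------

def read_gtf(path) -> list:
    """Parse gene/transcript/exon features into GeneModel objects."""
    genes: dict = {}
    tx: dict = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, feat, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            a = {}
            for item in attrs.strip().split(";"):
                item = item.strip()
                if not item:
                    continue
                k, v = item.split(" ", 1)
                a[k] = v.strip('"')
            start0, end0 = int(start) - 1, int(end)
            if feat == "gene":
                genes[a["gene_id"]] = {"biotype": a.get("gene_biotype", "other"),
                                       "chrom": chrom, "strand": strand, "tx": []}
            elif feat == "transcript":
                tx[a["transcript_id"]] = {"gene": a["gene_id"], "chrom": chrom,
                                          "strand": strand, "exons": []}
            elif feat == "exon":
                tx[a["transcript_id"]]["exons"].append((start0, end0))
    out = []
    for tid, t in tx.items():
        genes[t["gene"]]["tx"].append(
            Transcript(tid, t["chrom"], t["strand"], t["exons"]))
    for gid, g in genes.items():
        if g["tx"]:
            out.append(GeneModel(gid, g["biotype"], g["chrom"], g["strand"], g["tx"]))
    return out


def write_gtf(genes: list, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            s, e = g.span
            fh.write(f'{g.chrom}\tadmixomics\tgene\t{s+1}\t{e}\t.\t{g.strand}\t.\t'
                     f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";\n')
            for t in g.transcripts:
                ts, te = t.span
                fh.write(f'{g.chrom}\tadmixomics\ttranscript\t{ts+1}\t{te}\t.\t'
                         f'{t.strand}\t.\tgene_id "{g.gene_id}"; '
                         f'transcript_id "{t.transcript_id}";\n')
                for (a, b) in t.exons:
                    fh.write(f'{g.chrom}\tadmixomics\texon\t{a+1}\t{b}\t.\t'
                             f'{t.strand}\t.\tgene_id "{g.gene_id}"; '
                             f'transcript_id "{t.transcript_id}";\n')
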