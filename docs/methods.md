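# Methods

This note documents the models, defaults and numerical choices behind
`admixomics`, and what the synthetic-data generators do and do not
emulate.

## Ancestry inference

**Reference-only PCA.** SNP dosages g ∈ {0,1,2} are standardized with the
EIGENSTRAT convention (center 2p, scale √(2p(1−p)), p = panel allele
frequency). Axes are eigenvectors of the panel covariance only, so study
samples cannot rotate them. SNPs monomorphic in the panel or with missing
rate above 5% are dropped with a warning. Sign is fixed by making each
loading's largest-magnitude entry positive; projection imputes missing
dosages to the panel mean (zero after centering). 10 axes are retained by
default; this mirrors the top-ten output convention of the standard tool
and is configurable.

**k-NN calls.** Euclidean distance in the retained-axes space, majority
vote with k = 5 (small, odd, robust to a single outlying neighbor;
configurable). Ties are broken by the nearest population centroid among
the tied labels, and the tie is flagged. An optional "other" call fires
when the nearest-neighbor distance exceeds a configurable quantile of
within-population nearest-neighbor distances; there is no principled
universal rule here, so the default leaves it off.

**Admixture fractions.** The dosage vector is modeled per SNP as
Binomial(2, Σₐ qₐFₐ) with panel frequencies F fixed (clipped to
[10⁻⁶, 1−10⁻⁶]) and q free on the simplex. EM from the uniform point;
convergence when the log-likelihood improves < 10⁻⁸ (cap 5,000 EM steps).
Plain EM crawls near the simplex boundary, so each cycle performs two EM
steps plus a safeguarded extrapolation that is accepted only when it does
not lower the likelihood — the per-cycle likelihood stays monotone and
the fixed points are unchanged; converged samples leave the active set.
If all populations have (numerically) identical frequencies the
likelihood is flat; the estimator returns the uniform point flagged
degenerate. Estimates against *empirical* panel frequencies attenuate
slightly for near-pure samples (frequency noise makes small borrowings
from other populations profitable); recovery against the generating
frequencies is essentially exact. Mean absolute error on admixed samples
is ≈ 0.02 at 5,000 SNPs, Fst 0.1, 150 samples/population.

## Propensity-adjusted statistics

Group (the ancestry contrast of interest, coded 1) is regressed on age
(continuous) and grade (ordinal category coded by its integer rank; the
coding is a documented choice, not a reconstruction). Fitted
probabilities enter downstream models as a single covariate — no
matching or weighting. Perfect separation falls back to a ridge-penalized
Newton fit (intercept unpenalized, flagged `penalized`). Rank-based
models use the Blom inverse-normal transform ((r − 3/8)/(n + 1/4), ties
averaged). Fisher's exact test reports the hypergeometric two-sided p;
the displayed odds ratio is the sample OR with the Haldane 0.5 correction
applied only when a cell is zero (the p-value is never corrected). BH FDR
is the standard step-up.

## Mutational signatures

Channels are ordered substitution-major (C>A, C>G, C>T, T>A, T>C, T>G),
then 5′ base, then 3′ base, both alphabetical; purine-reference SNVs are
reverse-complemented into the pyrimidine representation. Refitting: NNLS
of the count-normalized spectrum on the catalog; weights normalized to
sum 1; weights < 0.06 discarded; then greedy pruning, re-evaluated lowest
weight first — a signature is removed for good when refitting without it
lowers the cosine similarity to the observed spectrum by at most 0.02.
The pruning order is a documented, deterministic choice. Final weights
are reported on the normalized scale without renormalization (sum ≤ 1), a
renormalized view is also available. A built-in set of three synthetic
block-structured signatures (pairwise cosine ≈ 0.16) ships for tests and
demos; real analyses should load a published 96 × S catalog TSV.

## Copy number

One common scale — log2 copy-number ratio centered at 0 — is used for
both the alteration matrix and wGII. The ±0.25 binarization threshold and
the 0.3 wGII deviation both apply on that scale; this is the
self-consistent reading of the two conventions, and a converter accepts
absolute-copy-number input. Boundary values count as altered (≥ / ≤).
Per-chromosome GII uses the covered length (sum of segment lengths) as
the denominator, which is robust to uncovered telomeres. Samples with
more than 2,000 segments are excluded before analysis. Region-level
change c is the length-weighted mean segment value over the region;
uncovered regions propagate as unaltered with a warning.

**Fixed-margin permutation engine.** The null keeps each tumor's overall
disruption (row sums) and each region's alteration frequency (column
sums) fixed, separately within amplification and deletion columns. The
sampler is the checkerboard-swap Markov chain: propose a random 2×2
submatrix; if it is [[1,0],[0,1]] or [[0,1],[1,0]], swap it. Failed
proposals are self-loops of the kernel and must be counted — terminating
after a fixed number of *successful* swaps samples the degree-biased jump
chain, which is measurably non-uniform (we verified this against complete
enumeration of small margin classes). Burn-in performs 50·(count of 1s) +
200 attempts and doubles as an acceptance-rate probe; thinning between
emissions is then scaled in attempts so each gap performs about
(count of 1s) successful swaps in expectation regardless of matrix
density. Uniformity over enumerated margin classes is asserted in the
test suite (chi-square). A matrix with no swappable 2×2 has a singleton
margin class; the stream emits copies and carries a degeneracy flag.

**Association test.** Observed Z per region from the logistic model
group ~ alteration + propensity; the same model is refit on every
permuted matrix. The solver is a damped Newton iteration vectorized
across permutation columns (it matches `statsmodels` to ~10⁻¹⁰ on single
fits); fits driven to separation are flagged NaN and dropped from the
null. Two-sided empirical p = (1 + #{|Z_null| ≥ |Z_obs| − 10⁻⁹}) /
(n_perm + 1); the 10⁻⁹ tolerance makes tie counting robust to
floating-point asymmetry, since discrete columns produce exact ties.
BH across regions; regions flagged at q < 0.25.

**Calibration note.** Under a global null with independent uniform
p-values, BH at q < 0.25 flags at least one of m = 20 regions in ≈ 25% of
datasets (the Simes identity); discreteness of the conditional
(hypergeometric-overlap) null lowers this to roughly 16% in our
measurements with an exact-enumeration sampler. This is a property of
BH at a liberal threshold, not of the permutation engine; the test suite
documents the observed rate.

## Expression

The DE stage is an explicitly simplified stand-in for a full NB
differential-expression framework: median-of-ratios size factors;
per-gene method-of-moments dispersion from within-group residual moments
of normalized counts (floored at 10⁻⁸, capped at 10); NB log-linear model
with log size-factor offsets fit by IRLS vectorized across genes (the
design matrix is shared); Wald test of the group coefficient against the
standard normal. No dispersion shrinkage, no fold-change shrinkage, no
independent filtering — results from an external DE tool can be
substituted via the `DEResult` TSV reader wherever those refinements
matter. All-zero genes are flagged and excluded from testing and from the
BH denominator. Null simulations at n = 40/40, 2,000 genes give uniform
p-values (KS); planted 2-fold signals are recovered with sensitivity
≥ 0.8 at empirical FDR ≤ 0.15 (q < 0.1).

## Enrichment

Pre-ranked GSEA uses the classical running sum: hit increments
∝ |metric|^w (default w = 1, normalized to +1 total), uniform miss
decrements (−1 total); ES is the extremum of the walk; ties in the
ranking are broken by item id (stable, documented). The null permutes
set membership over the universe (the pre-ranked convention), n_perm =
1,000 by default; NES divides ES by the mean |null ES| of matching sign
and p is computed within the matching sign with +1 smoothing. BH is
applied across sets (a divergence from GSEA-native FDR, flagged here).
SSEA applies the same machinery to samples ranked by one gene's
expression with cancer types as sample sets; fractional ranks are
(ascending rank)/n with ties averaged, so the top gene scores 1.0 and
the 2nd of 20 scores 0.95.

## lncRNA annotation

Classification is per transcript: same-strand coding overlap takes
precedence (exonic if ≥ 1 bp of exon is shared with a same-strand
overlapping coding gene, else intronic), then antisense
(opposite-strand span overlap only), else intergenic; gene class is the
transcript maximum under exonic > intronic > antisense > intergenic.
Span overlap (not exon overlap) defines antisense and intergenic.
Internally all intervals are 0-based half-open; GTF (1-based inclusive)
and BED readers normalize on load, and distances are gap distances
between intervals (overlap = 0). Chromatin-state proximity uses the gene
span with a 10 kb window (boundary inclusive); whether the span or the
TSS anchors the distance is not a settled convention, so the span is the
default and the window configurable. The AR-regulation cutoff is
calibrated on positive-control fold changes: the largest candidate cutoff
with control sensitivity ≥ 0.85 (default floor) is chosen; calls use
fold ≥ cutoff or ≤ 1/cutoff, boundaries inclusive.

## Synthetic data

The generators define the study conditions for all tests:

* **Genotypes** — Balding–Nichols: population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p ~ U(0.05, 0.95),
  genotypes Binomial(2, f); admixed samples draw each allele copy from a
  population chosen by the sample's fractions. Defaults for the demo and
  acceptance runs: 3 populations × 150, Fst 0.1, 5,000 SNPs. No linkage
  disequilibrium — panels behave like independent markers, so PCA
  separation here is cleaner than on real arrays.
* **Spectra** — multinomial draws from signature mixtures; row sums equal
  the requested mutation count exactly. The demo uses 2,000 SNVs per
  tumor; weight-recovery statements use 50,000, where multinomial noise
  is ≈ ±0.01 per weight.
* **Segments** — chromosomes tiled exactly (no gaps/overlaps) with
  Gaussian segment noise (sd 0.05) around 0; planted focal events add
  ±0.6 in carriers, with group-specific carrier probabilities; planted
  edges always coincide with segment boundaries. Effect 0.6 vs threshold
  0.25 at noise 0.05 makes binarization unambiguous (≥ 5 sd margins).
* **Counts** — NB via gamma-Poisson, dispersion 0.05, base means
  log-uniform on [20, 2000], log-normal size factors (sd 0.15); planted
  log2 fold changes ±1; confounding injected as group shifts in age
  (Gaussian, default −5 y) and grade (latent-normal ordinal shift).
* **Gene models** — coding genes 20 kb, 4 × 1 kb exons, spaced 100 kb on
  one strand; lncRNAs constructed per class, intergenic ones > 10 kb from
  any coding gene.

Every generator is a pure function of (parameters, seed). Passing tests
on these data demonstrate correctness of the statistical machinery under
the stated models — not robustness to LD, mutation hotspots, GC bias,
batch effects, or segmentation artifacts, none of which are simulated.

## Problem sizes and runtime

The default test suite and the acceptance script are sized for a single
CPU: SCNA calibration/power replicates use n = 200/200, m = 20 regions
and 1,000–2,000 permutations (the empirical-p resolution needed for the
q < 0.25 decision is ~0.0125, so 1,000 permutations is ample; the paper-
scale default of 10,000 remains the library default), DE runs use 2,000
genes, and ancestry runs 5,000 SNPs. The demo pipeline completes in
about half a minute.

## Known limitations

* The admixture estimator is supervised (panel frequencies fixed); it
  does not learn populations and inherits panel-frequency noise.
* The DE stand-in is anticonservative for very low counts where the
  normal Wald reference is poor; the pluggable DE reader exists for that
  reason.
* The permutation test's BH threshold of q < 0.25 is liberal by design
  (discovery screening); see the calibration note above.
* GTF parsing covers the gene/transcript/exon features the pipeline
  writes and consumes; it is not a general-purpose GTF validator.
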