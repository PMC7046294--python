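"""Segmented copy number: wGII and the margin-preserving SCNA permutation test.

Copy-number input is a segment table (SEG-style: sample, chromosome,
1-based inclusive start/end, log2 copy-number ratio). Two analyses live
here:

* the weighted Genome Instability Index (wGII): per sample, ploidy is the
  length-weighted median segment value; each autosome's GII is the fraction
  of its covered length deviating from ploidy by more than 0.3; wGII is the
  unweighted mean of the per-autosome GIIs so every chromosome counts
  equally regardless of size;

* a controlled permutation test for group-differential recurrent focal
  alterations: the binary tumors x regions matrix X (amplification regions
  marked altered at c >= +0.25, deletion regions at c <= -0.25, with c the
  length-weighted mean log2 ratio over the region) is shuffled by a
  checkerboard-swap Markov chain that preserves every row and column sum
  exactly, separately within amplification and deletion columns, and the
  observed logistic-model Z score for each region is ranked within the
  permutation distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import costats

logger = logging.getLogger(__name__)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = [
    "SegmentTable",
    "WgiiResult",
    "FocalRegionSet",
    "AlterationMatrix",
    "PermutationResult",
    "filter_hypersegmented",
    "compute_wgii",
    "region_change",
    "build_alteration_matrix",
    "permute_fixed_margins",
    "scna_association_test",
    "wgii_association",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "value"]
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class SegmentTable:
    """Segments for one or many samples; coordinates 1-based inclusive."""

    df: pd.DataFrame  # columns: sample, chrom, start, end, value [, num_mark]

    def __post_init__(self) -> None:
        missing = set(SEG_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        if (self.df["end"] < self.df["start"]).any():
            raise ValueError("segment end < start")
        # sortedness / non-overlap within sample+chromosome
        for (_, _), grp in self.df.groupby(["sample", "chrom"], sort=False):
            s = grp.sort_values("start")
            if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
                raise ValueError("overlapping segments within a sample chromosome")

    @classmethod
    def from_seg(cls, path) -> "SegmentTable":
        df = pd.read_csv(path, sep="\t")
        ren = {"ID": "sample", "Sample": "sample", "chromosome": "chrom",
               "loc.start": "start", "loc.end": "end", "seg.mean": "value",
               "num.mark": "num_mark"}
        df = df.rename(columns={c: ren.get(c, c) for c in df.columns})
        return cls(df)

    def to_seg(self, path) -> None:
        out = self.df.rename(columns={"sample": "ID", "chrom": "chromosome",
                                      "start": "loc.start", "end": "loc.end",
                                      "value": "seg.mean"})
        if "num_mark" not in self.df.columns:
            out["num.mark"] = ((self.df["end"] - self.df["start"]) // 1000 + 1).astype(int)
        else:
            out = out.rename(columns={"num_mark": "num.mark"})
        out = out[["ID", "chromosome", "loc.start", "loc.end", "num.mark", "seg.mean"]]
        out.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return self.df["sample"].unique().tolist()

    def for_sample(self, sample: str) -> pd.DataFrame:
        return self.df[self.df["sample"] == sample]


@dataclass
class WgiiResult:
    sample_id: str
    ploidy: float
    gii: dict            # chrom -> fraction in [0,1]
    wgii: float

    def __post_init__(self) -> None:
        assert 0.0 <= self.wgii <= 1.0


@dataclass
class FocalRegionSet:
    df: pd.DataFrame  # columns: region, chrom, start, end, type

    def __post_init__(self) -> None:
        need = {"region", "chrom", "start", "end", "type"}
        if need - set(self.df.columns):
            raise ValueError(f"region set missing columns: {sorted(need - set(self.df.columns))}")
        bad = set(self.df["type"]) - {"amplification", "deletion"}
        if bad:
            raise ValueError(f"unknown region types: {sorted(bad)}")

    @classmethod
    def from_bed(cls, path) -> "FocalRegionSet":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "region", "type"])
        df["start"] = df["start"] + 1  # BED is 0-based half-open
        return cls(df[["region", "chrom", "start", "end", "type"]])


@dataclass
class AlterationMatrix:
    """Binary tumors x regions matrix plus the underlying changes."""

    sample_ids: list[str]
    region_ids: list[str]
    X: np.ndarray            # (n, m) int 0/1
    changes: np.ndarray      # (n, m) float c_ij; NaN where region uncovered
    region_types: list[str]  # "amplification" | "deletion" per column
    threshold: float = 0.25

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.sample_ids, columns=self.region_ids)
        df.index.name = "sample"
        return df


@dataclass
class PermutationResult:
    df: pd.DataFrame  # region, type, z_obs, null_mean, null_sd, p, q, flagged
    n_perm: int
    degenerate: bool = False


# ---------------------------------------------------------------------------
# wGII
# ---------------------------------------------------------------------------

def filter_hypersegmented(segments: SegmentTable, max_segments: int = 2000) -> SegmentTable:
    """Drop samples with more than ``max_segments`` segments (logged)."""
    counts = segments.df.groupby("sample").size()
    drop = counts[counts > max_segments].index.tolist()
    if drop:
        logger.warning("excluding %d hypersegmented samples (> %d segments): %s",
                       len(drop), max_segments, drop[:5])
    return SegmentTable(segments.df[~segments.df["sample"].isin(drop)].reset_index(drop=True))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= half."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    return float(v[np.searchsorted(cw, 0.5 * cw[-1])])


def compute_wgii(segments: pd.DataFrame | SegmentTable, deviation: float = 0.3,
                 autosomes: tuple = AUTOSOMES, sample_id: str = "") -> WgiiResult:
    """wGII for one sample's segments.

    Ploidy is the length-weighted median segment value over all listed
    autosomes; per-chromosome GII uses the covered length (sum of segment
    lengths) as denominator; wGII is the unweighted mean of the GIIs.
    """
    df = segments.df if isinstance(segments, SegmentTable) else segments
    if sample_id == "" and "sample" in df.columns and len(df):
        sample_id = str(df["sample"].iloc[0])
    df = df[df["chrom"].isin(autosomes)]
    for c in autosomes:
        if c not in set(df["chrom"]):
            raise ValueError(f"sample {sample_id!r} has no segments on {c}")
    lengths = (df["end"] - df["start"] + 1).to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    ploidy = _weighted_median(values, lengths)
    gii = {}
    for c in autosomes:
        sel = (df["chrom"] == c).to_numpy()
        lc, vc = lengths[sel], values[sel]
        aberrant = np.abs(vc - ploidy) > deviation
        gii[c] = float(lc[aberrant].sum() / lc.sum())
    wgii = float(np.mean([gii[c] for c in autosomes]))
    return WgiiResult(sample_id=sample_id, ploidy=ploidy, gii=gii, wgii=wgii)


def compute_wgii_all(segments: SegmentTable, **kw) -> pd.DataFrame:
    rows = []
    for s in segments.samples:
        r = compute_wgii(segments.for_sample(s), sample_id=s, **kw)
        rows.append({"sample": s, "ploidy": r.ploidy, "wgii": r.wgii})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# alteration matrix
# ---------------------------------------------------------------------------

def region_change(segments: pd.DataFrame, chrom: str, start: int, end: int) -> float:
    """Length-weighted mean segment value over a region (c_ij).

    Returns NaN (with a warning upstream) when no segment overlaps.
    """
    if end < start:
        raise ValueError("zero- or negative-length region")
    sel = segments[(segments["chrom"] == chrom)
                   & (segments["end"] >= start) & (segments["start"] <= end)]
    if len(sel) == 0:
        return np.nan
    ov = (np.minimum(sel["end"], end) - np.maximum(sel["start"], start) + 1).to_numpy(dtype=float)
    return float(np.average(sel["value"].to_numpy(), weights=ov))


def build_alteration_matrix(segments: SegmentTable, regions: FocalRegionSet,
                            threshold: float = 0.25) -> AlterationMatrix:
    """Binarize per-region copy-number changes into the matrix X.

    X_ij = 1 iff the region is an amplification and c_ij >= +threshold, or
    a deletion and c_ij <= -threshold (boundary values count as altered).
    Regions with no overlapping segment are treated as unaltered (warned).
    """
    samples = segments.samples
    reg = regions.df.reset_index(drop=True)
    n, m = len(samples), len(reg)
    C = np.full((n, m), np.nan)
    # index segments as arrays per (sample, chromosome) once
    seg_idx: dict = {}
    for (s, c), grp in segments.df.groupby(["sample", "chrom"], sort=False):
        seg_idx[(s, c)] = (grp["start"].to_numpy(), grp["end"].to_numpy(),
                           grp["value"].to_numpy(dtype=float))
    reg_tuples = [(str(r["region"]), r["chrom"], int(r["start"]), int(r["end"]))
                  for _, r in reg.iterrows()]
    for i, s in enumerate(samples):
        for j, (_, chrom, start, end) in enumerate(reg_tuples):
            hit = seg_idx.get((s, chrom))
            if hit is None:
                continue
            st, en, vals = hit
            sel = (en >= start) & (st <= end)
            if not sel.any():
                continue
            ov = np.minimum(en[sel], end) - np.maximum(st[sel], start) + 1
            C[i, j] = np.average(vals[sel], weights=ov)
    if np.isnan(C).any():
        logger.warning("%d sample/region pairs uncovered by segments; treated as unaltered",
                       int(np.isnan(C).sum()))
    types = reg["type"].tolist()
    X = np.zeros((n, m), dtype=np.int8)
    for j, t in enumerate(types):
        c = C[:, j]
        if t == "amplification":
            X[:, j] = (c >= threshold) & ~np.isnan(c)
        else:
            X[:, j] = (c <= -threshold) & ~np.isnan(c)
    return AlterationMatrix(samples, reg["region"].astype(str).tolist(), X, C,
                            types, threshold)


# ---------------------------------------------------------------------------
# fixed-margin permutation engine
# ---------------------------------------------------------------------------

@njit(cache=True)
def _swap_chain(M, n_attempts, seed):  # pragma: no cover - jit-compiled
    """Run ``n_attempts`` checkerboard-swap attempts in place.

    Failed attempts are self-loops of the Markov kernel; they must be
    counted (stopping after a fixed number of successes would sample the
    degree-biased jump chain instead of the uniform distribution).
    Returns the number of successful swaps.
    """
    n, m = M.shape
    np.random.seed(seed)
    nn = n * n
    mm = m * m
    tot = nn * mm
    done = 0
    for _ in range(n_attempts):
        r = np.random.randint(tot)  # one draw encodes (i1, i2, j1, j2)
        ij = r // mm
        jj = r - ij * mm
        i1 = ij // n
        i2 = ij - i1 * n
        j1 = jj // m
        j2 = jj - j1 * m
        if i1 == i2 or j1 == j2:
            continue
        a = M[i1, j1]
        if a == M[i2, j2]:
            b = M[i1, j2]
            if b != a and M[i2, j1] == b:
                M[i1, j1] = b
                M[i2, j2] = b
                M[i1, j2] = a
                M[i2, j1] = a
                done += 1
    return done


def _has_checkerboard(M: np.ndarray) -> bool:
    """True iff some 2x2 submatrix is swappable (margin class size > 1)."""
    n, m = M.shape
    for j1 in range(m):
        for j2 in range(j1 + 1, m):
            col = M[:, j1] - M[:, j2]
            if (col > 0).any() and (col < 0).any():
                return True
    return False


def permute_fixed_margins(X: np.ndarray, region_types: list[str] | None = None,
                          n_perm: int = 10000, seed: int = 0):
    """Yield ``n_perm`` binary matrices with the row/column sums of X.

    Checkerboard-swap MCMC: repeatedly pick a random 2x2 submatrix and, if
    it is a checkerboard ([[1,0],[0,1]] or [[0,1],[1,0]]), swap it. Burn-in
    is 10x the number of ones and thinning 1x the number of ones, counted
    in attempted swaps. When ``region_types`` is given, amplification and
    deletion columns are permuted by independent chains so alterations
    never migrate between the two event classes. A matrix with no
    swappable submatrix has a singleton margin class: copies of X are
    emitted and the stream is flagged degenerate (``stream.degenerate``).
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.int8))
    if set(np.unique(X)) - {0, 1}:
        raise ValueError("X must be binary")
    if region_types is None:
        blocks = [np.arange(X.shape[1])]
    else:
        types = np.asarray(region_types)
        blocks = [np.where(types == "amplification")[0], np.where(types == "deletion")[0]]
        blocks = [b for b in blocks if b.size]

    rng = np.random.default_rng(seed)
    work = [X[:, b].copy() for b in blocks]
    swappable = [_has_checkerboard(w) for w in work]
    degenerate = not any(swappable)
    ones = [max(int(w.sum()), 1) for w in work]
    seeds = [int(rng.integers(0, 2**31 - 1)) for _ in blocks]

    # Burn-in doubles as an acceptance-rate probe: thinning is then scaled
    # in attempts so each emission gap performs about (count of 1s)
    # successful swaps in expectation, whatever the matrix density.
    thin = [0] * len(blocks)
    for b, w in enumerate(work):
        if not swappable[b]:
            continue
        probe = 50 * ones[b] + 200
        got = _swap_chain(w, probe, seeds[b] % (2**31 - 1))
        rate = max(got / probe, 1e-3)
        thin[b] = min(int(np.ceil(ones[b] / rate)), 500 * ones[b] + 1000)

    def stream():
        for t in range(n_perm):
            out = np.empty_like(X)
            for b, w in enumerate(work):
                if swappable[b]:
                    _swap_chain(w, thin[b], (seeds[b] + t + 1) % (2**31 - 1))
                out[:, blocks[b]] = w
            yield out

    gen = stream()
    gen = _FlaggedStream(gen, degenerate)
    return gen


class _FlaggedStream:
    """Iterator wrapper carrying the degeneracy flag of a permutation stream."""

    def __init__(self, gen, degenerate: bool):
        self._gen = gen
        self.degenerate = degenerate

    def __iter__(self):
        return self._gen

    def __next__(self):
        return next(self._gen)


# ---------------------------------------------------------------------------
# vectorized logistic Z scores (group ~ alteration + propensity)
# ---------------------------------------------------------------------------

def _logistic_z_batch(y: np.ndarray, Xcols: np.ndarray, ps: np.ndarray | None,
                      max_iter: int = 25, tol: float = 1e-8) -> np.ndarray:
    """Wald Z for the alteration coefficient, batched over columns.

    Fits logit(P(y=1)) = b0 + b1*x_k (+ b2*ps) independently for every
    column x_k of ``Xcols`` with a Newton solver vectorized across columns.
    Returns one Z per column (NaN where the fit is unstable, e.g. a
    constant column).
    """
    y = np.asarray(y, dtype=float)
    n, K = Xcols.shape
    use_ps = ps is not None and np.ptp(ps) > 1e-12
    p_dim = 3 if use_ps else 2
    beta = np.zeros((p_dim, K))
    Xc = np.asarray(Xcols, dtype=float)
    psv = np.asarray(ps, dtype=float) if use_ps else None

    degenerate = np.ptp(Xc, axis=0) <= 0
    # active-set Newton: converged columns are compacted away each iteration
    work = np.where(~degenerate)[0]
    for _ in range(max_iter):
        if work.size == 0:
            break
        Xw = Xc[:, work]
        bw = beta[:, work]
        eta = bw[0][None, :] + Xw * bw[1][None, :]
        if use_ps:
            eta = eta + psv[:, None] * bw[2][None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (Xw * r).sum(axis=0)
        a00 = W.sum(axis=0)
        a01 = (W * Xw).sum(axis=0)
        a11 = (W * Xw * Xw).sum(axis=0)
        if use_ps:
            g2 = (psv[:, None] * r).sum(axis=0)
            a02 = (W * psv[:, None]).sum(axis=0)
            a12 = (W * Xw * psv[:, None]).sum(axis=0)
            a22 = (W * (psv ** 2)[:, None]).sum(axis=0)
            H = np.stack([
                np.stack([a00, a01, a02], axis=0),
                np.stack([a01, a11, a12], axis=0),
                np.stack([a02, a12, a22], axis=0),
            ], axis=0)  # (3,3,k)
            G = np.stack([g0, g1, g2], axis=0)
        else:
            H = np.stack([
                np.stack([a00, a01], axis=0),
                np.stack([a01, a11], axis=0),
            ], axis=0)
            G = np.stack([g0, g1], axis=0)
        Ht = np.moveaxis(H, 2, 0)  # (k,p,p)
        Gt = np.moveaxis(G, 1, 0)[:, :, None]  # (k,p,1)
        # regularize the rare singular system
        eye = np.eye(p_dim) * 1e-10
        try:
            step = np.linalg.solve(Ht + eye, Gt)[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Ht + eye, Gt, rcond=None)[0][:, :, 0]
        step = np.clip(step, -5, 5)  # damped for separation robustness
        beta[:, work] = bw + step.T
        unconverged = np.max(np.abs(step), axis=1) >= tol
        work = work[unconverged]

    # final information matrix for SEs
    eta = beta[0][None, :] + Xc * beta[1][None, :]
    if use_ps:
        eta = eta + psv[:, None] * beta[2][None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    a00 = W.sum(axis=0)
    a01 = (W * Xc).sum(axis=0)
    a11 = (W * Xc * Xc).sum(axis=0)
    if use_ps:
        a02 = (W * psv[:, None]).sum(axis=0)
        a12 = (W * Xc * psv[:, None]).sum(axis=0)
        a22 = (W * (psv ** 2)[:, None]).sum(axis=0)
        H = np.stack([
            np.stack([a00, a01, a02], axis=0),
            np.stack([a01, a11, a12], axis=0),
            np.stack([a02, a12, a22], axis=0),
        ], axis=0)
    else:
        H = np.stack([
            np.stack([a00, a01], axis=0),
            np.stack([a01, a11], axis=0),
        ], axis=0)
    Ht = np.moveaxis(H, 2, 0)
    with np.errstate(all="ignore"):
        cov = np.linalg.pinv(Ht + np.eye(p_dim) * 1e-10)
        se1 = np.sqrt(cov[:, 1, 1])
        z = beta[1] / se1
    z[degenerate] = np.nan
    # flag blown-up fits (separation) rather than report huge Z
    z[np.abs(beta[1]) > 20] = np.nan
    return z


def scna_association_test(alt: AlterationMatrix, group: np.ndarray,
                          propensity, n_perm: int = 10000, seed: int = 0,
                          q_flag: float = 0.25, chunk: int = 200) -> PermutationResult:
    """Margin-preserving permutation test for group-differential regions.

    Observed Z per region comes from the logistic model
    group ~ alteration + propensity; the null distribution is the same Z
    recomputed on fixed-margin permutations of X (amplifications and
    deletions permuted separately). Two-sided empirical
    p = (1 + #{|Z_null| >= |Z_obs|}) / (n_perm + 1), BH-adjusted across
    regions, flagged at q < ``q_flag``.
    """
    y = np.asarray(group, dtype=float)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("need >=2 samples per group")
    ps = None
    if propensity is not None:
        ps = propensity.scores if isinstance(propensity, costats.PropensityModel) else np.asarray(propensity)
    X = alt.X.astype(float)
    m = X.shape[1]
    z_obs = _logistic_z_batch(y, X, ps)

    stream = permute_fixed_margins(alt.X, alt.region_types, n_perm=n_perm, seed=seed)
    exceed = np.zeros(m)
    n_null = np.zeros(m)
    null_sum = np.zeros(m)
    null_sq = np.zeros(m)
    buf = []
    abs_obs = np.abs(z_obs)

    def flush(buf):
        if not buf:
            return
        cols = np.concatenate([b.astype(float) for b in buf], axis=1)  # (n, m*B)
        zs = _logistic_z_batch(y, cols, ps).reshape(len(buf), m)
        for k in range(m):
            zk = zs[:, k]
            ok = np.isfinite(zk)
            # tie tolerance: discrete columns tie exactly; count ties as extreme
            exceed[k] += np.sum(np.abs(zk[ok]) >= abs_obs[k] - 1e-9)
            n_null[k] += ok.sum()
            null_sum[k] += zk[ok].sum()
            null_sq[k] += (zk[ok] ** 2).sum()

    for M in stream:
        buf.append(M)
        if len(buf) >= chunk:
            flush(buf)
            buf = []
    flush(buf)

    with np.errstate(invalid="ignore"):
        p = (1.0 + exceed) / (n_null + 1.0)
        null_mean = null_sum / np.maximum(n_null, 1)
        null_sd = np.sqrt(np.maximum(null_sq / np.maximum(n_null, 1) - null_mean ** 2, 0))
    p = np.clip(p, None, 1.0)
    p[~np.isfinite(z_obs)] = np.nan  # untestable region (constant column / separation)
    q = costats.bh_fdr(np.where(np.isfinite(p), p, 1.0))
    df = pd.DataFrame({
        "region": alt.region_ids,
        "type": alt.region_types,
        "z_obs": z_obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "p": p,
        "q": q,
        "flagged": q < q_flag,
    })
    return PermutationResult(df=df, n_perm=n_perm, degenerate=stream.degenerate)


def wgii_association(wgii: np.ndarray, group: np.ndarray,
                     propensity) -> costats.AssociationResult:
    """Linear model wGII ~ group + propensity."""
    wgii = np.asarray(wgii, dtype=float)
    if len(wgii) < 4:
        raise ValueError("need at least 4 samples")
    return costats.adjusted_linear(wgii, group, propensity, unit="wgii")
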