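"""Corroboration statistics for candidate linked regions.

Each statistic here gives an independent line of evidence on a region
flagged by the genotype scan:

* windowed Weir–Cockerham F_ST between the two homokaryotype groups
  (shifts from ~0 outside to ~1 inside a true inversion),
* pairwise r² linkage disequilibrium (a dense high-r² block spans a
  non-recombining region),
* windowed nucleotide diversity π and non-overlapping-window Tajima's D
  with an inside/outside Wilcoxon contrast (a polymorphic inversion at
  intermediate frequency behaves like balancing selection),
* identity-by-state distances with classical MDS (three karyotype
  clusters along axis 1 when restricted to region SNPs),
* the generalized-ESD (Rosner) outlier test for windowed F_ST scans.

r² is the squared Pearson correlation of genotype dosages (composite LD),
not the EM haplotype-frequency r²: the data are unphased and the block
structure is what matters.  Negative per-site F_ST components are kept as
computed, not clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from karyoscan.matrix import MISSING, GenotypeMatrix

__all__ = [
    "GroupAssignment",
    "OutlierResult",
    "WilcoxonResult",
    "wc_fst_site",
    "windowed_fst",
    "pairwise_r2",
    "windowed_pi",
    "windowed_tajimas_d",
    "compare_tajima_in_out",
    "ibs_distance",
    "classical_mds",
    "rosner_outliers",
    "bp_windows",
]


# ----------------------------------------------------------------------
# grouping and window helpers
# ----------------------------------------------------------------------

@dataclass
class GroupAssignment:
    """Mapping sample -> group label; exactly two non-empty groups."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        self.labels = labels

    @classmethod
    def from_tsv(cls, path: str) -> "GroupAssignment":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"],
                         dtype=str, comment="#")
        return cls(dict(zip(df["sample"], df["group"])))

    def indices(self, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        missing = [s for s in self.assignment if s not in samples]
        if missing:
            raise ValueError(f"samples not in matrix: {missing}")
        g1 = np.array([i for i, s in enumerate(samples)
                       if self.assignment.get(s) == self.labels[0]])
        g2 = np.array([i for i, s in enumerate(samples)
                       if self.assignment.get(s) == self.labels[1]])
        if len(g1) == 0 or len(g2) == 0:
            raise ValueError("both groups must be non-empty")
        return g1, g2


def bp_windows(pos_min: int, pos_max: int, window_bp: int, step_bp: int) -> np.ndarray:
    """bp-based window starts covering [pos_min, pos_max]; windows are
    [start, start + window_bp - 1], anchored at multiples of step_bp from 1."""
    first = ((pos_min - 1) // step_bp) * step_bp + 1
    starts = np.arange(first, pos_max + 1, step_bp, dtype=np.int64)
    return starts


# ----------------------------------------------------------------------
# Weir & Cockerham F_ST
# ----------------------------------------------------------------------

def _wc_components(G: np.ndarray, g1: np.ndarray, g2: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-population Weir & Cockerham (a, b, c) per site.

    G is (samples, sites); components are NaN where a group has no
    genotyped individual.
    """
    r = 2.0
    comps = []
    for idx in (g1, g2):
        sub = G[idx]
        ok = sub != MISSING
        n_i = ok.sum(axis=0).astype(float)                    # diploids genotyped
        alt = np.where(ok, sub, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(n_i > 0, alt / (2 * np.maximum(n_i, 1)), np.nan)
            h_i = np.where(n_i > 0,
                           np.where(ok, sub == 1, 0).sum(axis=0) / np.maximum(n_i, 1),
                           np.nan)
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps
    valid = (n1 > 0) & (n2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    # monomorphic across both groups: all components zero by convention
    mono = valid & ((pbar == 0) | (pbar == 1))
    for arr in (a, b, c):
        arr[mono] = 0.0
    return a, b, c


def wc_fst_site(gm: GenotypeMatrix, groups: GroupAssignment, site: int
                ) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) variance components (a, b, c) at one site.

    Per-site F_ST is a / (a + b + c), undefined when the denominator is
    zero (e.g. a site monomorphic in both groups).
    """
    g1, g2 = groups.indices(gm.samples)
    a, b, c = _wc_components(gm.G[:, [site]], g1, g2)
    return float(a[0]), float(b[0]), float(c[0])


def windowed_fst(
    gm: GenotypeMatrix, groups: GroupAssignment,
    window_bp: int = 10_000, step_bp: int = 2_500,
) -> pd.DataFrame:
    """Sliding-window weighted F_ST = sum(a) / sum(a+b+c) per bp window.

    Returns a frame with chrom, start_bp, end_bp, n_variants, value
    (NaN where no usable site falls in the window).
    """
    g1, g2 = groups.indices(gm.samples)
    frames = []
    for chrom, sub in gm.iter_chromosomes():
        a, b, c = _wc_components(sub.G, g1, g2)
        denom = a + b + c
        usable = np.isfinite(denom)
        pos = sub.sites["pos"].to_numpy()
        starts = bp_windows(int(pos.min()), int(pos.max()), window_bp, step_bp)
        rows = []
        for s in starts:
            e = s + window_bp - 1
            in_w = (pos >= s) & (pos <= e) & usable
            n = int(in_w.sum())
            if n == 0 or np.nansum(denom[in_w]) == 0:
                val = np.nan
            else:
                val = float(np.nansum(a[in_w]) / np.nansum(denom[in_w]))
            rows.append((chrom, int(s), int(e), n, val))
        frames.append(pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                                  "n_variants", "value"]))
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# linkage disequilibrium
# ----------------------------------------------------------------------

def pairwise_r2(
    gm: GenotypeMatrix, chrom: str,
    max_dist_bp: int = 100_000, r2_min: float = 0.7,
    thin_frac: float = 0.1, seed: int | None = None,
) -> pd.DataFrame:
    """Composite-LD r² for site pairs within ``max_dist_bp`` on one chromosome.

    Variants are first thinned (each kept independently with probability
    ``thin_frac`` under ``seed``); r² is the squared Pearson correlation
    of dosage vectors over samples non-missing at both sites.  Only pairs
    reaching ``r2_min`` are returned (chrom, pos_a, pos_b, r2), with
    pos_a < pos_b.  Zero-variance sites yield no pairs.
    """
    sub = gm.subset_sites(np.asarray(gm.sites["chrom"] == chrom))
    if sub.n_sites < 2:
        raise ValueError(f"need >= 2 sites on {chrom}")
    rng = np.random.default_rng(seed)
    if thin_frac < 1.0:
        keep = rng.random(sub.n_sites) < thin_frac
        sub = sub.subset_sites(keep)
    pos = sub.sites["pos"].to_numpy()
    G = sub.G.astype(float)
    G[G == MISSING] = np.nan
    n = sub.n_sites
    out_a, out_b, out_r2 = [], [], []
    for i in range(n - 1):
        jmax = int(np.searchsorted(pos, pos[i] + max_dist_bp, side="right"))
        if jmax <= i + 1:
            continue
        x = G[:, i]
        block = G[:, i + 1:jmax]
        ok = ~np.isnan(x)[:, None] & ~np.isnan(block)
        m = ok.sum(axis=0).astype(float)
        xs = np.where(ok, x[:, None], 0.0)
        ys = np.where(ok, block, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = xs.sum(axis=0) / m
            my = ys.sum(axis=0) / m
            sxy = (xs * ys).sum(axis=0) - m * mx * my
            sxx = (xs * xs).sum(axis=0) - m * mx * mx
            syy = (ys * ys).sum(axis=0) - m * my * my
            r2 = np.where((sxx > 0) & (syy > 0) & (m >= 2),
                          (sxy * sxy) / (sxx * syy), np.nan)
        hit = np.flatnonzero(r2 >= r2_min)
        for h in hit:
            out_a.append(int(pos[i]))
            out_b.append(int(pos[i + 1 + h]))
            out_r2.append(float(r2[h]))
    return pd.DataFrame({"chrom": chrom, "pos_a": out_a, "pos_b": out_b, "r2": out_r2})


def ld_block_span(pairs: pd.DataFrame, min_partners: int = 3) -> tuple[int, int] | None:
    """bp span of the dense high-LD block: positions participating in at
    least ``min_partners`` high-r² pairs; None when no such position."""
    if pairs.empty:
        return None
    counts = pd.concat([pairs["pos_a"], pairs["pos_b"]]).value_counts()
    dense = counts[counts >= min_partners].index.to_numpy()
    if dense.size == 0:
        return None
    return int(dense.min()), int(dense.max())


# ----------------------------------------------------------------------
# diversity statistics
# ----------------------------------------------------------------------

def _site_pi(G: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site pairwise diversity 2 j (m - j) / (m (m - 1)) with j the ALT
    allele count and m the non-missing allele count; returns (pi, j, m)."""
    ok = G != MISSING
    m = 2.0 * ok.sum(axis=0)
    j = np.where(ok, G, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(m > 1, 2.0 * j * (m - j) / (m * (m - 1)), np.nan)
    return pi, j, m


def windowed_pi(
    gm: GenotypeMatrix, window_bp: int = 10_000, step_bp: int = 2_500,
) -> pd.DataFrame:
    """Sliding-window nucleotide diversity: sum of per-site π over the
    window, divided by the window length in bp."""
    frames = []
    for chrom, sub in gm.iter_chromosomes():
        pi, _, _ = _site_pi(sub.G)
        pos = sub.sites["pos"].to_numpy()
        starts = bp_windows(int(pos.min()), int(pos.max()), window_bp, step_bp)
        rows = []
        for s in starts:
            e = s + window_bp - 1
            in_w = (pos >= s) & (pos <= e) & np.isfinite(pi)
            n = int(in_w.sum())
            val = float(pi[in_w].sum() / window_bp) if n else np.nan
            rows.append((chrom, int(s), int(e), n, val))
        frames.append(pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                                  "n_variants", "value"]))
    return pd.concat(frames, ignore_index=True)


def tajima_constants(m: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for m sampled chromosomes."""
    if m < 2:
        raise ValueError("need >= 2 chromosomes")
    i = np.arange(1, m)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m**2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def windowed_tajimas_d(gm: GenotypeMatrix, window_bp: int = 10_000) -> pd.DataFrame:
    """Tajima's D in non-overlapping bp windows.

    D = (π̂ - S/a1) / sqrt(e1 S + e2 S (S-1)) with π̂ the summed per-site
    pairwise diversity (not normalized by length) and S the segregating
    site count; NaN when S = 0 or the variance term vanishes.  The
    chromosome count m is twice the number of samples; sites where some
    genotypes are missing still contribute their per-site diversity,
    computed on the non-missing alleles.
    """
    m = 2 * gm.n_samples
    const = tajima_constants(m)
    frames = []
    for chrom, sub in gm.iter_chromosomes():
        pi, j, mm = _site_pi(sub.G)
        seg = (j > 0) & (j < mm)
        pos = sub.sites["pos"].to_numpy()
        starts = bp_windows(int(pos.min()), int(pos.max()), window_bp, window_bp)
        rows = []
        for s in starts:
            e = s + window_bp - 1
            in_w = (pos >= s) & (pos <= e) & seg & np.isfinite(pi)
            S = int(in_w.sum())
            if S == 0:
                val = np.nan
            else:
                var = const["e1"] * S + const["e2"] * S * (S - 1)
                val = (float(pi[in_w].sum() - S / const["a1"]) / np.sqrt(var)
                       if var > 0 else np.nan)
            rows.append((chrom, int(s), int(e), S, val))
        frames.append(pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                                  "n_variants", "value"]))
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# Wilcoxon inside/outside contrast
# ----------------------------------------------------------------------

@dataclass
class WilcoxonResult:
    u: float
    z: float
    p: float
    median_inside: float
    median_outside: float
    n_inside: int
    n_outside: int
    method: str


def compare_tajima_in_out(
    track: pd.DataFrame, regions: list[tuple[str, int, int]],
) -> WilcoxonResult:
    """Two-sided unpaired Wilcoxon rank-sum of windowed values inside vs
    outside the given (chrom, start_bp, end_bp) influence areas.

    A window counts as inside when it overlaps any region.  Exact
    enumeration is used when the smaller side has <= 10 windows and there
    are no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    vals = track["value"].to_numpy(dtype=float)
    inside = np.zeros(len(track), dtype=bool)
    for chrom, s, e in regions:
        inside |= ((track["chrom"] == chrom).to_numpy()
                   & (track["start_bp"].to_numpy() <= e)
                   & (track["end_bp"].to_numpy() >= s))
    ok = np.isfinite(vals)
    x = vals[inside & ok]
    y = vals[~inside & ok]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("need windowed values on both sides of the contrast")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u = float(res.statistic)
    mu = len(x) * len(y) / 2.0
    # z from the tie-corrected normal approximation (for reporting)
    nx, ny = len(x), len(y)
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return WilcoxonResult(
        u=u, z=float(z), p=float(res.pvalue),
        median_inside=float(np.median(x)), median_outside=float(np.median(y)),
        n_inside=len(x), n_outside=len(y), method=method,
    )


# ----------------------------------------------------------------------
# IBS distance and classical MDS
# ----------------------------------------------------------------------

def ibs_distance(gm: GenotypeMatrix, sites: np.ndarray | None = None) -> pd.DataFrame:
    """Identity-by-state distance matrix between samples.

    d(j, k) = sum over shared non-missing sites of |g_j - g_k| divided by
    2 x (number of shared sites); 0 for identical genotypes, 1 for
    opposite homozygotes everywhere.
    """
    G = gm.G if sites is None else gm.G[:, sites]
    Gf = G.astype(float)
    Gf[G == MISSING] = np.nan
    N = Gf.shape[0]
    D = np.zeros((N, N))
    for j in range(N):
        diff = np.abs(Gf[j][None, :] - Gf)
        shared = (~np.isnan(diff)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            D[j] = np.where(shared > 0, np.nansum(diff, axis=1) / (2.0 * shared), np.nan)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=gm.samples, columns=gm.samples)


def classical_mds(D: pd.DataFrame | np.ndarray, n_axes: int = 5
                  ) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-coordinates analysis of a symmetric distance matrix.

    Double-centers -D²/2, eigendecomposes, and returns coordinates
    (eigenvectors scaled by sqrt of the non-negative eigenvalues, axes in
    non-increasing eigenvalue order) plus the eigenvalues.  Each axis sign
    is fixed so its largest-magnitude loading is positive.
    """
    labels = list(D.index) if isinstance(D, pd.DataFrame) else None
    A = np.asarray(D, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (A**2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(n_axes, n)
    coords = np.zeros((n, k))
    for i in range(k):
        lam = max(evals[i], 0.0)
        v = evecs[:, i] * np.sqrt(lam)
        if np.abs(v).max() > 0 and v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, i] = v
    out = pd.DataFrame(coords, columns=[f"axis{i + 1}" for i in range(k)])
    if labels is not None:
        out.index = labels
    return out, evals[:k]


# ----------------------------------------------------------------------
# generalized ESD (Rosner) outlier test
# ----------------------------------------------------------------------

@dataclass
class OutlierResult:
    k_suspected: int
    stats: pd.DataFrame       # columns: index, value, R, lam, is_outlier
    outlier_indices: np.ndarray
    alpha: float

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)


def rosner_outliers(values: np.ndarray | pd.Series, alpha: float = 0.01,
                    k: int | None = None) -> OutlierResult:
    """Generalized extreme Studentized deviate test for up to k outliers.

    When ``k`` is not given it is set to the number of values outside
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR].  For i = 1..k the most extreme
    remaining point is removed and R_i = max|x - mean| / sd is compared
    with the Student-t critical value
    lambda_i = (n - i) t / sqrt((n - i - 1 + t²)(n - i + 1)),
    t the (1 - alpha / (2 (n - i + 1)))-quantile with n - i - 1 df.
    The declared outliers are the first i* points where i* is the
    largest i with R_i > lambda_i.
    """
    x = pd.Series(values, dtype=float).dropna()
    n = len(x)
    if n < 25:
        import warnings
        warnings.warn(f"generalized ESD assumes roughly normal data and n >= 25 (n={n})",
                      stacklevel=2)
    if k is None:
        q1, q3 = np.percentile(x, [25, 75])
        iqr = q3 - q1
        k = int(((x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)).sum())
    empty = pd.DataFrame(columns=["index", "value", "R", "lam", "is_outlier"])
    if k == 0:
        return OutlierResult(0, empty, np.array([], dtype=int), alpha)
    work = x.copy()
    rows = []
    last_sig = 0
    for i in range(1, k + 1):
        mu, sd = work.mean(), work.std(ddof=1)
        if sd == 0:
            raise ValueError("zero standard deviation in remaining data")
        dev = (work - mu).abs()
        idx = dev.idxmax()
        R = dev.loc[idx] / sd
        ni = n - i + 1  # points in play at step i
        p = 1.0 - alpha / (2.0 * ni)
        t = stats.t.ppf(p, df=ni - 2)
        lam = (ni - 1) * t / np.sqrt((ni - 2 + t**2) * ni)
        rows.append((idx, float(work.loc[idx]), float(R), float(lam), False))
        if R > lam:
            last_sig = i
        work = work.drop(idx)
    df = pd.DataFrame(rows, columns=["index", "value", "R", "lam", "is_outlier"])
    if last_sig > 0:
        df.loc[: last_sig - 1, "is_outlier"] = True
    out_idx = df.loc[df["is_outlier"], "index"].to_numpy()
    return OutlierResult(k, df, out_idx, alpha)
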