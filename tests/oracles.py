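"""Independent brute-force transcriptions of the defining formulas.

Everything here is written as a literal, loop-based transcription of the
textbook definitions, deliberately sharing no code with the package, so
the tests can compare the two routes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def wc_fst_components(g1: np.ndarray, g2: np.ndarray) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) two-population a, b, c from dosage vectors.

    g1, g2: dosage arrays for the two groups, -1 = missing.
    """
    r = 2
    pops = []
    for g in (g1, g2):
        g = np.asarray(g)
        g = g[g >= 0]
        n = len(g)                       # diploid individuals
        p = float(np.sum(g)) / (2 * n)   # alt allele frequency
        h = float(np.sum(g == 1)) / n    # observed heterozygote frequency
        pops.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = pops
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (
        s2 - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def site_pi(g: np.ndarray) -> float:
    """Per-site pairwise diversity by enumerating allele pairs."""
    alleles = []
    for d in np.asarray(g):
        if d >= 0:
            alleles.extend([1] * int(d) + [0] * (2 - int(d)))
    m = len(alleles)
    diff = 0
    for x, y in itertools.combinations(alleles, 2):
        diff += int(x != y)
    return diff / math.comb(m, 2)


def tajimas_d(G: np.ndarray) -> float:
    """Tajima's D for a window of dosage columns (samples x sites), no missing."""
    m = 2 * G.shape[0]
    seg_cols = [G[:, s] for s in range(G.shape[1])
                if 0 < np.sum(G[:, s]) < m]
    S = len(seg_cols)
    if S == 0:
        return float("nan")
    pi_hat = sum(site_pi(col) for col in seg_cols)
    a1 = sum(1.0 / i for i in range(1, m))
    a2 = sum(1.0 / i ** 2 for i in range(1, m))
    b1 = (m + 1) / (3 * (m - 1))
    b2 = 2 * (m ** 2 + m + 3) / (9 * m * (m - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_hat - S / a1) / math.sqrt(var)


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation by the definitional sums, skipping
    pairs with a missing member (-1)."""
    pairs = [(a, b) for a, b in zip(x, y) if a >= 0 and b >= 0]
    n = len(pairs)
    mx = sum(a for a, _ in pairs) / n
    my = sum(b for _, b in pairs) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a, _ in pairs)
    syy = sum((b - my) ** 2 for _, b in pairs)
    if sxx == 0 or syy == 0:
        return float("nan")
    return sxy * sxy / (sxx * syy)


def ibs_distance(gj: np.ndarray, gk: np.ndarray) -> float:
    shared = [(a, b) for a, b in zip(gj, gk) if a >= 0 and b >= 0]
    return sum(abs(a - b) for a, b in shared) / (2 * len(shared))


def wilcoxon_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group labelings.

    Assumes no ties.  Returns (U of x, p).
    """
    x, y = list(x), list(y)
    nx, ny = len(x), len(y)
    pooled = x + y
    u_obs = sum(1 for a in x for b in y if a > b)
    center = nx * ny / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(nx + ny), nx):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(nx + ny) if i not in comb]
        u = sum(1 for a in xs for b in ys if a > b)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return float(u_obs), count / total


def rosner_lambdas(n: int, alpha: float, k: int) -> list[float]:
    """Generalized-ESD critical values lambda_i for i = 1..k."""
    from scipy.stats import t as tdist

    lams = []
    for i in range(1, k + 1):
        p = 1 - alpha / (2 * (n - i + 1))
        t = tdist.ppf(p, n - i - 1)
        lam = (n - i) * t / math.sqrt((n - i - 1 + t ** 2) * (n - i + 1))
        lams.append(lam)
    return lams


def enumerate_windows(n_snps: int, window: int, step: int) -> list[tuple[int, int]]:
    """Window index spans by direct enumeration of the layout rule."""
    if window >= n_snps:
        return [(0, n_snps - 1)]
    spans = []
    start = 0
    while start + window <= n_snps:
        spans.append((start, start + window - 1))
        start += step
    if spans[-1][1] < n_snps - 1:
        spans.append((start, n_snps - 1))
    return spans
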