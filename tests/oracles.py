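"""Independent brute-force oracles used to check the package's statistics
and geometry against first principles. Nothing here calls the package."""

from itertools import combinations

import numpy as np
from scipy.optimize import least_squares


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann–Whitney p by full enumeration of all
    C(nx+ny, nx) group assignments of the pooled sample (no ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    ranks = pooled.argsort().argsort() + 1.0  # no ties by assumption
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    # the distribution is symmetric about nx*ny/2; two-sided via min tail
    mean = nx * (n - nx) / 2.0
    dev_obs = abs(u_obs - mean)
    combs = np.array(list(combinations(range(n), nx)))
    u_all = ranks[combs].sum(axis=1) - nx * (nx + 1) / 2.0
    return float(np.mean(np.abs(u_all - mean) >= dev_obs - 1e-12))


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns
    of the absolute differences (no zero diffs, no tied magnitudes)."""
    d = np.asarray(diffs, float)
    n = len(d)
    ranks = np.abs(d).argsort().argsort() + 1.0
    w_obs = ranks[d > 0].sum()
    mean = n * (n + 1) / 4.0
    dev_obs = abs(w_obs - mean)
    count = 0
    for mask in range(2**n):
        w = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        if abs(w - mean) >= dev_obs - 1e-12:
            count += 1
    return count / 2**n


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho as the Pearson correlation of midranks."""
    def midrank(a):
        a = np.asarray(a, float)
        order = a.argsort(kind="mergesort")
        ranks = np.empty(len(a))
        sa = a[order]
        i = 0
        while i < len(a):
            j = i
            while j + 1 < len(a) and sa[j + 1] == sa[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def geometric_sphere_fit(points, x0=None):
    """Iterative geometric least-squares sphere (minimizes true distances)."""
    pts = np.asarray(points, float)
    if x0 is None:
        c0 = pts.mean(axis=0)
        r0 = np.linalg.norm(pts - c0, axis=1).mean()
        x0 = np.r_[c0, r0]

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    sol = least_squares(resid, x0)
    return sol.x[:3], float(sol.x[3])
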