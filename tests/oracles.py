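"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written on a different code path from the
package (explicit loops, statsmodels fits, exhaustive enumeration) so the
comparisons in the tests are two-route checks, not self-agreement.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import statsmodels.api as sm


def wls_through_origin(bx, by, se_out):
    """Weighted least squares of by on bx through the origin (statsmodels)."""
    w = 1.0 / np.asarray(se_out) ** 2
    fit = sm.WLS(np.asarray(by), np.asarray(bx), weights=w).fit()
    return float(fit.params[0]), float(fit.bse[0] / np.sqrt(fit.scale))


def wls_with_intercept(bx, by, se_out):
    """Weighted regression with intercept; returns (intercept, slope)."""
    w = 1.0 / np.asarray(se_out) ** 2
    X = sm.add_constant(np.asarray(bx))
    fit = sm.WLS(np.asarray(by), X, weights=w).fit()
    return float(fit.params[0]), float(fit.params[1])


def exhaustive_clump(records, ld_lookup, p_threshold, r2_clump):
    """Enumerate all subsets; return the unique one that is pairwise
    LD-compatible and where every excluded candidate conflicts with some
    earlier-ranked retained variant. ``records``: list of (variant_id, pval).
    """
    cands = sorted(
        [(vid, p) for vid, p in records if p < p_threshold],
        key=lambda t: (t[1], t[0]),
    )
    ids = [vid for vid, _ in cands]
    rank = {vid: i for i, vid in enumerate(ids)}
    solutions = []
    for bits in itertools.product([0, 1], repeat=len(ids)):
        subset = [vid for vid, b in zip(ids, bits) if b]
        ok = all(
            ld_lookup(a, b) < r2_clump
            for a, b in itertools.combinations(subset, 2)
        )
        if not ok:
            continue
        excluded_justified = all(
            any(
                rank[s] < rank[c] and ld_lookup(c, s) >= r2_clump
                for s in subset
            )
            for c in ids
            if c not in subset
        )
        if excluded_justified:
            solutions.append(subset)
    assert len(solutions) == 1, f"expected unique maximal subset, got {len(solutions)}"
    return solutions[0]


def proxy_by_rule(target, candidates, r2_min):
    """``candidates``: list of (variant_id, r2_with_target, exposure_p).
    Sort by the documented rule and take the head; None when nothing passes.
    """
    passing = [(vid, r2, p) for vid, r2, p in candidates if r2 > r2_min]
    if not passing:
        return None
    passing.sort(key=lambda t: (-t[1], t[2], t[0]))
    return passing[0][0]


def presso_brute_force(bx, by, se_out, n_sim, seed):
    """Loop-based re-derivation of the resampling RSS test under the
    package's documented seed-stream contract (one generator, one
    standard_normal((n_sim, n)) call).
    """
    bx, by, se_out = map(np.asarray, (bx, by, se_out))
    n = len(bx)
    w = 1.0 / se_out**2

    def loo_slope(x, y, wts, skip):
        num = den = 0.0
        for j in range(len(x)):
            if j == skip:
                continue
            num += wts[j] * x[j] * y[j]
            den += wts[j] * x[j] * x[j]
        return num / den

    res_obs = np.empty(n)
    for j in range(n):
        b = loo_slope(bx, by, w, j)
        res_obs[j] = w[j] * (by[j] - b * bx[j]) ** 2
    rss_obs = res_obs.sum()

    child_main, _ = np.random.SeedSequence(seed).spawn(2)
    z = np.random.default_rng(child_main).standard_normal((n_sim, n))
    expected = np.array([loo_slope(bx, by, w, j) * bx[j] for j in range(n)])
    rss_sim = np.empty(n_sim)
    res_sim = np.empty((n_sim, n))
    for r in range(n_sim):
        y_r = expected + se_out * z[r]
        total = 0.0
        for j in range(n):
            b = loo_slope(bx, y_r, w, j)
            res_sim[r, j] = w[j] * (y_r[j] - b * bx[j]) ** 2
            total += res_sim[r, j]
        rss_sim[r] = total
    frac = float(np.mean(rss_sim >= rss_obs))
    global_p = frac if frac > 0 else 1.0 / (2.0 * n_sim)
    outlier_p = []
    for j in range(n):
        pj = float(np.mean(res_sim[:, j] >= res_obs[j]))
        if pj == 0:
            pj = 1.0 / (2.0 * n_sim)
        outlier_p.append(min(1.0, pj * n))
    return global_p, outlier_p


def power_binary_oracle(n_total, k, r2, or_, alpha=0.05):
    """Brion-style binary power via math.erf (no scipy)."""

    def phi(x):
        return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))

    def phi_inv(p):  # bisection, independent of scipy.ppf
        lo, hi = -10.0, 10.0
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if phi(mid) < p:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    z = phi_inv(1.0 - alpha / 2.0)
    ncp = math.sqrt(n_total * r2 * k * (1.0 - k)) * abs(math.log(or_))
    return phi(ncp - z)


def detectable_or_oracle(n_total, k, r2, target_power, alpha=0.05, tol=1e-12):
    """Invert power_binary_oracle by bisection on log-OR."""
    lo, hi = 1e-12, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if power_binary_oracle(n_total, k, r2, math.exp(mid), alpha) < target_power:
            lo = mid
        else:
            hi = mid
    return math.exp((lo + hi) / 2.0)
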