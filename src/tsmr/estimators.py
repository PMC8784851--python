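"""Causal-effect estimators over harmonized instruments.

Four methods: inverse-variance-weighted meta-analysis of per-SNP Wald ratios
(the primary estimator), MR-Egger weighted regression with a free intercept,
the weighted median, and the weighted mode. Each returns an
:class:`MREstimate` carrying the log-odds estimate, SE, odds ratio with 95%
CI, two-sided p and instrument count.

Conventions (switchable where noted): IVW applies multiplicative
random-effects inflation ``sqrt(Q/df)`` only when Q exceeds its degrees of
freedom; Egger p-values and CIs use t(n−2); the bootstrap SEs of the median
and mode estimators are parametric and seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .instruments import HarmonizedInstrument, InstrumentSet

__all__ = [
    "MREstimate",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
    "to_odds_ratio",
]

MODE_GRID_SIZE = 512


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass
class MREstimate:
    """One estimator's output on both log-odds and odds-ratio scales."""

    method: str
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extra: dict = field(default_factory=dict)


def to_odds_ratio(
    beta: float, se: float, df: int | None = None
) -> tuple[float, float, float, float]:
    """(OR, ci_low, ci_high, p): 95% CI and two-sided p, normal or t(df)."""
    if not se > 0:
        raise ValueError("se must be > 0")
    if df is None:
        crit = sps.norm.ppf(0.975)
        p = 2.0 * sps.norm.sf(abs(beta) / se)
    else:
        crit = sps.t.ppf(0.975, df)
        p = 2.0 * sps.t.sf(abs(beta) / se, df)
    return math.exp(beta), math.exp(beta - crit * se), math.exp(beta + crit * se), p


def _make_estimate(
    method: str, beta: float, se: float, n_snp: int, df: int | None = None, **extra
) -> MREstimate:
    or_, lo, hi, p = to_odds_ratio(beta, se, df=df)
    return MREstimate(method, beta, se, or_, lo, hi, p, n_snp, dict(extra))


def wald_ratio(inst: HarmonizedInstrument) -> tuple[float, float]:
    """Per-SNP ratio estimate: (beta_out/beta_exp, se_out/|beta_exp|)."""
    if inst.beta_exp == 0:
        raise ZeroDivisionError(f"{inst.variant_id}: beta_exp is 0, ratio undefined")
    return inst.beta_out / inst.beta_exp, inst.se_out / abs(inst.beta_exp)


def _ratio_arrays(instruments: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    pairs = [wald_ratio(i) for i in instruments]
    b = np.array([p[0] for p in pairs])
    se = np.array([p[1] for p in pairs])
    return b, se


def ivw(
    instruments: InstrumentSet,
    random_effects: str = "multiplicative",
    allow_single: bool = False,
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    ``random_effects``: "multiplicative" scales the fixed-effect SE by
    sqrt(Q/df) when Q > df; "fixed" never inflates.
    """
    n = len(instruments)
    if n < (1 if allow_single else 2):
        raise InsufficientInstrumentsError(f"IVW needs >= 2 instruments, got {n}")
    b, se = _ratio_arrays(instruments)
    w = 1.0 / se**2
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (b - beta) ** 2))
    df = n - 1
    scale = 1.0
    if random_effects == "multiplicative" and df > 0 and q > df:
        scale = math.sqrt(q / df)
    elif random_effects not in ("multiplicative", "fixed"):
        raise ValueError(f"unknown random_effects policy {random_effects!r}")
    return _make_estimate("IVW", beta, se_fixed * scale, n, q=q, q_df=df, se_scale=scale)


def mr_egger(instruments: InstrumentSet) -> MREstimate:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Inputs are re-oriented so every beta_exp >= 0; weights are 1/se_out²; SEs
    use the unscaled covariance times max(1, weighted RSS/(n−2)); p from
    t(n−2). The intercept, its SE and p go into ``extra``.
    """
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {n}")
    x = np.array([i.beta_exp for i in instruments])
    y = np.array([i.beta_out for i in instruments])
    sgn = np.where(x < 0, -1.0, 1.0)
    x, y = x * sgn, y * sgn
    w = np.array([1.0 / i.se_out**2 for i in instruments])

    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    rss_w = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss_w / (n - 2))
    cov = np.linalg.inv(xtwx) * sigma2
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(math.sqrt(cov[0, 0])), float(math.sqrt(cov[1, 1]))
    p_int = float(2.0 * sps.t.sf(abs(intercept) / se_int, n - 2)) if se_int > 0 else float("nan")
    return _make_estimate(
        "MR_Egger",
        slope,
        se_slope,
        n,
        df=n - 2,
        intercept=intercept,
        intercept_se=se_int,
        intercept_p=p_int,
        residual_scale=sigma2,
    )


def _weighted_median_core(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weight midpoints vs 0.5."""
    order = np.argsort(b, kind="stable")
    b, w = b[order], w[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2.0
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    return float(np.interp(0.5, s, b))


def _parametric_bootstrap(
    instruments: InstrumentSet,
    statistic,
    n_boot: int,
    seed: int,
) -> float:
    """SD of ``statistic(ratios, weights)`` over parametric redraws of betas."""
    rng = np.random.default_rng(seed)
    bx = np.array([i.beta_exp for i in instruments])
    sx = np.array([i.se_exp for i in instruments])
    by = np.array([i.beta_out for i in instruments])
    sy = np.array([i.se_out for i in instruments])
    n = len(bx)
    bx_r = bx + sx * rng.standard_normal((n_boot, n))
    by_r = by + sy * rng.standard_normal((n_boot, n))
    bx_r = np.where(bx_r == 0, np.finfo(float).tiny, bx_r)
    ratios = by_r / bx_r
    ses = sy / np.abs(bx_r)
    w = 1.0 / ses**2
    est = np.array([statistic(ratios[k], w[k]) for k in range(n_boot)])
    return float(np.std(est, ddof=1))


def weighted_median(
    instruments: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimator; SE by seeded parametric bootstrap."""
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {n}")
    b, se = _ratio_arrays(instruments)
    w = 1.0 / se**2
    beta = _weighted_median_core(b, w)
    se_boot = _parametric_bootstrap(instruments, _weighted_median_core, n_boot, seed)
    return _make_estimate("weighted_median", beta, se_boot, n, n_boot=n_boot)


def _silverman_bandwidth(b: np.ndarray, factor: float) -> float:
    n = len(b)
    sd = float(np.std(b, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(b, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.349) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    return factor * 0.9 * spread * n ** (-0.2)


def _weighted_mode_core(
    b: np.ndarray, w: np.ndarray, bandwidth_factor: float = 1.0
) -> float:
    h = _silverman_bandwidth(b, bandwidth_factor)
    if h <= 0:  # degenerate: all ratios identical
        return float(b[0])
    grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, MODE_GRID_SIZE)
    wn = w / w.sum()
    # density(g) = sum_j w'_j phi((g - b_j)/h)
    z = (grid[:, None] - b[None, :]) / h
    dens = np.exp(-0.5 * z**2) @ wn
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    instruments: InstrumentSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode estimator (normal-kernel density argmax over ratios)."""
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be > 0")
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs >= 3 instruments, got {n}")
    b, se = _ratio_arrays(instruments)
    w = 1.0 / se**2
    beta = _weighted_mode_core(b, w, bandwidth_factor)
    se_boot = _parametric_bootstrap(
        instruments,
        lambda bb, ww: _weighted_mode_core(bb, ww, bandwidth_factor),
        n_boot,
        seed,
    )
    return _make_estimate(
        "weighted_mode", beta, se_boot, n, n_boot=n_boot, bandwidth_factor=bandwidth_factor
    )
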