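"""Heterogeneity and pleiotropy diagnostics.

Cochran Q over Wald ratios, the Egger intercept test, a resampling-based
residual-sum-of-squares outlier test (global / per-SNP outlier / distortion),
leave-one-out re-estimation, and tidy data tables for scatter, funnel and
forest plots.

Seed-stream contract for the resampling test: a single
``numpy.random.default_rng(seed)`` generator supplies the whole
``(n_sim, n_snp)`` noise matrix in one call, so the result does not depend on
iteration order; the distortion test draws from a second generator spawned
from ``SeedSequence(seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import InsufficientInstrumentsError, MREstimate, ivw, mr_egger, _ratio_arrays
from .instruments import InstrumentSet

__all__ = [
    "DiagnosticsReport",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "plot_data",
    "run_diagnostics",
]


@dataclass
class PressoResult:
    global_p: float
    global_p_text: str
    outliers: list[tuple[str, float]]
    distortion_p: float | None
    n_sim: int
    rss_obs: float

    @property
    def outlier_ids(self) -> list[str]:
        return [vid for vid, _ in self.outliers]


@dataclass
class DiagnosticsReport:
    q: float
    q_df: int
    q_p: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    presso: PressoResult | None
    loo: pd.DataFrame = field(default_factory=pd.DataFrame)


def cochran_q(
    instruments: InstrumentSet, beta_ref: float | None = None
) -> tuple[float, int, float]:
    """Cochran Q over Wald ratios around ``beta_ref`` (fixed-effect IVW if None)."""
    n = len(instruments)
    if n < 2:
        raise InsufficientInstrumentsError(f"Cochran Q needs >= 2 instruments, got {n}")
    b, se = _ratio_arrays(instruments)
    w = 1.0 / se**2
    if beta_ref is None:
        beta_ref = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta_ref) ** 2))
    df = n - 1
    return q, df, float(sps.chi2.sf(q, df))


def egger_intercept_test(instruments: InstrumentSet) -> tuple[float, float, float]:
    """(intercept, SE, two-sided p from t(n−2)) of the Egger fit."""
    fit = mr_egger(instruments)
    return fit.extra["intercept"], fit.extra["intercept_se"], fit.extra["intercept_p"]


def _origin_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * x * y) / np.sum(w * x * x))


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Through-origin weighted slope excluding each SNP in turn (vectorized)."""
    sxy = np.sum(w * x * y)
    sxx = np.sum(w * x * x)
    return (sxy - w * x * y) / (sxx - w * x * x)


def mr_presso(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Resampling residual-sum-of-squares pleiotropy test.

    Observed statistic: for each SNP j the weighted squared residual of its
    outcome effect around the leave-one-out through-origin fit,
    w_j (b_out,j − beta(−j)·b_exp,j)² with w_j = 1/se_out,j²; the global RSS
    is their sum. The null distribution redraws outcome betas around their
    leave-one-out fitted values with their own SEs, ``n_sim`` times, and the
    RSS is recomputed with fresh leave-one-out fits per replicate.

    Per-SNP outlier p-values are empirical tail proportions Bonferroni-scaled
    by n_snp; the distortion test compares the all-SNP slope with the
    outlier-removed slope against random same-size inlier removals. Empirical
    p of exactly 0 is stored as 1/(2·n_sim) and printed "< 1/n_sim".
    """
    n = len(instruments)
    if n < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {n}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    x = np.array([i.beta_exp for i in instruments])
    y = np.array([i.beta_out for i in instruments])
    sy = np.array([i.se_out for i in instruments])
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(x, y, w)
    res_obs = w * (y - slopes_loo * x) ** 2
    rss_obs = float(res_obs.sum())

    ss = np.random.SeedSequence(seed)
    child_main, child_dist = ss.spawn(2)
    rng = np.random.default_rng(child_main)
    z = rng.standard_normal((n_sim, n))
    y_sim = slopes_loo * x + sy * z  # broadcast over replicates

    sxy_sim = y_sim @ (w * x)  # (n_sim,)
    sxx = float(np.sum(w * x * x))
    slopes_sim = (sxy_sim[:, None] - (w * x) * y_sim) / (sxx - w * x * x)
    res_sim = w * (y_sim - slopes_sim * x) ** 2
    rss_sim = res_sim.sum(axis=1)

    frac = float(np.mean(rss_sim >= rss_obs))
    if frac == 0.0:
        global_p = 1.0 / (2.0 * n_sim)
        global_text = f"< {1.0 / n_sim:g}"
    else:
        global_p = frac
        global_text = f"{frac:g}"

    outliers: list[tuple[str, float]] = []
    ids = instruments.variant_ids
    tail = np.mean(res_sim >= res_obs, axis=0)
    for j in range(n):
        pj = tail[j] if tail[j] > 0 else 1.0 / (2.0 * n_sim)
        pj_adj = min(1.0, pj * n)
        if pj_adj < outlier_alpha:
            outliers.append((ids[j], float(pj_adj)))

    distortion_p: float | None = None
    if outliers:
        out_idx = np.array([ids.index(v) for v, _ in outliers])
        inlier = np.setdiff1d(np.arange(n), out_idx)
        if len(inlier) >= 2:
            beta_all = _origin_slope(x, y, w)
            beta_in = _origin_slope(x[inlier], y[inlier], w[inlier])
            if beta_in != 0:
                obs_d = (beta_all - beta_in) / abs(beta_in)
                rng_d = np.random.default_rng(child_dist)
                k = min(len(out_idx), len(inlier) - 2)
                sims = np.empty(n_sim)
                for r in range(n_sim):
                    drop = rng_d.choice(inlier, size=k, replace=False)
                    keep = np.setdiff1d(np.arange(n), drop)
                    b_r = _origin_slope(x[keep], y[keep], w[keep])
                    sims[r] = (beta_all - b_r) / abs(b_r) if b_r != 0 else np.inf
                frac_d = float(np.mean(np.abs(sims) >= abs(obs_d)))
                distortion_p = frac_d if frac_d > 0 else 1.0 / (2.0 * n_sim)

    return PressoResult(global_p, global_text, outliers, distortion_p, n_sim, rss_obs)


def leave_one_out(instruments: InstrumentSet, **ivw_kwargs) -> pd.DataFrame:
    """One IVW estimate per dropped SNP; columns variant_id, beta, se, pval."""
    n = len(instruments)
    if n < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 instruments, got {n}")
    rows = []
    for inst in instruments:
        sub = instruments.subset([v for v in instruments.variant_ids if v != inst.variant_id])
        est = ivw(sub, **ivw_kwargs)
        rows.append(
            {"variant_id": inst.variant_id, "beta": est.beta, "se": est.se, "pval": est.pval}
        )
    return pd.DataFrame(rows, columns=["variant_id", "beta", "se", "pval"])


def run_diagnostics(
    instruments: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> DiagnosticsReport:
    """Full diagnostics bundle (Q, Egger intercept, resampling test, LOO)."""
    q, q_df, q_p = cochran_q(instruments)
    intercept, se_i, p_i = egger_intercept_test(instruments)
    presso = (
        mr_presso(instruments, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
        if len(instruments) >= 4
        else None
    )
    loo = leave_one_out(instruments)
    return DiagnosticsReport(q, q_df, q_p, intercept, se_i, p_i, presso, loo)


def plot_data(
    instruments: InstrumentSet, estimates: list[MREstimate]
) -> dict[str, pd.DataFrame]:
    """Tidy tables for scatter, funnel and forest plots.

    scatter: per-SNP (beta_exp, beta_out) with SE bars; lines: per-method
    slope (+ Egger intercept); funnel: Wald ratio vs precision with the IVW
    vertical; forest: per-SNP ratios with 95% CIs plus one summary row per
    method.
    """
    if not estimates:
        raise ValueError("estimates must be non-empty")
    b, se = _ratio_arrays(instruments)
    ids = instruments.variant_ids
    scatter = pd.DataFrame(
        {
            "variant_id": ids,
            "beta_exp": [i.beta_exp for i in instruments],
            "se_exp": [i.se_exp for i in instruments],
            "beta_out": [i.beta_out for i in instruments],
            "se_out": [i.se_out for i in instruments],
        }
    )
    lines = pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "slope": [e.beta for e in estimates],
            "intercept": [e.extra.get("intercept", 0.0) for e in estimates],
        }
    )
    ivw_beta = next((e.beta for e in estimates if e.method == "IVW"), float("nan"))
    funnel = pd.DataFrame(
        {"variant_id": ids, "wald_ratio": b, "precision": 1.0 / se, "ivw_beta": ivw_beta}
    )
    zc = sps.norm.ppf(0.975)
    forest = pd.DataFrame(
        {
            "label": ids + [e.method for e in estimates],
            "beta": list(b) + [e.beta for e in estimates],
            "ci_low": list(b - zc * se) + [math.log(e.ci_low) for e in estimates],
            "ci_high": list(b + zc * se) + [math.log(e.ci_high) for e in estimates],
            "is_summary": [False] * len(ids) + [True] * len(estimates),
        }
    )
    return {"scatter": scatter, "lines": lines, "funnel": funnel, "forest": forest}


def render_plots(tables: dict[str, pd.DataFrame], out_dir) -> list[str]:
    """Optional basic renderings of the plot tables as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    sc, ln = tables["scatter"], tables["lines"]
    fig, ax = plt.subplots()
    ax.errorbar(
        sc["beta_exp"], sc["beta_out"], xerr=sc["se_exp"], yerr=sc["se_out"],
        fmt="o", ms=3, lw=0.5, alpha=0.7,
    )
    xs = np.linspace(0, sc["beta_exp"].abs().max(), 50)
    for _, row in ln.iterrows():
        ax.plot(xs, row["intercept"] + row["slope"] * xs, label=row["method"])
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    p = out_dir / "scatter.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(str(p))

    fn = tables["funnel"]
    fig, ax = plt.subplots()
    ax.plot(fn["wald_ratio"], fn["precision"], "o", ms=3)
    ax.axvline(fn["ivw_beta"].iloc[0], color="k", lw=1)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("1 / SE")
    p = out_dir / "funnel.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(str(p))

    fr = tables["forest"]
    fig, ax = plt.subplots(figsize=(5, max(3, 0.12 * len(fr))))
    ypos = np.arange(len(fr))[::-1]
    ax.hlines(ypos, fr["ci_low"], fr["ci_high"], lw=0.8)
    ax.plot(fr["beta"], ypos, "s", ms=3)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_yticks(ypos)
    ax.set_yticklabels(fr["label"], fontsize=5)
    p = out_dir / "forest.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(str(p))
    return written
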