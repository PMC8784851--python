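"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generative model follows the standard instrumental-variable decomposition
for summary data: each SNP j has a true effect on the exposure (gamma_j), an
optional direct (pleiotropic) path to the outcome (alpha_j), and a total
outcome effect Gamma_j = beta_causal * gamma_j + alpha_j. Observed effect
estimates are drawn normally around the truths with per-SNP standard errors
from the binary-trait approximation

    SE = 1 / sqrt(2 * N * f * (1 - f) * K * (1 - K))

where f is the effect-allele frequency and K the case fraction of the study.
Palindromic variants, strand flips, allele swaps, LD blocks and displaced
outliers can be injected to exercise every harmonization and diagnostic path.
Everything is reproducible from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .gwas_io import LDInfo, SummaryStats, VariantAssociation, write_ld, write_summary_stats
from .instruments import COMPLEMENT

__all__ = [
    "Pleiotropy",
    "SimConfig",
    "SimTruth",
    "simulate_two_sample",
    "make_fixture",
    "PRESETS",
]

_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and COMPLEMENT[a] != b
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

INSIDE_SLOPE = 0.5  # coupling of pleiotropy to instrument strength when violated


@dataclass(frozen=True)
class Pleiotropy:
    """Law of the direct SNP→outcome path: none, balanced(sd) or directional(mean, sd)."""

    kind: str = "none"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.kind == "balanced" and self.mean != 0.0:
            raise ValueError("balanced pleiotropy has mean 0 by definition")
        if self.sd < 0:
            raise ValueError("pleiotropy sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    n_snp: int = 150
    n_exp: int = 394_283
    n_out: int = 1_683_768
    k_exp: float = 46_802 / 394_283
    k_out: float = 38_984 / 1_683_768
    beta_causal: float = 0.0
    #: SNP-exposure effect magnitudes are |Normal(gamma_mean, gamma_sd)|;
    #: signs are random unless gamma_sign_random is False.
    gamma_mean: float = 0.055
    gamma_sd: float = 0.015
    gamma_sign_random: bool = True
    pleiotropy: Pleiotropy = Pleiotropy()
    inside_violated: bool = False
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    n_palindromic: int = 0
    #: (index, displacement in outcome SEs) pairs
    outliers: tuple = ()
    #: ((block_size, within_block_r2), ...) over consecutive leading SNPs
    ld_blocks: tuple = ()
    flip_strand_fraction: float = 0.0
    swap_allele_fraction: float = 0.0
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    seed: int = 0

    def validate(self) -> None:
        if self.n_snp <= 0 or self.n_exp <= 0 or self.n_out <= 0:
            raise ValueError("counts must be positive")
        for name in ("k_exp", "k_out"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (0.0 < self.eaf_low < self.eaf_high < 1.0):
            raise ValueError("need 0 < eaf_low < eaf_high < 1")
        if self.n_palindromic < 0 or self.n_palindromic > self.n_snp:
            raise ValueError("n_palindromic out of range")
        for idx, disp in self.outliers:
            if not (0 <= idx < self.n_snp):
                raise ValueError(f"outlier index {idx} out of range")
        if self.gamma_sd == 0.0 and self.n_snp > 1 and self.outliers:
            raise ValueError(
                "degenerate config: zero gamma spread with multiple SNPs and planted outliers"
            )
        total = sum(size for size, _ in self.ld_blocks)
        if total > self.n_snp:
            raise ValueError("ld_blocks cover more SNPs than n_snp")
        for _, r2 in self.ld_blocks:
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"block r2 {r2} outside [0, 1]")
        for frac in (self.flip_strand_fraction, self.swap_allele_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SimTruth:
    """Generating parameters of one synthetic dataset."""

    config: SimConfig
    variant_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    big_gamma: np.ndarray
    eaf: np.ndarray
    r2_true: float

    def __post_init__(self):
        if not np.allclose(
            self.big_gamma, self.config.beta_causal * self.gamma + self.alpha
        ):
            raise ValueError("Gamma identity violated")


def _binary_se(n: int, f: np.ndarray, k: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * f * (1.0 - f) * k * (1.0 - k))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return np.maximum(p, math.ulp(0.0))


def simulate_two_sample(
    config: SimConfig,
) -> tuple[SummaryStats, SummaryStats, SimTruth, LDInfo]:
    """Draw one synthetic exposure/outcome summary-statistics pair."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_snp
    width = max(7, len(str(n)))
    ids = [f"rs{i:0{width}d}" for i in range(1, n + 1)]

    eaf = rng.uniform(config.eaf_low, config.eaf_high, size=n)
    gamma = np.abs(rng.normal(config.gamma_mean, config.gamma_sd, size=n))
    if config.gamma_sign_random:
        gamma *= rng.choice([-1.0, 1.0], size=n)

    pl = config.pleiotropy
    if pl.kind == "none":
        alpha = np.zeros(n)
    else:
        alpha = rng.normal(pl.mean, pl.sd, size=n)
    if config.inside_violated:
        mag = np.abs(gamma)
        alpha = alpha + INSIDE_SLOPE * (mag - mag.mean())
    big_gamma = config.beta_causal * gamma + alpha

    se_exp = _binary_se(config.n_exp, eaf, config.k_exp)
    se_out = _binary_se(config.n_out, eaf, config.k_out)
    beta_exp = gamma + se_exp * rng.standard_normal(n)
    beta_out = big_gamma + se_out * rng.standard_normal(n)
    for idx, disp in config.outliers:
        beta_out[idx] += disp * se_out[idx]

    # allele assignment; palindromic variants occupy rng-chosen positions
    pal_idx = set(
        rng.choice(n, size=config.n_palindromic, replace=False).tolist()
        if config.n_palindromic
        else []
    )
    pairs = []
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if j in pal_idx else _NONPALINDROMIC_PAIRS
        pairs.append(pool[rng.integers(len(pool))])

    flip = rng.random(n) < config.flip_strand_fraction
    swap = rng.random(n) < config.swap_allele_fraction

    exposure = SummaryStats(
        trait_label=config.exposure_label,
        n_cases=int(round(config.k_exp * config.n_exp)),
        n_controls=int(round((1 - config.k_exp) * config.n_exp)),
    )
    outcome = SummaryStats(
        trait_label=config.outcome_label,
        n_cases=int(round(config.k_out * config.n_out)),
        n_controls=int(round((1 - config.k_out) * config.n_out)),
    )
    p_exp = _two_sided_p(beta_exp, se_exp)
    p_out = _two_sided_p(beta_out, se_out)
    for j, vid in enumerate(ids):
        ea, oa = pairs[j]
        exposure.add(
            VariantAssociation(
                vid, ea, oa, float(eaf[j]), float(beta_exp[j]), float(se_exp[j]),
                float(p_exp[j]), config.n_exp, exposure.n_cases, exposure.n_controls,
            )
        )
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(beta_out[j]), float(eaf[j])
        if swap[j]:
            o_ea, o_oa = o_oa, o_ea
            o_beta = -o_beta
            o_eaf = 1.0 - o_eaf
        if flip[j] and j not in pal_idx:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        outcome.add(
            VariantAssociation(
                vid, o_ea, o_oa, o_eaf, o_beta, float(se_out[j]),
                float(p_out[j]), config.n_out, outcome.n_cases, outcome.n_controls,
            )
        )

    ld = LDInfo(panel_label="simulated")
    pos = 0
    for size, r2 in config.ld_blocks:
        block = ids[pos : pos + size]
        for a_i in range(len(block)):
            for b_i in range(a_i + 1, len(block)):
                ld.set_r2(block[a_i], block[b_i], r2)
        pos += size

    r2_true = float(np.sum(gamma**2 / (gamma**2 + se_exp**2 * config.n_exp)))
    truth = SimTruth(config, ids, gamma, alpha, big_gamma, eaf, r2_true)
    return exposure, outcome, truth, ld


# ---------------------------------------------------------------------------
# fixture presets mirroring the study's six exposure-outcome cells

_EXPOSURES = {
    "asthma": dict(
        n_exp=394_283,
        k_exp=46_802 / 394_283,
        n_snp=150,
        gamma_mean=0.055,
        gamma_sd=0.015,
        exposure_label="asthma",
    ),
    "msasthma": dict(
        n_exp=57_695,
        k_exp=10_549 / 57_695,
        n_snp=24,
        gamma_mean=0.13,
        gamma_sd=0.03,
        exposure_label="moderate_to_severe_asthma",
    ),
}

_OUTCOMES = {
    "susceptibility": dict(
        n_out=38_984 + 1_644_784,
        k_out=38_984 / (38_984 + 1_644_784),
        outcome_label="covid19_susceptibility",
    ),
    "hospitalization": dict(
        n_out=9_986 + 1_877_672,
        k_out=9_986 / (9_986 + 1_877_672),
        outcome_label="covid19_hospitalization",
    ),
    "severe": dict(
        n_out=5_101 + 1_383_241,
        k_out=5_101 / (5_101 + 1_383_241),
        outcome_label="covid19_severe",
    ),
}

PRESETS: dict[str, SimConfig] = {}
for _e, _ecfg in _EXPOSURES.items():
    for _o, _ocfg in _OUTCOMES.items():
        PRESETS[f"{_e}_{_o}"] = SimConfig(
            **_ecfg,
            **_ocfg,
            n_palindromic=2,
            ld_blocks=((3, 0.8), (2, 0.5)),
            flip_strand_fraction=0.1,
            swap_allele_fraction=0.2,
        )
# alias: HGI C2 is "any confirmed infection vs population"
PRESETS["asthma_any"] = PRESETS["asthma_susceptibility"]
PRESETS["msasthma_any"] = PRESETS["msasthma_susceptibility"]


def make_fixture(name: str, out_dir: str | Path = ".", seed: int = 0) -> dict[str, Path]:
    """Write a preset's exposure/outcome/LD/truth files; returns their paths."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = replace(PRESETS[name], seed=seed)
    exposure, outcome, truth, ld = simulate_two_sample(config)
    paths = {
        "exposure": out_dir / f"{name}.exposure.tsv",
        "outcome": out_dir / f"{name}.outcome.tsv",
        "ld": out_dir / f"{name}.ld.tsv",
        "truth": out_dir / f"{name}.truth.tsv",
    }
    write_summary_stats(exposure, paths["exposure"])
    write_summary_stats(outcome, paths["outcome"])
    write_ld(ld, paths["ld"])
    with open(paths["truth"], "w") as fh:
        fh.write("variant_id\tgamma\talpha\tGamma\n")
        for vid, g, a, gg in zip(truth.variant_ids, truth.gamma, truth.alpha, truth.big_gamma):
            fh.write(f"{vid}\t{g!r}\t{a!r}\t{gg!r}\n")
    return paths
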