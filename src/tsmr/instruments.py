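"""Instrument selection, proxy lookup, allele harmonization and strength.

Selection is greedy LD clumping: candidates below the significance threshold
are ranked by ascending p (ties broken by variant id) and a candidate is
retained iff its r² with every already-retained variant is below the clump
threshold. Harmonization expresses exposure and outcome effects on a shared
effect allele, resolving allele swaps and strand flips and dropping
palindromic variants with intermediate allele frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .gwas_io import LDInfo, SummaryStats

__all__ = [
    "HarmonizedInstrument",
    "InstrumentSet",
    "ProvenanceRecord",
    "NoInstrumentsError",
    "select_instruments",
    "find_proxy",
    "harmonize",
    "variance_explained",
    "f_statistic",
    "COMPLEMENT",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

WEAK_F_THRESHOLD = 10.0


class NoInstrumentsError(RuntimeError):
    """No variant passed the significance threshold (pipeline must abort)."""


@dataclass
class HarmonizedInstrument:
    """A variant with exposure and outcome effects on the same effect allele.

    ``n_exp`` (exposure-study sample size) is carried so that per-SNP R² and
    F can be computed from the record alone.
    """

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: float | None
    n_exp: int | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.se_exp > 0 and self.se_out > 0):
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")


@dataclass
class ProvenanceRecord:
    variant_id: str
    decision: str  # retained | clumped | proxied | palindrome_dropped | unmatched | removed
    detail: str = ""


@dataclass
class InstrumentSet:
    """Ordered harmonized instruments plus the audit trail of selection."""

    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    provenance: list[ProvenanceRecord] = field(default_factory=list)
    exposure_label: str = ""
    outcome_label: str = ""

    def __len__(self) -> int:
        return len(self.instruments)

    def __iter__(self):
        return iter(self.instruments)

    @property
    def variant_ids(self) -> list[str]:
        return [i.variant_id for i in self.instruments]

    @property
    def f_per_snp(self) -> dict[str, float]:
        out = {}
        for inst in self.instruments:
            r2 = variance_explained(inst)
            if r2 is not None and inst.n_exp:
                out[inst.variant_id] = f_statistic(r2, inst.n_exp)
        return out

    @property
    def f_mean(self) -> float | None:
        fs = self.f_per_snp
        return sum(fs.values()) / len(fs) if fs else None

    @property
    def r2_total(self) -> float:
        """Cumulative variance explained: sum of per-SNP R² where computable."""
        total = 0.0
        n_missing = 0
        for inst in self.instruments:
            r2 = variance_explained(inst)
            if r2 is None:
                n_missing += 1
            else:
                total += r2
        if n_missing:
            warnings.warn(
                f"{n_missing} instrument(s) lack eaf or n; excluded from cumulative R2",
                stacklevel=2,
            )
        return total

    def subset(self, keep_ids) -> "InstrumentSet":
        keep = set(keep_ids)
        return InstrumentSet(
            instruments=[i for i in self.instruments if i.variant_id in keep],
            provenance=list(self.provenance),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
        )


def select_instruments(
    exposure: SummaryStats,
    ld: LDInfo,
    p_threshold: float = 5e-8,
    r2_clump: float = 0.001,
) -> list[str]:
    """Greedy p-value-ranked LD clumping; deterministic given the input.

    Returns variant ids ordered by ascending p (ties broken lexicographically).
    Raises :class:`NoInstrumentsError` if no variant passes ``p_threshold``.
    """
    if not (0 < p_threshold < 1 and 0 < r2_clump < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    candidates = sorted(
        (rec for rec in exposure.records.values() if rec.pval < p_threshold),
        key=lambda r: (r.pval, r.variant_id),
    )
    if not candidates:
        raise NoInstrumentsError(
            f"no variant in {exposure.trait_label!r} with p < {p_threshold}"
        )
    kept: list[str] = []
    for rec in candidates:
        if all(ld.r2(rec.variant_id, k) < r2_clump for k in kept):
            kept.append(rec.variant_id)
    return kept


def find_proxy(
    target: str,
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDInfo,
    r2_min: float = 0.6,
) -> str | None:
    """Best available proxy for ``target``, or None.

    Candidates must be present in both the exposure and outcome tables with
    r²(target, candidate) > ``r2_min``. Ties on r² are broken by smaller
    exposure p-value, then lexicographic id.
    """
    best: tuple[float, float, str] | None = None  # (-r2, p_exp, id)
    for vid in outcome.records:
        if vid == target or vid not in exposure:
            continue
        r2 = ld.r2(target, vid)
        if r2 > r2_min:
            key = (-r2, exposure[vid].pval, vid)
            if best is None or key < best:
                best = key
    return best[2] if best else None


def _is_palindromic_pair(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    instrument_ids: list[str],
    palindrome_maf_limit: float = 0.4,
    proxied: dict[str, str] | None = None,
) -> InstrumentSet:
    """Harmonize exposure and outcome effects onto the exposure effect allele.

    For each instrument: matching alleles are kept as-is; swapped alleles
    negate the outcome beta (``flipped`` flag); strand-complement alleles are
    complemented first and then matched; palindromic variants with exposure
    EAF inside (limit, 1−limit) are dropped; irreconcilable allele sets are
    dropped. Every exclusion is recorded in the provenance trail.

    ``proxied`` maps instrument id -> original target id, for flagging
    proxy-substituted variants.
    """
    lo, hi = palindrome_maf_limit, 1.0 - palindrome_maf_limit
    proxied = proxied or {}
    iset = InstrumentSet(
        exposure_label=exposure.trait_label, outcome_label=outcome.trait_label
    )
    for vid in instrument_ids:
        if vid not in exposure or vid not in outcome:
            iset.provenance.append(
                ProvenanceRecord(vid, "unmatched", "absent from exposure or outcome table")
            )
            continue
        e = exposure[vid]
        o = outcome[vid]
        flags: set[str] = set()
        if vid in proxied:
            flags.add("proxy_used")

        if _is_palindromic_pair(e.effect_allele, e.other_allele):
            flags.add("palindromic")
            if e.eaf is None:
                iset.provenance.append(
                    ProvenanceRecord(vid, "palindrome_dropped", "no exposure EAF to resolve strand")
                )
                continue
            if lo < e.eaf < hi:
                iset.provenance.append(
                    ProvenanceRecord(
                        vid, "palindrome_dropped", f"intermediate EAF {e.eaf:.3g}"
                    )
                )
                continue
            # strand unambiguous enough: align by allele letters
            if o.effect_allele == e.effect_allele and o.other_allele == e.other_allele:
                beta_out = o.beta
            elif o.effect_allele == e.other_allele and o.other_allele == e.effect_allele:
                beta_out = -o.beta
                flags.add("flipped")
            else:
                iset.provenance.append(
                    ProvenanceRecord(
                        vid,
                        "unmatched",
                        f"alleles {e.effect_allele}/{e.other_allele} vs "
                        f"{o.effect_allele}/{o.other_allele}",
                    )
                )
                continue
        else:
            oe, oo = o.effect_allele, o.other_allele
            if {oe, oo} != {e.effect_allele, e.other_allele}:
                ce, co = COMPLEMENT[oe], COMPLEMENT[oo]
                if {ce, co} == {e.effect_allele, e.other_allele}:
                    oe, oo = ce, co
                else:
                    iset.provenance.append(
                        ProvenanceRecord(
                            vid,
                            "unmatched",
                            f"alleles {e.effect_allele}/{e.other_allele} vs {oe}/{oo}",
                        )
                    )
                    continue
            if oe == e.effect_allele and oo == e.other_allele:
                beta_out = o.beta
            else:  # swapped
                beta_out = -o.beta
                flags.add("flipped")

        iset.instruments.append(
            HarmonizedInstrument(
                variant_id=vid,
                beta_exp=e.beta,
                se_exp=e.se,
                beta_out=beta_out,
                se_out=o.se,
                eaf=e.eaf,
                n_exp=e.n_total,
                flags=frozenset(flags),
            )
        )
        detail = "flags=" + ",".join(sorted(flags)) if flags else ""
        iset.provenance.append(ProvenanceRecord(vid, "retained", detail))
    return iset


def variance_explained(inst: HarmonizedInstrument) -> float | None:
    """Per-SNP proportion of exposure variance explained.

    R² = 2β²f(1−f) / (2β²f(1−f) + 2·se²·N·f(1−f)). Returns None when the
    effect-allele frequency or sample size is unavailable.
    """
    if inst.eaf is None or not inst.n_exp:
        return None
    f = inst.eaf
    num = 2.0 * inst.beta_exp**2 * f * (1.0 - f)
    den = num + 2.0 * inst.se_exp**2 * inst.n_exp * f * (1.0 - f)
    if den == 0.0:
        return 0.0
    return num / den


def f_statistic(r2: float, n: int) -> float:
    """Instrument-strength F = R² × (N − 2) / (1 − R²)."""
    if not (0.0 <= r2 < 1.0):
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    return r2 * (n - 2) / (1.0 - r2)


def is_weak(f: float) -> bool:
    """Conventional weak-instrument flag: F ≤ 10."""
    return f <= WEAK_F_THRESHOLD
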