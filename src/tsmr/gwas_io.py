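"""Reading, validating and writing GWAS summary-statistics tables and LD info.

The canonical on-disk format is a delimited text table (TSV by default, CSV
accepted) with header columns::

    variant_id  effect_allele  other_allele  eaf  beta  se  pval  n_total
    [n_cases  n_controls]

Missing optional values are written as ``NA``. Floats are serialized with
``repr`` so that a write → read → write cycle is byte-identical from the
second write onward.

Pairwise LD is a three-column delimited file ``id1  id2  r2``; the mapping is
symmetric, ``r2(v, v) = 1`` by convention and absent pairs are treated as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "VariantAssociation",
    "SummaryStats",
    "LDInfo",
    "DIALECTS",
    "CANONICAL_COLUMNS",
    "SummaryStatsError",
    "RowValidationError",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld",
    "write_ld",
]

VALID_ALLELES = frozenset("ACGT")

CANONICAL_COLUMNS = (
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n_total",
    "n_cases",
    "n_controls",
)

MANDATORY_COLUMNS = CANONICAL_COLUMNS[:8]

#: Named column dialects: canonical name -> source column name.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    # COVID-19 Host Genetics Initiative release-5 meta-analysis layout.
    "covid_hgi_r5": {
        "variant_id": "rsid",
        "effect_allele": "ALT",
        "other_allele": "REF",
        "eaf": "all_meta_AF",
        "beta": "all_inv_var_meta_beta",
        "se": "all_inv_var_meta_sebeta",
        "pval": "all_inv_var_meta_p",
        "n_total": "all_meta_sample_N",
        "n_cases": "all_inv_var_meta_cases",
        "n_controls": "all_inv_var_meta_controls",
    },
}

_TINY_P = math.ulp(0.0)  # smallest positive subnormal float


class SummaryStatsError(ValueError):
    """Configuration-level failure: missing file, missing mandatory column."""


class RowValidationError(ValueError):
    """Raised in strict mode when one or more rows violate record invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        preview = "; ".join(problems[:5])
        more = "" if len(problems) <= 5 else f" (+{len(problems) - 5} more)"
        super().__init__(f"{len(problems)} invalid row(s): {preview}{more}")


@dataclass
class VariantAssociation:
    """One variant's association record in one GWAS."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n_total: int
    n_cases: int | None = None
    n_controls: int | None = None

    def problems(self) -> list[str]:
        """Return invariant violations (empty list means the record is valid)."""
        out: list[str] = []
        if not self.variant_id:
            out.append("empty variant_id")
        if self.effect_allele not in VALID_ALLELES:
            out.append(f"effect_allele {self.effect_allele!r} not in A/C/G/T")
        if self.other_allele not in VALID_ALLELES:
            out.append(f"other_allele {self.other_allele!r} not in A/C/G/T")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele == other_allele")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            out.append(f"eaf {self.eaf} outside [0, 1]")
        if not (self.se > 0):
            out.append(f"se {self.se} not > 0")
        if not (0.0 < self.pval <= 1.0):
            out.append(f"pval {self.pval} outside (0, 1]")
        if not (self.n_total > 0):
            out.append(f"n_total {self.n_total} not > 0")
        return out

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryStats:
    """A GWAS summary-statistics table keyed by variant id."""

    trait_label: str
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    ancestry: str = ""
    n_cases: int | None = None
    n_controls: int | None = None
    #: per-row validation messages collected by the reader (lenient mode)
    validation_log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def __getitem__(self, variant_id: str) -> VariantAssociation:
        return self.records[variant_id]

    def add(self, rec: VariantAssociation) -> None:
        if rec.variant_id in self.records:
            raise SummaryStatsError(f"duplicate variant_id {rec.variant_id!r}")
        self.records[rec.variant_id] = rec

    @property
    def variant_ids(self) -> list[str]:
        return list(self.records)


@dataclass
class LDInfo:
    """Symmetric pairwise r² lookup. Absent pairs are treated as r² = 0."""

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    panel_label: str = ""

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 {r2} outside [0, 1] for pair ({a}, {b})")
        if a == b:
            if r2 != 1.0:
                raise ValueError(f"r2({a}, {a}) must be 1, got {r2}")
            return
        self.pairs[self._key(a, b)] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b), 0.0)


# ---------------------------------------------------------------------------
# parsing helpers


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        if math.isnan(x):
            return "NA"
        return repr(x)
    return str(x)


def _parse_float(tok: str) -> float | None:
    tok = tok.strip()
    if tok in ("", "NA", "NaN", "nan", "."):
        return None
    return float(tok)


def _parse_int(tok: str) -> int | None:
    v = _parse_float(tok)
    if v is None:
        return None
    return int(round(v))


def _sniff_sep(header_line: str, path: Path) -> str:
    if "\t" in header_line:
        return "\t"
    if "," in header_line:
        return ","
    if path.suffix.lower() == ".csv":
        return ","
    return "\t"


def read_summary_stats(
    path: str | Path,
    dialect: str | Mapping[str, str] = "canonical",
    *,
    trait_label: str | None = None,
    strict: bool = True,
    sep: str | None = None,
) -> SummaryStats:
    """Read a summary-statistics table into a validated :class:`SummaryStats`.

    Parameters
    ----------
    path:
        Delimited text file (TSV or CSV; the delimiter is sniffed from the
        header unless ``sep`` is given).
    dialect:
        Name of a preset in :data:`DIALECTS` or an explicit mapping from
        canonical column names to the file's column names.
    strict:
        If True (default), any row violating the record invariants raises
        :class:`RowValidationError` listing every offending row. If False,
        offending rows are dropped and reported in ``stats.validation_log``.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryStatsError(f"no such file: {path}")
    colmap = dict(DIALECTS[dialect]) if isinstance(dialect, str) else dict(dialect)

    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SummaryStatsError(f"empty file: {path}")
    use_sep = sep or _sniff_sep(lines[0], path)
    header = lines[0].split(use_sep)
    index: dict[str, int] = {}
    for canon in CANONICAL_COLUMNS:
        src = colmap.get(canon, canon)
        if src in header:
            index[canon] = header.index(src)
    missing = [c for c in MANDATORY_COLUMNS if c not in index]
    if missing:
        raise SummaryStatsError(
            f"{path}: mandatory column(s) missing: {missing} "
            f"(header was {header})"
        )

    stats = SummaryStats(trait_label=trait_label or path.stem)
    problems: list[str] = []
    clamped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        toks = line.split(use_sep)

        def tok(canon: str) -> str:
            i = index.get(canon)
            return toks[i] if i is not None and i < len(toks) else ""

        try:
            pval = _parse_float(tok("pval"))
            if pval == 0.0:
                pval = _TINY_P
                clamped += 1
            rec = VariantAssociation(
                variant_id=tok("variant_id").strip(),
                effect_allele=tok("effect_allele").strip().upper(),
                other_allele=tok("other_allele").strip().upper(),
                eaf=_parse_float(tok("eaf")),
                beta=_parse_float(tok("beta")),
                se=_parse_float(tok("se")),
                pval=pval,
                n_total=_parse_int(tok("n_total")),
                n_cases=_parse_int(tok("n_cases")),
                n_controls=_parse_int(tok("n_controls")),
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"line {lineno}: unparseable ({exc})")
            continue
        if rec.beta is None or rec.se is None or rec.pval is None or rec.n_total is None:
            problems.append(f"line {lineno} ({rec.variant_id}): missing mandatory value")
            continue
        row_problems = rec.problems()
        if rec.variant_id in stats.records:
            row_problems.append("duplicate variant_id")
        if row_problems:
            problems.append(f"line {lineno} ({rec.variant_id}): " + "; ".join(row_problems))
            continue
        stats.records[rec.variant_id] = rec

    if clamped:
        warnings.warn(
            f"{path}: {clamped} zero p-value(s) clamped to {_TINY_P!r}",
            stacklevel=2,
        )
    if problems:
        if strict:
            raise RowValidationError(problems)
        stats.validation_log.extend(problems)
    return stats


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write ``stats`` as a canonical tab-delimited table (header always present)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for rec in stats.records.values():
            fh.write(
                "\t".join(
                    _fmt(v)
                    for v in (
                        rec.variant_id,
                        rec.effect_allele,
                        rec.other_allele,
                        rec.eaf,
                        rec.beta,
                        rec.se,
                        rec.pval,
                        rec.n_total,
                        rec.n_cases,
                        rec.n_controls,
                    )
                )
                + "\n"
            )


def read_ld(path: str | Path, panel_label: str = "") -> LDInfo:
    """Read a three-column (id1, id2, r2) delimited file into :class:`LDInfo`."""
    path = Path(path)
    if not path.exists():
        raise SummaryStatsError(f"no such file: {path}")
    ld = LDInfo(panel_label=panel_label or path.stem)
    with open(path, newline="") as fh:
        lines = fh.read().splitlines()
    if not lines:
        return ld
    use_sep = _sniff_sep(lines[0], path)
    body = lines
    first = lines[0].split(use_sep)
    if len(first) >= 3 and first[2].strip().lower() in ("r2", "r^2", "rsq"):
        body = lines[1:]
    for lineno, line in enumerate(body, start=1 + (len(body) != len(lines))):
        if not line.strip():
            continue
        toks = line.split(use_sep)
        if len(toks) < 3:
            raise SummaryStatsError(f"{path} line {lineno}: expected 3 columns")
        a, b, r2_tok = toks[0].strip(), toks[1].strip(), toks[2]
        r2 = _parse_float(r2_tok)
        if r2 is None or not (0.0 <= r2 <= 1.0):
            raise SummaryStatsError(f"{path} line {lineno}: r2 {r2_tok!r} outside [0, 1]")
        ld.set_r2(a, b, r2)
    return ld


def write_ld(ld: LDInfo, path: str | Path) -> None:
    """Write pairwise LD as a three-column TSV with header."""
    with open(path, "w", newline="") as fh:
        fh.write("id1\tid2\tr2\n")
        for (a, b), r2 in ld.pairs.items():
            fh.write(f"{a}\t{b}\t{_fmt(r2)}\n")
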