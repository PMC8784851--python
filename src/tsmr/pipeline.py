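"""Config-driven orchestration: selection → harmonization → estimation →
diagnostics → power, with provenance and deterministic report files.

The report bundle mirrors the two headline tables of a two-sample MR study:
``estimates.tsv`` (one row per exposure–outcome–method) and
``diagnostics.tsv`` (Q, global resampling p, Egger intercept), plus outlier,
leave-one-out, provenance, power and plot-data files and a ``run.log`` that
echoes the config. Outputs contain no timestamps, so two runs of the same
config are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diagnostics import plot_data, run_diagnostics
from .estimators import ivw, mr_egger, weighted_median, weighted_mode
from .gwas_io import SummaryStats, read_ld, read_summary_stats
from .instruments import InstrumentSet, find_proxy, harmonize, select_instruments
from .power import PowerQuery, detectable_or, mr_power_binary

__all__ = ["AnalysisConfig", "OutcomeSpec", "ReportBundle", "run_analysis", "load_config"]

ALL_METHODS = ("IVW", "weighted_median", "weighted_mode", "MR_Egger")

ESTIMATE_COLUMNS = [
    "exposure", "outcome", "method", "nsnp", "beta", "se", "or",
    "ci_low", "ci_high", "pval",
]


@dataclass
class OutcomeSpec:
    label: str
    path: str
    dialect: str = "canonical"
    n_cases: int | None = None
    n_controls: int | None = None


@dataclass
class AnalysisConfig:
    exposure_label: str
    exposure_path: str
    outcomes: list[OutcomeSpec]
    ld_path: str | None = None
    exposure_dialect: str = "canonical"
    p_threshold: float = 5e-8
    r2_clump: float = 0.001
    r2_proxy: float = 0.6
    palindrome_maf_limit: float = 0.4
    methods: tuple = ALL_METHODS
    n_boot: int = 1000
    presso_n_sim: int = 1000
    outlier_alpha: float = 0.05
    target_power: float = 0.8
    alpha: float = 0.05
    bonferroni: bool = False
    seed: int | None = None
    out_dir: str = "tsmr_out"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        for name in ("p_threshold", "r2_clump", "r2_proxy", "alpha", "target_power"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if not (0.0 < self.palindrome_maf_limit < 0.5):
            raise ValueError("palindrome_maf_limit must lie in (0, 0.5)")
        bad = [m for m in self.methods if m not in ALL_METHODS]
        if bad:
            raise ValueError(f"unknown method(s) {bad}; choose from {ALL_METHODS}")
        if not self.outcomes:
            raise ValueError("at least one outcome is required")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a flat YAML config file into an :class:`AnalysisConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    exposure = raw.pop("exposure")
    outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes")]
    cfg = AnalysisConfig(
        exposure_label=exposure["label"],
        exposure_path=exposure["path"],
        exposure_dialect=exposure.get("dialect", "canonical"),
        outcomes=outcomes,
        **raw,
    )
    cfg.validate()
    return cfg


@dataclass
class ReportBundle:
    estimates: pd.DataFrame
    diagnostics: pd.DataFrame
    outliers: pd.DataFrame
    loo: pd.DataFrame
    provenance: pd.DataFrame
    power: pd.DataFrame
    instrument_sets: dict[str, InstrumentSet] = field(default_factory=dict)
    out_dir: Path | None = None


def _estimate_row(exposure: str, outcome: str, est) -> dict:
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": est.method,
        "nsnp": est.n_snp,
        "beta": est.beta,
        "se": est.se,
        "or": est.or_,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pval,
    }


def _study_counts(spec: OutcomeSpec, stats: SummaryStats) -> tuple[int | None, int | None]:
    cases, controls = spec.n_cases, spec.n_controls
    if cases is None or controls is None:
        for rec in stats.records.values():
            cases = cases if cases is not None else rec.n_cases
            controls = controls if controls is not None else rec.n_controls
            if cases is not None and controls is not None:
                break
    return cases, controls


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full pipeline for every exposure–outcome pair in the config."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"tsmr {__version__}"]
    import numpy, scipy

    log_lines.append(f"numpy {numpy.__version__}, scipy {scipy.__version__}, pandas {pd.__version__}")
    log_lines.append("config:")
    log_lines.extend("  " + ln for ln in yaml.safe_dump(_config_dict(config)).splitlines())

    exposure = read_summary_stats(
        config.exposure_path, config.exposure_dialect, trait_label=config.exposure_label
    )
    ld = read_ld(config.ld_path) if config.ld_path else _empty_ld()
    selected = select_instruments(exposure, ld, config.p_threshold, config.r2_clump)
    log_lines.append(
        f"exposure {config.exposure_label}: {len(exposure)} variants, "
        f"{len(selected)} selected at p<{config.p_threshold:g}, r2<{config.r2_clump:g}"
    )

    est_rows, diag_rows, out_rows, loo_rows, prov_rows, power_rows = [], [], [], [], [], []
    isets: dict[str, InstrumentSet] = {}
    n_tests = len(config.outcomes) * len(config.methods)

    for spec in config.outcomes:
        outcome = read_summary_stats(spec.path, spec.dialect, trait_label=spec.label)
        ids, proxied = [], {}
        for vid in selected:
            if vid in outcome:
                ids.append(vid)
            else:
                proxy = find_proxy(vid, exposure, outcome, ld, config.r2_proxy)
                if proxy is None:
                    prov_rows.append(
                        {"exposure": config.exposure_label, "outcome": spec.label,
                         "variant_id": vid, "decision": "removed", "detail": "no proxy found"}
                    )
                elif proxy in ids:
                    prov_rows.append(
                        {"exposure": config.exposure_label, "outcome": spec.label,
                         "variant_id": vid, "decision": "removed",
                         "detail": f"proxy {proxy} already an instrument"}
                    )
                else:
                    ids.append(proxy)
                    proxied[proxy] = vid
                    prov_rows.append(
                        {"exposure": config.exposure_label, "outcome": spec.label,
                         "variant_id": vid, "decision": "proxied",
                         "detail": f"proxy {proxy}, r2={ld.r2(vid, proxy):g}"}
                    )
        iset = harmonize(exposure, outcome, ids, config.palindrome_maf_limit, proxied)
        for rec in iset.provenance:
            prov_rows.append(
                {"exposure": config.exposure_label, "outcome": spec.label,
                 "variant_id": rec.variant_id, "decision": rec.decision, "detail": rec.detail}
            )
        if len(iset) == 0:
            _write_provenance(prov_rows, out_dir)
            raise RuntimeError(
                f"empty instrument set after harmonization for outcome {spec.label!r}; "
                f"see {out_dir / 'provenance.tsv'}"
            )
        isets[spec.label] = iset
        log_lines.append(f"outcome {spec.label}: {len(iset)} harmonized instruments")

        estimates = []
        for method in config.methods:
            if method == "IVW":
                est = ivw(iset, allow_single=True)
                if len(iset) == 1:
                    est.method = "Wald_ratio"
            elif method == "MR_Egger":
                est = mr_egger(iset)
            elif method == "weighted_median":
                est = weighted_median(iset, n_boot=config.n_boot, seed=config.seed)
            else:
                est = weighted_mode(iset, n_boot=config.n_boot, seed=config.seed)
            estimates.append(est)
            est_rows.append(_estimate_row(config.exposure_label, spec.label, est))

        diag = run_diagnostics(
            iset, n_sim=config.presso_n_sim, seed=config.seed,
            outlier_alpha=config.outlier_alpha,
        )
        diag_rows.append(
            {"exposure": config.exposure_label, "outcome": spec.label,
             "Q": diag.q, "Q_df": diag.q_df, "Q_p": diag.q_p,
             "presso_global_p": diag.presso.global_p if diag.presso else None,
             "presso_global_p_text": diag.presso.global_p_text if diag.presso else "",
             "presso_distortion_p": diag.presso.distortion_p if diag.presso else None,
             "egger_intercept": diag.egger_intercept,
             "egger_intercept_p": diag.egger_intercept_p}
        )
        if diag.presso:
            for vid, p_out in diag.presso.outliers:
                out_rows.append(
                    {"exposure": config.exposure_label, "outcome": spec.label,
                     "variant_id": vid, "outlier_p": p_out}
                )
            if diag.presso.outliers:
                keep = [v for v in iset.variant_ids if v not in diag.presso.outlier_ids]
                est2 = ivw(iset.subset(keep), allow_single=True)
                est2.method = "IVW_outlier_removed"
                estimates.append(est2)
                est_rows.append(_estimate_row(config.exposure_label, spec.label, est2))
        for _, row in diag.loo.iterrows():
            loo_rows.append(
                {"exposure": config.exposure_label, "outcome": spec.label, **row.to_dict()}
            )

        cases, controls = _study_counts(spec, outcome)
        if cases is not None and controls is not None:
            n_total = cases + controls
            q = PowerQuery(
                n_total=n_total, k=cases / n_total, r2=iset.r2_total,
                alpha=config.alpha, target_power=config.target_power,
            )
            det = detectable_or(q)
            power_rows.append(
                {"exposure": config.exposure_label, "outcome": spec.label,
                 "n_total": n_total, "n_cases": cases, "k": cases / n_total,
                 "r2": iset.r2_total, "alpha": config.alpha,
                 "target_power": config.target_power, "detectable_or": det,
                 "power_at_detectable_or": mr_power_binary(
                     PowerQuery(n_total=n_total, k=cases / n_total, r2=iset.r2_total,
                                or_=det, alpha=config.alpha)
                 )}
            )

        tables = plot_data(iset, estimates)
        for kind, df in tables.items():
            df.to_csv(out_dir / f"{spec.label}.{kind}.tsv", sep="\t", index=False)

    if config.bonferroni:
        for row in est_rows:
            row["pval_bonferroni"] = min(1.0, row["pval"] * n_tests)

    bundle = ReportBundle(
        estimates=pd.DataFrame(est_rows),
        diagnostics=pd.DataFrame(diag_rows),
        outliers=pd.DataFrame(out_rows, columns=["exposure", "outcome", "variant_id", "outlier_p"]),
        loo=pd.DataFrame(loo_rows, columns=["exposure", "outcome", "variant_id", "beta", "se", "pval"]),
        provenance=pd.DataFrame(prov_rows, columns=["exposure", "outcome", "variant_id", "decision", "detail"]),
        power=pd.DataFrame(power_rows),
        instrument_sets=isets,
        out_dir=out_dir,
    )
    bundle.estimates.to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
    bundle.diagnostics.to_csv(out_dir / "diagnostics.tsv", sep="\t", index=False)
    bundle.outliers.to_csv(out_dir / "outliers.tsv", sep="\t", index=False)
    bundle.loo.to_csv(out_dir / "loo.tsv", sep="\t", index=False)
    _write_provenance(prov_rows, out_dir)
    bundle.power.to_csv(out_dir / "power.tsv", sep="\t", index=False)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return bundle


def _write_provenance(prov_rows: list[dict], out_dir: Path) -> None:
    pd.DataFrame(
        prov_rows, columns=["exposure", "outcome", "variant_id", "decision", "detail"]
    ).to_csv(out_dir / "provenance.tsv", sep="\t", index=False)


def _empty_ld():
    from .gwas_io import LDInfo

    return LDInfo(panel_label="none")


def _config_dict(config: AnalysisConfig) -> dict:
    d = {
        "exposure": {
            "label": config.exposure_label,
            "path": config.exposure_path,
            "dialect": config.exposure_dialect,
        },
        "outcomes": [
            {"label": o.label, "path": o.path, "dialect": o.dialect,
             "n_cases": o.n_cases, "n_controls": o.n_controls}
            for o in config.outcomes
        ],
    }
    for k in (
        "ld_path", "p_threshold", "r2_clump", "r2_proxy", "palindrome_maf_limit",
        "n_boot", "presso_n_sim", "outlier_alpha", "target_power", "alpha",
        "bonferroni", "seed",
    ):  # out_dir deliberately not echoed: reports stay byte-identical wherever written
        d[k] = getattr(config, k)
    d["methods"] = list(config.methods)
    return d
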