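"""Config-driven end-to-end two-sample MR analysis.

Fixed stage order: p-value screen -> LD clumping -> harmonization ->
weak-instrument (F) filter -> confounder blocklist -> estimation ->
sensitivity diagnostics -> directionality test.  Every stage's removals
are tallied in a QC ledger whose counts sum exactly to the extracted
instrument count, and per-SNP dispositions go to a sidecar file so the
accounting can be audited.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import estimators, sensitivity
from .harmonize import HarmonizedInstrument, HarmonizeLog, harmonize_datasets
from .instruments import (
    ClumpSpec,
    apply_blocklist,
    greedy_clump,
    select_by_pvalue,
)
from .steiger import SteigerResult, steiger_test
from .sumstats import (
    LDTable,
    SummaryDataset,
    dedup_records,
    read_blocklist,
    read_ld_table,
    read_sumstats,
)

__version__ = "0.1.0"

#: instrument minima per method
_METHOD_MIN = {"ivw_fe": 1, "ivw_re": 2, "egger": 3, "weighted_median": 3}
DEFAULT_METHODS = ("ivw_fe", "ivw_re", "egger", "weighted_median")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one exposure-outcome analysis."""

    exposure_path: str
    outcome_path: str
    seed: int
    out_dir: str | None = None
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    exposure_trait_type: str = "binary"
    outcome_trait_type: str = "binary"
    exposure_n: float | None = None
    outcome_n: float | None = None
    clump: ClumpSpec = field(default_factory=ClumpSpec)
    f_min: float = 10.0
    palindrome_policy: str = "remove"
    blocklist_path: str | None = None
    ld_path: str | None = None
    methods: Sequence[str] = DEFAULT_METHODS
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("clump"), Mapping):
            raw["clump"] = ClumpSpec(**raw["clump"])
        return cls(**raw)

    def digest(self) -> str:
        payload = asdict(self)
        payload["methods"] = list(self.methods)
        payload.pop("out_dir", None)  # hash the analysis, not where it is written
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class QCCounts:
    """Instrument accounting across the pipeline stages."""

    significant: int = 0
    extracted: int = 0  # post-clump instrument count
    lost_at_outcome: int = 0
    palindromic_removed: int = 0
    incompatible_removed: int = 0
    weak_removed: int = 0
    blocklist_removed: int = 0
    final: int = 0

    def conserved(self) -> bool:
        return self.final == (
            self.extracted
            - self.lost_at_outcome
            - self.palindromic_removed
            - self.incompatible_removed
            - self.weak_removed
            - self.blocklist_removed
        )


@dataclass
class RunReport:
    """Outputs and provenance of one pipeline run."""

    qc: QCCounts
    results: dict  # method -> MRResult, or "skipped: ..." string
    sensitivity: sensitivity.SensitivityReport | None
    steiger: SteigerResult | None
    instruments: list[HarmonizedInstrument]
    harmonize_log: HarmonizeLog | None
    dispositions: dict  # snp_id -> final disposition string
    config_hash: str = ""
    seed: int = 0
    version: str = __version__


def _filter_weak_instruments(
    insts: list[HarmonizedInstrument], f_min: float
) -> tuple[list[HarmonizedInstrument], list[str]]:
    kept, dropped = [], []
    for inst in insts:
        (kept if inst.f_stat >= f_min else dropped).append(inst)
    return kept, [i.snp_id for i in dropped] if dropped else []


def run_analysis(config: AnalysisConfig) -> RunReport:
    """Execute the full analysis described by ``config``."""
    exposure, _ = read_sumstats(
        config.exposure_path,
        column_map=config.exposure_columns,
        trait_type=config.exposure_trait_type,
        trait_label=config.exposure_label,
        n_default=config.exposure_n,
    )
    outcome, _ = read_sumstats(
        config.outcome_path,
        column_map=config.outcome_columns,
        trait_type=config.outcome_trait_type,
        trait_label=config.outcome_label,
        n_default=config.outcome_n,
    )
    exposure = dedup_records(exposure)
    outcome = dedup_records(outcome)

    dispositions: dict[str, str] = {}

    significant = select_by_pvalue(exposure, config.clump.p_threshold)
    for rec in exposure.records:
        if rec.snp_id not in {r.snp_id for r in significant.records}:
            dispositions[rec.snp_id] = "dropped_pvalue"

    ld = read_ld_table(config.ld_path)[0] if config.ld_path else LDTable()
    clumped, clump_log = greedy_clump(significant, ld, config.clump)
    dispositions.update({s: d for s, d in clump_log.dispositions.items() if d != "retained"})

    insts, harm_log = harmonize_datasets(clumped, outcome, policy=config.palindrome_policy)
    for s in harm_log.lost_at_outcome:
        dispositions[s] = "lost_at_outcome"
    for s in harm_log.removed_palindromic:
        dispositions[s] = "removed_palindromic"
    for s in harm_log.removed_incompatible:
        dispositions[s] = "removed_incompatible"

    insts, weak_ids = _filter_weak_instruments(insts, config.f_min)
    for s in weak_ids:
        dispositions[s] = "dropped_weak_F"

    blocklist = read_blocklist(config.blocklist_path) if config.blocklist_path else set()
    blocked = [i for i in insts if i.snp_id in blocklist]
    insts = [i for i in insts if i.snp_id not in blocklist]
    for inst in blocked:
        dispositions[inst.snp_id] = "dropped_blocklist"
    for inst in insts:
        dispositions[inst.snp_id] = "retained"

    qc = QCCounts(
        significant=len(significant),
        extracted=len(clumped),
        lost_at_outcome=len(harm_log.lost_at_outcome),
        palindromic_removed=len(harm_log.removed_palindromic),
        incompatible_removed=len(harm_log.removed_incompatible),
        weak_removed=len(weak_ids),
        blocklist_removed=len(blocked),
        final=len(insts),
    )

    results: dict[str, object] = {}
    for method in config.methods:
        minimum = _METHOD_MIN.get(method)
        if minimum is None:
            results[method] = f"skipped: unknown method {method!r}"
            continue
        if len(insts) < minimum:
            results[method] = f"skipped: minimum {minimum} instruments, have {len(insts)}"
            continue
        if method == "ivw_fe":
            results[method] = estimators.ivw(insts, model="fixed")
        elif method == "ivw_re":
            results[method] = estimators.ivw(insts, model="random")
        elif method == "egger":
            results[method] = estimators.egger(insts)
        elif method == "weighted_median":
            results[method] = estimators.weighted_median(insts, n_boot=config.n_boot, seed=config.seed)

    sens = None
    if len(insts) >= 3:
        sens = sensitivity.sensitivity_report(
            insts,
            n_sim=config.presso_n_sim,
            signif_threshold=config.presso_threshold,
            seed=config.seed,
        )

    steiger_res = None
    n_exp = config.exposure_n or exposure.n_default
    n_out = config.outcome_n or outcome.n_default
    if insts and n_exp and n_out:
        steiger_res = steiger_test(insts, n_exp, n_out)
    elif insts:
        warnings.warn("sample sizes unknown; Steiger test skipped (set exposure_n/outcome_n)")

    report = RunReport(
        qc=qc,
        results=results,
        sensitivity=sens,
        steiger=steiger_res,
        instruments=insts,
        harmonize_log=harm_log,
        dispositions=dispositions,
        config_hash=config.digest(),
        seed=config.seed,
    )
    if config.out_dir:
        write_report_tables(report, config.out_dir, exposure_label=config.exposure_label, outcome_label=config.outcome_label)
    return report


def _float_or_na(value) -> str:
    return "NA" if value is None else f"{value:.6g}"


def write_report_tables(
    report: RunReport,
    out_dir,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> dict[str, Path]:
    """Write results.tsv, sensitivity.tsv, harmonized.tsv, loo.tsv,
    funnel.tsv, the per-SNP disposition sidecar and a JSON run report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for method, res in report.results.items():
        if isinstance(res, str):
            rows.append(
                {"Exposure": exposure_label, "Method": method, "nSNP": "NA", "Beta": "NA",
                 "OR": "NA", "CI_low": "NA", "CI_high": "NA", "P": res}
            )
        else:
            rows.append(
                {"Exposure": exposure_label, "Method": method, "nSNP": res.n_snp,
                 "Beta": f"{res.beta:.6g}", "OR": f"{res.or_:.6g}",
                 "CI_low": f"{res.ci_low:.6g}", "CI_high": f"{res.ci_high:.6g}",
                 "P": f"{res.pval:.6g}"}
            )
    paths["results"] = out / "results.tsv"
    result_cols = ["Exposure", "Method", "nSNP", "Beta", "OR", "CI_low", "CI_high", "P"]
    pd.DataFrame(rows, columns=result_cols).to_csv(paths["results"], sep="\t", index=False)

    sens = report.sensitivity
    sens_row = {
        "Exposure": exposure_label,
        "Outcome": outcome_label,
        "Egger_intercept": _float_or_na(sens.egger_intercept if sens else None),
        "Egger_intercept_P": _float_or_na(sens.egger_intercept_p if sens else None),
        "Q": _float_or_na(sens.q if sens else None),
        "Q_P": _float_or_na(sens.q_p if sens else None),
        "PRESSO_before_P": _float_or_na(sens.presso.global_p if sens and sens.presso else None),
        "PRESSO_after_P": _float_or_na(
            sens.presso.corrected.pval if sens and sens.presso and sens.presso.corrected else None
        ),
    }
    paths["sensitivity"] = out / "sensitivity.tsv"
    pd.DataFrame([sens_row]).to_csv(paths["sensitivity"], sep="\t", index=False)

    harm_rows = [
        {"snp": i.snp_id, "beta_exp": i.beta_exp, "se_exp": i.se_exp,
         "beta_out": i.beta_out, "se_out": i.se_out,
         "eaf_exp": i.eaf_exp, "eaf_out": i.eaf_out,
         "f_stat": i.f_stat, "action": i.action}
        for i in report.instruments
    ]
    paths["harmonized"] = out / "harmonized.tsv"
    pd.DataFrame(
        harm_rows,
        columns=["snp", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out", "f_stat", "action"],
    ).to_csv(paths["harmonized"], sep="\t", index=False)

    paths["loo"] = out / "loo.tsv"
    (sens.loo if sens is not None else pd.DataFrame(columns=["excluded_snp", "beta", "se", "pval"])).to_csv(
        paths["loo"], sep="\t", index=False
    )
    paths["funnel"] = out / "funnel.tsv"
    (sens.funnel if sens is not None else pd.DataFrame(columns=["snp_id", "ratio", "precision"])).to_csv(
        paths["funnel"], sep="\t", index=False
    )

    paths["dispositions"] = out / "qc_dispositions.tsv"
    pd.DataFrame(
        sorted(report.dispositions.items()), columns=["snp", "disposition"]
    ).to_csv(paths["dispositions"], sep="\t", index=False)

    summary = {
        "version": report.version,
        "seed": report.seed,
        "config_hash": report.config_hash,
        "qc": asdict(report.qc),
        "steiger": None
        if report.steiger is None
        else {
            "r2_exposure": report.steiger.r2_exposure,
            "r2_outcome": report.steiger.r2_outcome,
            "correct_direction": report.steiger.correct_direction,
            "steiger_p": report.steiger.steiger_p,
        },
    }
    paths["run_report"] = out / "run_report.json"
    with open(paths["run_report"], "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
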