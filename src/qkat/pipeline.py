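"""End-to-end run: parse exports -> split -> call -> QC -> impute.

Mirrors the analysis arm of the typing workflow: per-plate exports are
parsed and mapped onto reactions via a manifest, copy numbers are called
with per-plate calibration, combined into the cohort spreadsheet, checked
against the LD rules and finally imputed against a reference haplotype
table.  Every stage logs its record counts; a failing stage aborts with
the stage name while earlier outputs are left on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .assay import AssayPanel, load_assay_panel
from .calling import build_profiles, call_cq_table, profiles_to_frame, write_profiles
from .errors import ConfigError, QkatError
from .haplotypes import builtin_reference_haplotypes, load_haplotype_table
from .impute import impute_cohort, write_imputation_outputs
from .ldqc import builtin_rules, check_cohort, cohort_qc_summary, load_rules
from .loci import LOCI
from .plates import parse_plate_export, split_by_reaction

log = logging.getLogger("qkat.pipeline")


@dataclass
class RunConfig:
    export_files: list[str]
    manifest: str                      # CSV: plate,reaction
    out_dir: str
    calibration_mode: str = "most_frequent_cn"
    calibrator_id: str | None = None
    calibrator_profile: str | None = None   # CSV: locus,copy_number
    haplotype_table: str | None = None      # None -> builtin synthetic table
    rules: str | None = None                # None -> builtin rules
    impute: bool = True
    xlsx: bool = False
    panel_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad run config {path}: {exc}") from exc

    def validate(self) -> None:
        for f in list(self.export_files) + [self.manifest]:
            if not Path(f).exists():
                raise ConfigError(f"input file missing: {f}")
        if self.calibration_mode == "calibrator_sample":
            if not self.calibrator_id or not self.calibrator_profile:
                raise ConfigError("calibrator_sample mode needs calibrator_id "
                                  "and calibrator_profile")
            if not Path(self.calibrator_profile).exists():
                raise ConfigError(f"calibrator profile missing: {self.calibrator_profile}")
        for opt in (self.haplotype_table, self.rules):
            if opt is not None and not Path(opt).exists():
                raise ConfigError(f"input file missing: {opt}")


@dataclass
class RunResult:
    profiles: list
    calls: list
    reports: list
    assignments: list | None
    outputs: dict[str, Path] = field(default_factory=dict)


def _load_calibrator_profile(path: str) -> dict[str, int]:
    frame = pd.read_csv(path)
    if {"locus", "copy_number"} <= set(frame.columns):
        return dict(zip(frame["locus"], frame["copy_number"].astype(int)))
    # single-row wide format: one column per locus
    row = frame.iloc[0]
    return {loc: int(row[loc]) for loc in LOCI if loc in frame.columns}


def run_pipeline(config: RunConfig, panel: AssayPanel | None = None) -> RunResult:
    """Execute the full analysis; deterministic given inputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = panel or load_assay_panel(config.panel_dir)
    outputs: dict[str, Path] = {}

    stage = "parse"
    try:
        exports = [parse_plate_export(f) for f in config.export_files]
        for exp in exports:
            exp.raise_if_errors()
        log.info("parse: %d plates, %d rows", len(exports),
                 sum(len(e.rows) for e in exports))

        stage = "split"
        manifest_frame = pd.read_csv(config.manifest)
        manifest = dict(zip(manifest_frame["plate"].astype(str),
                            manifest_frame["reaction"].astype(int)))
        cq_table = split_by_reaction(exports, panel, manifest)
        outputs["cq_table"] = out_dir / "cq_table.csv"
        cq_table.to_csv(outputs["cq_table"], index=False)
        log.info("split: %d measurements over %d reactions",
                 len(cq_table), cq_table["reaction"].nunique())

        stage = "call"
        calibrator_profile = (_load_calibrator_profile(config.calibrator_profile)
                              if config.calibrator_profile else None)
        calls = call_cq_table(cq_table, panel, mode=config.calibration_mode,
                              calibrator_id=config.calibrator_id,
                              calibrator_profile=calibrator_profile)
        profiles = build_profiles(calls)
        outputs["profiles"] = out_dir / "profiles.csv"
        write_profiles(profiles, outputs["profiles"], xlsx=config.xlsx)
        log.info("call: %d calls, %d profiles", len(calls), len(profiles))

        stage = "qc"
        rules = load_rules(config.rules) if config.rules else builtin_rules()
        reports = check_cohort(profiles, rules)
        summary = cohort_qc_summary(reports, rules)
        outputs["qc_summary"] = out_dir / "qc_summary.csv"
        summary.to_csv(outputs["qc_summary"], index=False)
        n_bad = sum(not r.conforms for r in reports)
        log.info("qc: %d/%d samples violate LD rules", n_bad, len(reports))

        assignments = None
        if config.impute:
            stage = "impute"
            table = (load_haplotype_table(config.haplotype_table)
                     if config.haplotype_table else builtin_reference_haplotypes())
            assignments = impute_cohort(profiles, table)
            paths = write_imputation_outputs(assignments, out_dir / "imputation")
            outputs.update({f"imputation_{k}": v for k, v in paths.items()})
            n_un = sum(a.status == "unassigned" for a in assignments)
            log.info("impute: %d samples, %d unassigned", len(assignments), n_un)
    except QkatError as exc:
        raise QkatError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return RunResult(profiles=profiles, calls=calls, reports=reports,
                     assignments=assignments, outputs=outputs)
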