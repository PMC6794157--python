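"""Linkage-disequilibrium consistency checks on copy-number profiles.

European-population KIR haplotype structure fixes ten arithmetic relations
between locus copy numbers (framework genes at two copies, allelic pairs
summing to two, activating genes travelling with their haplotype partners).
A called profile that violates any of them almost certainly contains a
miscall — or, rarely, a genuinely unusual haplotype — and is flagged for
manual re-checking of the raw plate data.  The rules are data, not code:
a CSV of equalities that can be swapped for non-European rule sets, where
these relations are known to hold less strictly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .calling import CopyNumberProfile
from .errors import ValidationError
from .loci import LOCI


@dataclass(frozen=True)
class LdConstraint:
    """One equality: sum(lhs loci) == sum(rhs loci) + constant."""

    lhs: tuple[str, ...]
    rhs: tuple[str, ...]
    constant: int

    def evaluate(self, cn: Mapping[str, int]) -> tuple[bool, str]:
        left = sum(cn[l] for l in self.lhs)
        right = sum(cn[l] for l in self.rhs) + self.constant
        lhs_text = "+".join(self.lhs)
        rhs_text = "+".join(list(self.rhs) + ([str(self.constant)] if self.constant or
                                              not self.rhs else []))
        return left == right, f"{lhs_text}={left} vs {rhs_text}={right}"

    @property
    def loci(self) -> set[str]:
        return set(self.lhs) | set(self.rhs)


@dataclass(frozen=True)
class LdRule:
    rule_id: int
    description: str
    constraints: tuple[LdConstraint, ...]

    @property
    def loci(self) -> set[str]:
        return set().union(*(c.loci for c in self.constraints))


@dataclass
class LdReport:
    sample_id: str
    violations: list[dict] = field(default_factory=list)
    not_evaluable: list[int] = field(default_factory=list)

    @property
    def conforms(self) -> bool:
        return not self.violations


def _parse_side(text: str) -> tuple[tuple[str, ...], int]:
    loci: list[str] = []
    constant = 0
    for term in text.split("+"):
        term = term.strip()
        if term.isdigit():
            constant += int(term)
        elif term in LOCI:
            loci.append(term)
        else:
            raise ValidationError(f"unknown locus {term!r} in rule expression {text!r}")
    return tuple(loci), constant


def _rules_from_rows(rows: list[dict]) -> list[LdRule]:
    grouped: dict[int, dict] = {}
    for row in rows:
        rid = int(row["rule_id"])
        lhs, lconst = _parse_side(row["lhs"])
        rhs, rconst = _parse_side(row["rhs"])
        if lconst:
            raise ValidationError(f"rule {rid}: constants belong on the rhs")
        entry = grouped.setdefault(rid, {"desc": row["description"], "cons": []})
        entry["cons"].append(LdConstraint(lhs=lhs, rhs=rhs, constant=rconst))
    return [LdRule(rule_id=rid, description=e["desc"], constraints=tuple(e["cons"]))
            for rid, e in sorted(grouped.items())]


def builtin_rules() -> list[LdRule]:
    """The ten packaged European-population rules."""
    text = resources.files("qkat.data").joinpath("ld_rules.csv").read_text("utf-8")
    return _rules_from_rows(list(csv.DictReader(text.splitlines())))


def load_rules(path: str | Path) -> list[LdRule]:
    with open(path, newline="", encoding="utf-8") as fh:
        return _rules_from_rows(list(csv.DictReader(fh)))


def check_profile(profile: CopyNumberProfile | Mapping[str, int],
                  rules: Iterable[LdRule] | None = None) -> LdReport:
    """Evaluate every rule on one profile.

    Rules touching loci that were not called are reported as not evaluable
    rather than violated.
    """
    if rules is None:
        rules = builtin_rules()
    if isinstance(profile, CopyNumberProfile):
        sample_id, cn = profile.sample_id, profile.copy_numbers
    else:
        sample_id, cn = "sample", dict(profile)
    report = LdReport(sample_id=sample_id)
    for rule in rules:
        if not rule.loci <= set(cn):
            report.not_evaluable.append(rule.rule_id)
            continue
        for constraint in rule.constraints:
            ok, observed = constraint.evaluate(cn)
            if not ok:
                report.violations.append({
                    "rule_id": rule.rule_id,
                    "description": rule.description,
                    "observed": observed,
                })
    return report


def check_cohort(profiles: Iterable[CopyNumberProfile],
                 rules: Iterable[LdRule] | None = None) -> list[LdReport]:
    rules = list(rules) if rules is not None else builtin_rules()
    return [check_profile(p, rules) for p in profiles]


def cohort_qc_summary(reports: Iterable[LdReport],
                      rules: Iterable[LdRule] | None = None) -> pd.DataFrame:
    """Per-sample conformity plus per-rule violation counts, worst first.

    Returns a table with one row per sample (``kind == 'sample'``) and one
    per rule of the rule set used (``kind == 'rule'``), each carrying its
    violation count.  ``rules`` defaults to the builtin set; pass the same
    (possibly empty) rule list the reports were generated with.
    """
    reports = list(reports)
    if not reports:
        raise ValidationError("no reports to summarise")
    rule_ids = sorted(r.rule_id for r in (builtin_rules() if rules is None else rules))
    rule_counts: dict[int, int] = {}
    rows = []
    for rep in reports:
        for v in rep.violations:
            rule_counts[v["rule_id"]] = rule_counts.get(v["rule_id"], 0) + 1
        rows.append({"kind": "sample", "id": rep.sample_id,
                     "violations": len(rep.violations),
                     "conforms": rep.conforms})
    for rid in sorted(set(rule_ids) | set(rule_counts)):
        rows.append({"kind": "rule", "id": f"rule_{rid}",
                     "violations": rule_counts.get(rid, 0), "conforms": None})
    frame = pd.DataFrame(rows, columns=["kind", "id", "violations", "conforms"])
    return frame.sort_values(["kind", "violations"], ascending=[True, False],
                             kind="stable").reset_index(drop=True)
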