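"""Haplotype-pair imputation from copy-number profiles.

Given a reference table of gene-content haplotypes with population
frequencies, every unordered pair (including self-pairs) whose per-locus
copy-number sums reproduce a sample's profile is enumerated — exhaustive
enumeration over a reference list of at most a few hundred haplotypes is
the algorithm, not an approximation.  Pairs are ranked by their
Hardy-Weinberg combined frequency ``f1*f2`` (doubled for heterozygous
pairs), and three cohort-level files are written: every compatible pair,
the trimmed best-frequency pairs, and the samples no pair can explain —
candidates for miscalls or genuinely novel haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calling import CopyNumberProfile
from .errors import ValidationError
from .haplotypes import HaplotypeTable
from .loci import LOCI


@dataclass
class PairAssignment:
    sample_id: str
    pairs: list[tuple[str, str, float]]  # (hap1, hap2, combined frequency), hap1<=hap2
    status: str = "assigned"             # "assigned" | "trimmed_best" | "unassigned"
    warnings: list[str] = field(default_factory=list)


def combined_frequency(f1: float, f2: float, homozygous: bool) -> float:
    """Hardy-Weinberg genotype frequency of an unordered haplotype pair."""
    return f1 * f2 if homozygous else 2.0 * f1 * f2


def impute_all_pairs(profile: CopyNumberProfile | Mapping[str, int],
                     table: HaplotypeTable,
                     wildcard_loci: frozenset[str] = frozenset()) -> PairAssignment:
    """All haplotype pairs whose gene-content sums match the profile.

    Matching is over all 20 measured loci except ``wildcard_loci`` (loci
    whose calls are distrusted and allowed to match any sum).  An empty
    result is status ``unassigned``.
    """
    if isinstance(profile, CopyNumberProfile):
        sample_id, cn = profile.sample_id, profile.copy_numbers
    else:
        sample_id, cn = "sample", dict(profile)
    loci = [l for l in LOCI if l not in wildcard_loci]
    missing = [l for l in loci if l not in cn]
    if missing:
        raise ValidationError(f"profile lacks loci referenced by matching: {missing}")

    haps = table.haplotypes
    if not haps:
        return PairAssignment(sample_id=sample_id, pairs=[], status="unassigned")
    content = np.array([[h.gene_content[l] for l in loci] for h in haps], dtype=int)
    target = np.array([cn[l] for l in loci], dtype=int)

    # Vectorised pair scan: sums of row i and rows j >= i against the target.
    pairs: list[tuple[str, str, float]] = []
    for i in range(len(haps)):
        sums = content[i] + content[i:]
        hits = np.flatnonzero((sums == target).all(axis=1)) + i
        for j in hits:
            h1, h2 = haps[i], haps[int(j)]
            a, b = sorted((h1.name, h2.name))
            pairs.append((a, b, combined_frequency(h1.frequency, h2.frequency,
                                                   homozygous=i == j)))
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    status = "assigned" if pairs else "unassigned"
    return PairAssignment(sample_id=sample_id, pairs=pairs, status=status)


def trim_best(assignment: PairAssignment) -> PairAssignment:
    """Keep only the pairs tied at the maximum combined frequency."""
    if assignment.status == "unassigned" or not assignment.pairs:
        return PairAssignment(sample_id=assignment.sample_id, pairs=[],
                              status="unassigned",
                              warnings=assignment.warnings
                              + ["trim requested for unassigned sample"])
    best = max(f for _, _, f in assignment.pairs)
    kept = [p for p in assignment.pairs if p[2] == best]
    return PairAssignment(sample_id=assignment.sample_id, pairs=kept,
                          status="trimmed_best", warnings=list(assignment.warnings))


def impute_cohort(profiles: Iterable[CopyNumberProfile | Mapping[str, int]],
                  table: HaplotypeTable,
                  wildcard_loci: frozenset[str] = frozenset()) -> list[PairAssignment]:
    return [impute_all_pairs(p, table, wildcard_loci) for p in profiles]


def write_imputation_outputs(assignments: Iterable[PairAssignment],
                             prefix: str | Path) -> dict[str, Path]:
    """Write the three cohort files next to ``prefix``.

    ``<prefix>.all.csv`` lists every compatible pair per sample,
    ``<prefix>.best.csv`` the trimmed highest-combined-frequency pairs
    (Hardy-Weinberg weighting, heterozygous pairs doubled), and
    ``<prefix>.unassigned.csv`` the samples with no compatible pair
    (possible novel haplotypes).  All three files are always created.
    """
    prefix = Path(prefix)
    if prefix.parent != Path("") and not prefix.parent.exists():
        prefix.parent.mkdir(parents=True, exist_ok=True)
    assignments = list(assignments)
    all_rows, best_rows, unassigned_rows = [], [], []
    for asg in assignments:
        if asg.status == "unassigned":
            unassigned_rows.append({"sample_id": asg.sample_id,
                                    "note": "no reference haplotype pair matches; "
                                            "possible novel haplotype or miscall"})
            continue
        for h1, h2, freq in asg.pairs:
            all_rows.append({"sample_id": asg.sample_id, "hap1": h1, "hap2": h2,
                             "combined_frequency": freq})
        for h1, h2, freq in trim_best(asg).pairs:
            best_rows.append({"sample_id": asg.sample_id, "hap1": h1, "hap2": h2,
                              "combined_frequency": freq})
    paths = {
        "all": prefix.with_suffix(".all.csv"),
        "best": prefix.with_suffix(".best.csv"),
        "unassigned": prefix.with_suffix(".unassigned.csv"),
    }
    try:
        pd.DataFrame(all_rows, columns=["sample_id", "hap1", "hap2",
                                        "combined_frequency"]).to_csv(
            paths["all"], index=False)
        pd.DataFrame(best_rows, columns=["sample_id", "hap1", "hap2",
                                         "combined_frequency"]).to_csv(
            paths["best"], index=False)
        pd.DataFrame(unassigned_rows, columns=["sample_id", "note"]).to_csv(
            paths["unassigned"], index=False)
    except OSError as exc:
        raise ValidationError(f"cannot write imputation outputs near {prefix}: {exc}")
    return paths
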