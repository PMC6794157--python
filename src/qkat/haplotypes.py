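"""Gene-content KIR haplotypes and reference haplotype tables.

A haplotype is described by which KIR genes it carries (gene content), not
by alleles.  Per haplotype each measured locus contributes 0 or 1 copy,
except 2DL5 where the 2DL5A and 2DL5B genes are collapsed into a single
measurement and a haplotype may contribute 0-2 copies.

The structural constraints of the European KIR region hold per haplotype:
framework genes (3DL3, 3DP1, 2DL4, 3DL2) are always present; 2DL2/2DL3 and
3DL1/3DS1 are allelic pairs occupying one slot each; the exon-4 and exon-9
assays of 3DL1 and 3DL2 see the same gene; 2DS2 travels with 2DL2, 2DP1
with 2DL1, 2DS1 with 3DS1; 2DS3/2DS5 are carried with 2DL5; and 2DS1 and
2DS4 are mutually exclusive per haplotype with 2DS4 resolved into
full-length and 22-bp-deleted variants.

The packaged reference table is a small synthetic stand-in for a
population reference list (real cohorts should supply their own CSV with
one column per locus plus name and frequency).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ValidationError
from .loci import FRAMEWORK_LOCI, LOCI

#: KIR genes counted when summarising a haplotype's gene content; exon-4 and
#: exon-9 measurements collapse to one gene, 2DS4 variants to 2DS4, and the
#: pseudogenes 2DP1/3DP1 are excluded.
_GENE_OF_LOCUS = {
    "3DL3": "3DL3", "2DS2": "2DS2", "2DL2": "2DL2", "2DL3": "2DL3",
    "2DL1": "2DL1", "2DL4": "2DL4", "3DL1ex4": "3DL1", "3DL1ex9": "3DL1",
    "3DS1": "3DS1", "2DL5": "2DL5", "2DS3": "2DS3", "2DS5": "2DS5",
    "2DS1": "2DS1", "2DS4Total": "2DS4", "2DS4FL": "2DS4", "2DS4Del": "2DS4",
    "3DL2ex4": "3DL2", "3DL2ex9": "3DL2",
}


@dataclass(frozen=True)
class Haplotype:
    name: str
    gene_content: dict[str, int]   # locus -> copies contributed
    frequency: float

    def copies(self, locus: str) -> int:
        return self.gene_content[locus]

    def genes_present(self) -> set[str]:
        """Distinct KIR genes carried (pseudogenes excluded)."""
        return {
            gene for locus, gene in _GENE_OF_LOCUS.items()
            if self.gene_content.get(locus, 0) > 0
        }


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]
    source: str = "user"

    def __iter__(self):
        return iter(self.haplotypes)

    def __len__(self):
        return len(self.haplotypes)

    def __getitem__(self, name: str) -> Haplotype:
        for hap in self.haplotypes:
            if hap.name == name:
                return hap
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [h.name for h in self.haplotypes]


def validate_haplotype(hap: Haplotype) -> list[str]:
    """Check the per-haplotype structural constraints; returns messages."""
    c = hap.gene_content
    problems = []
    missing = [l for l in LOCI if l not in c]
    if missing:
        return [f"missing loci: {missing}"]
    for locus in FRAMEWORK_LOCI:
        if c[locus] != 1:
            problems.append(f"framework locus {locus} contributes {c[locus]}, expected 1")
    checks = [
        ("2DL2+2DL3", c["2DL2"] + c["2DL3"], 1),
        ("3DL1ex4+3DS1", c["3DL1ex4"] + c["3DS1"], 1),
        ("3DL1ex4-3DL1ex9", c["3DL1ex4"] - c["3DL1ex9"], 0),
        ("3DL2ex4-3DL2ex9", c["3DL2ex4"] - c["3DL2ex9"], 0),
        ("2DS2-2DL2", c["2DS2"] - c["2DL2"], 0),
        ("2DP1-2DL1", c["2DP1"] - c["2DL1"], 0),
        ("2DS3+2DS5-2DL5", c["2DS3"] + c["2DS5"] - c["2DL5"], 0),
        ("3DS1-2DS1", c["3DS1"] - c["2DS1"], 0),
        ("2DS1+2DS4Total", c["2DS1"] + c["2DS4Total"], 1),
        ("2DS4FL+2DS4Del-2DS4Total", c["2DS4FL"] + c["2DS4Del"] - c["2DS4Total"], 0),
    ]
    for label, got, want in checks:
        if got != want:
            problems.append(f"{hap.name}: {label} = {got}, expected {want}")
    return problems


def _table_from_rows(rows: list[dict], source: str,
                     normalise: bool = False) -> HaplotypeTable:
    haps = []
    for row in rows:
        content = {locus: int(row[locus]) for locus in LOCI}
        haps.append(Haplotype(name=row["name"], gene_content=content,
                              frequency=float(row["frequency"])))
    names = [h.name for h in haps]
    if len(set(names)) != len(names):
        raise ValidationError("haplotype names are not unique")
    for hap in haps:
        if not 0.0 <= hap.frequency <= 1.0:
            raise ValidationError(f"{hap.name}: frequency {hap.frequency} outside [0,1]")
        problems = validate_haplotype(hap)
        if problems:
            raise ValidationError(f"invalid haplotype {hap.name}: " + "; ".join(problems))
    total = sum(h.frequency for h in haps)
    if normalise and total > 0 and abs(total - 1.0) > 1e-9:
        haps = [Haplotype(h.name, h.gene_content, h.frequency / total) for h in haps]
    return HaplotypeTable(haplotypes=haps, source=source)


def builtin_reference_haplotypes() -> HaplotypeTable:
    """The packaged synthetic reference table (frequencies sum to 1).

    Contains the two canonical A-group haplotypes (full-length vs deleted
    2DS4) and four B-group haplotypes covering the common activating-gene
    configurations, with frequencies chosen so the cohort-level modal copy
    number at every locus among amplifying samples matches the packaged
    most-frequent-copy-number defaults.
    """
    text = resources.files("qkat.data").joinpath("haplotypes.csv").read_text("utf-8")
    return _table_from_rows(list(csv.DictReader(text.splitlines())),
                            source="builtin-synthetic", normalise=True)


def load_haplotype_table(path: str | Path) -> HaplotypeTable:
    """Load a user reference table (CSV: name, frequency, one column per locus)."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return _table_from_rows(rows, source=str(path), normalise=True)


def profile_from_pair(hap1: Haplotype, hap2: Haplotype) -> dict[str, int]:
    """Per-locus copy numbers of the unordered pair (sum of contributions)."""
    return {locus: hap1.copies(locus) + hap2.copies(locus) for locus in LOCI}
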