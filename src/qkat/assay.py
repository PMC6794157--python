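"""The multiplex qPCR assay panel: primers, probes, reactions and defaults.

Ten multiplex reactions each amplify two KIR targets plus the STAT6
reference, read on three fluorescence channels.  The panel ships as four
CSV fixtures (primers, probes, reactions, most-frequent copy numbers) and
is validated on load; :func:`validate_panel` additionally recomputes every
printed primer/probe length, GC% and amplicon size from the sequences and
coordinates, so a transcription error in the fixture cannot pass silently.

Coordinates are 1-based inclusive positions on the locus coding sequence;
no strand arithmetic is performed.  STAT6 primers carry no coordinates, so
its amplicon size (129 bp) is stored as a literal and cannot be recomputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

from .errors import PanelError, UnsupportedComputation, ValidationError
from .loci import CHANNELS, CHANNEL_YELLOW, LOCI, REFERENCE_LOCUS

_DNA = set("ACGT")


@dataclass(frozen=True)
class Primer:
    """One amplification primer with its printed annotation columns."""

    name: str
    direction: str                 # "forward" | "reverse"
    sequence: str
    length_nt: int
    exon: int | None = None
    start_pos: int | None = None   # 1-based inclusive
    end_pos: int | None = None
    tm: float | None = None        # printed melting temperature, not recomputed
    gc_printed: float | None = None
    alleles_missed: str = ""


@dataclass(frozen=True)
class Probe:
    """One hydrolysis probe (5' dye, 3' quencher)."""

    name: str
    sense: str                     # "sense" | "antisense" | "unspecified"
    dye_5p: str
    quencher_3p: str
    sequence: str
    length_nt: int
    exon: int | None = None
    start_pos: int | None = None
    end_pos: int | None = None
    tm: float | None = None
    gc_printed: float | None = None


@dataclass(frozen=True)
class ReactionDef:
    """One multiplex reaction: two KIR targets plus the STAT6 reference."""

    reaction_number: int
    target_a: str
    target_b: str
    reference_locus: str
    channel_map: dict[str, str]            # locus -> filter name
    probe_map: dict[str, str]              # locus -> probe name
    primer_concentrations: dict[str, float]  # primer -> nM
    probe_concentrations: dict[str, float]   # probe -> nM

    @property
    def targets(self) -> tuple[str, str]:
        return (self.target_a, self.target_b)


@dataclass
class AssayPanel:
    """The full 10-reaction panel with per-assay primers and defaults."""

    reactions: list[ReactionDef]
    primers: dict[str, Primer]                    # primer name -> Primer
    probes: dict[str, Probe]
    assay_primers: dict[str, list[Primer]]        # assay/locus -> its primers
    printed_amplicon: dict[str, int]              # assay/locus -> printed bp
    default_copy_number: dict[str, int]           # locus -> most frequent CN
    loci: tuple[str, ...] = field(default=LOCI)

    def reaction(self, number: int) -> ReactionDef:
        for rxn in self.reactions:
            if rxn.reaction_number == number:
                return rxn
        raise KeyError(number)

    def reaction_for_locus(self, locus: str) -> ReactionDef:
        for rxn in self.reactions:
            if locus in rxn.targets:
                return rxn
        raise KeyError(locus)

    def channel_to_locus(self, reaction_number: int) -> dict[str, str]:
        rxn = self.reaction(reaction_number)
        return {ch: loc for loc, ch in rxn.channel_map.items()}


@dataclass(frozen=True)
class Discrepancy:
    """A printed table cell that computation does not reproduce."""

    kind: str          # "primer_length" | "primer_gc" | "probe_length" | ...
    name: str          # primer/probe/assay the cell belongs to
    printed: float
    computed: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}[{self.name}]: printed {self.printed}, computed {self.computed}"


def gc_percent(sequence: str) -> float:
    """GC content as a percentage, rounded half-away-from-zero to 1 decimal.

    Raises :class:`ValidationError` for an empty or non-A/C/G/T sequence.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    bad = set(sequence) - _DNA
    if bad:
        raise ValidationError(f"non-ACGT characters in sequence: {sorted(bad)}")
    frac = Decimal(100 * (sequence.count("G") + sequence.count("C"))) / Decimal(len(sequence))
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def amplicon_length(fwd: Primer, rev: Primer) -> int:
    """Amplicon size in bp from primer coordinates (1-based inclusive)."""
    if fwd.start_pos is None or rev.end_pos is None:
        raise UnsupportedComputation(
            f"primers {fwd.name}/{rev.name} carry no genomic positions"
        )
    return rev.end_pos - fwd.start_pos + 1


def _opt_int(value: str) -> int | None:
    return int(value) if value not in ("", None) else None


def _opt_float(value: str) -> float | None:
    return float(value) if value not in ("", None) else None


def _data_path(name: str):
    return resources.files("qkat.data").joinpath(name)


def _read_rows(source, name: str) -> list[dict]:
    if source is None:
        text = _data_path(name).read_text(encoding="utf-8")
    else:
        text = (Path(source) / name).read_text(encoding="utf-8")
    return list(csv.DictReader(text.splitlines()))


def load_assay_panel(source: str | Path | None = None) -> AssayPanel:
    """Load the panel from the packaged fixture or a directory of CSVs.

    The directory must contain ``primers.csv``, ``probes.csv``,
    ``reactions.csv`` and ``defaults.csv``.  Structural invariants (reaction
    numbering, STAT6 presence, locus/channel bijection, DNA alphabet) are
    enforced here; numeric printed columns are checked by
    :func:`validate_panel`.
    """
    primer_rows = _read_rows(source, "primers.csv")
    probe_rows = _read_rows(source, "probes.csv")
    reaction_rows = _read_rows(source, "reactions.csv")
    default_rows = _read_rows(source, "defaults.csv")

    primers: dict[str, Primer] = {}
    assay_primers: dict[str, list[Primer]] = {}
    printed_amplicon: dict[str, int] = {}
    for i, row in enumerate(primer_rows, start=2):
        seq = row["sequence"].strip().upper()
        if not seq or set(seq) - _DNA:
            raise PanelError("primer sequence is not plain A/C/G/T DNA",
                             field="sequence", line=i)
        try:
            primer = Primer(
                name=row["primer"], direction=row["direction"], sequence=seq,
                length_nt=int(row["length"]), exon=_opt_int(row["exon"]),
                start_pos=_opt_int(row["start"]), end_pos=_opt_int(row["end"]),
                tm=_opt_float(row["tm"]), gc_printed=_opt_float(row["gc_percent"]),
                alleles_missed=row["alleles_missed"],
            )
        except (KeyError, TypeError) as exc:
            raise PanelError(f"malformed primer row: {exc}", line=i) from exc
        if primer.direction not in ("forward", "reverse"):
            raise PanelError("direction must be forward/reverse",
                             field="direction", line=i)
        primers.setdefault(primer.name, primer)
        assay_primers.setdefault(row["assay"], []).append(primer)
        printed_amplicon[row["assay"]] = int(row["amplicon_bp"])

    probes: dict[str, Probe] = {}
    for i, row in enumerate(probe_rows, start=2):
        try:
            probes[row["name"]] = Probe(
                name=row["name"], sense=row["sense"], dye_5p=row["dye_5p"],
                quencher_3p=row["quencher_3p"],
                sequence=row["sequence"].strip().upper(),
                length_nt=int(row["length"]), exon=_opt_int(row["exon"]),
                start_pos=_opt_int(row["start"]), end_pos=_opt_int(row["end"]),
                tm=_opt_float(row["tm"]), gc_printed=_opt_float(row["gc_percent"]),
            )
        except (KeyError, TypeError) as exc:
            raise PanelError(f"malformed probe row: {exc}", line=i) from exc

    by_reaction: dict[int, list[dict]] = {}
    for i, row in enumerate(reaction_rows, start=2):
        try:
            by_reaction.setdefault(int(row["reaction"]), []).append(row)
        except ValueError as exc:
            raise PanelError("reaction number is not an integer",
                             field="reaction", line=i) from exc

    if sorted(by_reaction) != list(range(1, 11)):
        raise PanelError(
            f"expected reaction numbers 1-10 exactly once, got {sorted(by_reaction)}",
            field="reaction",
        )

    reactions: list[ReactionDef] = []
    locus_owner: dict[str, int] = {}
    for number, rows in sorted(by_reaction.items()):
        roles = {row["role"]: row for row in rows}
        if len(rows) != 3 or set(roles) != {"kir_a", "kir_b", "reference"}:
            raise PanelError(
                f"reaction {number} must have exactly kir_a, kir_b and reference rows",
                field="role",
            )
        if roles["reference"]["locus"] != REFERENCE_LOCUS:
            raise PanelError(
                f"reaction {number} reference locus is {roles['reference']['locus']!r}, "
                f"expected {REFERENCE_LOCUS}", field="locus",
            )
        channel_map, probe_map = {}, {}
        primer_conc: dict[str, float] = {}
        probe_conc: dict[str, float] = {}
        for row in rows:
            locus = row["locus"]
            if row["channel"] not in CHANNELS:
                raise PanelError(f"unknown channel {row['channel']!r} in reaction {number}",
                                 field="channel")
            channel_map[locus] = row["channel"]
            probe_map[locus] = row["probe"]
            if row["probe"] not in probes:
                raise PanelError(f"unknown probe {row['probe']!r} in reaction {number}",
                                 field="probe")
            for name in row["forward_primers"].split("|") + [row["reverse_primer"]]:
                if name not in primers:
                    raise PanelError(f"unknown primer {name!r} in reaction {number}",
                                     field="forward_primers")
                primer_conc[name] = float(row["forward_nM"] if name != row["reverse_primer"]
                                          else row["reverse_nM"])
            probe_conc[row["probe"]] = float(row["probe_nM"])
            if locus != REFERENCE_LOCUS:
                if locus in locus_owner:
                    raise PanelError(f"locus {locus} targeted by reactions "
                                     f"{locus_owner[locus]} and {number}", field="locus")
                locus_owner[locus] = number
        if channel_map[REFERENCE_LOCUS] != CHANNEL_YELLOW:
            raise PanelError(f"STAT6 must read on the {CHANNEL_YELLOW} filter "
                             f"in reaction {number}", field="channel")
        if len(set(channel_map.values())) != 3:
            raise PanelError(f"reaction {number} channels are not distinct",
                             field="channel")
        reactions.append(ReactionDef(
            reaction_number=number,
            target_a=roles["kir_a"]["locus"], target_b=roles["kir_b"]["locus"],
            reference_locus=REFERENCE_LOCUS,
            channel_map=channel_map, probe_map=probe_map,
            primer_concentrations=primer_conc, probe_concentrations=probe_conc,
        ))

    if set(locus_owner) != set(LOCI):
        missing = set(LOCI) - set(locus_owner)
        extra = set(locus_owner) - set(LOCI)
        raise PanelError(f"locus/reaction mapping is not a bijection onto the panel "
                         f"(missing={sorted(missing)}, unknown={sorted(extra)})",
                         field="locus")

    defaults = {row["locus"]: int(row["most_frequent_cn"]) for row in default_rows}
    if set(defaults) != set(LOCI):
        raise PanelError("defaults table does not cover the 20 panel loci",
                         field="locus")

    return AssayPanel(
        reactions=reactions, primers=primers, probes=probes,
        assay_primers=assay_primers, printed_amplicon=printed_amplicon,
        default_copy_number=defaults,
    )


def computed_amplicon(panel: AssayPanel, assay: str) -> int:
    """Amplicon size recomputed from coordinates for one assay.

    Assays with more than one forward primer (3DL3) use the outermost
    forward start, matching the single printed value.
    """
    prims = panel.assay_primers[assay]
    fwds = [p for p in prims if p.direction == "forward"]
    revs = [p for p in prims if p.direction == "reverse"]
    if any(p.start_pos is None for p in fwds) or any(p.end_pos is None for p in revs):
        raise UnsupportedComputation(f"assay {assay} has primers without positions")
    outer_fwd = min(fwds, key=lambda p: p.start_pos)
    return amplicon_length(outer_fwd, revs[0])


def validate_panel(panel: AssayPanel) -> list[Discrepancy]:
    """Recompute every printed length, GC% and amplicon size and compare.

    Returns an empty list when the fixture reproduces every printed cell,
    otherwise one :class:`Discrepancy` per mismatching cell.
    """
    out: list[Discrepancy] = []
    for primer in panel.primers.values():
        if len(primer.sequence) != primer.length_nt:
            out.append(Discrepancy("primer_length", primer.name,
                                   primer.length_nt, len(primer.sequence)))
        if primer.start_pos is not None and primer.end_pos is not None:
            span = primer.end_pos - primer.start_pos + 1
            if span != primer.length_nt:
                out.append(Discrepancy("primer_span", primer.name,
                                       primer.length_nt, span))
    for probe in panel.probes.values():
        if len(probe.sequence) != probe.length_nt:
            out.append(Discrepancy("probe_length", probe.name,
                                   probe.length_nt, len(probe.sequence)))
    for primer in panel.primers.values():
        if primer.gc_printed is not None and gc_percent(primer.sequence) != primer.gc_printed:
            out.append(Discrepancy("primer_gc", primer.name, primer.gc_printed,
                                   gc_percent(primer.sequence)))
    for probe in panel.probes.values():
        if probe.gc_printed is not None and gc_percent(probe.sequence) != probe.gc_printed:
            out.append(Discrepancy("probe_gc", probe.name, probe.gc_printed,
                                   gc_percent(probe.sequence)))
    for assay, printed in panel.printed_amplicon.items():
        if assay == REFERENCE_LOCUS:
            continue  # STAT6 has no coordinates; 129 bp is a stored literal
        computed = computed_amplicon(panel, assay)
        if computed != printed:
            out.append(Discrepancy("amplicon", assay, printed, computed))
    return out
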