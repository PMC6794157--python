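"""384-well plate geometry and the tab-delimited plate-export dialect.

Samples are dispensed in quadruplicate from a 96-well source plate onto a
384-well qPCR plate: source position (r, c) maps to the 2x2 block of wells
(2r-1..2r, 2c-1..2c), one plate per multiplex reaction.

Vendor batch exports are not standardised, so qkat defines a documented
tab-delimited dialect::

    # qkat-plate-export v1
    # plate: <plate id>
    # analysis: <second_derivative_max | fit_points>
    well<TAB>sample<TAB>filter<TAB>cq

with one row per (well, fluorescence filter), an empty ``cq`` field meaning
no amplification (dropout), and filters named by their nm bands
(465-510 / 533-580 / 618-660; common vendor spellings are accepted).
Real vendor files can be adapted by renaming columns to this dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import math
import pandas as pd

from .assay import AssayPanel
from .errors import ParseError
from .loci import CHANNEL_ALIASES

ROWS_384 = "ABCDEFGHIJKLMNOP"
N_COLS_384 = 24
ROWS_96 = "ABCDEFGH"
N_COLS_96 = 12

CQ_COLUMNS = ["plate", "reaction", "well", "sample_id", "replicate", "locus", "cq"]

ANALYSIS_METHODS = ("second_derivative_max", "fit_points")


def parse_well(name: str) -> tuple[int, int]:
    """Well name like ``A1``/``P24`` -> 0-based (row, col); raises ParseError."""
    name = name.strip()
    if len(name) < 2 or name[0] not in ROWS_384 or not name[1:].isdigit():
        raise ParseError(f"invalid 384-well position {name!r}")
    col = int(name[1:])
    if not 1 <= col <= N_COLS_384:
        raise ParseError(f"invalid 384-well position {name!r}")
    return ROWS_384.index(name[0]), col - 1


def well_name(row: int, col: int) -> str:
    return f"{ROWS_384[row]}{col + 1}"


def quadruplicate_wells(source_index: int) -> list[str]:
    """The four 384-well positions of a 96-well source position.

    ``source_index`` is the 0-based row-major position on the 96-well
    source plate (0 = A1, 11 = A12, 95 = H12).  Replicates are ordered
    within the 2x2 block row-major.
    """
    if not 0 <= source_index < 96:
        raise ValueError(f"source index {source_index} outside 0..95")
    r96, c96 = divmod(source_index, N_COLS_96)
    return [well_name(2 * r96 + dr, 2 * c96 + dc)
            for dr in (0, 1) for dc in (0, 1)]


def source_position(well: str) -> tuple[int, int]:
    """Inverse of the quadruplicate layout: well -> (source index, replicate 1-4)."""
    r, c = parse_well(well)
    replicate = 2 * (r % 2) + (c % 2) + 1
    return (r // 2) * N_COLS_96 + c // 2, replicate


@dataclass
class PlateExport:
    """One parsed per-plate results export."""

    plate_id: str
    analysis_method: str
    rows: pd.DataFrame            # columns: well, sample, filter, cq (NaN = dropout)
    errors: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_errors(self) -> None:
        if self.errors:
            first = self.errors[0]
            raise ParseError(
                f"plate {self.plate_id}: {len(self.errors)} bad rows; first: "
                f"line {first['line']}: [{first['category']}] {first['message']}"
            )


def write_plate_export(path: str | Path, plate_id: str, rows: pd.DataFrame,
                       analysis_method: str = "second_derivative_max") -> None:
    """Write a plate export in the qkat dialect (``rows``: well/sample/filter/cq)."""
    if analysis_method not in ANALYSIS_METHODS:
        raise ParseError(f"unknown analysis method {analysis_method!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# qkat-plate-export v1\n")
        fh.write(f"# plate: {plate_id}\n")
        fh.write(f"# analysis: {analysis_method}\n")
        fh.write("well\tsample\tfilter\tcq\n")
        for rec in rows.itertuples(index=False):
            cq = "" if pd.isna(rec.cq) else f"{rec.cq:.4f}"
            fh.write(f"{rec.well}\t{rec.sample}\t{rec.filter}\t{cq}\n")


def parse_plate_export(path: str | Path) -> PlateExport:
    """Parse one export file; malformed rows are collected, not dropped.

    Row-level problems (invalid well, unknown filter, duplicate well/filter,
    unreadable Cq) land in :attr:`PlateExport.errors` with the offending
    line number; file-level problems raise :class:`ParseError`.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    records: list[dict] = []
    errors: list[dict] = []
    seen: set[tuple[str, str]] = set()
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, value = body.split(":", 1)
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = line.split("\t")
                if cols != ["well", "sample", "filter", "cq"]:
                    raise ParseError(f"{path.name}: unexpected header {cols}")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                errors.append({"line": lineno, "category": "malformed",
                               "message": f"expected 4 fields, got {len(parts)}"})
                continue
            well, sample, filt, cq_text = (p.strip() for p in parts)
            try:
                parse_well(well)
            except ParseError as exc:
                errors.append({"line": lineno, "category": "invalid_well",
                               "message": str(exc)})
                continue
            channel = CHANNEL_ALIASES.get(filt)
            if channel is None:
                errors.append({"line": lineno, "category": "unknown_filter",
                               "message": f"unknown filter {filt!r} in well {well}"})
                continue
            if (well, channel) in seen:
                errors.append({"line": lineno, "category": "duplicate_well",
                               "message": f"duplicate measurement for well {well}, "
                                          f"filter {channel}"})
                continue
            seen.add((well, channel))
            if cq_text == "":
                cq = math.nan
            else:
                try:
                    cq = float(cq_text)
                except ValueError:
                    errors.append({"line": lineno, "category": "bad_cq",
                                   "message": f"unreadable Cq {cq_text!r} in well {well}"})
                    continue
            records.append({"well": well, "sample": sample,
                            "filter": channel, "cq": cq})
    if not header_seen:
        raise ParseError(f"{path.name}: no header row found")
    method = meta.get("analysis", "second_derivative_max")
    if method not in ANALYSIS_METHODS:
        raise ParseError(f"{path.name}: unknown analysis method {method!r}")
    rows = pd.DataFrame(records, columns=["well", "sample", "filter", "cq"])
    return PlateExport(plate_id=meta.get("plate", path.stem),
                       analysis_method=method, rows=rows, errors=errors)


def split_by_reaction(exports: list[PlateExport], panel: AssayPanel,
                      manifest: dict[str, int]) -> pd.DataFrame:
    """Map exported plates onto reactions and loci.

    ``manifest`` maps plate id -> reaction number (the role of the
    split_file/roche2sds step).  Channels become loci through the panel's
    per-reaction channel map, and wells are grouped into quadruplicates by
    the 96->384 block layout.  Returns one tidy table with columns
    ``plate, reaction, well, sample_id, replicate, locus, cq``.
    """
    frames = []
    for export in exports:
        if export.plate_id not in manifest:
            raise ParseError(f"plate {export.plate_id!r} has no manifest entry")
        reaction = manifest[export.plate_id]
        chan_to_locus = panel.channel_to_locus(reaction)
        rows = export.rows.copy()
        unknown = set(rows["filter"]) - set(chan_to_locus)
        if unknown:
            raise ParseError(f"plate {export.plate_id}: filters {sorted(unknown)} "
                             f"not mapped for reaction {reaction}")
        rows["locus"] = rows["filter"].map(chan_to_locus)
        pos = rows["well"].map(lambda w: source_position(w))
        rows["replicate"] = [p[1] for p in pos]
        rows["plate"] = export.plate_id
        rows["reaction"] = reaction
        rows = rows.rename(columns={"sample": "sample_id"})
        frames.append(rows[CQ_COLUMNS])
    return pd.concat(frames, ignore_index=True)
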