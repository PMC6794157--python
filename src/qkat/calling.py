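"""Copy-number calling by relative quantification (delta-delta-Cq).

Within each well the KIR-target Cq is referenced to the same well's STAT6
Cq (a fixed two-copy gene), giving a delta-Cq that is invariant to the
amount of DNA dispensed into the well.  Quadruplicate wells are combined
by the median (with the median absolute deviation kept as a dispersion
flag), and each plate is calibrated per locus by one of two anchors:

* **calibrator sample** — a control of known copy number on the plate;
* **most frequent copy number** — the plate-median delta-Cq paired with
  the panel's most-frequent-copy-number default for the locus (the modal
  copy number among amplifying European-origin samples).

The copy-number estimate is ``CN0 * 2**(-ddCq)`` where ``ddCq`` is the
sample's delta-Cq minus the anchor delta-Cq, rounded half-away-from-zero
to an integer call.  Absence of amplification in at least half the
replicates (with an intact STAT6 signal) is called copy number 0 — zero
copies have a qualitative signature, not a quantitative one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assay import AssayPanel
from .errors import CalibrationError, ValidationError
from .loci import LOCI, REFERENCE_LOCUS

#: Calls above this value are flagged implausible and capped.
MAX_COPY_NUMBER = 8

#: Aggregated replicate dispersion (MAD, cycles) above which a call is flagged.
DISPERSION_FLAG_THRESHOLD = 0.5

#: Confidence below which a call is flagged low-confidence.
LOW_CONFIDENCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class AggregatedDeltaCq:
    delta_cq: float | None     # None = dropout (no amplification)
    n_used: int
    dispersion: float | None   # MAD of the replicate delta-Cq values

    @property
    def is_dropout(self) -> bool:
        return self.delta_cq is None


@dataclass(frozen=True)
class Anchor:
    """Per-locus calibration anchor: (delta-Cq0, CN0)."""

    delta_cq: float
    copy_number: int
    source: str     # "calibrator" | "plate_median" | "default_fallback"


@dataclass
class CopyNumberCall:
    sample_id: str
    locus: str
    delta_cq: float | None
    ddcq: float | None
    cn_estimate: float
    cn_called: int
    confidence: float
    n_replicates_used: int
    dispersion: float | None = None
    flags: list[str] = field(default_factory=list)
    plate: str | None = None


@dataclass
class CopyNumberProfile:
    sample_id: str
    copy_numbers: dict[str, int]
    flags: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, locus: str) -> int:
        return self.copy_numbers[locus]

    def get(self, locus: str, default=None):
        return self.copy_numbers.get(locus, default)


def round_half_away_from_zero(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def well_delta_cq(kir_cq: float, stat6_cq: float) -> float:
    """Within-well delta-Cq (KIR minus STAT6).  Both values must be present:
    an absent STAT6 is a reference failure, not evidence of copy number 0."""
    if stat6_cq is None or (isinstance(stat6_cq, float) and math.isnan(stat6_cq)):
        raise ValidationError("STAT6 Cq absent: well invalid (reference failure)")
    if kir_cq is None or (isinstance(kir_cq, float) and math.isnan(kir_cq)):
        raise ValidationError("KIR Cq absent: use the dropout path, not delta-Cq")
    return kir_cq - stat6_cq


def aggregate_replicates(delta_cqs: Iterable[float | None]) -> AggregatedDeltaCq:
    """Combine replicate delta-Cq values (None/NaN = dropout well).

    Dropout in at least half the replicates yields an aggregate dropout;
    otherwise the median of the non-dropout values with their MAD.
    """
    values = list(delta_cqs)
    if not values:
        raise ValidationError("no replicates to aggregate")
    present = [v for v in values
               if v is not None and not (isinstance(v, float) and math.isnan(v))]
    n_dropout = len(values) - len(present)
    if 2 * n_dropout >= len(values):
        return AggregatedDeltaCq(delta_cq=None, n_used=len(present), dispersion=None)
    arr = np.asarray(present, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    return AggregatedDeltaCq(delta_cq=med, n_used=len(present), dispersion=mad)


def calibrate(per_sample_dcq: Mapping[str, AggregatedDeltaCq], locus: str,
              mode: str, calibrator_id: str | None = None,
              calibrator_cn: int | None = None,
              default_cn: int | None = None,
              min_samples: int = 5) -> Anchor:
    """Build the calibration anchor for one locus on one plate.

    ``calibrator_sample`` mode anchors at the calibrator's aggregated
    delta-Cq and its known copy number.  A calibrator whose known copy
    number at this locus is 0 never amplifies and cannot anchor a ratio;
    such loci fall back to defaults-based anchoring (flagged via the
    anchor source).  ``most_frequent_cn`` mode anchors at the median
    delta-Cq of the plate's amplifying samples, paired with the panel
    default copy number.
    """
    if mode == "calibrator_sample":
        if calibrator_id is None or calibrator_cn is None:
            raise CalibrationError("calibrator id and known copy number required")
        if calibrator_cn > 0:
            agg = per_sample_dcq.get(calibrator_id)
            if agg is None:
                raise CalibrationError(
                    f"calibrator {calibrator_id!r} absent from plate ({locus})")
            if agg.is_dropout:
                raise CalibrationError(
                    f"calibrator {calibrator_id!r} dropped out at {locus} "
                    f"but its known copy number is {calibrator_cn}")
            return Anchor(delta_cq=agg.delta_cq, copy_number=calibrator_cn,
                          source="calibrator")
        anchor = calibrate(per_sample_dcq, locus, "most_frequent_cn",
                           default_cn=default_cn, min_samples=min_samples)
        return Anchor(anchor.delta_cq, anchor.copy_number, "default_fallback")
    if mode == "most_frequent_cn":
        if default_cn is None:
            raise CalibrationError(f"no default copy number supplied for {locus}")
        present = [a.delta_cq for a in per_sample_dcq.values() if not a.is_dropout]
        if len(present) < min_samples:
            raise CalibrationError(
                f"{locus}: only {len(present)} amplifying samples on the plate; "
                f">= {min_samples} needed for most-frequent-CN calibration")
        return Anchor(delta_cq=float(np.median(present)), copy_number=default_cn,
                      source="plate_median")
    raise CalibrationError(f"unknown calibration mode {mode!r}")


def call_copy_number(sample_id: str, locus: str, agg: AggregatedDeltaCq,
                     anchor: Anchor) -> CopyNumberCall:
    """Turn an aggregated delta-Cq into an integer copy-number call."""
    flags: list[str] = []
    if agg.is_dropout:
        call = CopyNumberCall(sample_id=sample_id, locus=locus, delta_cq=None,
                              ddcq=None, cn_estimate=0.0, cn_called=0,
                              confidence=1.0, n_replicates_used=agg.n_used,
                              dispersion=agg.dispersion, flags=flags)
        return call
    ddcq = agg.delta_cq - anchor.delta_cq
    estimate = anchor.copy_number * 2.0 ** (-ddcq)
    called = round_half_away_from_zero(estimate)
    if called > MAX_COPY_NUMBER:
        called = MAX_COPY_NUMBER
        flags.append("implausible")
    confidence = max(0.0, 1.0 - 2.0 * abs(estimate - called) / max(called, 1))
    if confidence < LOW_CONFIDENCE_THRESHOLD:
        flags.append("low_confidence")
    if agg.dispersion is not None and agg.dispersion > DISPERSION_FLAG_THRESHOLD:
        flags.append("high_dispersion")
    if anchor.source == "default_fallback":
        flags.append("calibrator_fallback")
    return CopyNumberCall(sample_id=sample_id, locus=locus, delta_cq=agg.delta_cq,
                          ddcq=ddcq, cn_estimate=estimate, cn_called=called,
                          confidence=confidence, n_replicates_used=agg.n_used,
                          dispersion=agg.dispersion, flags=flags)


def call_cq_table(cq_table: pd.DataFrame, panel: AssayPanel, mode: str,
                  calibrator_id: str | None = None,
                  calibrator_profile: Mapping[str, int] | None = None,
                  min_samples: int = 5) -> list[CopyNumberCall]:
    """Run delta-delta-Cq calling over a tidy Cq table (all plates/reactions).

    Calibration is per plate and per locus.  Wells whose STAT6 channel
    failed are excluded and the affected sample flagged.
    """
    calls: list[CopyNumberCall] = []
    for (plate, _reaction), group in cq_table.groupby(["plate", "reaction"]):
        wide = group.pivot_table(index=["sample_id", "replicate"], columns="locus",
                                 values="cq", aggfunc="first", dropna=False)
        if REFERENCE_LOCUS not in wide.columns:
            raise ValidationError(f"plate {plate}: no {REFERENCE_LOCUS} measurements")
        kir_loci = [c for c in wide.columns if c != REFERENCE_LOCUS]
        ref_ok = wide[REFERENCE_LOCUS].notna()
        for locus in kir_loci:
            per_sample: dict[str, AggregatedDeltaCq] = {}
            ref_failed: set[str] = set()
            for sample_id, sample_wells in wide.groupby(level="sample_id"):
                ok = ref_ok.loc[sample_id]
                if not ok.all():
                    ref_failed.add(str(sample_id))
                valid = sample_wells[ok.values]
                if valid.empty:
                    continue
                dcqs = (valid[locus] - valid[REFERENCE_LOCUS]).tolist()
                per_sample[str(sample_id)] = aggregate_replicates(dcqs)
            cal_cn = calibrator_profile.get(locus) if calibrator_profile else None
            anchor = calibrate(per_sample, locus, mode,
                               calibrator_id=calibrator_id, calibrator_cn=cal_cn,
                               default_cn=panel.default_copy_number.get(locus),
                               min_samples=min_samples)
            for sample_id, agg in per_sample.items():
                call = call_copy_number(sample_id, locus, agg, anchor)
                call.plate = str(plate)
                if sample_id in ref_failed:
                    call.flags.append("reference_well_failure")
                calls.append(call)
    return calls


def build_profiles(calls: Iterable[CopyNumberCall],
                   expected_loci: tuple[str, ...] = LOCI) -> list[CopyNumberProfile]:
    """Combine per-reaction calls into one profile per sample.

    Duplicate (sample, locus) calls from different plates are kept only if
    concordant; discordant duplicates keep the higher-confidence call and
    flag the locus ``conflict``.  Loci never typed are flagged ``missing``.
    """
    by_sample: dict[str, dict[str, CopyNumberCall]] = {}
    flags: dict[str, dict[str, list[str]]] = {}
    for call in calls:
        slot = by_sample.setdefault(call.sample_id, {})
        fl = flags.setdefault(call.sample_id, {})
        if call.locus in slot:
            prev = slot[call.locus]
            if prev.cn_called != call.cn_called:
                fl.setdefault(call.locus, []).append("conflict")
                if call.confidence > prev.confidence:
                    slot[call.locus] = call
            continue
        slot[call.locus] = call
        if call.flags:
            fl.setdefault(call.locus, []).extend(call.flags)
    profiles = []
    for sample_id in sorted(by_sample):
        slot = by_sample[sample_id]
        fl = flags[sample_id]
        for locus in expected_loci:
            if locus not in slot:
                fl.setdefault(locus, []).append("missing")
        profiles.append(CopyNumberProfile(
            sample_id=sample_id,
            copy_numbers={loc: slot[loc].cn_called for loc in expected_loci
                          if loc in slot},
            flags={k: v for k, v in fl.items() if v},
        ))
    return profiles


def profiles_to_frame(profiles: Iterable[CopyNumberProfile],
                      loci: tuple[str, ...] = LOCI) -> pd.DataFrame:
    """Combined spreadsheet: one row per sample, one column per locus."""
    rows = []
    for prof in profiles:
        row = {"sample_id": prof.sample_id}
        row.update({loc: prof.copy_numbers.get(loc) for loc in loci})
        row["flags"] = ";".join(f"{loc}:{'|'.join(fl)}"
                                for loc, fl in sorted(prof.flags.items()))
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", *loci, "flags"])


def frame_to_profiles(frame: pd.DataFrame,
                      loci: tuple[str, ...] = LOCI) -> list[CopyNumberProfile]:
    """Inverse of :func:`profiles_to_frame` (flags parsed back per locus)."""
    profiles = []
    for rec in frame.to_dict("records"):
        flags: dict[str, list[str]] = {}
        for item in str(rec.get("flags", "") or "").split(";"):
            if ":" in item:
                locus, fl = item.split(":", 1)
                flags[locus] = fl.split("|")
        copy_numbers = {loc: int(rec[loc]) for loc in loci
                        if loc in rec and pd.notna(rec[loc])}
        profiles.append(CopyNumberProfile(sample_id=str(rec["sample_id"]),
                                          copy_numbers=copy_numbers, flags=flags))
    return profiles


def write_profiles(profiles: Iterable[CopyNumberProfile], path: str | Path,
                   xlsx: bool = False) -> None:
    frame = profiles_to_frame(list(profiles))
    frame.to_csv(path, index=False)
    if xlsx:
        frame.to_excel(Path(path).with_suffix(".xlsx"), index=False)
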