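"""Synthetic qPCR cohorts: haplotype pairs, plate layouts, Cq values, curves.

The generator emulates the experimental design of the typing assay: each
sample is an unordered pair of reference haplotypes drawn under
Hardy-Weinberg random pairing, dispensed in quadruplicate onto one
384-well plate per multiplex reaction.  Per well, the KIR-channel Cq
follows the relative-quantification model

    Cq_KIR   = C_kir  - log2(k)  + drift(well) + N(0, cq_noise_sd)
    Cq_STAT6 = C_ref             + drift(well) + N(0, cq_noise_sd)

where ``k`` is the true copy number at the locus.  A copy number of zero
produces no amplification: the well's KIR channel carries the dropout
sentinel (absent Cq, NaN).  ``drift`` models plate-position variation in
dispensed DNA amount and is shared between the two channels of a well, so
it cancels in the within-well delta-Cq; the optional asymmetric mode draws
it per channel instead, reproducing the copy-number scatter seen on plates
with uneven DNA concentration.

PCR efficiency is ideal (one cycle per doubling); probe cross-talk and
allele dropout are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay import AssayPanel, load_assay_panel
from .errors import ConfigError
from .haplotypes import Haplotype, HaplotypeTable, builtin_reference_haplotypes, \
    profile_from_pair
from .loci import LOCI, REFERENCE_LOCUS
from .plates import CQ_COLUMNS, quadruplicate_wells, write_plate_export


@dataclass
class SimConfig:
    """Study-design parameters for a synthetic cohort."""

    n_samples: int = 96
    haplotype_table: HaplotypeTable | None = None   # None -> builtin table
    cq_noise_sd: float = 0.1          # per-channel Cq noise, cycles
    concentration_drift_sd: float = 0.3  # per-well DNA-amount drift, cycles
    replicates: int = 4
    seed: int = 0
    control_pair: tuple[str, str] | None = None  # force first sample's pair
    asymmetric_drift: bool = False    # drift per channel instead of per well
    kir_baseline_cq: float = 25.0     # Cq of a single-copy KIR target
    stat6_baseline_cq: float = 24.0   # Cq of the two-copy reference

    def __post_init__(self):
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.cq_noise_sd < 0 or self.concentration_drift_sd < 0:
            raise ConfigError("noise parameters must be >= 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")

    def table(self) -> HaplotypeTable:
        if self.haplotype_table is None:
            return builtin_reference_haplotypes()
        return self.haplotype_table


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    samples: list[dict]   # sample_id, hap1, hap2, profile (locus -> CN)

    def profile(self, sample_id: str) -> dict[str, int]:
        for s in self.samples:
            if s["sample_id"] == sample_id:
                return s["profile"]
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": s["sample_id"], "hap1": s["hap1"], "hap2": s["hap2"],
                 **s["profile"]} for s in self.samples]
        return pd.DataFrame(rows, columns=["sample_id", "hap1", "hap2", *LOCI])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_cohort(config: SimConfig) -> CohortTruth:
    """Draw haplotype pairs independently with Hardy-Weinberg probabilities.

    Deterministic under a fixed seed.  If ``control_pair`` is set, the first
    sample carries exactly that pair (a plate control of known genotype).
    """
    table = config.table()
    if len(table) == 0:
        raise ConfigError("haplotype table is empty")
    freqs = np.array([h.frequency for h in table], dtype=float)
    if freqs.sum() <= 0:
        raise ConfigError("haplotype frequencies sum to zero")
    freqs = freqs / freqs.sum()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5A]))
    idx = rng.choice(len(table.haplotypes), size=(config.n_samples, 2), p=freqs)
    haps = table.haplotypes
    samples = []
    width = max(3, len(str(config.n_samples)))
    for i in range(config.n_samples):
        h1, h2 = haps[idx[i, 0]], haps[idx[i, 1]]
        if i == 0 and config.control_pair is not None:
            h1, h2 = table[config.control_pair[0]], table[config.control_pair[1]]
        if h2.name < h1.name:
            h1, h2 = h2, h1
        samples.append({
            "sample_id": f"S{i + 1:0{width}d}",
            "hap1": h1.name, "hap2": h2.name,
            "profile": profile_from_pair(h1, h2),
        })
    return CohortTruth(samples=samples)


def synthesize_cq(truth: CohortTruth, config: SimConfig,
                  panel: AssayPanel | None = None) -> pd.DataFrame:
    """Per-well Cq values for all 10 reaction plates of a cohort.

    Returns a tidy table with columns ``plate, reaction, well, sample_id,
    replicate, locus, cq`` including the STAT6 reference rows; dropout wells
    (copy number 0) carry NaN.  Plates are named ``P<reaction>``.
    """
    panel = panel or load_assay_panel()
    if len(truth.samples) > 96:
        raise ConfigError("one plate set holds at most 96 samples; "
                          "simulate additional cohorts for more")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC9]))
    rows = []
    for rxn in panel.reactions:
        plate_id = f"P{rxn.reaction_number}"
        for s_index, sample in enumerate(truth.samples):
            wells = quadruplicate_wells(s_index)[: config.replicates]
            for replicate, well in enumerate(wells, start=1):
                if config.asymmetric_drift:
                    drift_kir = rng.normal(0.0, config.concentration_drift_sd)
                    drift_a, drift_b = drift_kir, rng.normal(
                        0.0, config.concentration_drift_sd)
                    drift_ref = rng.normal(0.0, config.concentration_drift_sd)
                    drifts = {rxn.target_a: drift_a, rxn.target_b: drift_b,
                              REFERENCE_LOCUS: drift_ref}
                else:
                    drift = rng.normal(0.0, config.concentration_drift_sd)
                    drifts = {rxn.target_a: drift, rxn.target_b: drift,
                              REFERENCE_LOCUS: drift}
                for locus in (rxn.target_a, rxn.target_b, REFERENCE_LOCUS):
                    noise = rng.normal(0.0, config.cq_noise_sd)
                    if locus == REFERENCE_LOCUS:
                        cq = config.stat6_baseline_cq + drifts[locus] + noise
                    else:
                        k = sample["profile"][locus]
                        if k == 0:
                            cq = np.nan
                        else:
                            cq = (config.kir_baseline_cq - np.log2(k)
                                  + drifts[locus] + noise)
                    rows.append((plate_id, rxn.reaction_number, well,
                                 sample["sample_id"], replicate, locus, cq))
    return pd.DataFrame(rows, columns=CQ_COLUMNS)


def write_cohort_exports(cq_table: pd.DataFrame, panel: AssayPanel,
                         out_dir: str | Path,
                         analysis_method: str = "second_derivative_max",
                         ) -> dict[str, int]:
    """Write one plate-export file per reaction plate plus a manifest.

    Returns the manifest (plate id -> reaction number); also written as
    ``manifest.csv`` in ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    for (plate_id, reaction), group in cq_table.groupby(["plate", "reaction"]):
        rxn = panel.reaction(int(reaction))
        rows = group.copy()
        rows["filter"] = rows["locus"].map(rxn.channel_map)
        rows = rows.rename(columns={"sample_id": "sample"})
        write_plate_export(out_dir / f"{plate_id}.txt", str(plate_id),
                           rows[["well", "sample", "filter", "cq"]],
                           analysis_method=analysis_method)
        manifest[str(plate_id)] = int(reaction)
    pd.DataFrame(sorted(manifest.items()), columns=["plate", "reaction"]).to_csv(
        out_dir / "manifest.csv", index=False)
    return manifest


@dataclass
class CurveParams:
    """Shape of synthetic amplification curves (logistic + baseline)."""

    slope: float = 0.8            # logistic steepness per cycle
    plateau: float = 10.0         # fluorescence units above baseline
    baseline: float = 0.05        # constant background fluorescence
    noise_sd: float = 0.0         # additive Gaussian fluorescence noise
    n_cycles: int = 40
    position_for: str = "second_derivative_max"   # which caller recovers Cq
    noise_band: float = 1.0       # threshold assumed by fit_points positioning

    # Offset between the logistic midpoint m and the second-derivative
    # maximum: the max of d2F/dc2 sits at m - ln(2+sqrt(3))/slope.
    @property
    def sdm_offset(self) -> float:
        return float(np.log(2.0 + np.sqrt(3.0)) / self.slope)


def synthesize_curves(cq_table: pd.DataFrame,
                      params: CurveParams | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Per-well amplification curves whose called Cq matches the table.

    For each (well, locus) row of ``cq_table`` a logistic curve
    ``F(c) = plateau / (1 + exp(-slope (c - m))) + baseline`` is generated
    with the midpoint ``m`` positioned so that the configured Cq-calling
    method recovers the row's Cq; dropout rows become flat baseline.
    Returns a long table (plate, reaction, well, sample_id, replicate,
    locus, cycle, fluorescence).
    """
    params = params or CurveParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCF]))
    cycles = np.arange(1, params.n_cycles + 1, dtype=float)
    frames = []
    for rec in cq_table.itertuples(index=False):
        if np.isnan(rec.cq):
            signal = np.full_like(cycles, params.baseline)
        else:
            if params.position_for == "second_derivative_max":
                m = rec.cq + params.sdm_offset
            elif params.position_for == "fit_points":
                # Exact band crossing of the logistic-plus-baseline curve:
                # band = plateau/(1+exp(-slope (c-m))) + baseline at c = cq.
                if params.noise_band <= params.baseline:
                    raise ConfigError("noise band must exceed the curve baseline")
                ratio = params.plateau / (params.noise_band - params.baseline) - 1.0
                if ratio <= 0:
                    raise ConfigError("noise band must sit below the plateau")
                m = rec.cq + np.log(ratio) / params.slope
            else:
                raise ConfigError(f"unknown positioning {params.position_for!r}")
            signal = params.plateau / (1.0 + np.exp(-params.slope * (cycles - m))) \
                + params.baseline
        if params.noise_sd > 0:
            signal = signal + rng.normal(0.0, params.noise_sd, size=len(cycles))
        frames.append(pd.DataFrame({
            "plate": rec.plate, "reaction": rec.reaction, "well": rec.well,
            "sample_id": rec.sample_id, "replicate": rec.replicate,
            "locus": rec.locus, "cycle": cycles.astype(int),
            "fluorescence": signal,
        }))
    return pd.concat(frames, ignore_index=True)
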