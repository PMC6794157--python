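"""Simulate a 96-sample qPCR cohort and write instrument-style exports.

Haplotype pairs are drawn under Hardy-Weinberg pairing from the built-in
synthetic reference table; each sample lands in quadruplicate on one
384-well plate per reaction, with Gaussian Cq noise and per-well DNA
concentration drift.
"""

from pathlib import Path

from qkat import SimConfig, load_assay_panel, sample_cohort, synthesize_cq, \
    write_cohort_exports

out = Path("scratch/example_cohort")
config = SimConfig(n_samples=96, seed=1, cq_noise_sd=0.1,
                   concentration_drift_sd=0.3,
                   control_pair=("A-2DS4FL", "A-2DS4FL"))
panel = load_assay_panel()

truth = sample_cohort(config)
pairs = [(s["hap1"], s["hap2"]) for s in truth.samples]
print(f"{len(pairs)} samples; first three pairs: {pairs[:3]}")

cq = synthesize_cq(truth, config, panel)
print(f"{len(cq)} well/channel measurements "
      f"({cq['cq'].isna().sum()} dropout wells = copy number 0)")

out.mkdir(parents=True, exist_ok=True)
truth.to_csv(out / "truth.csv")
manifest = write_cohort_exports(cq, panel, out)
print(f"wrote {len(manifest)} plate exports + manifest to {out}/")
# The exports feed the `qkat calltype` CLI or qkat.run_pipeline directly.
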