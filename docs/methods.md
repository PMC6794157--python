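# Methods

## Relative quantification model

The assay types 20 KIR measurements in ten multiplex reactions, each
reading two KIR targets (FAM and ATTO647N/Cy5 channels) and the two-copy
reference gene *STAT6* (ATTO550/yellow channel) from the same well.  The
copy-number model assumes 100% PCR efficiency — one cycle per template
doubling — so for copy number *k* > 0

    Cq_KIR(k) = C_locus − log2(k) + drift(well) + ε,
    Cq_STAT6  = C_ref            + drift(well) + ε′,

with `drift` the well's DNA-amount offset (shared by both channels of a
well, because both amplify the same aliquot) and ε Gaussian instrument
noise.  The within-well ΔCq = Cq_KIR − Cq_STAT6 removes `drift` exactly;
the between-sample ΔΔCq removes the locus constant `C_locus − C_ref`,
leaving CN̂ = CN₀·2^(−ΔΔCq).  Efficiency below 100%, probe cross-talk and
allele dropout (annotated per primer in the panel fixture) are not
modelled.

Zero copies produce no amplification at all.  They are therefore called
qualitatively — no Cq in at least half the replicate wells, with *STAT6*
intact — never by rounding a small estimate down.  Conversely an estimate
of exactly 0.5 rounds *up* (half-away-from-zero): a quantitative signal,
however weak, is evidence of at least one copy.  An absent *STAT6* makes
the well invalid (reference failure), not evidence of copy number 0.

## Replicates, calibration and confidence

Quadruplicate ΔCq values are combined by the median, with the median
absolute deviation kept and flagged above 0.5 cycles.  The median keeps
one bad well from dragging the aggregate; the ≥-half dropout rule
balances a single failed well against true absence.

Calibration is per plate and per locus, in one of two modes:

* **calibrator sample** — anchor (ΔCq, CN) from a control of known copy
  number.  Where the control's known copy number is 0 (it never
  amplifies), the locus falls back to the defaults-based anchor below and
  the call is flagged `calibrator_fallback`; an *unexpected* dropout of a
  nonzero-copy calibrator is an error.
* **most frequent copy number** — anchor at the median ΔCq of the
  plate's amplifying samples, paired with the packaged per-locus default.
  The defaults table is read as the modal copy number *among amplifying
  samples*: samples with zero copies contribute no ΔCq, so they cannot be
  part of the cluster the anchor identifies.  (Read as unconditional
  marginal modes the printed defaults would be arithmetically
  inconsistent with the allelic-pair relations — e.g. 2DL2+2DL3 = 2
  forces mode(2DL3) = 2 − mode(2DL2).)  The plate median equals the modal
  cluster's centre whenever that cluster holds a majority of amplifying
  samples, which the built-in cohort design guarantees (≥ 0.62 at every
  locus); cohorts where a default class is not the majority need a
  calibrator sample instead.

The per-call confidence is `max(0, 1 − 2·|CN̂ − CN|/max(CN, 1))` — 1 when
the estimate sits on the integer, 0 at the rounding boundary.  Vendor
confidence metrics are proprietary; this definition is the package's own
and is reported as such.  Calls above 8 copies are capped and flagged
implausible.  Calibration mode-or-batch granularity is per plate (each
plate carries its own control well in the assay design).

## Cq extraction

* **Second derivative maximum.**  The fluorescence trace is fitted with a
  quintic smoothing spline whose smoothing factor is `n·σ̂²`, where σ̂ is
  a robust (MAD-based) noise estimate from successive differences over
  the baseline cycles 3–12; on noiseless data the spline interpolates.
  The Cq is the location of the spline's second-derivative maximum found
  by bounded optimisation, checked in tests against the analytic logistic
  location m − ln(2+√3)/k (error ≤ 0.02 cycles at typical steepness
  k = 0.8; ≤ 0.06 for k in 0.7–1.2).  Plain Savitzky-Golay differencing
  (window 5, order 3) was evaluated and rejected: its window bias shifts
  the curvature peak by −0.17 cycles at k = 0.8 and −0.33 at k = 1.2.
  Known limitation: for unusually shallow curves (k < 0.6) the early
  signal rise leaks into the baseline-noise estimate and the bias can
  reach ~0.15 cycles; because the offset is almost translation-invariant
  it still cancels in ΔΔCq.
* **Fit points.**  Log-linear least squares through the first 3 cycles
  above the user-set noise band; the Cq is the fitted band crossing.
  Exact on a pure exponential; doubling the band adds exactly one cycle
  at 100% efficiency.  Fewer than 3 above-band cycles, a non-positive
  fitted slope, or a crossing outside the observed cycle range yield an
  absent Cq.
* **Flat-curve classification** uses the signal rise (median of the last
  three cycles minus the baseline median) against 5× the baseline noise
  sd, strict inequality, with a tiny floor on the sd so noiseless flat
  traces classify as flat.

The two methods differ by a constant offset on ideal curves; since
calibrator and samples are analysed with the same method, the offset
cancels in ΔΔCq.

## Synthetic cohorts

The generator emulates the study design: Hardy-Weinberg pairing of
reference haplotypes (no inbreeding or population structure), 96 samples
per plate set, quadruplicate wells laid out as 2×2 blocks on 384-well
plates, one plate per reaction.  Defaults — Cq noise sd 0.1 cycles,
concentration drift sd 0.3 cycles — are plausible instrument magnitudes
chosen once as configuration, not measured claims.  Drift is drawn per
well and shared across that well's channels; the `asymmetric_drift` mode
draws it per channel instead, which breaks the ΔCq cancellation and
reproduces the copy-number scatter characteristic of plates with uneven
DNA concentrations.  Amplification curves, when requested, are logistic
(steepness 0.8/cycle, plateau 10 units, baseline 0.05) with the midpoint
placed so the configured Cq method recovers the target Cq exactly
(analytic second-derivative offset, or the exact band-crossing of the
logistic-plus-baseline for fit points).

The packaged reference table is **synthetic**: six haplotypes (the two
canonical A-group forms, differing in full-length vs 22-bp-deleted 2DS4,
and four B-group configurations) satisfying all per-haplotype structural
constraints.  Frequencies (0.40/0.27/0.10/0.07/0.11/0.05) were chosen so
that at every locus the modal copy number among amplifying samples equals
the packaged defaults with a ≥ 0.62 majority, and so that all 21 unordered
pair profiles are distinct (noise-free imputation recovers the true pair
uniquely).  Real European reference lists are larger and contain ambiguous
pairs and rarer haplotypes; passing tests on the synthetic table therefore
demonstrate the machinery (enumeration, ranking, trimming, unassignment),
not population-level imputation accuracy.  User tables are supplied as CSV
(name, frequency, one column per locus) and validated on load.

## LD rules and imputation

Rules are stored as coefficient data (`ld_rules.csv`), one equality per
row, grouped into the ten published European-population checks; rule 1 is
evaluated over the five framework measurement columns (3DL2 is measured
twice) and rule 9's haplotype-level exclusivity is implemented as the
printed arithmetic 2DS1+2DS4Total = 2.  Every panel locus appears in at
least one equality, so any single-locus ±1 error breaks at least one rule
(verified exhaustively over all built-in pairs).  Violations annotate —
they never suppress — downstream imputation, matching the workflow's
"re-check the raw data" role; profiles with distrusted loci can wildcard
them explicitly during matching instead.

Imputation enumerates all unordered reference pairs (self-pairs included)
over the 20 measured loci; the exon-4/exon-9 and 2DS4-variant columns all
participate in matching.  Combined pair frequency uses the Hardy-Weinberg
2·f₁·f₂ heterozygote factor; trimming keeps all ties at the maximum.

## Numerical and interface choices

* GC% is rounded half-away-from-zero to one decimal; amplicon length is
  `rev.end − fwd.start + 1` on the 1-based inclusive coding-sequence
  coordinates of the panel fixture.  The 3DL3 assay has two forward
  primers and uses the outermost start; *STAT6* primers carry no
  coordinates, so its 129 bp amplicon is a stored literal and excluded
  from recomputation.  Printed melting temperatures are carried as
  annotations only (the underlying melting model is not specified), as is
  the per-primer list of alleles at risk of dropout.
* The plate-export dialect is a documented tab-delimited format (header
  `well/sample/filter/cq`, `#`-prefixed metadata, empty Cq = dropout);
  vendor files need only a column rename.  Row-level problems are
  collected with line numbers, never silently dropped.  Plate→reaction
  assignment uses an explicit manifest CSV rather than a file-naming
  convention.
* Problem sizes in the test suite follow the assay's plate design — 96
  samples × 4 replicates × 10 reactions; the noise-robustness check runs
  20 such cohorts.
* The pipeline is deterministic given inputs and seed; outputs carry no
  timestamps, so repeated runs are byte-identical.
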