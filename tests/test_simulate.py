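"""Synthetic cohort generator: sampling, Cq model, curve synthesis."""

import numpy as np
import pandas as pd
import pytest

from qkat import (CurveParams, HaplotypeTable, SimConfig, check_profile,
                  sample_cohort, second_derivative_max_cq, synthesize_cq,
                  synthesize_curves, AmplificationCurve, fit_points_cq)
from qkat.errors import ConfigError
from qkat.loci import REFERENCE_LOCUS


def test_same_seed_reproduces_cohort(builtin_table):
    config = SimConfig(n_samples=20, seed=42)
    a = sample_cohort(config).to_frame()
    b = sample_cohort(config).to_frame()
    pd.testing.assert_frame_equal(a, b)


def test_degenerate_table_yields_homozygotes(builtin_table):
    only_a = HaplotypeTable([h for h in builtin_table if h.name == "A-2DS4FL"])
    config = SimConfig(n_samples=10, seed=0, haplotype_table=only_a)
    truth = sample_cohort(config)
    assert all(s["hap1"] == s["hap2"] == "A-2DS4FL" for s in truth.samples)


def test_truth_profiles_conform_to_ld_rules(builtin_table):
    truth = sample_cohort(SimConfig(n_samples=50, seed=3))
    for sample in truth.samples:
        assert check_profile(sample["profile"]).conforms


def test_empty_table_is_config_error():
    with pytest.raises(ConfigError):
        sample_cohort(SimConfig(n_samples=5, haplotype_table=HaplotypeTable([])))


def test_control_pair_is_first_sample(builtin_table):
    config = SimConfig(n_samples=5, seed=0, control_pair=("B-01", "A-2DS4FL"))
    truth = sample_cohort(config)
    assert {truth.samples[0]["hap1"], truth.samples[0]["hap2"]} == {"B-01", "A-2DS4FL"}


class TestCqModel:
    def _cq_for(self, panel, pair, locus, seed=0):
        table_cfg = SimConfig(n_samples=1, seed=seed, cq_noise_sd=0.0,
                              concentration_drift_sd=0.0, control_pair=pair)
        truth = sample_cohort(table_cfg)
        cq = synthesize_cq(truth, table_cfg, panel)
        return cq[cq["locus"] == locus]["cq"]

    def test_one_copy_vs_two_copies_differ_by_one_cycle(self, panel):
        # log2 model: doubling the copy number lowers the Cq by one cycle.
        two = float(self._cq_for(panel, ("A-2DS4FL", "A-2DS4FL"), "2DL4").iloc[0])
        one = float(self._cq_for(panel, ("A-2DS4FL", "B-01"), "2DL5").iloc[0])
        assert two == pytest.approx(one - 1.0, abs=1e-9)

    def test_zero_copies_dropout_all_four_wells(self, panel):
        values = self._cq_for(panel, ("A-2DS4FL", "A-2DS4FL"), "3DS1")
        assert len(values) == 4 and values.isna().all()

    def test_delta_cq_invariant_to_drift(self, panel):
        """Concentration drift hits both channels of a well equally, so the
        within-well delta-Cq carries no drift at all."""
        config = SimConfig(n_samples=4, seed=5, cq_noise_sd=0.0,
                           concentration_drift_sd=1.5)
        truth = sample_cohort(config)
        cq = synthesize_cq(truth, config, panel)
        wide = cq.pivot_table(index=["reaction", "sample_id", "replicate"],
                              columns="locus", values="cq", aggfunc="first",
                              dropna=False)
        for rxn in panel.reactions:
            sub = wide.loc[rxn.reaction_number]
            for locus in rxn.targets:
                dcq = (sub[locus] - sub[REFERENCE_LOCUS]).dropna()
                # one distinct value per sample-independent copy number
                for sample_id, group in dcq.groupby(level="sample_id"):
                    assert group.nunique() == 1

    def test_asymmetric_drift_breaks_the_invariance(self, panel):
        config = SimConfig(n_samples=4, seed=5, cq_noise_sd=0.0,
                           concentration_drift_sd=1.5, asymmetric_drift=True)
        truth = sample_cohort(config)
        cq = synthesize_cq(truth, config, panel)
        wide = cq.pivot_table(index=["reaction", "sample_id", "replicate"],
                              columns="locus", values="cq", aggfunc="first",
                              dropna=False)
        sub = wide.loc[5]
        dcq = (sub["2DL4"] - sub[REFERENCE_LOCUS]).dropna()
        spread = dcq.groupby(level="sample_id").agg(lambda g: g.max() - g.min())
        assert (spread > 0.1).any()


class TestCurves:
    def _one_row_table(self, cq):
        return pd.DataFrame([{"plate": "P5", "reaction": 5, "well": "A1",
                              "sample_id": "S1", "replicate": 1,
                              "locus": "2DL4", "cq": cq}])

    def test_sdm_positioning_recovers_target_cq(self):
        curves = synthesize_curves(self._one_row_table(23.0),
                                   CurveParams(noise_sd=0.0))
        trace = curves.sort_values("cycle")
        result = second_derivative_max_cq(AmplificationCurve(
            "A1", "x", trace["cycle"].to_numpy(float),
            trace["fluorescence"].to_numpy()))
        assert result.cq == pytest.approx(23.0, abs=0.05)

    def test_fit_points_positioning_recovers_target_cq(self):
        params = CurveParams(noise_sd=0.0, position_for="fit_points",
                             noise_band=0.5)
        curves = synthesize_curves(self._one_row_table(23.0), params)
        trace = curves.sort_values("cycle")
        result = fit_points_cq(AmplificationCurve(
            "A1", "x", trace["cycle"].to_numpy(float),
            trace["fluorescence"].to_numpy()), noise_band=0.5)
        assert result.cq == pytest.approx(23.0, abs=0.05)

    def test_dropout_row_becomes_flat_baseline(self):
        curves = synthesize_curves(self._one_row_table(np.nan),
                                   CurveParams(noise_sd=0.0))
        assert curves["fluorescence"].nunique() == 1
        trace = curves.sort_values("cycle")
        result = second_derivative_max_cq(AmplificationCurve(
            "A1", "x", trace["cycle"].to_numpy(float),
            trace["fluorescence"].to_numpy()))
        assert result.cq is None

    def test_midpoint_shift_translates_recovered_cq(self):
        cqs = []
        for target in (20.0, 25.0):
            curves = synthesize_curves(self._one_row_table(target),
                                       CurveParams(noise_sd=0.0))
            trace = curves.sort_values("cycle")
            cqs.append(second_derivative_max_cq(AmplificationCurve(
                "A1", "x", trace["cycle"].to_numpy(float),
                trace["fluorescence"].to_numpy())).cq)
        assert cqs[1] - cqs[0] == pytest.approx(5.0, abs=0.01)
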