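"""Delta-delta-Cq copy-number calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qkat import (AggregatedDeltaCq, Anchor, SimConfig, aggregate_replicates,
                  build_profiles, calibrate, call_copy_number, call_cq_table,
                  sample_cohort, synthesize_cq, well_delta_cq)
from qkat.calling import round_half_away_from_zero
from qkat.errors import CalibrationError, ValidationError


@pytest.mark.parametrize("kir,stat6,expected", [
    (25.0, 25.0, 0.0),
    (26.0, 25.0, 1.0),
    (24.0, 25.0, -1.0),
])
def test_well_delta_cq(kir, stat6, expected):
    assert well_delta_cq(kir, stat6) == expected


def test_absent_stat6_is_reference_failure_not_copy_zero():
    with pytest.raises(ValidationError, match="reference"):
        well_delta_cq(25.0, float("nan"))


class TestAggregateReplicates:
    def test_clean_quadruplicate(self):
        agg = aggregate_replicates([1.0, 1.0, 1.0, 1.0])
        assert (agg.delta_cq, agg.n_used, agg.dispersion) == (1.0, 4, 0.0)

    def test_all_dropout(self):
        agg = aggregate_replicates([math.nan] * 4)
        assert agg.is_dropout and agg.n_used == 0

    def test_median_robust_to_one_outlier(self):
        agg = aggregate_replicates([0.9, 1.0, 1.1, 9.0])
        assert agg.delta_cq == pytest.approx(1.05)
        assert agg.n_used == 4 and agg.dispersion < 0.2

    @pytest.mark.parametrize("values,expect_dropout", [
        ([math.nan, math.nan, 1.0, 1.0], True),    # half dropped: dropout
        ([math.nan, 1.0, 1.0, 1.0], False),
        ([math.nan, 1.0], True),
    ])
    def test_half_dropout_rule(self, values, expect_dropout):
        assert aggregate_replicates(values).is_dropout is expect_dropout


class TestCalibrate:
    def _plate(self, values):
        return {f"S{i}": AggregatedDeltaCq(v, 4, 0.0) for i, v in enumerate(values)}

    def test_calibrator_mode_is_identity_anchor(self):
        plate = self._plate([0.7, 1.0, 1.3, 0.9, 1.1, 0.8])
        anchor = calibrate(plate, "2DL4", "calibrator_sample",
                           calibrator_id="S0", calibrator_cn=2)
        assert (anchor.delta_cq, anchor.copy_number) == (0.7, 2)
        assert anchor.source == "calibrator"

    def test_most_frequent_mode_uses_plate_median_and_default(self, panel):
        plate = self._plate([1.0, 1.2, 0.8, 1.1, 0.9, 1.0])
        for locus, expected_cn in (("3DS1", 1), ("2DL4", 2)):
            anchor = calibrate(plate, locus, "most_frequent_cn",
                               default_cn=panel.default_copy_number[locus])
            assert anchor.copy_number == expected_cn
            assert anchor.delta_cq == pytest.approx(1.0)

    def test_missing_calibrator_raises(self):
        with pytest.raises(CalibrationError, match="absent"):
            calibrate(self._plate([1.0] * 6), "2DL4", "calibrator_sample",
                      calibrator_id="nope", calibrator_cn=2)

    def test_dropout_calibrator_with_nonzero_cn_raises(self):
        plate = self._plate([1.0] * 6)
        plate["S0"] = AggregatedDeltaCq(None, 0, None)
        with pytest.raises(CalibrationError, match="dropped out"):
            calibrate(plate, "2DL4", "calibrator_sample",
                      calibrator_id="S0", calibrator_cn=2)

    def test_zero_cn_calibrator_falls_back_to_defaults(self):
        plate = self._plate([1.0] * 6)
        plate["S0"] = AggregatedDeltaCq(None, 0, None)
        anchor = calibrate(plate, "3DS1", "calibrator_sample",
                           calibrator_id="S0", calibrator_cn=0, default_cn=1)
        assert anchor.source == "default_fallback" and anchor.copy_number == 1

    def test_too_few_samples_for_most_frequent_mode(self):
        with pytest.raises(CalibrationError, match="amplifying samples"):
            calibrate(self._plate([1.0, 1.1]), "2DL4", "most_frequent_cn",
                      default_cn=2)

    def test_modes_agree_when_calibrator_sits_at_plate_median(self):
        values = [0.8, 0.9, 1.0, 1.1, 1.2]
        plate = self._plate(values)
        mode1 = calibrate(plate, "2DL4", "calibrator_sample",
                          calibrator_id="S2", calibrator_cn=2)
        mode2 = calibrate(plate, "2DL4", "most_frequent_cn", default_cn=2)
        assert mode1.delta_cq == mode2.delta_cq
        assert mode1.copy_number == mode2.copy_number


class TestCallCopyNumber:
    def _call(self, dcq, anchor_dcq=0.0, anchor_cn=2):
        agg = AggregatedDeltaCq(dcq, 4, 0.0)
        return call_copy_number("S1", "2DL4", agg, Anchor(anchor_dcq, anchor_cn, "calibrator"))

    def test_zero_ddcq_is_anchor_copy_number(self):
        call = self._call(0.0)
        assert (call.cn_estimate, call.cn_called, call.confidence) == (2.0, 2, 1.0)

    def test_one_cycle_earlier_doubles(self):
        call = self._call(-1.0)
        assert call.cn_estimate == pytest.approx(4.0) and call.cn_called == 4

    def test_half_copy_ties_away_from_zero(self):
        call = self._call(1.0, anchor_cn=1)
        assert call.cn_estimate == pytest.approx(0.5)
        assert call.cn_called == 1  # a zero call requires real non-amplification
        assert "low_confidence" in call.flags

    def test_dropout_calls_zero(self):
        call = call_copy_number("S1", "3DS1", AggregatedDeltaCq(None, 0, None),
                                Anchor(0.0, 1, "plate_median"))
        assert (call.cn_called, call.cn_estimate) == (0, 0.0)

    def test_estimate_within_half_copy_of_call(self):
        for dcq in np.linspace(-1.8, 1.8, 25):
            call = self._call(float(dcq))
            assert abs(call.cn_estimate - call.cn_called) <= 0.5 + 1e-12

    def test_implausible_calls_are_capped_and_flagged(self):
        call = self._call(-3.0)   # estimate 16
        assert call.cn_called == 8 and "implausible" in call.flags


@settings(derandomize=True, max_examples=40)
@given(dcq=st.floats(min_value=-2.0, max_value=2.0),
       step=st.floats(min_value=0.01, max_value=1.0))
def test_estimate_strictly_decreasing_in_delta_cq(dcq, step):
    anchor = Anchor(0.0, 2, "calibrator")
    lo = call_copy_number("S", "2DL4", AggregatedDeltaCq(dcq, 4, 0.0), anchor)
    hi = call_copy_number("S", "2DL4", AggregatedDeltaCq(dcq + step, 4, 0.0), anchor)
    assert hi.cn_estimate < lo.cn_estimate


@pytest.mark.parametrize("value,expected", [(0.5, 1), (1.5, 2), (2.49, 2), (2.5, 3)])
def test_round_half_away_from_zero(value, expected):
    assert round_half_away_from_zero(value) == expected


class TestBuildProfiles:
    def _calls(self, panel, cq, mode="most_frequent_cn", **kw):
        return call_cq_table(cq, panel, mode=mode, **kw)

    def test_noise_free_round_trip_both_modes(self, panel, noise_free_cohort):
        config, truth, cq = noise_free_cohort
        for mode, kw in (("most_frequent_cn", {}),
                         ("calibrator_sample",
                          {"calibrator_id": "S001",
                           "calibrator_profile": truth.profile("S001")})):
            profiles = build_profiles(self._calls(panel, cq, mode, **kw))
            for profile in profiles:
                assert profile.copy_numbers == truth.profile(profile.sample_id), \
                    (mode, profile.sample_id)

    def test_missing_reaction_flags_its_loci(self, panel, noise_free_cohort):
        _, truth, cq = noise_free_cohort
        without_r5 = cq[cq["reaction"] != 5]
        profiles = build_profiles(self._calls(panel, without_r5))
        prof = profiles[0]
        assert "3DS1" not in prof.copy_numbers and "2DL4" not in prof.copy_numbers
        assert prof.flags["3DS1"] == ["missing"] and prof.flags["2DL4"] == ["missing"]

    def test_concordant_duplicate_plates_merge_silently(self, panel, noise_free_cohort):
        _, truth, cq = noise_free_cohort
        r5 = cq[cq["reaction"] == 5]
        duplicate = r5.assign(plate="P5bis")
        calls = self._calls(panel, __import__("pandas").concat([cq, duplicate]))
        profiles = build_profiles(calls)
        for prof in profiles:
            assert prof.copy_numbers == truth.profile(prof.sample_id)
            assert "conflict" not in [f for fl in prof.flags.values() for f in fl]

    def test_discordant_duplicate_is_conflict_flag(self):
        from qkat.calling import CopyNumberCall

        def call(cn, conf, plate):
            return CopyNumberCall(sample_id="S1", locus="2DL4", delta_cq=0.0,
                                  ddcq=0.0, cn_estimate=float(cn), cn_called=cn,
                                  confidence=conf, n_replicates_used=4, plate=plate)

        profiles = build_profiles([call(2, 0.9, "P5"), call(3, 0.4, "P5bis")],
                                  expected_loci=("2DL4",))
        assert profiles[0].copy_numbers["2DL4"] == 2      # higher confidence wins
        assert "conflict" in profiles[0].flags["2DL4"]
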