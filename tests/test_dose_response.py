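"""Tests of the FAC dilution ladder, threshold calling and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slicequant.cohorts import reference_cohort, reference_thresholds
from slicequant.dose_response import (
    NonMonotoneFlagsWarning,
    ReadoutSeries,
    build_dilution_table,
    call_threshold,
    classify_threshold,
    classify_tumor,
    cohort_counts,
    edu_effect_flags,
    tunel_effect_flags,
)
from slicequant.pipeline import DoseResponseCriteria, simulate_and_recover
from slicequant.quantify import SliceSummary
from slicequant.simulate import FieldSpec, TumorSimProfile

# the printed FAC ladder: (dilution, 5-FU μM, doxorubicin μM, 4-HC μM)
EXPECTED_TABLE = [
    (1, 460.0, 10.0, 220.0),
    (2, 230.0, 5.0, 110.0),
    (3, 115.0, 2.5, 55.0),
    (4, 46.0, 1.0, 22.0),
    (5, 23.0, 0.5, 11.0),
    (6, 11.5, 0.25, 5.5),
    (7, 4.6, 0.1, 2.2),
    (8, 2.3, 0.05, 1.1),
    (9, 1.15, 0.025, 0.55),
    (10, 0.46, 0.01, 0.22),
    (11, 0.0, 0.0, 0.0),
]


class TestDilutionTable:
    def test_reproduces_all_33_concentrations(self):
        table = build_dilution_table().table
        for d, c5, cd, c4 in EXPECTED_TABLE:
            row = table[table["dilution"] == d].iloc[0]
            assert row["c_5fu_um"] == pytest.approx(c5, rel=1e-12)
            assert row["c_dox_um"] == pytest.approx(cd, rel=1e-12)
            assert row["c_4hc_um"] == pytest.approx(c4, rel=1e-12)

    def test_decade_spacing_every_three_steps(self):
        series = build_dilution_table()
        for d in range(1, 8):
            for drug in ("5fu", "dox", "4hc"):
                assert series.concentration(d, drug) / series.concentration(
                    d + 3, drug
                ) == pytest.approx(10.0, rel=1e-12)

    def test_molar_ratio_invariant_across_rows(self):
        series = build_dilution_table()
        for d in range(1, 11):
            cd = series.concentration(d, "dox")
            assert series.concentration(d, "5fu") / cd == pytest.approx(46.0)
            assert series.concentration(d, "4hc") / cd == pytest.approx(22.0)

    def test_control_row_zero(self):
        series = build_dilution_table()
        assert all(series.concentration(11, drug) == 0 for drug in ("5fu", "dox", "4hc"))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_dilution_table(top_c_dox=0)
        with pytest.raises(ValueError):
            build_dilution_table(ratio=(46, -1, 22))


def _series(readout, medians, control_median, control_iqr=1.0):
    """ReadoutSeries from plain per-dilution medians."""
    summaries = {}
    for d, med in medians.items():
        summaries[d] = SliceSummary(
            n_fields=10,
            proliferation_index_median=med,
            tunel_pct_median=med,
            tunel_pct_iqr=0.5,
        )
    summaries[11] = SliceSummary(
        n_fields=10,
        proliferation_index_median=control_median,
        tunel_pct_median=control_median,
        tunel_pct_iqr=control_iqr,
    )
    return ReadoutSeries(readout, summaries=summaries)


class TestEffectFlags:
    def test_edu_no_flags_when_equal_to_control(self):
        s = _series("edu", {d: 10.0 for d in range(2, 8)}, 10.0)
        assert not any(edu_effect_flags(s).values())

    def test_edu_all_zero_all_flagged(self):
        s = _series("edu", {d: 0.0 for d in range(2, 8)}, 10.0)
        assert all(edu_effect_flags(s).values())

    def test_edu_missing_control(self):
        summaries = {2: SliceSummary(proliferation_index_median=1.0)}
        s = ReadoutSeries("edu", summaries=summaries)
        with pytest.raises(ValueError, match="control"):
            edu_effect_flags(s)

    def test_tunel_no_flags_when_equal_to_control(self):
        s = _series("tunel", {d: 2.0 for d in range(2, 8)}, 2.0, control_iqr=1.0)
        assert not any(tunel_effect_flags(s).values())

    def test_tunel_strong_induction_flagged(self):
        # control median 2%, IQR 1% -> cut 3.5%; 40% at dilution 2 flags
        s = _series("tunel", {2: 40.0, 3: 2.0}, 2.0, control_iqr=1.0)
        flags = tunel_effect_flags(s)
        assert flags == {2: True, 3: False}

    def test_edu_recovery_threshold_5(self):
        """A tumor switching at dilution 5 yields flags exactly {1..5} in
        >= 90% of seeds at default noise."""
        prof = TumorSimProfile(tumor_id="T", true_threshold=5)
        hits = 0
        for seed in range(10):
            rec = simulate_and_recover(
                [prof],
                dilutions=range(1, 8),
                spec=FieldSpec(seed=3000 + seed),
                render=False,
            )
            hits += rec["T"] == 5
        assert hits >= 9

    def test_tunel_recovery_resistant_profile(self):
        """A resistant tumor (threshold 2) flags only dilutions {1, 2} in
        >= 90% of seeds at default noise."""
        prof = TumorSimProfile(tumor_id="T", true_threshold=2)
        hits = 0
        for seed in range(10):
            rec = simulate_and_recover(
                [prof],
                dilutions=range(1, 8),
                spec=FieldSpec(seed=4000 + seed),
                readout="tunel",
                render=False,
            )
            hits += rec["T"] == 2
        assert hits >= 9


class TestCallThreshold:
    def test_worked_example_flags_2_3(self):
        flags = {2: True, 3: True, 4: False, 5: False, 6: False, 7: False}
        assert call_threshold(flags) == 3

    def test_no_flags_none(self):
        assert call_threshold({d: False for d in range(2, 8)}) is None

    def test_isolated_weak_flag_ignored_with_warning(self):
        flags = {2: True, 3: True, 4: False, 5: True, 6: False, 7: False}
        with pytest.warns(NonMonotoneFlagsWarning):
            assert call_threshold(flags) == 3

    def test_empty_flags_error(self):
        with pytest.raises(ValueError, match="empty"):
            call_threshold({})

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        flags=st.lists(st.booleans(), min_size=1, max_size=9),
        flip=st.integers(min_value=0, max_value=8),
    )
    def test_monotone_under_flag_growth(self, flags, flip):
        """Turning a false flag true never decreases the threshold."""
        flip = flip % len(flags)
        base = {d + 1: f for d, f in enumerate(flags)}
        grown = dict(base)
        grown[flip + 1] = True
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonMonotoneFlagsWarning)
            t0 = call_threshold(base)
            t1 = call_threshold(grown)
        assert (t0 or 0) <= (t1 or 0)


class TestClassification:
    @pytest.mark.parametrize(
        "threshold, expected",
        [
            (7, "sensitive"),
            (8, "sensitive"),
            (2, "resistant"),
            (1, "resistant"),
            (None, "resistant"),
            (5, "intermediate"),
            (3, "intermediate"),
        ],
    )
    def test_class_boundaries(self, threshold, expected):
        assert classify_threshold(threshold) == expected

    def test_classify_tumor_per_readout(self):
        p = classify_tumor("072", {"morphology": 2, "edu": 2, "tunel": 2})
        assert set(p.classes.values()) == {"resistant"}

    def test_deterministic_and_order_independent(self):
        flags = {2: True, 3: True, 4: False}
        t1 = call_threshold(dict(sorted(flags.items())))
        t2 = call_threshold(dict(sorted(flags.items(), reverse=True)))
        assert t1 == t2
        assert classify_threshold(t1) == classify_threshold(t2)


class TestCohortCounts:
    def test_reference_morphology_split(self):
        profiles = [
            classify_tumor(t, {"morphology": thr})
            for t, thr in reference_thresholds("morphology").items()
        ]
        counts, missing = cohort_counts(profiles, "morphology")
        assert counts == {2: 3, 3: 7, 5: 5}
        assert missing == 0
        assert sum(counts.values()) == 15

    def test_missing_values_reported_separately(self):
        profiles = [
            classify_tumor(t, {"edu": thr})
            for t, thr in reference_thresholds("edu").items()
        ]
        counts, missing = cohort_counts(profiles, "edu")
        assert missing == 1  # one tumor's EdU threshold was not available
        assert sum(counts.values()) == 14

    def test_single_profile(self):
        counts, missing = cohort_counts([classify_tumor("T", {"edu": 4})], "edu")
        assert counts == {4: 1} and missing == 0

    def test_reference_cohort_shape(self):
        df = reference_cohort()
        assert len(df) == 15
        assert df["threshold_morphology"].isin([2, 3, 5]).all()
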