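import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mscox.cohort import (
    build_person_period,
    categorize_sbp,
    classify_treatment,
    locf_impute,
)
from mscox.errors import (
    ConfigurationError,
    InvalidMeasurementError,
    MalformedInputError,
    MissingBaselineError,
)

from conftest import make_baseline, make_visits


class TestCategorizeSbp:
    @pytest.mark.parametrize(
        "sbp,expected",
        [
            (119.9, "tight"),
            (120.0, "usual"),
            (139.999, "usual"),
            (140.0, "uncontrolled"),
            (149.5, "uncontrolled"),
            (80.0, "tight"),
        ],
    )
    def test_boundaries(self, sbp, expected):
        assert categorize_sbp(sbp) == expected

    def test_vectorized(self):
        out = categorize_sbp([110.0, 125.0, 160.0])
        assert list(out) == ["tight", "usual", "uncontrolled"]

    @pytest.mark.parametrize("bad", [0.0, -10.0, np.nan, np.inf])
    def test_invalid_measurements(self, bad):
        with pytest.raises(InvalidMeasurementError):
            categorize_sbp(bad)

    @given(st.floats(min_value=1e-3, max_value=400.0, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_partitions_and_monotone(self, sbp):
        """Every positive SBP gets exactly one category, monotone in SBP."""
        order = {"tight": 0, "usual": 1, "uncontrolled": 2}
        cat = categorize_sbp(sbp)
        assert cat in order
        higher = categorize_sbp(min(sbp + 25.0, 400.0))
        assert order[higher] >= order[cat]


class TestClassifyTreatment:
    @pytest.mark.parametrize(
        "n_drugs,threshold,expected",
        [(3, 3, 1), (3, 4, 0), (0, 2, 0), (2, 2, 1), (5, 3, 1), (2, 3, 0)],
    )
    def test_thresholds(self, n_drugs, threshold, expected):
        assert classify_treatment(n_drugs, threshold) == expected

    def test_unsupported_threshold(self):
        with pytest.raises(ConfigurationError):
            classify_treatment(3, 5)

    def test_vectorized(self):
        out = classify_treatment(np.array([0, 2, 3, 4]), 3)
        assert list(out) == [0, 0, 1, 1]


class TestLocf:
    def test_fills_gap_with_last_observed(self):
        v = make_visits("a", [2, 3], [150.0, 130.0], visits=[0, 2])
        out = locf_impute(v)
        assert list(out["visit"]) == [0, 1, 2]
        filled = out[out["visit"] == 1].iloc[0]
        assert filled["sbp"] == 150.0
        assert filled["n_drugs"] == 2
        assert filled["observed"] == 0
        assert filled["event"] == 0

    def test_fully_observed_unchanged(self):
        v = make_visits("a", [2, 2, 3], [150.0, 145.0, 140.0])
        out = locf_impute(v)
        pd.testing.assert_frame_equal(out, v[out.columns], check_dtype=False)

    def test_nothing_extended_past_last_visit(self):
        v = make_visits("a", [2], [150.0])
        out = locf_impute(v)
        assert len(out) == 1 and out["visit"].iloc[0] == 0

    def test_idempotent(self):
        v = pd.concat(
            [
                make_visits("a", [2, 3], [150.0, 130.0], visits=[0, 3]),
                make_visits("b", [1, 2, 2], [140.0, 139.0, 138.0], visits=[0, 1, 4]),
            ],
            ignore_index=True,
        )
        once = locf_impute(v)
        twice = locf_impute(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_baseline_raises(self):
        with pytest.raises(MissingBaselineError):
            locf_impute(make_visits("a", [2], [150.0], visits=[3]))
        with pytest.raises(MissingBaselineError):
            locf_impute(pd.DataFrame(columns=["subject_id", "visit"]))

    def test_visit_bounds(self):
        v = make_visits("a", [2, 2], [150.0, 150.0], visits=[0, 14])
        with pytest.raises(MalformedInputError):
            locf_impute(v)


class TestBuildPersonPeriod:
    def test_monotone_recoding(self):
        """A drug count dipping back below threshold stays 'exposed'."""
        baselines = pd.DataFrame([make_baseline("a")])
        v = make_visits("a", [2, 2, 3, 2, 3], [150.0] * 5)
        ppt, info = build_person_period(baselines, v, 3)
        assert list(ppt["exposure"]) == [0, 0, 1, 1, 1]
        assert info.n_recoded_exposure == 1
        assert list(ppt["at_risk_initiation"]) == [1, 1, 1, 0, 0]

    def test_truncates_after_first_event(self):
        baselines = pd.DataFrame([make_baseline("a")])
        v = make_visits("a", [2] * 6, [150.0] * 6, event=[0, 0, 0, 0, 1, 0])
        ppt, info = build_person_period(baselines, v, 3)
        assert list(ppt["visit"]) == [0, 1, 2, 3, 4]
        assert info.n_rows_dropped_post_event == 1
        assert ppt["event"].iloc[-1] == 1

    def test_never_treated_full_follow_up(self):
        baselines = pd.DataFrame([make_baseline("a")])
        v = make_visits("a", [2] * 14, [150.0] * 14)
        ppt, _ = build_person_period(baselines, v, 3)
        assert len(ppt) == 14
        assert (ppt["exposure"] == 0).all()
        assert (ppt["event"] == 0).all()
        assert (ppt["at_risk_initiation"] == 1).all()

    def test_person_time_conserved(self, tiny_cohort):
        baselines, visits = tiny_cohort
        ppt, info = build_person_period(baselines, visits, 3)
        expected = visits.groupby("subject_id")["visit"].max().add(1).sum()
        assert info.n_rows == len(ppt) == expected

    def test_lag_columns(self, tiny_cohort):
        baselines, visits = tiny_cohort
        ppt, _ = build_person_period(baselines, visits, 3)
        a = ppt[ppt["subject_id"] == "a"]
        # lag at visit 0 falls back to the baseline category
        assert a["sbp_cat_lag"].iloc[0] == a["sbp_cat_base"].iloc[0]
        assert a["sbp_cat_lag"].iloc[1] == a["sbp_cat"].iloc[0]

    def test_censoring_flag_on_final_row(self, tiny_cohort):
        baselines, visits = tiny_cohort
        ppt, _ = build_person_period(baselines, visits, 3)
        c = ppt[ppt["subject_id"] == "c"]
        assert list(c["censored"]) == [0, 1]

    def test_duplicate_rows_rejected(self):
        baselines = pd.DataFrame([make_baseline("a")])
        v = make_visits("a", [2, 2], [150.0, 150.0], visits=[0, 0])
        with pytest.raises(MalformedInputError):
            build_person_period(baselines, v, 3)

    def test_gap_rejected_before_locf(self):
        baselines = pd.DataFrame([make_baseline("a")])
        v = make_visits("a", [2, 2], [150.0, 150.0], visits=[0, 2])
        with pytest.raises(MalformedInputError):
            build_person_period(baselines, v, 3)

    def test_at_risk_is_complement_of_lagged_exposure(self, sim_fixture):
        ppt = sim_fixture["ppt"]
        a_lag = (
            ppt.groupby("subject_id")["exposure"].shift(1).fillna(0).astype(int)
        )
        assert (ppt["at_risk_initiation"] == (1 - a_lag)).all()
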