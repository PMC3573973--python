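import numpy as np
import pandas as pd
import pytest

from mscox.cohort import build_person_period, locf_impute
from mscox.errors import ConfigurationError, MalformedInputError, PositivityError
from mscox.simulate import get_scenario, simulate_cohort
from mscox.weights import (
    PooledLogisticFit,
    combine_weights,
    compute_stabilized_ipcw,
    compute_stabilized_iptw,
    estimate_weights,
    fit_censoring_models,
    fit_initiation_models,
    weight_diagnostics,
)


def _fit(fitted, mask, role="test"):
    fitted = np.asarray(fitted, float)
    return PooledLogisticFit(
        role=role,
        params=pd.Series(dtype=float),
        fitted=fitted,
        row_mask=np.asarray(mask, bool),
        converged=True,
        n_rows_used=int(np.sum(mask)),
    )


def _mini_ppt(subject_ids, visits, exposure, at_risk, censored=None):
    n = len(subject_ids)
    return pd.DataFrame(
        {
            "subject_id": subject_ids,
            "visit": visits,
            "exposure": exposure,
            "at_risk_initiation": at_risk,
            "event": [0] * n,
            "censored": censored if censored is not None else [0] * n,
        }
    )


class TestStabilizedIptw:
    def test_hand_computed_product(self):
        """Initiation at visit 1: factors (0.7/0.5) then (0.3/0.5)."""
        ppt = _mini_ppt(["s", "s"], [0, 1], [0, 1], [1, 1])
        num = _fit([0.3, 0.3], [True, True])
        den = _fit([0.5, 0.5], [True, True])
        sw = compute_stabilized_iptw(ppt, num, den)
        assert np.allclose(sw.to_numpy(), [1.4, 0.84])

    def test_identical_models_give_unit_weights(self):
        ppt = _mini_ppt(["s", "s", "s"], [0, 1, 2], [0, 0, 1], [1, 1, 1])
        num = _fit([0.2, 0.3, 0.4], [True] * 3)
        sw = compute_stabilized_iptw(ppt, num, num)
        assert np.allclose(sw.to_numpy(), 1.0)

    def test_weight_frozen_after_initiation(self):
        """Initiation at visit 0 fixes the weight for the whole series."""
        ppt = _mini_ppt(["s", "s", "s"], [0, 1, 2], [1, 1, 1], [1, 0, 0])
        num = _fit([0.3, np.nan, np.nan], [True, False, False])
        den = _fit([0.5, np.nan, np.nan], [True, False, False])
        sw = compute_stabilized_iptw(ppt, num, den)
        assert np.allclose(sw.to_numpy(), 0.6)

    def test_positivity_violation_detected_without_clipping(self):
        ppt = _mini_ppt(["s"], [0], [1], [1])
        num = _fit([0.3], [True])
        den = _fit([1.0], [True])
        with pytest.raises(PositivityError):
            compute_stabilized_iptw(ppt, num, den, probability_clip=None)
        # with clipping enabled the ratio is formed from clipped values
        sw = compute_stabilized_iptw(ppt, num, den, probability_clip=1e-6)
        assert np.isfinite(sw.to_numpy()).all()


class TestStabilizedIpcw:
    def test_single_interval_ratio(self):
        ppt = _mini_ppt(["s"], [0], [0], [1])
        num = _fit([0.02], [True])  # dropout probabilities
        den = _fit([0.05], [True])
        sw = compute_stabilized_ipcw(ppt, num, den)
        assert np.allclose(sw.to_numpy(), 0.98 / 0.95)

    def test_no_dropout_scenario_gives_unit_weights(self):
        cfg = get_scenario("invest_like").config.replace(
            n_subjects=500, seed=3, drop_intercept=-np.inf, miss_prob=0.0
        )
        b, v = simulate_cohort(cfg)
        ppt, _ = build_person_period(b, locf_impute(v), 3)
        num, den = fit_censoring_models(ppt)
        sw = compute_stabilized_ipcw(ppt, num, den)
        assert np.allclose(sw.to_numpy(), 1.0)


class TestCombineAndDiagnostics:
    def test_product_and_identity(self):
        ppt = _mini_ppt(["s", "t"], [0, 0], [0, 0], [1, 1])
        sw_t = pd.Series([1.4, 0.9], index=ppt.index)
        sw_c = pd.Series([1.0, 1.1], index=ppt.index)
        wt = combine_weights(ppt, sw_t, sw_c)
        assert np.allclose(wt["sw_combined"], sw_t * sw_c)
        assert wt["truncated"].sum() == 0

    def test_winsorization_flags_extremes(self):
        n = 200
        ppt = _mini_ppt([f"s{i}" for i in range(n)], [0] * n, [0] * n, [1] * n)
        sw_t = pd.Series(np.ones(n), index=ppt.index)
        sw_t.iloc[0] = 50.0
        sw_c = pd.Series(np.ones(n), index=ppt.index)
        wt = combine_weights(ppt, sw_t, sw_c, truncation=(1, 99))
        assert wt["truncated"].iloc[0] == 1
        assert wt["sw_combined"].iloc[0] == pytest.approx(
            np.percentile(np.where(np.arange(n) == 0, 50.0, 1.0), 99)
        )

    def test_misaligned_tables_rejected(self):
        ppt = _mini_ppt(["s", "t"], [0, 0], [0, 0], [1, 1])
        sw = pd.Series([1.0], index=[0])
        with pytest.raises(MalformedInputError):
            combine_weights(ppt, sw, sw)

    def test_bad_truncation_percentiles(self):
        ppt = _mini_ppt(["s"], [0], [0], [1])
        one = pd.Series([1.0], index=ppt.index)
        with pytest.raises(ConfigurationError):
            combine_weights(ppt, one, one, truncation=(99, 1))

    def test_diagnostics_on_unit_weights(self):
        ppt = _mini_ppt(["s", "s", "t"], [0, 1, 0], [0] * 3, [1] * 3)
        one = pd.Series(np.ones(3), index=ppt.index)
        wt = combine_weights(ppt, one, one)
        d = weight_diagnostics(wt)
        assert d["overall_mean"] == 1.0
        assert d["overall_sd"] == 0.0
        assert d["max_weight"] == wt["sw_combined"].max()
        assert (d["per_visit"]["mean"] == 1.0).all()


class TestOnSimulatedCohort:
    def test_sw_treat_constant_after_initiation(self, sim_fixture):
        ppt, wt = sim_fixture["ppt"], sim_fixture["weights"]
        merged = ppt[["subject_id", "visit", "exposure"]].assign(
            sw_treat=wt["sw_treat"].to_numpy()
        )
        exposed = merged[merged["exposure"] == 1]
        assert (exposed.groupby("subject_id")["sw_treat"].nunique() == 1).all()

    def test_all_weights_positive_and_mean_near_one(self, sim_fixture):
        wt = sim_fixture["weights"]
        assert (wt["sw_combined"] > 0).all()
        assert wt["sw_combined"].mean() == pytest.approx(1.0, abs=0.1)
        prod = wt["sw_treat"] * wt["sw_cens"]
        assert np.allclose(wt["sw_combined"], prod)

    def test_initiation_fit_restricted_to_at_risk_rows(self, sim_fixture):
        ppt = sim_fixture["ppt"]
        num, den = fit_initiation_models(ppt)
        n_at_risk = int((ppt["at_risk_initiation"] == 1).sum())
        assert num.n_rows_used == den.n_rows_used == n_at_risk
        # numerator terms are a strict subset of denominator terms
        assert set(num.params.index) < set(den.params.index)


@pytest.fixture(scope="module")
def recovery_fits():
    """One large cohort with known initiation and dropout coefficients."""
    cfg = get_scenario("invest_like").config.replace(
        n_subjects=50_000, seed=21, miss_prob=0.0
    )
    b, v = simulate_cohort(cfg)
    ppt, _ = build_person_period(b, locf_impute(v), 3)
    return cfg, ppt


class TestParameterRecovery:
    def test_initiation_confounding_coefficient(self, recovery_fits):
        cfg, ppt = recovery_fits
        _, den = fit_initiation_models(ppt)
        est = den.params["sbp_now_uncontrolled"]
        assert est == pytest.approx(cfg.init_uncontrolled, abs=0.15)
        assert den.params["sbp_lag_uncontrolled"] == pytest.approx(0.0, abs=0.15)

    def test_dropout_informative_coefficient(self, recovery_fits):
        cfg, ppt = recovery_fits
        _, den = fit_censoring_models(ppt)
        assert den.params["sbp_now_uncontrolled"] == pytest.approx(
            cfg.drop_uncontrolled, abs=0.15
        )

    def test_weights_degenerate_without_confounding_or_informative_dropout(self):
        """No time-dependent confounding, random dropout: weights pile at 1."""
        cfg = get_scenario("no_confounding").config.replace(
            n_subjects=50_000, seed=23
        )
        b, v = simulate_cohort(cfg)
        ppt, _ = build_person_period(b, locf_impute(v), 3)
        wt = estimate_weights(ppt)
        assert wt["sw_combined"].std() < 0.1

    def test_null_confounding_coefficients_near_zero(self):
        """Initiation independent of SBP: denominator SBP terms vanish."""
        cfg = get_scenario("no_confounding").config.replace(
            n_subjects=20_000, seed=22
        )
        b, v = simulate_cohort(cfg)
        ppt, _ = build_person_period(b, locf_impute(v), 3)
        _, den = fit_initiation_models(ppt)
        for term in ("sbp_now_tight", "sbp_now_uncontrolled"):
            est, se = den.params[term], den.bse[term]
            assert abs(est) < 3 * se
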