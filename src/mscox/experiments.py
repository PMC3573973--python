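"""Replicated simulation experiments validating the estimators.

Each function runs a self-contained Monte Carlo study against the
scenario library and returns plain dictionaries of summary numbers; the
acceptance script and the test suite both call these.  Replicate seeds are
spawned from a single base seed, so every experiment is reproducible.
"""

from __future__ import annotations

import logging

import numpy as np

from .cohort import build_person_period, locf_impute
from .design import REDUCED_BASELINE_TERMS
from .estimation import (
    ModelSpec,
    fit_mscm,
    fit_partial_likelihood_cox,
    fit_standard_cox,
)
from .simulate import get_scenario, simulate_cohort, true_marginal_hr
from .weights import estimate_weights, weight_diagnostics

logger = logging.getLogger(__name__)


def spawn_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def run_estimators(
    config,
    n_subjects: int,
    seed: int,
    threshold: int = 3,
    spec=None,
    keep_tables: bool = False,
):
    """Simulate one cohort and fit both estimators on it.

    Large intermediate tables are dropped unless ``keep_tables`` is set,
    so replicated experiments hold only one cohort in memory at a time.
    """
    cfg = config.replace(n_subjects=n_subjects, seed=seed)
    baselines, visits = simulate_cohort(cfg)
    ppt, info = build_person_period(baselines, locf_impute(visits), threshold)
    del baselines, visits
    wt = estimate_weights(ppt)
    spec = spec or ModelSpec()
    out = {
        "mscm": fit_mscm(ppt, wt, spec),
        "standard": fit_standard_cox(ppt, spec),
        "info": info,
    }
    if keep_tables:
        out["ppt"] = ppt
        out["weights"] = wt
    return out


def null_coverage_experiment(
    n_reps: int = 200, n_subjects: int = 2000, seed: int = 0
) -> dict:
    """95% CI coverage of the true null (HR = 1) under strong confounding.

    The marginal structural model should cover near the nominal rate; the
    unweighted comparator, biased by time-dependent confounding and
    informative dropout, should under-cover.
    """
    sc = get_scenario("null_confounded")
    seeds = spawn_seeds(seed, n_reps)
    cover_m, cover_s, n_ok = 0, 0, 0
    for s in seeds:
        try:
            out = run_estimators(sc.config, n_subjects, s)
        except Exception as exc:  # rare small-sample separation
            logger.warning("null-coverage replicate failed: %s", exc)
            continue
        n_ok += 1
        if out["mscm"].ci_lower <= 1.0 <= out["mscm"].ci_upper:
            cover_m += 1
        if out["standard"].ci_lower <= 1.0 <= out["standard"].ci_upper:
            cover_s += 1
    return {
        "n_reps": n_ok,
        "mscm_coverage": cover_m / n_ok,
        "standard_coverage": cover_s / n_ok,
    }


def recovery_experiment(
    n_seeds: int = 10,
    n_subjects: int = 50_000,
    seed: int = 0,
    oracle_n: int = 200_000,
) -> dict:
    """Parameter recovery of the true marginal log hazard ratio.

    Recomputes the truth oracle for the ``invest_like`` scenario, then
    measures each estimator's absolute log-HR error over independent
    cohorts.
    """
    sc = get_scenario("invest_like")
    oracle = true_marginal_hr(sc.config, n_oracle=oracle_n, seed=sc.oracle_seed)
    log_oracle = float(np.log(oracle))
    errs_m, errs_s, hrs_m, hrs_s = [], [], [], []
    for s in spawn_seeds(seed, n_seeds):
        out = run_estimators(sc.config, n_subjects, s)
        errs_m.append(abs(out["mscm"].log_hr - log_oracle))
        errs_s.append(abs(out["standard"].log_hr - log_oracle))
        hrs_m.append(out["mscm"].hr)
        hrs_s.append(out["standard"].hr)
    return {
        "oracle_hr": oracle,
        "oracle_log_hr": log_oracle,
        "mscm_median_abs_error": float(np.median(errs_m)),
        "standard_median_abs_error": float(np.median(errs_s)),
        "mscm_median_hr": float(np.median(hrs_m)),
        "standard_median_hr": float(np.median(hrs_s)),
        "n_seeds": n_seeds,
    }


def bias_direction_experiment(
    n_reps: int = 100, n_subjects: int = 10_000, seed: int = 0
) -> dict:
    """How often the unweighted estimate sits strictly closer to the null.

    Under confounding by indication with a protective treatment, the
    unweighted hazard ratio should be attenuated toward 1 relative to the
    weighted one in nearly every replicate.
    """
    sc = get_scenario("invest_like")
    closer = 0
    n_ok = 0
    for s in spawn_seeds(seed, n_reps):
        out = run_estimators(sc.config, n_subjects, s)
        n_ok += 1
        if abs(out["standard"].log_hr) < abs(out["mscm"].log_hr):
            closer += 1
    return {"n_reps": n_ok, "fraction_standard_closer_to_null": closer / n_ok}


def weight_mean_experiment(n_subjects: int = 20_000, seed: int = 0) -> dict:
    """Stabilized-weight mean property on a correctly specified scenario."""
    sc = get_scenario("invest_like")
    cfg = sc.config.replace(n_subjects=n_subjects, seed=seed)
    baselines, visits = simulate_cohort(cfg)
    ppt, _ = build_person_period(baselines, locf_impute(visits), 3)
    wt = estimate_weights(ppt)
    diag = weight_diagnostics(wt)
    per_visit = diag["per_visit"]["mean"]
    return {
        "overall_mean": diag["overall_mean"],
        "per_visit_mean_min": float(per_visit.min()),
        "per_visit_mean_max": float(per_visit.max()),
        "max_weight": diag["max_weight"],
        "n_rows": int(len(wt)),
    }


def equivalence_experiment(n_subjects: int = 50_000, seed: int = 0) -> dict:
    """Without confounding the two estimators should coincide."""
    sc = get_scenario("no_confounding")
    out = run_estimators(sc.config, n_subjects, seed)
    gap = abs(out["mscm"].log_hr - out["standard"].log_hr)
    return {
        "abs_log_hr_gap": float(gap),
        "mscm_hr": out["mscm"].hr,
        "standard_hr": out["standard"].hr,
    }


def rare_event_cox_experiment(n_subjects: int = 50_000, seed: int = 0) -> dict:
    """Discrete-time pooled logistic vs. partial-likelihood Cox.

    With per-interval event probabilities under 1% the two log hazard
    ratios should agree closely.  A reduced covariate set keeps the
    time-varying Cox fit affordable; both models use the same terms.
    """
    sc = get_scenario("no_confounding")
    # lower the baseline event intercept to put every interval safely in
    # the rare-event regime (< 1% per interval)
    cfg = sc.config.replace(n_subjects=n_subjects, seed=seed, out_intercept=-5.6)
    baselines, visits = simulate_cohort(cfg)
    ppt, _ = build_person_period(baselines, locf_impute(visits), 3)
    spec = ModelSpec(baseline_terms=REDUCED_BASELINE_TERMS)
    pooled = fit_standard_cox(ppt, spec)
    cox = fit_partial_likelihood_cox(ppt, spec)
    return {
        "abs_log_hr_gap": float(abs(pooled.log_hr - cox.log_hr)),
        "pooled_logistic_hr": pooled.hr,
        "partial_likelihood_hr": cox.hr,
        "per_interval_event_prob": float(ppt["event"].mean()),
    }


def structural_checks(seed: int = 0, n_subjects: int = 2000) -> dict:
    """Exact structural identities of the pipeline.

    Checks: unity weights reproduce the unweighted fit; identical
    numerator and denominator models force stabilized weights to one;
    exposure is monotone and no person-time follows a first event; a fixed
    seed reproduces the cohort bit for bit.
    """
    import pandas as pd

    from .estimation import align_weights, _fit_pooled
    from .weights import combine_weights, compute_stabilized_iptw, fit_initiation_models

    sc = get_scenario("invest_like")
    cfg = sc.config.replace(n_subjects=n_subjects, seed=seed)
    baselines, visits = simulate_cohort(cfg)
    b2, v2 = simulate_cohort(cfg)
    deterministic = baselines.equals(b2) and visits.equals(v2)

    ppt, _ = build_person_period(baselines, locf_impute(visits), 3)
    by_subj = ppt.groupby("subject_id")
    monotone = bool((by_subj["exposure"].diff().fillna(0) >= 0).all())
    # an event must terminate the series: events only on subjects' final rows
    last_rows = by_subj.tail(1).index
    post_event = bool(ppt.loc[~ppt.index.isin(last_rows), "event"].eq(0).all())

    spec = ModelSpec()
    unit = pd.DataFrame(
        {
            "subject_id": ppt["subject_id"],
            "visit": ppt["visit"],
            "sw_combined": 1.0,
        }
    )
    est_w = _fit_pooled(ppt, spec, align_weights(ppt, unit), "mscm")
    est_u = fit_standard_cox(ppt, spec)
    unity_ok = bool(
        np.max(np.abs(est_w.params.to_numpy() - est_u.params.to_numpy())) < 1e-6
    )

    num, den = fit_initiation_models(ppt)
    sw_same = compute_stabilized_iptw(ppt, num, num)
    identical_ok = bool(np.allclose(sw_same.to_numpy(), 1.0))

    return {
        "deterministic": deterministic,
        "monotone_exposure": monotone,
        "no_post_event_rows": post_event,
        "unity_weights_match_unweighted": unity_ok,
        "identical_models_give_unit_weights": identical_ok,
        "all_passed": bool(
            deterministic and monotone and post_event and unity_ok and identical_ok
        ),
    }
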