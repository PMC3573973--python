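"""Synthetic longitudinal cohorts with time-dependent confounding.

The generator follows the causal structure of step-up antihypertensive
therapy: systolic blood pressure (SBP) evolves autoregressively around a
setpoint; uncontrolled SBP raises the probability of *initiating*
aggressive treatment (>= the configured drug count); treatment, once
started, is never discontinued, lowers subsequent SBP (mediation) and may
act on the outcome hazard directly; SBP category drives both the event
hazard and dropout (informative censoring).  Visits may be missed at
random and are left as absent rows for downstream LOCF imputation.

Event and dropout are drawn per interval with event taking precedence;
either terminates the series.  The per-interval event probabilities are
kept rare (< 2%) so the pooled-logistic hazard-ratio approximation holds.

All randomness is pre-drawn in a fixed order from a single seeded
generator, so a given ``(config, seed)`` is fully deterministic and the
counterfactual regimes share common random numbers — the basis of the
low-variance truth oracle in :func:`true_marginal_hr`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import scipy.special
from scipy.special import expit

from .cohort import (
    MAX_VISITS,
    RACE_LEVELS,
    SBP_TIGHT_UPPER,
    SBP_USUAL_UPPER,
)
from .errors import ConfigurationError, InsufficientOracleError


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the generative model.

    Baseline marginals default to the enrollment characteristics of a
    large hypertensive coronary-artery-disease cohort (age 66.1 (9.8)
    years, 52.1% women, baseline SBP 149.5 (19.7) mm Hg, and the listed
    comorbidity prevalences).  Logit-scale coefficients use the *usual*
    SBP-control category as reference; age enters in decades over 65.
    """

    n_subjects: int = 10_000
    n_visits: int = MAX_VISITS
    seed: int = 0

    # --- baseline covariate marginals ---
    age_mean: float = 66.1
    age_sd: float = 9.8
    age_min: float = 50.0
    female_frac: float = 0.521
    race_probs: tuple = (0.484, 0.134, 0.356, 0.026)  # white, black, hispanic, other
    strategy_frac: float = 0.499
    prev_mi: float = 0.320
    prev_stroke_tia: float = 0.072
    prev_chf: float = 0.056
    prev_diabetes: float = 0.284
    prev_renal: float = 0.019
    prev_pvd: float = 0.120
    prev_revasc: float = 0.273
    prev_smoking: float = 0.463
    sbp_baseline_mean: float = 149.5
    sbp_baseline_sd: float = 19.7
    sbp_floor: float = 80.0

    # --- SBP dynamics (mm Hg) ---
    # untreated SBP follows an AR(1) pull toward the setpoint; treatment
    # subtracts a level shift from the visit after initiation onward, so
    # the full lowering is reached within one visit and the hazard depends
    # on treatment only through the current state
    sbp_setpoint: float = 148.0
    sbp_ar: float = 0.7          # autoregressive pull toward the setpoint
    sbp_noise_sd: float = 8.0    # per-visit innovation
    sbp_treatment_effect: float = 7.0  # mm Hg lowering while treated

    # --- drug counts ---
    # conventional subjects take aggressive_drugs-1 or -2 drugs, aggressive
    # subjects aggressive_drugs or +1; the 4th drug is more likely when SBP
    # is uncontrolled at initiation, so higher exposure thresholds select
    # more strongly confounded subgroups (threshold sensitivity analyses)
    conventional_drugs: int = 2
    aggressive_drugs: int = 3
    conventional_high_frac: float = 0.6   # P(2 rather than 1 drugs)
    aggressive_high_frac: float = 0.35    # base P(4 rather than 3 drugs)
    aggressive_high_uncontrolled: float = 0.8  # logit increment if uncontrolled

    # --- treatment initiation model (logit) ---
    init_intercept: float = -2.2
    init_trend: float = 0.0       # per-visit linear trend
    init_tight: float = -0.7
    init_uncontrolled: float = 1.2
    init_age: float = 0.10

    # --- outcome (event-per-interval) model (logit) ---
    out_intercept: float = -5.2
    out_tight: float = -0.3
    out_uncontrolled: float = 0.7
    out_treatment: float = -0.10  # direct effect
    out_age: float = 0.35
    out_mi: float = 0.30

    # --- dropout model (logit) ---
    drop_intercept: float = -3.5
    drop_tight: float = 0.0
    drop_uncontrolled: float = 0.8
    drop_treatment: float = -0.2

    # --- missed visits ---
    miss_prob: float = 0.05

    # use continuous SBP (mm Hg over the setpoint, per 10 mm Hg) in the
    # event hazard instead of the categories — misspecification experiments
    continuous_sbp_hazard: bool = False
    out_sbp_per_10mmhg: float = 0.15

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 1 <= self.n_visits <= MAX_VISITS:
            raise ConfigurationError(f"n_visits must be in [1, {MAX_VISITS}]")
        for name in (
            "female_frac",
            "strategy_frac",
            "miss_prob",
            "conventional_high_frac",
            "aggressive_high_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        for name in (
            "prev_mi", "prev_stroke_tia", "prev_chf", "prev_diabetes",
            "prev_renal", "prev_pvd", "prev_revasc", "prev_smoking",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.race_probs) - 1.0) > 1e-8 or min(self.race_probs) < 0:
            raise ConfigurationError("race_probs must be a probability vector")
        if not 0.0 <= self.sbp_ar < 1.0:
            raise ConfigurationError("sbp_ar must be in [0,1)")
        if self.aggressive_drugs <= self.conventional_drugs:
            raise ConfigurationError("aggressive_drugs must exceed conventional_drugs")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class Regime:
    """Treatment assignment regime for counterfactual simulation."""

    kind: str = "natural"  # natural | never | always_from_visit
    start_visit: int = 0

    def __post_init__(self):
        if self.kind not in ("natural", "never", "always_from_visit"):
            raise ConfigurationError(f"unknown regime kind {self.kind!r}")


NATURAL = Regime("natural")
NEVER = Regime("never")


def always_from_visit(k: int) -> Regime:
    return Regime("always_from_visit", k)


def _sbp_codes(sbp: np.ndarray) -> np.ndarray:
    """0 = tight, 1 = usual, 2 = uncontrolled."""
    return np.searchsorted(
        np.array([SBP_TIGHT_UPPER, SBP_USUAL_UPPER]), sbp, side="right"
    )


def simulate_cohort(
    config: SimulationConfig, regime: Regime = NATURAL
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns ``(baselines, visits)`` tables.

    The visits table has absent rows for missed visits (to be completed by
    LOCF) except that an event occurring in the interval after a missed
    visit is still recorded, with the last observed SBP and drug count and
    ``observed=0``.  Dropout is only drawn at attended, non-terminal visits.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, K = config.n_subjects, config.n_visits

    # --- baseline draws (fixed order: part of the determinism contract) ---
    a = (config.age_min - config.age_mean) / config.age_sd
    age = scipy.stats.truncnorm.rvs(
        a, np.inf, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    female = (rng.random(n) < config.female_frac).astype(np.int64)
    race = np.array(RACE_LEVELS, dtype=object)[
        rng.choice(len(RACE_LEVELS), size=n, p=config.race_probs)
    ]
    strategy = (rng.random(n) < config.strategy_frac).astype(np.int64)
    prevs = {
        "hist_mi": config.prev_mi,
        "hist_stroke_tia": config.prev_stroke_tia,
        "hist_chf": config.prev_chf,
        "hist_diabetes": config.prev_diabetes,
        "hist_renal": config.prev_renal,
        "hist_pvd": config.prev_pvd,
        "hist_revasc": config.prev_revasc,
        "hist_smoking": config.prev_smoking,
    }
    flags = {k: (rng.random(n) < p).astype(np.int64) for k, p in prevs.items()}
    sbp0 = np.maximum(
        rng.normal(config.sbp_baseline_mean, config.sbp_baseline_sd, n),
        config.sbp_floor,
    )
    # per-subject drug-count levels: conventional count fixed at baseline,
    # aggressive count resolved at initiation (depends on SBP there)
    conv_drugs = np.where(
        rng.random(n) < config.conventional_high_frac,
        config.conventional_drugs,
        config.conventional_drugs - 1,
    ).astype(np.int64)
    u_high = rng.random(n)

    # --- pre-drawn per-visit streams (common random numbers across regimes) ---
    noise = rng.normal(0.0, config.sbp_noise_sd, (n, K))
    u_init = rng.random((n, K))
    u_event = rng.random((n, K))
    u_drop = rng.random((n, K))
    u_miss = rng.random((n, K))

    age_c = (age - 65.0) / 10.0
    active = np.ones(n, dtype=bool)
    a_treat = np.zeros(n, dtype=bool)
    agg_drugs = np.zeros(n, dtype=np.int64)  # resolved at initiation
    base_logit_high = scipy.special.logit(config.aggressive_high_frac)
    z_prev = sbp0.copy()  # latent untreated SBP process
    sbp_obs = sbp0.copy()

    rec = {c: [] for c in ("subject_id", "visit", "n_drugs", "sbp", "observed", "event", "dropped")}
    ids = np.arange(n, dtype=np.int64)

    for k in range(K):
        if k == 0:
            z_k = sbp0.copy()
        else:
            z_k = (
                config.sbp_setpoint
                + config.sbp_ar * (z_prev - config.sbp_setpoint)
                + noise[:, k]
            )
        # full treatment-induced lowering from the visit after initiation
        sbp_k = np.maximum(
            z_k - config.sbp_treatment_effect * a_treat, config.sbp_floor
        )
        cat = _sbp_codes(sbp_k)
        tight = cat == 0
        uncontrolled = cat == 2

        missed = (k > 0) & (u_miss[:, k] < config.miss_prob)

        if regime.kind == "natural":
            logit_init = (
                config.init_intercept
                + config.init_trend * k
                + config.init_tight * tight
                + config.init_uncontrolled * uncontrolled
                + config.init_age * age_c
            )
            newly = (
                active & ~a_treat & ~missed & (u_init[:, k] < expit(logit_init))
            )
        elif regime.kind == "always_from_visit":
            newly = ~a_treat & (k >= regime.start_visit)
        else:  # "never"
            newly = np.zeros(n, dtype=bool)
        if newly.any():
            p_high = expit(
                base_logit_high + config.aggressive_high_uncontrolled * uncontrolled
            )
            agg_drugs[newly] = config.aggressive_drugs + (
                u_high[newly] < p_high[newly]
            ).astype(np.int64)
            a_treat = a_treat | newly

        n_drugs = np.where(a_treat, agg_drugs, conv_drugs)

        if config.continuous_sbp_hazard:
            sbp_term = config.out_sbp_per_10mmhg * (sbp_k - config.sbp_setpoint) / 10.0
        else:
            sbp_term = config.out_tight * tight + config.out_uncontrolled * uncontrolled
        logit_event = (
            config.out_intercept
            + sbp_term
            + config.out_treatment * a_treat
            + config.out_age * age_c
            + config.out_mi * flags["hist_mi"]
        )
        event = active & (u_event[:, k] < expit(logit_event))

        logit_drop = (
            config.drop_intercept
            + config.drop_tight * tight
            + config.drop_uncontrolled * uncontrolled
            + config.drop_treatment * a_treat
        )
        can_drop = active & ~event & ~missed & (k < K - 1)
        drop = can_drop & (u_drop[:, k] < expit(logit_drop))

        emit = active & (~missed | event)
        rec_sbp = np.where(missed, sbp_obs, sbp_k)
        m = emit
        rec["subject_id"].append(ids[m])
        rec["visit"].append(np.full(m.sum(), k, dtype=np.int64))
        rec["n_drugs"].append(n_drugs[m].astype(np.int64))
        rec["sbp"].append(rec_sbp[m])
        rec["observed"].append((~missed[m]).astype(np.int64))
        rec["event"].append(event[m].astype(np.int64))
        rec["dropped"].append(drop[m].astype(np.int64))

        attended = active & ~missed
        sbp_obs = np.where(attended, sbp_k, sbp_obs)
        active = active & ~event & ~drop
        z_prev = z_k

    baselines = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "female": female,
            "race": race,
            "strategy": strategy,
            **flags,
            "sbp_baseline": sbp0,
        }
    )
    visits = pd.DataFrame({c: np.concatenate(v) for c, v in rec.items()})
    visits = visits.sort_values(["subject_id", "visit"], kind="mergesort").reset_index(
        drop=True
    )
    return baselines, visits


def _dropout_free(config: SimulationConfig) -> SimulationConfig:
    return config.replace(
        miss_prob=0.0,
        drop_intercept=-np.inf,
        drop_tight=0.0,
        drop_uncontrolled=0.0,
        drop_treatment=0.0,
    )


def true_marginal_hr(
    config: SimulationConfig, n_oracle: int = 500_000, seed: int | None = None
) -> float:
    """True marginal hazard ratio by counterfactual simulation.

    Simulates the same subjects (common random numbers) under
    treat-everyone-from-baseline and treat-no-one regimes with dropout and
    missed visits disabled (full counterfactual follow-up), then fits an
    unconfounded discrete-time model — event counts on regime and visit
    indicators, pooled over both arms — and returns the exponentiated
    regime coefficient.  This is the estimand targeted by the marginal
    structural model and the oracle for all parameter-recovery tests.
    """
    import statsmodels.api as sm

    if n_oracle < 10_000:
        raise InsufficientOracleError(
            f"oracle needs n_oracle >= 10000, got {n_oracle}"
        )
    cfg = _dropout_free(config).replace(
        n_subjects=n_oracle, seed=config.seed if seed is None else seed
    )
    tabs = []
    for arm, regime in ((0, NEVER), (1, always_from_visit(0))):
        _, visits = simulate_cohort(cfg, regime)
        g = visits.groupby("visit")["event"].agg(events="sum", at_risk="count")
        g = g.reset_index()
        g["arm"] = arm
        tabs.append(g)
    tab = pd.concat(tabs, ignore_index=True)
    endog = np.column_stack(
        [tab["events"].to_numpy(float), (tab["at_risk"] - tab["events"]).to_numpy(float)]
    )
    X = pd.DataFrame({"const": 1.0, "arm": tab["arm"].to_numpy(float)})
    for lv in sorted(tab["visit"].unique())[1:]:
        X[f"visit_{lv}"] = (tab["visit"] == lv).to_numpy(float)
    res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    return float(np.exp(res.params["arm"]))


@dataclass(frozen=True)
class Scenario:
    """A named simulation scenario with its frozen truth-oracle value.

    ``oracle_hr`` was computed once with :func:`true_marginal_hr` at
    ``(oracle_n, oracle_seed)``; ``scenario_oracle_hr`` recomputes it.
    """

    name: str
    description: str
    config: SimulationConfig
    oracle_hr: float
    oracle_seed: int = 202_406
    oracle_n: int = 200_000

    def recompute_oracle(self, n_oracle: int | None = None, seed: int | None = None) -> float:
        return true_marginal_hr(
            self.config,
            n_oracle=self.oracle_n if n_oracle is None else n_oracle,
            seed=self.oracle_seed if seed is None else seed,
        )

    def metadata(self) -> dict:
        return {
            "name": self.name,
            "description": self.description,
            "oracle_hr": self.oracle_hr,
            "oracle_seed": self.oracle_seed,
            "oracle_n": self.oracle_n,
            "config": dataclasses.asdict(self.config),
        }


def scenario_library() -> dict[str, Scenario]:
    """Named generating mechanisms used throughout the validation suite.

    * ``invest_like`` — protective total effect (true marginal HR ~ 0.80)
      with strong confounding by SBP and informative dropout; event
      incidence near 10%.
    * ``null_confounded`` — treatment affects neither SBP nor the hazard,
      but initiation and dropout strongly follow SBP: the null scenario in
      which naive estimators are biased.
    * ``no_confounding`` — initiation and dropout independent of SBP;
      treatment effects present.  MSCM and standard model should agree.
    * ``mediation_only`` — no direct effect; treatment acts only by
      lowering SBP.
    """
    base = SimulationConfig()
    lib = {}

    lib["invest_like"] = Scenario(
        name="invest_like",
        description=(
            "Step-up therapy cohort: uncontrolled SBP drives initiation and "
            "events, treatment lowers SBP and has a direct protective "
            "effect, dropout is informative."
        ),
        config=base,
        oracle_hr=0.8024,
    )

    lib["null_confounded"] = Scenario(
        name="null_confounded",
        description=(
            "No treatment effect on SBP or the hazard; strong confounding "
            "by SBP in initiation and informative dropout."
        ),
        config=base.replace(
            sbp_treatment_effect=0.0,
            out_treatment=0.0,
            sbp_setpoint=138.0,
            sbp_ar=0.85,
            init_intercept=-2.4,
            init_tight=-1.2,
            init_uncontrolled=1.6,
            out_tight=-0.5,
            out_uncontrolled=1.0,
            drop_uncontrolled=0.8,
        ),
        oracle_hr=1.0,
    )

    lib["no_confounding"] = Scenario(
        name="no_confounding",
        description=(
            "Initiation and dropout independent of SBP; protective direct "
            "and mediated treatment effects."
        ),
        config=base.replace(
            init_tight=0.0,
            init_uncontrolled=0.0,
            init_intercept=-1.9,
            drop_tight=0.0,
            drop_uncontrolled=0.0,
            drop_treatment=0.0,
        ),
        oracle_hr=0.8024,
    )

    lib["mediation_only"] = Scenario(
        name="mediation_only",
        description=(
            "No direct effect; treatment lowers SBP, and SBP category "
            "drives the hazard (and initiation)."
        ),
        config=base.replace(out_treatment=0.0),
        oracle_hr=0.8835,
    )
    return lib


def get_scenario(name: str) -> Scenario:
    lib = scenario_library()
    if name not in lib:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {sorted(lib)}"
        )
    return lib[name]
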