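"""Longitudinal cohort data model and person-period expansion.

The cohort is a pair of tables: one row per subject (baseline covariates
measured at enrollment) and one row per attended subject-visit (systolic
blood pressure, number of concurrent antihypertensive drugs, event and
dropout flags).  Analyses run on a discrete-time *person-period* table with
one row per subject per visit interval.

Discrete-time convention
------------------------
Interval ``k`` spans ``(visit k, visit k+1]``.  The event flag stored on the
record at visit ``k`` refers to the interval that visit opens, so an event
is attributed to the exposure and confounder state measured at visit ``k``.
Visits are treated as equally spaced.  A subject's series terminates at the
first event, at dropout (``dropped=1`` on the final record), or at the
administrative end of the study (visit ``K-1``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    InvalidMeasurementError,
    MalformedInputError,
    MissingBaselineError,
)

logger = logging.getLogger(__name__)

#: Maximum number of scheduled visits in a series (indices 0..13).
MAX_VISITS = 14

#: SBP control categories, ordered from lowest to highest pressure.
SBP_CATEGORIES = ("tight", "usual", "uncontrolled")
SBP_TIGHT_UPPER = 120.0  # tight control: < 120 mm Hg
SBP_USUAL_UPPER = 140.0  # usual control: [120, 140); uncontrolled: >= 140

#: Exposure thresholds supported for the aggressive/conventional contrast.
SUPPORTED_THRESHOLDS = (2, 3, 4)

RACE_LEVELS = ("white", "black", "hispanic", "other")

COMORBIDITY_FLAGS = (
    "hist_mi",
    "hist_stroke_tia",
    "hist_chf",
    "hist_diabetes",
    "hist_renal",
    "hist_pvd",
    "hist_revasc",
    "hist_smoking",
)

BASELINE_COLUMNS = (
    "subject_id",
    "age",
    "female",
    "race",
    "strategy",
    *COMORBIDITY_FLAGS,
    "sbp_baseline",
)

VISIT_COLUMNS = ("subject_id", "visit", "n_drugs", "sbp", "observed", "event", "dropped")


def categorize_sbp(sbp):
    """Map systolic blood pressure (mm Hg) to its control category.

    Categories are left-closed / right-open: ``< 120`` is ``tight``,
    ``[120, 140)`` is ``usual`` and ``>= 140`` is ``uncontrolled``.

    Parameters
    ----------
    sbp : float or array-like
        Systolic blood pressure in mm Hg; must be finite and positive.

    Returns
    -------
    str or numpy.ndarray of str
        Scalar input gives a scalar category, array input an array.
    """
    arr = np.asarray(sbp, dtype=float)
    if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
        raise InvalidMeasurementError(
            "systolic blood pressure must be finite and positive (mm Hg)"
        )
    codes = np.searchsorted(
        np.array([SBP_TIGHT_UPPER, SBP_USUAL_UPPER]), arr, side="right"
    )
    cats = np.take(np.array(SBP_CATEGORIES, dtype=object), codes)
    if arr.ndim == 0:
        return str(cats)
    return cats.astype(str)


def classify_treatment(n_drugs, aggressive_threshold: int = 3):
    """Classify a drug count as aggressive (1) or conventional (0) treatment.

    Aggressive treatment means at least ``aggressive_threshold`` concurrent
    antihypertensive drugs (primary contrast: >=3 vs <=2; sensitivity
    contrasts use thresholds 2 and 4).
    """
    if aggressive_threshold not in SUPPORTED_THRESHOLDS:
        raise ConfigurationError(
            f"aggressive_threshold must be one of {SUPPORTED_THRESHOLDS}, "
            f"got {aggressive_threshold!r}"
        )
    arr = np.asarray(n_drugs)
    if arr.size and (np.any(arr < 0) or not np.issubdtype(arr.dtype, np.number)):
        raise InvalidMeasurementError("n_drugs must be a non-negative count")
    out = (arr >= aggressive_threshold).astype(np.int64)
    if arr.ndim == 0:
        return int(out)
    return out


def _check_duplicates(visits: pd.DataFrame) -> None:
    dup = visits.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        bad = visits.loc[dup, ["subject_id", "visit"]].iloc[0]
        raise MalformedInputError(
            f"duplicate visit record for subject {bad['subject_id']!r} "
            f"at visit {int(bad['visit'])}"
        )


def locf_impute(visits: pd.DataFrame, n_visits: int = MAX_VISITS) -> pd.DataFrame:
    """Fill missed interior visits by last observation carried forward.

    Every scheduled visit up to a subject's last attended visit receives a
    record; filled records copy ``sbp`` and ``n_drugs`` from the most recent
    attended visit and are marked ``observed=0``.  Nothing is fabricated
    beyond the last attended visit (lost subjects are censored at their last
    visit).  The operation is idempotent.

    Parameters
    ----------
    visits : pandas.DataFrame
        Visit records sorted or sortable by (subject_id, visit).  Missing
        visits are absent rows.  An ``observed`` column is optional for raw
        input (present rows default to observed).
    n_visits : int
        Visit indices must lie in ``[0, n_visits)``.

    Returns
    -------
    pandas.DataFrame with columns :data:`VISIT_COLUMNS`.
    """
    if visits.empty:
        raise MissingBaselineError("empty visit series: no baseline visit")
    visits = visits.copy()
    if "observed" not in visits.columns:
        visits["observed"] = 1
    _check_duplicates(visits)
    if visits["visit"].min() < 0 or visits["visit"].max() >= n_visits:
        raise MalformedInputError(
            f"visit indices must lie in [0, {n_visits}), "
            f"got range [{visits['visit'].min()}, {visits['visit'].max()}]"
        )
    first = visits.groupby("subject_id")["visit"].min()
    if (first > 0).any():
        bad = first[first > 0].index[0]
        raise MissingBaselineError(f"subject {bad!r} has no baseline (visit 0) record")

    visits = visits.sort_values(["subject_id", "visit"], kind="mergesort")
    last = visits.groupby("subject_id", sort=True)["visit"].max()
    counts = (last + 1).to_numpy()
    full = pd.DataFrame(
        {
            "subject_id": np.repeat(last.index.to_numpy(), counts),
            "visit": np.concatenate([np.arange(c) for c in counts]),
        }
    )
    merged = full.merge(visits, on=["subject_id", "visit"], how="left")
    n_filled = int(merged["observed"].isna().sum())
    if n_filled:
        logger.info("LOCF filled %d missed visit records", n_filled)
    grp = merged.groupby("subject_id", sort=False)
    merged[["sbp", "n_drugs"]] = grp[["sbp", "n_drugs"]].ffill()
    merged["observed"] = merged["observed"].fillna(0).astype(np.int64)
    merged["event"] = merged["event"].fillna(0).astype(np.int64)
    merged["dropped"] = merged["dropped"].fillna(0).astype(np.int64)
    merged["n_drugs"] = merged["n_drugs"].astype(np.int64)
    merged["visit"] = merged["visit"].astype(np.int64)
    return merged[list(VISIT_COLUMNS)]


@dataclass(frozen=True)
class PersonPeriodInfo:
    """Bookkeeping emitted alongside a person-period table."""

    aggressive_threshold: int
    n_subjects: int
    n_rows: int
    n_events: int
    n_recoded_exposure: int
    n_rows_dropped_post_event: int

    def to_dict(self) -> dict:
        return {
            "aggressive_threshold": self.aggressive_threshold,
            "n_subjects": self.n_subjects,
            "n_rows": self.n_rows,
            "n_events": self.n_events,
            "n_recoded_exposure": self.n_recoded_exposure,
            "n_rows_dropped_post_event": self.n_rows_dropped_post_event,
        }


def build_person_period(
    baselines: pd.DataFrame,
    visits: pd.DataFrame,
    aggressive_threshold: int = 3,
) -> tuple[pd.DataFrame, PersonPeriodInfo]:
    """Expand LOCF-completed visit records into a person-period table.

    One row per subject-interval, carrying:

    * ``exposure`` — 1 from the first visit at which the subject's drug
      count reached the aggressive threshold onward.  Raw reversals (drug
      count later falling below threshold) are recoded to sustained
      exposure, mirroring an intention-to-treat exposure; the number of
      recoded rows is counted and logged.
    * ``sbp_cat`` / ``sbp_cat_lag`` / ``sbp_cat_base`` — SBP control
      category at the current visit, the previous visit (baseline category
      at visit 0), and enrollment.
    * ``event`` — event in the interval this visit opens; rows after a
      first event are discarded (person-time accrued after a nonfatal event
      is excluded).
    * ``censored`` — dropout at the end of this interval (final row only).
    * ``at_risk_initiation`` — 1 while the subject has not yet initiated
      aggressive treatment at the previous visit.

    Baseline covariates are merged onto every row.

    Returns
    -------
    (pandas.DataFrame, PersonPeriodInfo)
    """
    if baselines.duplicated(subset=["subject_id"]).any():
        raise MalformedInputError("duplicate subject_id in baseline table")
    _check_duplicates(visits)

    df = visits.sort_values(["subject_id", "visit"], kind="mergesort").copy()
    # Visits must be LOCF-completed: contiguous indices starting at 0.
    grp = df.groupby("subject_id", sort=False)
    pos = grp.cumcount()
    if (df["visit"].to_numpy() != pos.to_numpy()).any():
        raise MalformedInputError(
            "visit indices are not contiguous from 0; run locf_impute first"
        )

    raw_a = classify_treatment(df["n_drugs"].to_numpy(), aggressive_threshold)
    df["exposure"] = grp_cummax = (
        pd.Series(raw_a, index=df.index).groupby(df["subject_id"], sort=False).cummax()
    )
    n_recoded = int((grp_cummax.to_numpy() != raw_a).sum())
    if n_recoded:
        logger.warning(
            "monotone-exposure recoding applied to %d rows (threshold %d)",
            n_recoded,
            aggressive_threshold,
        )

    # Truncate strictly after the first event.
    cum_event = df.groupby("subject_id", sort=False)["event"].cumsum()
    keep = (cum_event - df["event"]) == 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d person-periods accrued after a first event", n_dropped)
    df = df.loc[keep].copy()

    base = baselines.set_index("subject_id")
    missing = df.loc[~df["subject_id"].isin(base.index), "subject_id"]
    if len(missing):
        raise MalformedInputError(
            f"subject {missing.iloc[0]!r} has visits but no baseline record"
        )

    df["sbp_cat"] = categorize_sbp(df["sbp"].to_numpy())
    base_cat = pd.Series(
        categorize_sbp(base["sbp_baseline"].to_numpy()), index=base.index
    )
    df["sbp_cat_base"] = df["subject_id"].map(base_cat)
    lag = df.groupby("subject_id", sort=False)["sbp_cat"].shift(1)
    df["sbp_cat_lag"] = lag.fillna(df["sbp_cat_base"])

    a_lag = (
        df.groupby("subject_id", sort=False)["exposure"].shift(1).fillna(0).astype(int)
    )
    df["at_risk_initiation"] = (a_lag == 0).astype(np.int64)
    df["censored"] = df["dropped"].astype(np.int64)
    df["exposure"] = df["exposure"].astype(np.int64)

    # categorical dtypes keep large person-period tables compact
    for col in ("sbp_cat", "sbp_cat_lag", "sbp_cat_base"):
        df[col] = pd.Categorical(df[col], categories=SBP_CATEGORIES)

    cov_cols = [c for c in BASELINE_COLUMNS if c != "subject_id"]
    ppt = df.merge(baselines[["subject_id", *cov_cols]], on="subject_id", how="left")
    if ppt["race"].dtype == object:
        ppt["race"] = pd.Categorical(ppt["race"], categories=RACE_LEVELS)
    ppt = ppt[
        [
            "subject_id",
            "visit",
            "exposure",
            "at_risk_initiation",
            "sbp_cat",
            "sbp_cat_lag",
            "sbp_cat_base",
            "sbp",
            "n_drugs",
            "observed",
            "event",
            "censored",
            *cov_cols,
        ]
    ].reset_index(drop=True)

    info = PersonPeriodInfo(
        aggressive_threshold=aggressive_threshold,
        n_subjects=int(ppt["subject_id"].nunique()),
        n_rows=int(len(ppt)),
        n_events=int(ppt["event"].sum()),
        n_recoded_exposure=n_recoded,
        n_rows_dropped_post_event=n_dropped,
    )
    return ppt, info
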