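"""Design-matrix construction shared by the weight and outcome models.

All pooled logistic models use the same vocabulary of terms:

* baseline covariates — centred age (decades over 65), female, randomized
  strategy, race/ethnicity indicators (white reference), eight comorbidity
  flags, and baseline SBP control category (usual reference);
* visit indicators — one per visit (saturated discrete-time baseline,
  first visit as reference), with sparse levels merged (see
  :func:`merge_sparse_visit_levels`);
* time-dependent SBP terms — control-category indicators at the current
  and previous visit (usual reference), used only by denominator models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COMORBIDITY_FLAGS, RACE_LEVELS

#: Full default baseline-covariate term list.
DEFAULT_BASELINE_TERMS = (
    "age_c",
    "female",
    "strategy",
    "race_black",
    "race_hispanic",
    "race_other",
    *COMORBIDITY_FLAGS,
    "sbp_base_tight",
    "sbp_base_uncontrolled",
)

#: Small covariate set for quick fits and the Cox cross-validation.
REDUCED_BASELINE_TERMS = (
    "age_c",
    "female",
    "sbp_base_tight",
    "sbp_base_uncontrolled",
)


def baseline_design(ppt: pd.DataFrame, terms=None) -> pd.DataFrame:
    """Return the baseline covariate columns of the design matrix."""
    terms = DEFAULT_BASELINE_TERMS if terms is None else tuple(terms)
    cols = {}
    for t in terms:
        if t == "age_c":
            cols[t] = (ppt["age"].to_numpy(float) - 65.0) / 10.0
        elif t in ("female", "strategy") or t in COMORBIDITY_FLAGS:
            cols[t] = ppt[t].to_numpy(float)
        elif t.startswith("race_"):
            level = t.removeprefix("race_")
            if level not in RACE_LEVELS:
                raise KeyError(f"unknown race level in term {t!r}")
            cols[t] = (ppt["race"] == level).to_numpy(float)
        elif t.startswith("sbp_base_"):
            cols[t] = (ppt["sbp_cat_base"] == t.removeprefix("sbp_base_")).to_numpy(
                float
            )
        else:
            raise KeyError(f"unknown baseline term {t!r}")
    return pd.DataFrame(cols, index=ppt.index)


def sbp_category_design(ppt: pd.DataFrame, lagged: bool = True) -> pd.DataFrame:
    """Indicators for current (and optionally previous-visit) SBP category."""
    cols = {
        "sbp_now_tight": (ppt["sbp_cat"] == "tight").to_numpy(float),
        "sbp_now_uncontrolled": (ppt["sbp_cat"] == "uncontrolled").to_numpy(float),
    }
    if lagged:
        cols["sbp_lag_tight"] = (ppt["sbp_cat_lag"] == "tight").to_numpy(float)
        cols["sbp_lag_uncontrolled"] = (ppt["sbp_cat_lag"] == "uncontrolled").to_numpy(
            float
        )
    return pd.DataFrame(cols, index=ppt.index)


def merge_sparse_visit_levels(
    visit: np.ndarray, success: np.ndarray
) -> tuple[np.ndarray, int]:
    """Merge visit strata with zero successes into the previous stratum.

    A saturated per-visit indicator basis separates when some visit has no
    successes (no initiations, no dropouts) among the fitted rows.  Such a
    level is merged with the nearest earlier retained level (the first
    level, if empty, is merged forward).  Returns the merged labels and the
    number of original levels that were merged away.
    """
    visit = np.asarray(visit)
    success = np.asarray(success)
    levels = np.unique(visit)
    counts = {lv: int(success[visit == lv].sum()) for lv in levels}
    nonempty = [lv for lv in levels if counts[lv] > 0]
    if not nonempty:
        # degenerate: no successes anywhere; collapse to a single stratum
        return np.full_like(visit, levels[0]), int(len(levels) - 1)
    mapping: dict = {}
    for lv in levels:
        if counts[lv] > 0:
            mapping[lv] = lv
        else:
            earlier = [ne for ne in nonempty if ne < lv]
            mapping[lv] = earlier[-1] if earlier else nonempty[0]
    merged = np.array([mapping[lv] for lv in visit])
    n_merged = int(len(levels) - len(np.unique(merged)))
    return merged, n_merged


def visit_design(labels: np.ndarray, index) -> pd.DataFrame:
    """Visit-indicator columns (reference = lowest label)."""
    levels = np.unique(labels)
    cols = {
        f"visit_{int(lv)}": (labels == lv).astype(float) for lv in levels[1:]
    }
    return pd.DataFrame(cols, index=index)


def with_intercept(*parts: pd.DataFrame) -> pd.DataFrame:
    """Concatenate design blocks and prepend an intercept column."""
    base = parts[0]
    X = pd.concat(
        [pd.DataFrame({"const": np.ones(len(base))}, index=base.index), *parts],
        axis=1,
    )
    return X.astype(float)
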