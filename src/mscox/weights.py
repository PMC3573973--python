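"""Stabilized inverse-probability-of-treatment and -censoring weights.

Both weight families are estimated by pooled logistic regressions on the
person-period table and combined per subject-visit:

* **IPTW** — among subjects still untreated at the previous visit, the
  probability of initiating aggressive treatment at visit ``k``.  The
  numerator model conditions on baseline covariates (including baseline SBP
  category) and visit indicators; the denominator adds SBP category at the
  current and previous visit.  The stabilized weight is the cumulative
  product over visits up to (and including) initiation of the ratio of the
  probabilities of the observed treatment status; after initiation the
  factors are 1 (treatment continues with probability one under the
  monotone-exposure assumption), so the weight is frozen at its value at
  initiation.
* **IPCW** — the probability of remaining uncensored (not dropping out)
  through each interval, with the numerator conditioning on baseline
  covariates, visit indicators and current exposure, the denominator adding
  the time-dependent SBP terms.  Event rows count as uncensored in their
  final interval; administrative end-of-study is not treated as dropout.

The combined analysis weight is the product ``sw_treat * sw_cens``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import (
    DEFAULT_BASELINE_TERMS,
    baseline_design,
    merge_sparse_visit_levels,
    sbp_category_design,
    visit_design,
    with_intercept,
)
from .errors import ConfigurationError, FitError, MalformedInputError, PositivityError

logger = logging.getLogger(__name__)

#: Default clipping bounds applied to fitted probabilities before ratios.
DEFAULT_PROBABILITY_CLIP = 1e-6


@dataclass
class PooledLogisticFit:
    """A fitted pooled logistic model for one weight-model role.

    ``fitted`` holds per-row predicted probabilities aligned to the full
    person-period table (NaN on rows the model does not apply to);
    ``row_mask`` marks the rows used in estimation.
    """

    role: str
    params: pd.Series
    fitted: np.ndarray
    row_mask: np.ndarray
    converged: bool
    n_rows_used: int
    bse: pd.Series | None = None
    n_visit_levels_merged: int = 0

    def __post_init__(self):
        used = self.fitted[self.row_mask]
        if used.size and (np.nanmin(used) <= 0.0 or np.nanmax(used) >= 1.0):
            # fitted probabilities should be interior; clipping happens later
            logger.debug("fit %s produced boundary probabilities", self.role)


def _fit_pooled_logit(X: pd.DataFrame, y: np.ndarray, role: str):
    """Fit a logistic regression, Newton first, IRLS as fallback."""
    try:
        res = sm.Logit(y, X).fit(method="newton", maxiter=100, disp=0)
        if res.mle_retvals.get("converged", False):
            return res
    except Exception:
        pass  # singular Hessian / separation: retry with IRLS below
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(maxiter=100, tol=1e-8)
    except Exception as exc:  # perfect separation, singular matrix, ...
        raise FitError(f"pooled logistic fit failed for {role}: {exc}", role) from exc
    if not res.converged:
        raise FitError(f"pooled logistic fit did not converge for {role}", role)
    return res


def _make_fit(ppt, X, y, mask, role, n_merged) -> PooledLogisticFit:
    res = _fit_pooled_logit(X, y, role)
    fitted = np.full(len(ppt), np.nan)
    # predict() gives probabilities for both Logit and GLM results
    # (Logit's .fittedvalues is the linear predictor)
    fitted[mask] = np.asarray(res.predict(X))
    return PooledLogisticFit(
        role=role,
        params=res.params,
        fitted=fitted,
        row_mask=mask,
        converged=bool(res.converged),
        n_rows_used=int(mask.sum()),
        bse=res.bse,
        n_visit_levels_merged=n_merged,
    )


def fit_initiation_models(
    ppt: pd.DataFrame, baseline_terms=None
) -> tuple[PooledLogisticFit, PooledLogisticFit]:
    """Fit numerator and denominator models for treatment initiation.

    Restricted to rows at risk of initiation (not yet treated at the
    previous visit); the outcome is initiation at the current visit.
    Returns ``(numerator, denominator)`` fits with per-row probabilities.
    """
    baseline_terms = DEFAULT_BASELINE_TERMS if baseline_terms is None else baseline_terms
    mask = ppt["at_risk_initiation"].to_numpy() == 1
    sub = ppt.loc[mask]
    y = sub["exposure"].to_numpy(float)  # at-risk + exposed now == initiation
    labels, n_merged = merge_sparse_visit_levels(sub["visit"].to_numpy(), y)
    if n_merged:
        logger.info("initiation models: merged %d sparse visit strata", n_merged)
    vis = visit_design(labels, sub.index)
    base = baseline_design(sub, baseline_terms)
    X_num = with_intercept(base, vis)
    num = _make_fit(ppt, X_num, y, mask, "iptw_numerator", n_merged)
    del X_num
    X_den = with_intercept(base, vis, sbp_category_design(sub))
    den = _make_fit(ppt, X_den, y, mask, "iptw_denominator", n_merged)
    return num, den


def fit_censoring_models(
    ppt: pd.DataFrame, baseline_terms=None
) -> tuple[PooledLogisticFit, PooledLogisticFit]:
    """Fit numerator and denominator models for dropout.

    All person-period rows contribute; the outcome is dropout at the end of
    the interval (event rows and administrative end-of-study rows count as
    uncensored).  Both models include current exposure; the denominator adds
    the time-dependent SBP terms.  Fitted values are dropout probabilities.
    """
    baseline_terms = DEFAULT_BASELINE_TERMS if baseline_terms is None else baseline_terms
    mask = np.ones(len(ppt), dtype=bool)
    y = ppt["censored"].to_numpy(float)
    if y.sum() == 0:
        # no dropout anywhere: degenerate fits with probability 0
        zero = PooledLogisticFit(
            role="ipcw_degenerate",
            params=pd.Series(dtype=float),
            fitted=np.zeros(len(ppt)),
            row_mask=mask,
            converged=True,
            n_rows_used=len(ppt),
        )
        num = replace(zero, role="ipcw_numerator")
        den = replace(zero, role="ipcw_denominator")
        return num, den
    labels, n_merged = merge_sparse_visit_levels(ppt["visit"].to_numpy(), y)
    if n_merged:
        logger.info("censoring models: merged %d sparse visit strata", n_merged)
    vis = visit_design(labels, ppt.index)
    base = baseline_design(ppt, baseline_terms)
    expo = pd.DataFrame({"exposure": ppt["exposure"].to_numpy(float)}, index=ppt.index)
    X_num = with_intercept(base, expo, vis)
    num = _make_fit(ppt, X_num, y, mask, "ipcw_numerator", n_merged)
    del X_num
    X_den = with_intercept(base, expo, vis, sbp_category_design(ppt))
    den = _make_fit(ppt, X_den, y, mask, "ipcw_denominator", n_merged)
    return num, den


def _clipped(p: np.ndarray, clip: float | None, role: str) -> np.ndarray:
    if clip is None:
        eps = np.finfo(float).eps
        bad = np.where((p <= eps) | (p >= 1 - eps))[0]
        if bad.size:
            raise PositivityError(
                f"{role}: fitted probability at machine 0/1 on row {int(bad[0])}"
            )
        return p
    n_clip = int(np.sum((p < clip) | (p > 1 - clip)))
    if n_clip:
        logger.info("%s: clipped %d fitted probabilities to [%g, %g]", role, n_clip, clip, 1 - clip)
    return np.clip(p, clip, 1 - clip)


def compute_stabilized_iptw(
    ppt: pd.DataFrame,
    numerator: PooledLogisticFit,
    denominator: PooledLogisticFit,
    probability_clip: float | None = DEFAULT_PROBABILITY_CLIP,
) -> pd.Series:
    """Per-row stabilized treatment weights (cumulative within subject).

    For pre-initiation rows the factor uses probabilities of remaining
    unexposed, at initiation the probabilities of initiating, and after
    initiation the factor is 1, so ``sw_treat`` is constant from initiation
    onward.
    """
    factor = np.ones(len(ppt))
    mask = numerator.row_mask
    if mask.any():
        pn = _clipped(numerator.fitted[mask], probability_clip, "iptw numerator")
        pd_ = _clipped(denominator.fitted[mask], probability_clip, "iptw denominator")
        a = ppt.loc[mask, "exposure"].to_numpy()
        factor[mask] = np.where(a == 1, pn / pd_, (1.0 - pn) / (1.0 - pd_))
    sw = (
        pd.Series(factor, index=ppt.index)
        .groupby(ppt["subject_id"], sort=False)
        .cumprod()
    )
    sw.name = "sw_treat"
    return sw


def compute_stabilized_ipcw(
    ppt: pd.DataFrame,
    numerator: PooledLogisticFit,
    denominator: PooledLogisticFit,
    probability_clip: float | None = DEFAULT_PROBABILITY_CLIP,
) -> pd.Series:
    """Per-row stabilized censoring weights (cumulative within subject).

    Each interval contributes the ratio of the numerator to denominator
    probability of remaining uncensored through that interval.
    """
    # fitted values are dropout probabilities; convert to staying probabilities
    pn_drop = _clipped(numerator.fitted, probability_clip, "ipcw numerator")
    pd_drop = _clipped(denominator.fitted, probability_clip, "ipcw denominator")
    factor = (1.0 - pn_drop) / (1.0 - pd_drop)
    sw = (
        pd.Series(factor, index=ppt.index)
        .groupby(ppt["subject_id"], sort=False)
        .cumprod()
    )
    sw.name = "sw_cens"
    return sw


def combine_weights(
    ppt: pd.DataFrame,
    sw_treat: pd.Series,
    sw_cens: pd.Series,
    truncation: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Combine treatment and censoring weights into the analysis weights.

    ``sw_combined = sw_treat * sw_cens``; if ``truncation`` percentiles
    ``(p_lo, p_hi)`` (in percent) are given, combined weights are winsorized
    to those empirical percentiles and flagged.  Default: no truncation.
    """
    if not (len(ppt) == len(sw_treat) == len(sw_cens)) or not (
        ppt.index.equals(sw_treat.index) and ppt.index.equals(sw_cens.index)
    ):
        raise MalformedInputError("weight series are not aligned to the person-period table")
    combined = sw_treat.to_numpy() * sw_cens.to_numpy()
    truncated = np.zeros(len(ppt), dtype=np.int64)
    if truncation is not None:
        lo_p, hi_p = truncation
        if not (0 <= lo_p < hi_p <= 100):
            raise ConfigurationError(f"invalid truncation percentiles {truncation!r}")
        lo, hi = np.percentile(combined, [lo_p, hi_p])
        truncated = ((combined < lo) | (combined > hi)).astype(np.int64)
        combined = np.clip(combined, lo, hi)
    return pd.DataFrame(
        {
            "subject_id": ppt["subject_id"].to_numpy(),
            "visit": ppt["visit"].to_numpy(),
            "sw_treat": sw_treat.to_numpy(),
            "sw_cens": sw_cens.to_numpy(),
            "sw_combined": combined,
            "truncated": truncated,
        },
        index=ppt.index,
    )


def estimate_weights(
    ppt: pd.DataFrame,
    baseline_terms=None,
    truncation: tuple[float, float] | None = None,
    probability_clip: float | None = DEFAULT_PROBABILITY_CLIP,
) -> pd.DataFrame:
    """Full weight pipeline: fit all four models and combine the weights."""
    it_num, it_den = fit_initiation_models(ppt, baseline_terms)
    c_num, c_den = fit_censoring_models(ppt, baseline_terms)
    sw_t = compute_stabilized_iptw(ppt, it_num, it_den, probability_clip)
    sw_c = compute_stabilized_ipcw(ppt, c_num, c_den, probability_clip)
    return combine_weights(ppt, sw_t, sw_c, truncation)


def weight_diagnostics(weight_table: pd.DataFrame, bounds=(0.1, 10.0)) -> dict:
    """Summaries of the combined weights, overall and per visit."""
    if weight_table.empty:
        raise MalformedInputError("empty weight table")
    w = weight_table["sw_combined"]
    per_visit = (
        weight_table.groupby("visit")["sw_combined"]
        .agg(["mean", "std", "min", "max"])
        .fillna(0.0)
    )
    qs = weight_table.groupby("visit")["sw_combined"].quantile([0.01, 0.5, 0.99]).unstack()
    per_visit = per_visit.join(qs.rename(columns={0.01: "p1", 0.5: "p50", 0.99: "p99"}))
    lo, hi = bounds
    return {
        "overall_mean": float(w.mean()),
        "overall_sd": float(w.std(ddof=0)),
        "max_weight": float(w.max()),
        "min_weight": float(w.min()),
        "n_truncated": int(weight_table["truncated"].sum()),
        "n_outside_bounds": int(((w < lo) | (w > hi)).sum()),
        "per_visit": per_visit,
    }
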