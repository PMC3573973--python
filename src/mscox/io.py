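"""Readers, writers, run configuration and the end-to-end pipeline.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header row,
missing values as empty fields.  A cohort is two CSVs — a baseline table
keyed by ``subject_id`` and a visit table with one row per attended
subject-visit (missing visits are absent rows).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    BASELINE_COLUMNS,
    MAX_VISITS,
    RACE_LEVELS,
    SUPPORTED_THRESHOLDS,
    VISIT_COLUMNS,
    build_person_period,
    locf_impute,
)
from .errors import ConfigurationError, SchemaError
from .estimation import (
    ModelSpec,
    bootstrap_ci,
    compare_models,
    fit_mscm,
    fit_standard_cox,
)
from .simulate import get_scenario, simulate_cohort
from .weights import estimate_weights, weight_diagnostics

logger = logging.getLogger(__name__)

_REQUIRED_VISIT_COLS = ("subject_id", "visit", "n_drugs", "sbp", "event", "dropped")


def write_cohort(baselines: pd.DataFrame, visits: pd.DataFrame, out_dir) -> dict:
    """Write the two cohort CSVs; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bpath = out_dir / "baseline.csv"
    vpath = out_dir / "visits.csv"
    baselines.to_csv(bpath, index=False)
    visits.to_csv(vpath, index=False)
    return {"baseline": str(bpath), "visits": str(vpath)}


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} CSV is missing required column(s): {missing}")


def read_cohort(baseline_path, visits_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the cohort CSV pair.

    Schema violations (missing columns, duplicate keys, out-of-range visit
    indices, non-numeric SBP, invalid flags) raise :class:`SchemaError`
    naming the offending column or row.
    """
    baselines = pd.read_csv(baseline_path)
    visits = pd.read_csv(visits_path)
    _require_columns(baselines, BASELINE_COLUMNS, "baseline")
    _require_columns(visits, _REQUIRED_VISIT_COLS, "visits")

    if baselines["subject_id"].duplicated().any():
        dup = baselines.loc[baselines["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise SchemaError(f"duplicate subject_id {dup!r} in baseline CSV")
    dup_mask = visits.duplicated(subset=["subject_id", "visit"])
    if dup_mask.any():
        row = int(np.flatnonzero(dup_mask)[0]) + 2  # 1-based incl. header
        raise SchemaError(f"duplicate (subject_id, visit) in visits CSV at line {row}")

    for col in ("sbp",):
        if not np.issubdtype(visits[col].dtype, np.number):
            raise SchemaError(f"visits column {col!r} must be numeric")
        if visits[col].isna().any():
            row = int(np.flatnonzero(visits[col].isna())[0]) + 2
            raise SchemaError(f"missing sbp in visits CSV at line {row}")
    if not np.issubdtype(visits["visit"].dtype, np.integer):
        raise SchemaError("visits column 'visit' must be integer")
    bad = (visits["visit"] < 0) | (visits["visit"] >= MAX_VISITS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise SchemaError(
            f"visit index out of range [0, {MAX_VISITS}) at line {row} of visits CSV"
        )
    if (baselines["age"] < 50).any():
        raise SchemaError("baseline ages below 50 are outside the eligible range")
    if (baselines["sbp_baseline"] <= 0).any():
        raise SchemaError("baseline SBP must be positive")
    unknown_race = set(baselines["race"].unique()) - set(RACE_LEVELS)
    if unknown_race:
        raise SchemaError(f"unknown race level(s) {sorted(unknown_race)}")
    for flagcol in [c for c in BASELINE_COLUMNS if c.startswith("hist_")] + [
        "female",
        "strategy",
    ]:
        if not baselines[flagcol].isin([0, 1]).all():
            raise SchemaError(f"baseline column {flagcol!r} must be 0/1")
    if "observed" not in visits.columns:
        visits = visits.assign(observed=1)
    return baselines, visits[list(VISIT_COLUMNS)]


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run."""

    out_dir: str = "mscox_run"
    seed: int = 0
    threshold: int = 3
    scenario: str | None = "invest_like"
    n_subjects: int = 10_000
    baseline_csv: str | None = None
    visits_csv: str | None = None
    model: str = "both"  # mscm | standard | both
    ci_method: str = "robust"  # robust | bootstrap
    ci_level: float = 0.95
    bootstrap_reps: int = 200
    truncation: tuple | None = None
    compare_thresholds: tuple = (3, 2, 4)
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.threshold not in SUPPORTED_THRESHOLDS:
            raise ConfigurationError(
                f"threshold must be in {SUPPORTED_THRESHOLDS}, got {self.threshold}"
            )
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must be in (0, 1)")
        if self.model not in ("mscm", "standard", "both"):
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.ci_method not in ("robust", "bootstrap"):
            raise ConfigurationError(f"unknown ci method {self.ci_method!r}")
        if self.scenario is None and (self.baseline_csv is None or self.visits_csv is None):
            raise ConfigurationError("need either a scenario or cohort CSV paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if "truncation" in raw and raw["truncation"] is not None:
            raw["truncation"] = tuple(raw["truncation"])
        if "compare_thresholds" in raw:
            raw["compare_thresholds"] = tuple(raw["compare_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truncation"] = list(self.truncation) if self.truncation else None
        d["compare_thresholds"] = list(self.compare_thresholds)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute cohort → weights → estimation (→ comparison) and write outputs.

    Returns a results bundle (also written to ``out_dir``): person-period
    and weight CSVs, diagnostics, hazard-ratio estimates, and a manifest
    with the config hash and seed sufficient to regenerate every artifact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/read"
    try:
        if config.scenario is not None:
            sc = get_scenario(config.scenario)
            cfg = sc.config.replace(n_subjects=config.n_subjects, seed=config.seed)
            baselines, visits = simulate_cohort(cfg)
        else:
            baselines, visits = read_cohort(config.baseline_csv, config.visits_csv)
        write_cohort(baselines, visits, out)

        stage = "prepare"
        visits_c = locf_impute(visits)
        ppt, info = build_person_period(baselines, visits_c, config.threshold)
        ppt.to_csv(out / "person_period.csv", index=False)
        with open(out / "person_period.json", "w") as fh:
            json.dump(info.to_dict(), fh, indent=2)

        stage = "weights"
        wt = estimate_weights(ppt, truncation=config.truncation)
        wt.to_csv(out / "weights.csv", index=False)
        diag = weight_diagnostics(wt)
        diag_out = {k: v for k, v in diag.items() if k != "per_visit"}
        diag_out["per_visit"] = diag["per_visit"].reset_index().to_dict("records")
        with open(out / "weight_diagnostics.json", "w") as fh:
            json.dump(diag_out, fh, indent=2)

        stage = "estimation"
        spec = ModelSpec(ci_level=config.ci_level)
        results = {}
        if config.model in ("mscm", "both"):
            if config.ci_method == "bootstrap":
                est = bootstrap_ci(
                    ppt, spec, B=config.bootstrap_reps, seed=config.seed,
                    truncation=config.truncation,
                )
            else:
                est = fit_mscm(ppt, wt, spec)
            results["mscm"] = est.to_dict()
        if config.model in ("standard", "both"):
            results["standard_cox"] = fit_standard_cox(ppt, spec).to_dict()

        comparison = None
        if config.model == "both":
            stage = "comparison"
            comparison = compare_models(
                baselines, visits_c, config.compare_thresholds, spec,
                truncation=config.truncation,
            )
            comparison.to_csv(out / "comparison.csv", index=False)

        stage = "report"
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
            "n_rows_person_period": info.n_rows,
            "n_events": info.n_events,
            "n_recoded_exposure": info.n_recoded_exposure,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {
        "results": results,
        "comparison": comparison,
        "info": info,
        "manifest": manifest,
        "out_dir": str(out),
    }
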