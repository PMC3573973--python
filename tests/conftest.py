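import numpy as np
import pandas as pd
import pytest

from mscox.cohort import build_person_period, locf_impute
from mscox.simulate import get_scenario, simulate_cohort
from mscox.weights import estimate_weights


def make_baseline(subject_id, sbp_baseline=150.0, age=66.0, **kw):
    row = {
        "subject_id": subject_id,
        "age": age,
        "female": 1,
        "race": "white",
        "strategy": 0,
        "hist_mi": 0,
        "hist_stroke_tia": 0,
        "hist_chf": 0,
        "hist_diabetes": 0,
        "hist_renal": 0,
        "hist_pvd": 0,
        "hist_revasc": 0,
        "hist_smoking": 0,
        "sbp_baseline": sbp_baseline,
    }
    row.update(kw)
    return row


def make_visits(subject_id, n_drugs, sbp, event=None, dropped=None, visits=None):
    """Build a visit series from parallel per-visit lists."""
    k = len(n_drugs)
    visits = list(range(k)) if visits is None else visits
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "visit": visits,
            "n_drugs": n_drugs,
            "sbp": sbp,
            "observed": 1,
            "event": event if event is not None else [0] * k,
            "dropped": dropped if dropped is not None else [0] * k,
        }
    )


@pytest.fixture
def tiny_cohort():
    """Three hand-built subjects: a step-up initiator, an event, a dropout."""
    baselines = pd.DataFrame(
        [
            make_baseline("a", sbp_baseline=150.0),
            make_baseline("b", sbp_baseline=118.0),
            make_baseline("c", sbp_baseline=135.0),
        ]
    )
    visits = pd.concat(
        [
            make_visits("a", [2, 2, 3, 3], [150, 145, 148, 132]),
            make_visits("b", [2, 3, 3], [118, 122, 125], event=[0, 0, 1]),
            make_visits("c", [2, 2], [135, 141], dropped=[0, 1]),
        ],
        ignore_index=True,
    )
    return baselines, visits


@pytest.fixture(scope="session")
def sim_fixture():
    """One mid-sized simulated cohort shared across estimation tests."""
    cfg = get_scenario("invest_like").config.replace(n_subjects=4000, seed=11)
    baselines, visits = simulate_cohort(cfg)
    ppt, info = build_person_period(baselines, locf_impute(visits), 3)
    weights = estimate_weights(ppt)
    return {
        "config": cfg,
        "baselines": baselines,
        "visits": visits,
        "ppt": ppt,
        "info": info,
        "weights": weights,
    }
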