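import numpy as np
import pandas as pd
import pytest

from geosurv import spatial, synthetic_data

#: covariate marginals guaranteeing exposure in every model level
FULL_MARGINALS = {
    "sex": {"male": 0.5},
    "residence": {"rural": 0.6},
    "preceding_interval": {"lt24": 0.3},
    "antenatal": {"none": 0.2},
    "delivery_place": {"home": 0.5},
    "wealth": {"middle": 0.33, "low": 0.33},
    "education": {"primary_or_less": 0.6},
    "marital": {"single": 0.15},
}


@pytest.fixture(scope="session")
def drc_graph():
    return spatial.drc_provinces()


def make_sim_config(
    seed,
    graph,
    n_children=3000,
    gamma=None,
    baseline_hazard=None,
    f_str=None,
    f_unstr=None,
    mother_age_curvature=0.0,
    p_heap=0.0,
    censoring="uniform",
):
    """Small-scale simulation settings used across recovery tests: declining
    monthly baseline hazard, uniform provinces, all effects zero unless set."""
    if baseline_hazard is None:
        t = np.arange(1, 61)
        baseline_hazard = np.exp(-5.15 - 0.02 * t)
    R = graph.n_regions
    return synthetic_data.SimConfig(
        n_children=n_children,
        seed=seed,
        province_labels=graph.labels,
        province_probs=tuple([1.0 / R] * R),
        covariate_marginals=FULL_MARGINALS,
        gamma=gamma or {},
        baseline_hazard=tuple(baseline_hazard),
        f_str=tuple(f_str if f_str is not None else [0.0] * R),
        f_unstr=tuple(f_unstr if f_unstr is not None else [0.0] * R),
        mother_age_curvature=mother_age_curvature,
        p_heap=p_heap,
        censoring=censoring,
    )


def make_records(
    n,
    rng,
    graph,
    death_prob=0.15,
    max_reported_age=80,
):
    """Hand-rolled random birth-record frame (independent of the simulator)."""
    from geosurv.data_model import CATEGORY_LEVELS

    cols = {
        "child_id": [f"k{i}" for i in range(n)],
        "event": rng.binomial(1, death_prob, n),
        "age_months": rng.integers(0, max_reported_age, n),
        "province": rng.choice(graph.labels, n),
        "mother_age_at_birth": rng.uniform(15, 45, n).round(1),
    }
    for fld, levels in CATEGORY_LEVELS.items():
        cols[fld] = rng.choice(levels, n)
    return pd.DataFrame(cols)
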