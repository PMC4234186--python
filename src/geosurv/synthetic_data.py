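"""DHS-like synthetic birth histories with known ground truth.

The generator draws, per child, categorical covariates and a province,
builds the monthly death hazard

    h_it = logit^-1( logit(h0(t)) + w_i' gamma + f_age(a_i) + f_str(s_i) + f_unstr(s_i) ),

runs the Bernoulli month-by-month survival process, censors at a uniform
interview age (births fall uniformly in the five-year survey window), and
finally applies an age-heaping operator that relocates reported death ages
inside a window to the nearest of the classic digit-preference targets
24/30/36 months.  Heaping moves reported ages only; it never changes who
died.  The full truth (effects and per-child true death month) is returned
alongside the records so recovery tests never reverse-engineer it.
"""

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import CATEGORY_LEVELS, MAX_AGE_MONTHS
from .spatial import drc_provinces

__all__ = ["SimConfig", "generate", "default_paper_like_config"]

_DEATH_TARGET = 1005 / 8992  # observed-death fraction the default config calibrates to


def _logit(p):
    return np.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs, including the truth."""

    n_children: int
    seed: int
    province_labels: tuple
    province_probs: tuple
    #: marginal probability of the *non-reference* level(s), per categorical field
    covariate_marginals: dict
    #: true log-odds ratios keyed "field:level"
    gamma: dict
    #: true baseline monthly hazard, one value per month 1..60
    baseline_hazard: tuple
    #: true centered spatial effects, one per province (same order as labels)
    f_str: tuple
    f_unstr: tuple
    #: quadratic U-shape of mother's age: curvature * ((age - vertex)/10)^2, centered
    mother_age_curvature: float = 0.15
    mother_age_vertex: float = 27.0
    #: Beta(shape1, shape2) scaled to [14, 45] for mother's age at birth
    mother_age_beta: tuple = (1.8, 3.2)
    p_heap: float = 0.25
    heap_targets: tuple = (24, 30, 36)
    heap_window: tuple = (18, 42)  # half-open (lo, hi]: true ages lo < a <= hi
    censoring: str = "uniform"  # "uniform": interview age uniform on 0..59; "none": full follow-up

    def __post_init__(self):
        if self.n_children < 1:
            raise ValueError("n_children must be at least 1")
        probs = np.asarray(self.province_probs, float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("province probabilities must be non-negative and sum to 1")
        if len(self.province_labels) != len(probs):
            raise ValueError("province labels and probabilities differ in length")
        h = np.asarray(self.baseline_hazard, float)
        if h.shape[0] != MAX_AGE_MONTHS or (h < 0).any() or (h > 1).any():
            raise ValueError("baseline_hazard must give 60 values in [0, 1]")
        if not (0.0 <= self.p_heap <= 1.0):
            raise ValueError("p_heap must lie in [0, 1]")
        if self.censoring not in ("uniform", "none"):
            raise ValueError("censoring must be 'uniform' or 'none'")
        for fld, marg in self.covariate_marginals.items():
            if fld not in CATEGORY_LEVELS:
                raise ValueError(f"unknown covariate {fld!r}")
            total = sum(marg.values())
            if total > 1.0 + 1e-9 or any(v < 0 for v in marg.values()):
                raise ValueError(f"invalid marginal probabilities for {fld!r}")

    def mother_age_effect(self, age):
        """Centered U-shaped true effect of mother's age at birth."""
        age = np.asarray(age, float)
        raw = self.mother_age_curvature * ((age - self.mother_age_vertex) / 10.0) ** 2
        # center against the age distribution's own expectation (numeric)
        lo, hi = 14.0, 45.0
        grid = np.linspace(lo, hi, 400)
        from scipy.stats import beta as beta_dist

        a, b = self.mother_age_beta
        w = beta_dist.pdf((grid - lo) / (hi - lo), a, b)
        w = w / w.sum()
        mean = np.sum(self.mother_age_curvature * ((grid - self.mother_age_vertex) / 10.0) ** 2 * w)
        return raw - mean


def _draw_covariates(cfg, rng):
    n = cfg.n_children
    cols = {}
    for fld, levels in CATEGORY_LEVELS.items():
        marg = cfg.covariate_marginals.get(fld, {})
        probs = [marg.get(level, 0.0) for level in levels[1:]]
        ref_p = 1.0 - sum(probs)
        full = np.array([ref_p] + probs)
        cols[fld] = rng.choice(list(levels), size=n, p=full)
    return cols


def generate(cfg):
    """Simulate birth records; returns ``(records_frame, truth_dict)``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_children
    cols = _draw_covariates(cfg, rng)
    prov_idx = rng.choice(len(cfg.province_labels), size=n, p=np.asarray(cfg.province_probs))
    province = np.asarray(cfg.province_labels)[prov_idx]
    lo, hi = 14.0, 45.0
    a, b = cfg.mother_age_beta
    mother_age = lo + (hi - lo) * rng.beta(a, b, size=n)
    mother_age = np.clip(mother_age, 10.0, 49.0)

    lp_child = np.zeros(n)
    for key, val in cfg.gamma.items():
        fld, level = key.split(":")
        lp_child += (cols[fld] == level) * float(val)
    lp_child += cfg.mother_age_effect(mother_age)
    f_tot = np.asarray(cfg.f_str, float) + np.asarray(cfg.f_unstr, float)
    lp_child += f_tot[prov_idx]

    h0 = np.asarray(cfg.baseline_hazard, float)
    hazards = _sigmoid(_logit(np.clip(h0, 1e-12, 1 - 1e-12))[None, :] + lp_child[:, None])

    u = rng.random((n, MAX_AGE_MONTHS))
    dies = u < hazards
    any_death = dies.any(axis=1)
    death_t = np.where(any_death, dies.argmax(axis=1) + 1, 0)  # interval 1..60, 0 = never

    if cfg.censoring == "uniform":
        censor_age = rng.integers(0, MAX_AGE_MONTHS, size=n)  # completed months at interview
    else:  # full five-year follow-up for every child
        censor_age = np.full(n, MAX_AGE_MONTHS)
    observed_death = any_death & (death_t <= censor_age)
    true_age_at_death = death_t - 1  # completed months

    reported_age = np.where(observed_death, true_age_at_death, censor_age)
    # heaping: relocate reported death ages inside (lo, hi] to the nearest target
    wlo, whi = cfg.heap_window
    heapable = observed_death & (true_age_at_death > wlo) & (true_age_at_death <= whi)
    do_heap = heapable & (rng.random(n) < cfg.p_heap)
    if do_heap.any():
        targets = np.asarray(cfg.heap_targets, float)
        dist = np.abs(true_age_at_death[do_heap, None] - targets[None, :])
        nearest = targets[dist.argmin(axis=1)].astype(int)  # ties -> first target
        reported_age = reported_age.copy()
        reported_age[do_heap] = nearest

    records = pd.DataFrame(
        {
            "child_id": [f"c{i:06d}" for i in range(n)],
            "event": observed_death.astype(int),
            "age_months": reported_age.astype(int),
            **cols,
            "province": province,
            "mother_age_at_birth": np.round(mother_age, 2),
        }
    )
    truth = {
        "config": asdict(cfg),
        "gamma": dict(cfg.gamma),
        "baseline_hazard": list(map(float, h0)),
        "f_str": list(map(float, cfg.f_str)),
        "f_unstr": list(map(float, cfg.f_unstr)),
        "true_death_interval": death_t.tolist(),  # 0 = survived all 60 months
        "true_age_at_death": np.where(any_death, true_age_at_death, -1).tolist(),
        "censor_age": censor_age.tolist(),
        "n_observed_deaths": int(observed_death.sum()),
    }
    return records, truth


def _expected_observed_death_fraction(delta, h0_shape, lp_child):
    """P(death observed before a uniform interview age) averaged over children."""
    h = _sigmoid(_logit(h0_shape)[None, :] + delta + lp_child[:, None])
    surv = np.cumprod(1.0 - h, axis=1)
    prev = np.concatenate([np.ones((h.shape[0], 1)), surv[:, :-1]], axis=1)
    death_prob = prev * h  # P(die in interval t)
    t = np.arange(1, MAX_AGE_MONTHS + 1)
    p_obs = (MAX_AGE_MONTHS - t) / MAX_AGE_MONTHS  # P(uniform censor age >= t)
    return float((death_prob * p_obs[None, :]).mean(axis=0).sum())


_CALIBRATION_CACHE = {}


def default_paper_like_config(seed=2007, n_children=8992, p_heap=0.25):
    """The study-like default: 11 provinces, ~9,000 births, ~11% observed deaths.

    The baseline hazard declines log-linearly over months 1..60 and its
    level is calibrated (deterministically, against a fixed internal
    reference population) so the expected number of observed deaths matches
    the 1,005 / 8,992 fraction of the emulated survey.  Covariate effect
    *orderings* follow the study's descriptive tables (rural excess, short
    preceding interval excess, home-delivery and single-mother excess,
    wealth/education gradients); spatial defaults put Maniema high and
    North Kivu / Kinshasa low.
    """
    graph = drc_provinces()
    labels = graph.labels
    # population shares: Kinshasa, Bas-Congo, Bandundu, Equateur, Orientale,
    # North-Kivu, South-Kivu, Maniema, Katanga, Kasai-Oriental, Kasai-Occidental
    probs = np.array([0.09, 0.05, 0.11, 0.10, 0.12, 0.08, 0.07, 0.03, 0.15, 0.11, 0.09])
    probs = probs / probs.sum()
    marginals = {
        "sex": {"male": 0.51},
        "residence": {"rural": 0.65},
        "preceding_interval": {"lt24": 0.25},
        "antenatal": {"none": 0.20},
        "delivery_place": {"home": 0.60},
        "wealth": {"middle": 0.35, "low": 0.40},
        "education": {"primary_or_less": 0.70},
        "marital": {"single": 0.10},
    }
    gamma = {
        "residence:rural": float(np.log(1.30)),
        "sex:male": float(np.log(1.10)),
        "preceding_interval:lt24": float(np.log(1.45)),
        "antenatal:none": float(np.log(1.05)),
        "delivery_place:home": float(np.log(1.20)),
        "wealth:low": float(np.log(1.30)),
        "wealth:middle": float(np.log(1.15)),
        "education:primary_or_less": float(np.log(1.15)),
        "marital:single": float(np.log(1.20)),
    }
    spatial = {
        "Kinshasa": -0.30,
        "Bas-Congo": 0.05,
        "Bandundu": -0.10,
        "Equateur": 0.00,
        "Orientale": 0.10,
        "North-Kivu": -0.25,
        "South-Kivu": 0.10,
        "Maniema": 0.30,
        "Katanga": 0.00,
        "Kasai-Oriental": 0.10,
        "Kasai-Occidental": 0.05,
    }
    f_str = np.array([spatial[lab] for lab in labels])
    f_str = f_str - f_str.mean()
    f_unstr = np.zeros(len(labels))

    # declining baseline shape, level calibrated on a fixed reference
    # population (cached: it does not depend on seed, n_children or p_heap)
    if "h0" in _CALIBRATION_CACHE:
        return SimConfig(
            n_children=n_children,
            seed=seed,
            province_labels=labels,
            province_probs=tuple(map(float, probs)),
            covariate_marginals=marginals,
            gamma=gamma,
            baseline_hazard=_CALIBRATION_CACHE["h0"],
            f_str=tuple(map(float, f_str)),
            f_unstr=tuple(map(float, f_unstr)),
            p_heap=p_heap,
        )
    t = np.arange(1, MAX_AGE_MONTHS + 1)
    shape = np.exp(-0.035 * t)
    shape = shape / shape[0]
    cal_rng = np.random.default_rng(123456789)
    n_cal = 20000
    cal_cols = {}
    for fld, levels in CATEGORY_LEVELS.items():
        marg = marginals.get(fld, {})
        p_nonref = [marg.get(level, 0.0) for level in levels[1:]]
        full = np.array([1.0 - sum(p_nonref)] + p_nonref)
        cal_cols[fld] = cal_rng.choice(list(levels), size=n_cal, p=full)
    lp = np.zeros(n_cal)
    for key, val in gamma.items():
        fld, level = key.split(":")
        lp += (cal_cols[fld] == level) * val
    cal_prov = cal_rng.choice(len(labels), size=n_cal, p=probs)
    lp += (f_str + f_unstr)[cal_prov]
    cal_age = 14.0 + 31.0 * cal_rng.beta(1.8, 3.2, size=n_cal)
    # same centered U-shape the generator applies
    grid = np.linspace(14.0, 45.0, 400)
    from scipy.stats import beta as beta_dist

    w = beta_dist.pdf((grid - 14.0) / 31.0, 1.8, 3.2)
    w = w / w.sum()
    age_mean = np.sum(0.15 * ((grid - 27.0) / 10.0) ** 2 * w)
    lp += 0.15 * ((cal_age - 27.0) / 10.0) ** 2 - age_mean

    from scipy.optimize import brentq

    h0_shape = np.clip(shape * 0.005, 1e-9, 0.5)  # provisional level, rescaled below

    def objective(delta):
        return _expected_observed_death_fraction(delta, h0_shape, lp) - _DEATH_TARGET

    delta = brentq(objective, -4.0, 4.0, xtol=1e-6)
    h0 = _sigmoid(_logit(h0_shape) + delta)
    _CALIBRATION_CACHE["h0"] = tuple(map(float, h0))

    return SimConfig(
        n_children=n_children,
        seed=seed,
        province_labels=labels,
        province_probs=tuple(map(float, probs)),
        covariate_marginals=marginals,
        gamma=gamma,
        baseline_hazard=tuple(map(float, h0)),
        f_str=tuple(map(float, f_str)),
        f_unstr=tuple(map(float, f_unstr)),
        p_heap=p_heap,
    )
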