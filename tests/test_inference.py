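"""The augmented Gibbs sampler: likelihood, conjugate updates, block draws,
constraint preservation and seeded determinism."""

import numpy as np
import pandas as pd
import pytest

from geosurv import data_model, inference, summaries
from geosurv.inference import (
    McmcConfig,
    ModelSpec,
    fit,
    loglik,
    update_block,
    update_variance,
)
from geosurv.smoothers import rw2_penalty
from geosurv import synthetic_data

from conftest import make_sim_config


# ---------------------------------------------------------------- likelihood
def test_loglik_trivial_values():
    assert loglik([0.0], [1.0]) == pytest.approx(np.log(0.5))
    assert loglik([-40.0], [0.0]) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        loglik([0.0, 1.0], [1.0])


def test_loglik_matches_bernoulli_product_oracle():
    rng = np.random.default_rng(11)
    eta = rng.normal(0, 2, size=20)
    y = rng.binomial(1, 0.5, size=20)
    p = 1 / (1 + np.exp(-eta))
    brute = float(np.log(np.prod(np.where(y == 1, p, 1 - p))))
    assert loglik(eta, y) == pytest.approx(brute, abs=1e-10)


def test_loglik_is_overflow_safe():
    assert np.isfinite(loglik([800.0, -800.0], [1.0, 0.0]))


# ---------------------------------------------------------- variance update
def test_update_variance_moment_check_against_closed_form():
    K = rw2_penalty(8)
    rng = np.random.default_rng(0)
    a, b = 2.0, 3.0
    rank = 6
    draws = np.array([update_variance(np.zeros(8), K, a, b, rng) for _ in range(100_000)])
    # f = 0: tau2 ~ IG(a + rank/2, b); mean = b / (a + rank/2 - 1)
    expect = b / (a + rank / 2 - 1)
    assert draws.mean() == pytest.approx(expect, rel=0.03)


def test_update_variance_determinism_and_scaling():
    K = rw2_penalty(5)
    f = np.arange(5.0) ** 2
    d1 = update_variance(f, K, 0.001, 0.001, np.random.default_rng(5))
    d2 = update_variance(f, K, 0.001, 0.001, np.random.default_rng(5))
    assert d1 == d2
    # scaling f by c scales the penalty quadratic form by c^2
    assert (3.0 * f) @ K @ (3.0 * f) == pytest.approx(9.0 * f @ K @ f)


# --------------------------------------------------------------- block draw
def test_update_block_single_coefficient_closed_form_moments():
    rng = np.random.default_rng(1)
    n = 50
    design = np.ones((n, 1))
    omega = np.full(n, 0.7)
    kappa = rng.normal(size=n)
    prior_prec = np.array([[2.0]])
    P = n * 0.7 + 2.0
    mean = kappa.sum() / P
    draws = np.array(
        [
            update_block(design, kappa, omega, np.zeros(n), prior_prec, rng)[0]
            for _ in range(40_000)
        ]
    )
    assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(1 / P / 40_000) + 1e-3)
    assert draws.var() == pytest.approx(1 / P, rel=0.05)


def test_update_block_reproduces_rw2_prior_without_data():
    # nearly-zero augmentation weights: the draw is prior-dominated and
    # f'Kf / tau2 behaves as chi-square with rank(K) degrees of freedom
    m, tau2 = 8, 0.5
    K = rw2_penalty(m)
    rng = np.random.default_rng(2)
    design = np.eye(m)
    omega = np.full(m, 1e-8)
    qforms = []
    for _ in range(4000):
        f = update_block(design, np.zeros(m), omega, np.zeros(m), K / tau2, rng)
        qforms.append(f @ K @ f / tau2)
    qforms = np.array(qforms)
    assert qforms.mean() == pytest.approx(m - 2, rel=0.1)
    assert qforms.var() == pytest.approx(2 * (m - 2), rel=0.25)


def test_update_block_seeded_reproducibility():
    design = np.ones((10, 2))
    design[:, 1] = np.arange(10)
    args = (design, np.zeros(10), np.ones(10), np.zeros(10), np.eye(2))
    d1 = update_block(*args, np.random.default_rng(3))
    d2 = update_block(*args, np.random.default_rng(3))
    assert np.array_equal(d1, d2)


def test_update_block_singular_precision_names_the_block():
    design = np.zeros((5, 2))
    with pytest.raises(np.linalg.LinAlgError, match="doomed"):
        update_block(design, np.zeros(5), np.zeros(5), np.zeros(5), np.zeros((2, 2)),
                     np.random.default_rng(0), block="doomed")


# ----------------------------------------------------------------- full fit
@pytest.fixture(scope="module")
def small_fit(drc_graph):
    cfg = make_sim_config(31, drc_graph, n_children=900,
                          gamma={"residence:rural": 0.3}, mother_age_curvature=0.1)
    records, _ = synthetic_data.generate(cfg)
    pp = data_model.expand(records)
    mcmc = McmcConfig(seed=8, n_iter=260, burn_in=60, thin=2)
    return fit(pp, ModelSpec.default(), drc_graph, mcmc), pp, mcmc


def test_fit_shapes_and_draw_count(small_fit, drc_graph):
    samples, _, mcmc = small_fit
    assert samples.n_draws == mcmc.n_draws == 100
    assert samples.gamma.shape == (100, 9)
    assert samples.f_str.shape == (100, drc_graph.n_regions)
    assert set(samples.tau2) == {"baseline", "mother_age", "spatial_str", "spatial_unstr"}


def test_fit_preserves_centering_constraints(small_fit):
    samples, pp, _ = small_fit
    # spatial effects: plain mean zero per draw
    assert np.abs(samples.f_str.mean(axis=1)).max() < 1e-10
    assert np.abs(samples.f_unstr.mean(axis=1)).max() < 1e-10
    # smooths: mean zero over the observed covariate distribution per draw
    t_curve = samples.smooth_draws("baseline", pp["t"].to_numpy(float))
    assert np.abs(t_curve.mean(axis=1)).max() < 1e-8
    child = pp.groupby("child_id", sort=False)
    age_curve = samples.smooth_draws("mother_age", pp["mother_age_at_birth"].to_numpy(float))
    assert np.abs(age_curve.mean(axis=1)).max() < 1e-8


def test_fit_is_deterministic_given_seed(small_fit, drc_graph):
    samples, pp, mcmc = small_fit
    again = fit(pp, ModelSpec.default(), drc_graph, mcmc)
    assert np.array_equal(samples.intercept, again.intercept)
    assert np.array_equal(samples.gamma, again.gamma)
    assert np.array_equal(samples.f_str, again.f_str)
    assert np.array_equal(samples.coef_baseline, again.coef_baseline)


def test_fit_rejects_empty_covariate_level(drc_graph):
    cfg = make_sim_config(5, drc_graph, n_children=200)
    records, _ = synthetic_data.generate(cfg)
    records["marital"] = "married"  # single-mother level now has zero exposure
    pp = data_model.expand(records)
    with pytest.raises(ValueError, match="marital:single"):
        fit(pp, ModelSpec.default(), drc_graph, McmcConfig(seed=1, n_iter=20, burn_in=10))


def test_fit_rejects_province_missing_from_graph(drc_graph):
    cfg = make_sim_config(6, drc_graph, n_children=200)
    records, _ = synthetic_data.generate(cfg)
    records.loc[records.index[:20], "province"] = "Atlantis"
    pp = data_model.expand(records)
    with pytest.raises(ValueError, match="Atlantis"):
        fit(pp, ModelSpec.default(), drc_graph, McmcConfig(seed=1, n_iter=20, burn_in=10))


def test_spatial_posterior_is_label_invariant(drc_graph):
    """Relabelling provinces permutes the spatial posterior (up to MC error)."""
    from geosurv.spatial import RegionGraph

    cfg = make_sim_config(77, drc_graph, n_children=1200,
                          f_str=[0.5 if lab == "Maniema" else -0.05 for lab in drc_graph.labels])
    records, _ = synthetic_data.generate(cfg)
    pp = data_model.expand(records)
    spec = ModelSpec(fixed_terms=(), baseline=None, mother_age=None)
    mcmc = McmcConfig(seed=13, n_iter=700, burn_in=200, thin=1)
    direct = fit(pp, spec, drc_graph, mcmc)

    perm = list(reversed(drc_graph.labels))
    graph2 = RegionGraph(labels=tuple(perm), neighbors=drc_graph.neighbors)
    permuted = fit(pp, spec, graph2, McmcConfig(seed=14, n_iter=700, burn_in=200, thin=1))
    a = dict(zip(direct.region_labels, direct.total_spatial().mean(axis=0)))
    b = dict(zip(permuted.region_labels, permuted.total_spatial().mean(axis=0)))
    for lab in drc_graph.labels:
        assert a[lab] == pytest.approx(b[lab], abs=0.12)


def test_gibbs_agrees_with_independent_metropolis_on_two_parameter_model():
    """Augmented Gibbs and a random-walk Metropolis sampler on the exact
    posterior must agree on a 2-parameter (intercept + binary covariate)
    discrete-time model."""
    rng = np.random.default_rng(21)
    n = 300
    x = rng.binomial(1, 0.5, n)
    true_eta = -1.2 + 0.9 * x
    y = rng.binomial(1, 1 / (1 + np.exp(-true_eta)))
    pp = pd.DataFrame(
        {"child_id": [f"r{i}" for i in range(n)], "t": 1, "y": y,
         "preceding_interval": np.where(x == 1, "lt24", "ge24")}
    )
    spec = ModelSpec(fixed_terms=(("preceding_interval", "lt24"),),
                     baseline=None, mother_age=None, spatial=None)
    samples = fit(pp, spec, None, McmcConfig(seed=2, n_iter=8000, burn_in=1000, thin=1))
    gibbs_means = np.array([samples.intercept.mean(), samples.gamma[:, 0].mean()])

    def logpost(beta):
        eta = beta[0] + beta[1] * x
        return loglik(eta, y) - 0.5e-6 * beta @ beta

    chain = np.zeros((40_000, 2))
    cur = np.zeros(2)
    cur_lp = logpost(cur)
    mrng = np.random.default_rng(99)
    for i in range(len(chain)):
        prop = cur + mrng.normal(0, 0.25, 2)
        lp = logpost(prop)
        if np.log(mrng.random()) < lp - cur_lp:
            cur, cur_lp = prop, lp
        chain[i] = cur
    mh_means = chain[5000:].mean(axis=0)
    assert np.allclose(gibbs_means, mh_means, atol=0.06)


def test_or_table_covers_simulated_truth_smoke(small_fit):
    samples, _, _ = small_fit
    tab = summaries.or_table(samples).set_index("term")
    row = tab.loc["residence:rural"]
    assert row.lo95 < np.exp(0.3) < row.hi95 or abs(np.log(row["or"]) - 0.3) < 0.4
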