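"""Posterior summaries: OR tables, smooth curves, region classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geosurv.inference import McmcConfig, ModelSpec, PosteriorSamples
from geosurv.smoothers import SplineBasis
from geosurv.summaries import classify_regions, curve_export, or_table

REGIONS = ("A", "B", "C")


def fake_samples(gamma_draws, f_str=None, f_unstr=None, baseline_coefs=None,
                 names=("residence:rural",)):
    S = len(gamma_draws)
    basis = SplineBasis((0.0, 60.0), 6)
    if baseline_coefs is None:
        baseline_coefs = np.zeros((S, basis.m))
    R = len(REGIONS)
    return PosteriorSamples(
        fixed_names=tuple(names),
        intercept=np.zeros(S),
        gamma=np.asarray(gamma_draws, float).reshape(S, len(names)),
        coef_baseline=np.asarray(baseline_coefs, float),
        coef_mother_age=None,
        f_str=np.zeros((S, R)) if f_str is None else np.asarray(f_str, float),
        f_unstr=np.zeros((S, R)) if f_unstr is None else np.asarray(f_unstr, float),
        tau2={},
        region_labels=REGIONS,
        baseline_basis=basis,
        mother_age_basis=None,
        model_spec=ModelSpec(fixed_terms=(("residence", "rural"),),
                             baseline=None, mother_age=None, spatial=None),
        mcmc_config=McmcConfig(seed=0, n_iter=2, burn_in=1),
    )


def test_or_table_degenerate_draws():
    tab = or_table(fake_samples(np.full(200, np.log(2.0)))).set_index("term")
    row = tab.loc["residence:rural"]
    assert row["or"] == pytest.approx(2.0)
    assert (row.lo95, row.hi95) == (pytest.approx(2.0), pytest.approx(2.0))
    tab0 = or_table(fake_samples(np.zeros(200))).set_index("term")
    assert tab0.loc["residence:rural", "or"] == pytest.approx(1.0)


def test_or_table_standard_normal_draws_closed_form_quantiles():
    rng = np.random.default_rng(0)
    tab = or_table(fake_samples(rng.standard_normal(100_000))).iloc[0]
    assert tab["lo95"] == pytest.approx(np.exp(-1.959964), rel=0.03)
    assert tab["hi95"] == pytest.approx(np.exp(1.959964), rel=0.03)
    assert tab["lo80"] == pytest.approx(np.exp(-1.281552), rel=0.03)


def test_or_table_unknown_term_errors():
    with pytest.raises(KeyError):
        or_table(fake_samples(np.zeros(150)), terms=["wealth:low"])


def test_or_table_requires_enough_draws():
    with pytest.raises(ValueError, match="100"):
        or_table(fake_samples(np.zeros(50)))


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_credible_regions_nest_and_commute_with_exp(seed):
    rng = np.random.default_rng(seed)
    draws = rng.normal(rng.normal(), abs(rng.normal()) + 0.1, size=500)
    row = or_table(fake_samples(draws)).iloc[0]
    assert row.lo95 <= row.lo80 <= row.hi80 <= row.hi95
    # quantiles on the log-odds scale then exp == quantiles on the OR scale
    lo, hi = np.quantile(np.exp(draws), [0.025, 0.975], method="inverted_cdf")
    assert row.lo95 == pytest.approx(lo, rel=1e-12)
    assert row.hi95 == pytest.approx(hi, rel=1e-12)


def test_curve_export_zero_coefficients_flat_zero():
    s = fake_samples(np.zeros(150))
    out = curve_export(s, "baseline", np.linspace(0, 60, 13))
    assert np.allclose(out["mean"], 0.0)
    assert np.allclose(out["hi80"] - out["lo80"], 0.0)


def test_curve_export_reproduces_line_in_nullspace():
    s0 = fake_samples(np.zeros(150))
    g = s0.baseline_basis.greville()
    coefs = np.tile(0.2 * g - 1.0, (150, 1))
    s = fake_samples(np.zeros(150), baseline_coefs=coefs)
    grid = np.linspace(0, 60, 7)
    out = curve_export(s, "baseline", grid)
    assert np.allclose(out["mean"], 0.2 * grid - 1.0)
    assert np.allclose(out["hi80"], out["lo80"])  # degenerate draws, no band


def test_curve_export_rejects_grid_outside_range():
    with pytest.raises(ValueError, match="range"):
        curve_export(fake_samples(np.zeros(150)), "baseline", [0.0, 61.0])


def test_classification_examples():
    S, R = 150, 3
    f = np.zeros((S, R))
    f[:, 0] = 0.3  # strictly positive draws
    rng = np.random.default_rng(1)
    f[:, 1] = rng.normal(0, 1, S)  # symmetric around zero
    f[:, 2] = -0.2
    cls = classify_regions(fake_samples(np.zeros(S), f_str=f)).set_index("region")
    assert cls.loc["A", "class"] == "higher"
    assert cls.loc["B", "class"] == "not_significant"
    assert cls.loc["C", "class"] == "lower"
    assert cls.loc["A", "mean_total_effect_or"] == pytest.approx(np.exp(0.3))


def test_classification_uses_total_of_both_components():
    S = 150
    f_str = np.full((S, 3), 0.2)
    f_unstr = np.full((S, 3), -0.2)
    cls = classify_regions(fake_samples(np.zeros(S), f_str=f_str, f_unstr=f_unstr))
    assert (cls["class"] == "not_significant").all()


def test_classification_nominal_level_validated():
    with pytest.raises(ValueError):
        classify_regions(fake_samples(np.zeros(150)), nominal=1.2)
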