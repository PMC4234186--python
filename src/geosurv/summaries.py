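"""Posterior reporting: odds-ratio tables, smooth-effect curves with 80%
bands, and the three-class posterior-probability province classification.

All credible regions are equal-tailed sample quantiles (the convention of
structured additive regression software); the OR point estimate is
exp(posterior mean of the log-odds coefficient).  Because exp is monotone,
quantiles commute with the transformation, so CRs may equivalently be read
on either scale.
"""

import numpy as np
import pandas as pd

__all__ = ["or_table", "curve_export", "classify_regions"]

MIN_DRAWS = 100


def _quantile(draws, q, axis=None):
    # interpolation-free sample quantiles: every bound is an actual draw, so
    # credible regions commute exactly with monotone transformations (exp)
    return np.quantile(draws, q, axis=axis, method="inverted_cdf")


def _check_draws(samples):
    if samples.n_draws < MIN_DRAWS:
        raise ValueError(
            f"at least {MIN_DRAWS} retained draws are required for summaries "
            f"(got {samples.n_draws})"
        )


def or_table(samples, terms=None, levels=(0.80, 0.95)):
    """Posterior odds-ratio table with equal-tailed credible regions.

    One row per fixed-effect term (``field:level``); OR = exp(mean of the
    coefficient draws), CRs = exp of the coefficient sample quantiles.
    """
    _check_draws(samples)
    if terms is None:
        terms = list(samples.fixed_names)
    rows = []
    for term in terms:
        draws = samples.coefficient(term)  # raises KeyError for unknown labels
        row = {"term": term, "or": float(np.exp(draws.mean()))}
        for lev in sorted(levels):
            alpha = (1.0 - lev) / 2.0
            lo, hi = _quantile(draws, [alpha, 1.0 - alpha])
            pct = int(round(lev * 100))
            row[f"lo{pct}"] = float(np.exp(lo))
            row[f"hi{pct}"] = float(np.exp(hi))
        rows.append(row)
    return pd.DataFrame(rows)


def curve_export(samples, term, grid, level=0.80):
    """Pointwise posterior mean and equal-tailed band of a centered smooth."""
    _check_draws(samples)
    curves = samples.smooth_draws(term, grid)  # (S, G); errors outside range
    alpha = (1.0 - level) / 2.0
    lo, hi = _quantile(curves, [alpha, 1.0 - alpha], axis=0)
    pct = int(round(level * 100))
    return pd.DataFrame(
        {
            "grid": np.asarray(grid, float),
            "mean": curves.mean(axis=0),
            f"lo{pct}": lo,
            f"hi{pct}": hi,
        }
    )


def classify_regions(samples, graph=None, nominal=0.80):
    """Three-class map table from the total spatial effect f_str + f_unstr.

    A region is ``higher`` when the equal-tailed interval at the nominal
    level lies strictly above zero, ``lower`` when strictly below, else
    ``not_significant`` — the sign-pattern coding of posterior-probability
    maps (white / grey / black).
    """
    if not (0.0 < nominal < 1.0):
        raise ValueError("nominal level must lie strictly between 0 and 1")
    _check_draws(samples)
    total = samples.total_spatial()  # (S, R)
    labels = samples.region_labels if graph is None else graph.labels
    if len(labels) != total.shape[1]:
        raise ValueError("graph does not match the fitted spatial term")
    alpha = (1.0 - nominal) / 2.0
    lo, hi = _quantile(total, [alpha, 1.0 - alpha], axis=0)
    mean = total.mean(axis=0)
    cls = np.where(lo > 0, "higher", np.where(hi < 0, "lower", "not_significant"))
    return pd.DataFrame(
        {
            "region": list(labels),
            "mean_total_effect": mean,
            "mean_total_effect_or": np.exp(mean),
            "lo": lo,
            "hi": hi,
            "class": cls,
        }
    )
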