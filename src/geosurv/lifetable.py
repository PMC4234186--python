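"""Synthetic-cohort life tables for under-five mortality (5q0).

The DHS-style estimator composes death probabilities over age segments of
the first five years: within each segment the monthly discrete hazard is
deaths / children at risk, censored children leaving the risk set at their
censoring age; the segment survival is the product of its monthly
survivals, and

    5q0 = 1000 * (1 - prod_segments S_seg).

With no censoring this reduces exactly to the empirical fraction dying
before 60 months.  Confidence intervals come from the Greenwood (delta
method) variance of the log survival composition, clipped to [0, 1000].
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MAX_AGE_MONTHS, records_to_frame

__all__ = ["LifeTable", "u5mr", "u5mr_by", "DEFAULT_SEGMENTS"]

#: Standard synthetic-cohort age segments in months, half-open [start, end).
DEFAULT_SEGMENTS = ((0, 1), (1, 3), (3, 6), (6, 12), (12, 24), (24, 36), (36, 48), (48, 60))


@dataclass(frozen=True)
class LifeTable:
    """Segment table plus the composed 5q0 per 1,000 live births."""

    segments: pd.DataFrame  # start, end, exposure_months, deaths, survival
    q5: float  # per 1,000
    ci_low: float
    ci_high: float
    n_children: int
    n_deaths: int

    def to_frame(self, level="overall"):
        return pd.DataFrame(
            [{"level": level, "rate": self.q5, "low": self.ci_low, "upper": self.ci_high,
              "births": self.n_children, "deaths": self.n_deaths}]
        )


def _monthly_risk_and_deaths(df, max_age):
    """Vectors (n_t, d_t) for t = 1..max_age from a birth-record frame."""
    age = pd.to_numeric(df["age_months"], errors="raise").to_numpy()
    event = df["event"].to_numpy().astype(int)
    # death interval (1-based); deaths at >= max_age are censored at max_age
    died = (event == 1) & (age < max_age)
    death_t = np.where(died, age + 1, 0)
    # last interval the child is at risk in: death interval, or censoring age
    exit_t = np.where(died, age + 1, np.minimum(age, max_age))
    n_t = np.zeros(max_age)
    d_t = np.zeros(max_age)
    counts = np.bincount(np.clip(exit_t, 0, max_age).astype(int), minlength=max_age + 1)
    # at risk in month t: exit_t >= t  -> reverse cumulative sum
    n_t = counts[::-1].cumsum()[::-1][1:].astype(float)
    dd = np.bincount(death_t[died].astype(int), minlength=max_age + 1)
    d_t = dd[1:].astype(float)
    return n_t, d_t


def u5mr(records, segments=DEFAULT_SEGMENTS, max_age=MAX_AGE_MONTHS):
    """Synthetic-cohort 5q0 per 1,000 live births with a 95% CI."""
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("empty birth-record input")
    n_t, d_t = _monthly_risk_and_deaths(df, max_age)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_t = np.where(n_t > 0, d_t / n_t, 0.0)
    seg_rows = []
    for start, end in segments:
        sl = slice(start, end)  # months start+1 .. end (1-based intervals)
        surv = float(np.prod(1.0 - q_t[sl]))
        seg_rows.append(
            {
                "start": start,
                "end": end,
                "exposure_months": float(n_t[sl].sum()),
                "deaths": float(d_t[sl].sum()),
                "survival": surv,
            }
        )
    seg = pd.DataFrame(seg_rows)
    S = float(seg["survival"].prod())
    q5 = 1000.0 * (1.0 - S)
    # Greenwood variance of log S over the months composing the table
    months = slice(segments[0][0], segments[-1][1])
    nn, dd = n_t[months], d_t[months]
    ok = (nn > 0) & (nn > dd)
    var_log_s = float(np.sum(dd[ok] / (nn[ok] * (nn[ok] - dd[ok]))))
    se = 1000.0 * S * np.sqrt(var_log_s)
    lo = float(np.clip(q5 - 1.96 * se, 0.0, 1000.0))
    hi = float(np.clip(q5 + 1.96 * se, 0.0, 1000.0))
    n_deaths = int(((df["event"].to_numpy().astype(int) == 1)
                    & (df["age_months"].to_numpy() < max_age)).sum())
    return LifeTable(segments=seg, q5=float(q5), ci_low=lo, ci_high=hi,
                     n_children=len(df), n_deaths=n_deaths)


def u5mr_by(records, by, segments=DEFAULT_SEGMENTS, max_age=MAX_AGE_MONTHS):
    """One LifeTable per level of a grouping field, empty levels absent."""
    df = records_to_frame(records)
    if by not in df.columns:
        raise KeyError(f"unknown grouping field {by!r}")
    out = {}
    for level, sub in df.groupby(by, sort=False):
        if len(sub):
            out[level] = u5mr(sub, segments=segments, max_age=max_age)
    return out
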