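"""Birth-history records and their person-period expansion.

One row per live birth (survival status plus age at death or censoring in
completed months) becomes one row per child-month lived: the discrete-time
survival likelihood is then an ordinary Bernoulli likelihood on the expanded
table, with y_it = 1 only in the month a death occurred.  Deaths reported at
60 months or later are not under-five deaths and are treated as censored at
60; censored children contribute only fully observed months.
"""

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Categorical model fields with their levels; the reference level is first.
CATEGORY_LEVELS = {
    "sex": ("female", "male"),
    "residence": ("urban", "rural"),
    "preceding_interval": ("ge24", "lt24"),
    "antenatal": ("one_plus", "none"),
    "delivery_place": ("hospital", "home"),
    "wealth": ("high", "middle", "low"),
    "education": ("secondary_plus", "primary_or_less"),
    "marital": ("married", "single"),
}

CATEGORICAL_FIELDS = tuple(CATEGORY_LEVELS)

REQUIRED_COLUMNS = (
    "child_id",
    "event",
    "age_months",
    *CATEGORICAL_FIELDS,
    "province",
    "mother_age_at_birth",
)

MAX_AGE_MONTHS = 60


@dataclass(frozen=True)
class BirthRecord:
    """One live birth with covariates, province and survival outcome."""

    child_id: str
    event: int
    age_months: int
    sex: str
    residence: str
    preceding_interval: str
    antenatal: str
    delivery_place: str
    wealth: str
    education: str
    marital: str
    province: str
    mother_age_at_birth: float


@dataclass(frozen=True)
class Finding:
    row: int
    child_id: object
    column: str
    message: str


@dataclass
class ValidationReport:
    findings: list = field(default_factory=list)

    @property
    def empty(self):
        return not self.findings

    def to_frame(self):
        return pd.DataFrame(
            [(f.row, f.child_id, f.column, f.message) for f in self.findings],
            columns=["row", "child_id", "column", "message"],
        )

    def __len__(self):
        return len(self.findings)


def records_to_frame(records):
    """Coerce a list of BirthRecord (or an existing frame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"birth-record table is missing columns: {missing}")
        return records.reset_index(drop=True)
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])


def validate(records, graph=None):
    """Report every invalid row: unknown levels, unknown province, bad ages.

    A reporting operation — never raises for bad data; a clean input yields
    an empty report.
    """
    df = records_to_frame(records)
    report = ValidationReport()

    def flag(mask, column, message):
        for i in np.flatnonzero(np.asarray(mask)):
            report.findings.append(
                Finding(int(i), df["child_id"].iloc[int(i)], column, message)
            )

    age = pd.to_numeric(df["age_months"], errors="coerce")
    flag(age.isna(), "age_months", "non-numeric age")
    flag(age < 0, "age_months", "negative age")
    event = pd.to_numeric(df["event"], errors="coerce")
    flag(~event.isin([0, 1]), "event", "event must be 0 or 1")
    for col, levels in CATEGORY_LEVELS.items():
        flag(~df[col].isin(levels), col, f"unknown level (expected one of {levels})")
    mage = pd.to_numeric(df["mother_age_at_birth"], errors="coerce")
    flag(mage.isna() | (mage < 10) | (mage > 49), "mother_age_at_birth",
         "mother's age at birth outside [10, 49]")
    if graph is not None:
        known = set(graph.labels)
        flag(~df["province"].isin(known), "province", "province not in region graph")
    else:
        flag(df["province"].isna(), "province", "missing province")
    return report


def expand(records, max_age=MAX_AGE_MONTHS):
    """Expand birth records into the person-period (child-month) table.

    A child dying at completed age ``a`` contributes ``min(a + 1, max_age)``
    monthly rows with y = 1 in the last row iff the death fell below
    ``max_age``; a censored child at age ``a`` contributes ``min(a, max_age)``
    all-zero rows (only completed months).  Interval t = 1..max_age covers
    age [t-1, t) months.
    """
    df = records_to_frame(records)
    age = pd.to_numeric(df["age_months"], errors="raise").to_numpy()
    neg = np.flatnonzero(age < 0)
    if neg.size:
        bad = df["child_id"].iloc[neg[0]]
        raise ValueError(f"record {bad!r} (row {neg[0]}) has negative age_months")
    event = df["event"].to_numpy().astype(int)

    n_rows = np.where(event == 1, np.minimum(age + 1, max_age), np.minimum(age, max_age))
    n_rows = n_rows.astype(int)
    keep = n_rows > 0
    idx = np.repeat(np.flatnonzero(keep), n_rows[keep])
    # interval index 1..k within each child
    t = np.concatenate([np.arange(1, k + 1) for k in n_rows[keep]]) if idx.size else np.array([], int)
    y = np.zeros(idx.size, dtype=int)
    if idx.size:
        last = np.cumsum(n_rows[keep]) - 1
        died = (event[keep] == 1) & (age[keep] < max_age)
        y[last[died]] = 1

    carried = ["child_id", *CATEGORICAL_FIELDS, "province", "mother_age_at_birth"]
    out = df.loc[idx, carried].reset_index(drop=True)
    out.insert(1, "t", t)
    out.insert(2, "y", y)
    return out


def collapse(person_periods):
    """Invert :func:`expand`: recover (event, observed months) per child."""
    grp = person_periods.groupby("child_id", sort=False)
    k = grp["t"].max()
    ev = grp["y"].last()
    out = pd.DataFrame({"child_id": k.index, "event": ev.to_numpy(int)})
    out["age_months"] = np.where(out["event"] == 1, k.to_numpy() - 1, k.to_numpy())
    return out.reset_index(drop=True)


def read_birth_records(path, graph=None, strict=True):
    """Read the delimited birth-record format (CSV, header row).

    Missing values in model columns are a validation error, not an
    imputation opportunity.  With ``strict`` the first findings raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df[list(REQUIRED_COLUMNS)].isna().any().any():
        bad = [c for c in REQUIRED_COLUMNS if df[c].isna().any()]
        raise ValueError(f"{path}: missing values in model columns {bad}")
    if strict:
        report = validate(df, graph=graph)
        if not report.empty:
            head = report.findings[:5]
            msgs = "; ".join(f"row {f.row} ({f.column}): {f.message}" for f in head)
            raise ValueError(f"{path}: {len(report)} invalid records — {msgs}")
    return df


def write_birth_records(df, path):
    records_to_frame(df).to_csv(path, index=False)
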