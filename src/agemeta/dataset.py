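"""Effect-size data model: schema, validation and I/O.

Each row of the CSV schema is one effect size on the correlation scale
(positive values = the trait increases with age), nested in a study.
Estimates (Level 2) are nested in studies (Level 3); sampling error is
Level 1. A :class:`MetaDataset` is the validated unit every fit consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

PREFERENCES = ("risk", "time", "social", "effort")

#: mandatory CSV columns, in canonical order
SCHEMA_COLUMNS = (
    "record_id", "study_id", "estimate_id", "preference", "r", "var_r",
    "n", "year", "metric", "design", "age_span_decades", "prop_female",
    "incentivized", "task_type", "domain", "context", "effort_type",
    "citations_per_year",
)

#: allowed levels for the categorical moderators ("missing" = empty cell)
CATEGORICAL_LEVELS = {
    "metric": {"pearson", "point_biserial"},
    "design": {"continuous", "extreme_group"},
    "incentivized": {"hypothetical", "incentivized", "missing"},
    "task_type": {"description", "experience", "missing"},
    "domain": {"gain", "loss", "mixed", "missing"},
    "context": {"lab", "online", "missing"},
    "effort_type": {"cognitive", "physical", "missing"},
}

_CATEGORICALS = tuple(CATEGORICAL_LEVELS)


class SchemaError(ValueError):
    """The CSV header does not match the expected schema."""


class ValidationError(ValueError):
    """One or more rows violate the data-model invariants."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        super().__init__("invalid rows:\n" + "\n".join(diagnostics))


@dataclass(frozen=True)
class EffectSizeRecord:
    """A single correlation-scale effect size with its nesting ids."""

    record_id: str
    study_id: str
    estimate_id: str
    preference: str
    r: float
    var_r: float
    n: int
    year: int
    metric: str
    design: str
    age_span_decades: float
    prop_female: float | None = None
    incentivized: str = "missing"
    task_type: str = "missing"
    domain: str = "missing"
    context: str = "missing"
    effort_type: str = "missing"
    citations_per_year: float | None = None


@dataclass
class MetaDataset:
    """Validated, deterministically ordered effect-size collection.

    Rows are sorted by (year, study_id, estimate_id) so that cumulative
    traces and fits are reproducible regardless of input row order.
    """

    df: pd.DataFrame
    preference: str = field(default="risk")

    def __post_init__(self):
        self.df = self.df.sort_values(
            ["year", "study_id", "estimate_id"], kind="mergesort"
        ).reset_index(drop=True)

    @property
    def k(self) -> int:
        """Number of effect sizes."""
        return len(self.df)

    @property
    def s(self) -> int:
        """Number of distinct studies."""
        return self.df["study_id"].nunique()

    @property
    def n_total(self) -> int:
        """Total participants: each study counted once at its largest record n.

        Estimates within a study typically share (subsets of) the same
        sample, so summing record-level n would double count.
        """
        return int(self.df.groupby("study_id")["n"].max().sum())

    @property
    def y(self) -> np.ndarray:
        return self.df["r"].to_numpy(float)

    @property
    def v(self) -> np.ndarray:
        return self.df["var_r"].to_numpy(float)

    @property
    def study_ids(self) -> np.ndarray:
        return self.df["study_id"].to_numpy()

    def records(self) -> Iterator[EffectSizeRecord]:
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            for c in ("prop_female", "citations_per_year"):
                if pd.isna(d[c]):
                    d[c] = None
            yield EffectSizeRecord(**d)

    def subset(self, mask) -> "MetaDataset":
        """New dataset from a boolean mask / index over rows."""
        return MetaDataset(self.df.loc[mask].copy(), self.preference)

    def to_csv(self, path: str | Path | None = None) -> str | None:
        out = self.df.loc[:, list(SCHEMA_COLUMNS)].copy()
        if path is None:
            buf = io.StringIO()
            out.to_csv(buf, index=False)
            return buf.getvalue()
        out.to_csv(path, index=False)
        return None

    def sha256(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_csv().encode()).hexdigest()


def _validate_rows(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    for i, row in df.iterrows():
        rid = row["record_id"]
        r, var_r, n = row["r"], row["var_r"], row["n"]
        if not np.isfinite(r) or abs(r) >= 1:
            problems.append(f"row {i} (record_id={rid}): |r| >= 1 (r={r})")
        if not np.isfinite(var_r) or var_r <= 0:
            problems.append(f"row {i} (record_id={rid}): var_r <= 0 (var_r={var_r})")
        if not np.isfinite(n) or n < 2 or int(n) != n:
            problems.append(f"row {i} (record_id={rid}): n must be an integer >= 2 (n={n})")
        if row["preference"] not in PREFERENCES:
            problems.append(f"row {i} (record_id={rid}): unknown preference {row['preference']!r}")
        span = row["age_span_decades"]
        if not np.isfinite(span) or span <= 0:
            problems.append(f"row {i} (record_id={rid}): age_span_decades must be > 0 (got {span})")
        pf = row["prop_female"]
        if not pd.isna(pf) and not (0 <= pf <= 1):
            problems.append(f"row {i} (record_id={rid}): prop_female outside [0,1] ({pf})")
        cpy = row["citations_per_year"]
        if not pd.isna(cpy) and cpy < 0:
            problems.append(f"row {i} (record_id={rid}): citations_per_year < 0 ({cpy})")
        for col in _CATEGORICALS:
            if row[col] not in CATEGORICAL_LEVELS[col]:
                problems.append(
                    f"row {i} (record_id={rid}): {col}={row[col]!r} not in "
                    f"{sorted(CATEGORICAL_LEVELS[col])}"
                )
    if df["record_id"].duplicated().any():
        dups = df.loc[df["record_id"].duplicated(), "record_id"].tolist()
        problems.append(f"duplicated record_id values: {dups}")
    # each estimate belongs to exactly one study
    est_study = df.groupby("estimate_id")["study_id"].nunique()
    for eid in est_study.index[est_study > 1]:
        problems.append(f"estimate_id {eid!r} appears under more than one study_id")
    return problems


def validate(df: pd.DataFrame, preference: str | None = None) -> pd.DataFrame:
    """Normalize and validate raw rows; raise with row-level diagnostics."""
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    df = df.loc[:, list(SCHEMA_COLUMNS)].copy()
    for col in ("record_id", "study_id", "estimate_id", "preference"):
        df[col] = df[col].astype(str)
    for col in _CATEGORICALS:
        df[col] = df[col].astype(object).where(df[col].notna(), "missing").astype(str)
        df[col] = df[col].replace("", "missing")
    for col in ("r", "var_r", "age_span_decades", "prop_female", "citations_per_year"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("n", "year"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    problems = _validate_rows(df)
    if preference is not None:
        bad = df.index[df["preference"] != preference]
        if len(bad) == len(df):
            problems.append(f"no rows with preference={preference!r}")
        df = df.drop(index=bad)
    elif df["preference"].nunique() > 1:
        problems.append("preference must be constant within a dataset")
    if problems:
        raise ValidationError(problems)
    df["n"] = df["n"].astype(int)
    df["year"] = df["year"].astype(int)
    return df


def load_dataset(path: str | Path, preference: str | None = None) -> MetaDataset:
    """Read a schema CSV and return the validated :class:`MetaDataset`.

    Rows that violate an invariant raise :class:`ValidationError` with one
    diagnostic per offending row; nothing is silently dropped. When
    ``preference`` is given, rows of other preferences are excluded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    df = validate(raw, preference)
    pref = preference or df["preference"].iloc[0]
    return MetaDataset(df, pref)


def from_dataframe(df: pd.DataFrame, preference: str | None = None) -> MetaDataset:
    """Validate an in-memory frame (same contract as :func:`load_dataset`)."""
    df = validate(df, preference)
    pref = preference or df["preference"].iloc[0]
    return MetaDataset(df, pref)


def age_span_decades(
    young_min: float | None,
    young_max: float | None,
    old_min: float | None,
    old_max: float | None,
    young_mean: float | None = None,
    old_mean: float | None = None,
) -> float:
    """Age span between the old and young groups, in decades.

    The reference age of a group is its mean when reported, otherwise the
    midpoint of its age range (a participant group aged 18-30 counts as 24).
    """

    def ref(mean, lo, hi, label):
        if mean is not None and not (isinstance(mean, float) and np.isnan(mean)):
            return float(mean)
        if lo is None or hi is None:
            raise ValueError(f"{label} group: both mean and age range are missing")
        if lo > hi:
            raise ValueError(f"{label} group: age range not ordered ({lo} > {hi})")
        return (float(lo) + float(hi)) / 2.0

    young = ref(young_mean, young_min, young_max, "young")
    old = ref(old_mean, old_min, old_max, "old")
    return (old - young) / 10.0
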