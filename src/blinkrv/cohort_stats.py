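"""Cohort statistics: median split, one-way ANOVA, correlation, normality.

Per-subject records carry blink rate (BR, blinks/min) and the scale exponent
alpha for a resting and an IQ-test session, plus the IQ score (one point per
problem, 0–13).  The analyses are: a median split of the cohort by IQ score
(strictly-above vs at-or-below), one-way ANOVAs comparing groups and
sessions, the Pearson correlation of resting alpha with IQ score (with the
least-squares regression line), and Shapiro-Wilk normality checks.  All
statistics are recomputed from the data; nothing is hard-coded.

Hypothesis tests delegate to scipy.stats (f_oneway, pearsonr, shapiro,
linregress) behind this module's result types.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("id", "rest_br", "rest_alpha", "iq_br", "iq_alpha", "iq_score")
MAX_IQ_SCORE = 13

NUMERIC_COLUMNS = ("rest_br", "rest_alpha", "iq_br", "iq_alpha", "iq_score")


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort row: per-session BR and alpha plus the IQ score."""

    id: int
    rest_br: float
    rest_alpha: float
    iq_br: float
    iq_alpha: float
    iq_score: int

    def __post_init__(self) -> None:
        if self.rest_br < 0 or self.iq_br < 0:
            raise ValueError("blink rates must be non-negative")
        if not 0 <= self.iq_score <= MAX_IQ_SCORE:
            raise ValueError(
                f"iq_score must lie in [0, {MAX_IQ_SCORE}], got {self.iq_score}"
            )


class CohortTable:
    """Ordered collection of subject records, backed by a DataFrame."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        if df.empty:
            raise ValueError("cohort table is empty")
        if df["id"].duplicated().any():
            dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique().tolist())
            raise ValueError(f"duplicate subject id(s): {dupes}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        for col in REQUIRED_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise")
        self.df = df
        # validates row invariants
        self._records = tuple(
            SubjectRecord(
                id=int(r.id), rest_br=float(r.rest_br), rest_alpha=float(r.rest_alpha),
                iq_br=float(r.iq_br), iq_alpha=float(r.iq_alpha),
                iq_score=int(r.iq_score),
            )
            for r in df.itertuples(index=False)
        )

    @property
    def records(self) -> tuple[SubjectRecord, ...]:
        return self._records

    def record(self, subject_id: int) -> SubjectRecord:
        for r in self._records:
            if r.id == subject_id:
                return r
        raise KeyError(f"no subject with id {subject_id}")

    def __len__(self) -> int:
        return len(self._records)


@dataclass(frozen=True)
class GroupSplit:
    """Median split of the cohort: high group scores strictly above threshold."""

    threshold: float
    high_group: tuple[int, ...]
    low_group: tuple[int, ...]


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA: F statistic, (between, within) df, upper-tail p."""

    F: float
    df: tuple[int, int]
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the least-squares regression line."""

    r: float
    p: float
    r_squared: float
    slope: float
    intercept: float
    n: int


def bundled_cohort_path() -> Path:
    """Path of the reference 24-subject cohort table shipped with the package."""
    return Path(resources.files("blinkrv").joinpath("data/table1.csv"))


def load_cohort(csv_path: str | Path | None = None) -> CohortTable:
    """Load a cohort table from CSV; defaults to the bundled reference table."""
    path = Path(csv_path) if csv_path is not None else bundled_cohort_path()
    df = pd.read_csv(path)
    return CohortTable(df)


def median_split(table: CohortTable, score_field: str = "iq_score") -> GroupSplit:
    """Split subjects by the sample median of their scores (strict > rule).

    The median of an even-sized sample is the mean of the two central order
    statistics.  Subjects scoring strictly above the median form the high
    group; everyone else (scores at or below) forms the low group.
    """
    scores = table.df[score_field].to_numpy(dtype=float)
    threshold = float(np.median(scores))
    ids = table.df["id"].to_numpy(dtype=int)
    high = tuple(int(i) for i in ids[scores > threshold])
    low = tuple(int(i) for i in ids[scores <= threshold])
    return GroupSplit(threshold=threshold, high_group=high, low_group=low)


def one_way_anova(values_a: Sequence[float], values_b: Sequence[float]) -> AnovaResult:
    """One-way ANOVA of two groups: F = MS_between / MS_within, df (1, n-2)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    df = (1, a.size + b.size - 2)
    if a.var(ddof=0) == 0 and b.var(ddof=0) == 0:
        if a.mean() == b.mean():
            return AnovaResult(F=0.0, df=df, p=1.0)
        raise ValueError(
            "infinite F: zero within-group variance with unequal group means"
        )
    F, p = stats.f_oneway(a, b)
    return AnovaResult(F=float(F), df=df, p=float(p))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-transform p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if xa.var() == 0 or ya.var() == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r, p = stats.pearsonr(xa, ya)
    fit = stats.linregress(xa, ya)
    return CorrelationResult(
        r=float(r), p=float(p), r_squared=float(r**2),
        slope=float(fit.slope), intercept=float(fit.intercept), n=int(xa.size),
    )


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (W, p)."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or v.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {v.size}")
    if v.var() == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    w, p = stats.shapiro(v)
    return float(w), float(p)


def session_summary(table: CohortTable) -> pd.DataFrame:
    """Mean and (n-1)-denominator SD per column, overall and per IQ group.

    Rows: ``overall``, ``high`` (scores strictly above the median), ``low``.
    Columns: MultiIndex (variable, {mean, sd, n}).  With a single row the SD
    is reported as missing (NaN).
    """
    split = median_split(table)
    groups = {
        "overall": table.df,
        "high": table.df[table.df["id"].isin(split.high_group)],
        "low": table.df[table.df["id"].isin(split.low_group)],
    }
    out = {}
    for name, sub in groups.items():
        row = {}
        for col in NUMERIC_COLUMNS:
            vals = sub[col].to_numpy(dtype=float)
            row[(col, "mean")] = vals.mean() if vals.size else np.nan
            row[(col, "sd")] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[(col, "n")] = vals.size
        out[name] = row
    df = pd.DataFrame(out).T
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


def group_anova(table: CohortTable, column: str) -> AnovaResult:
    """ANOVA of one column between the median-split IQ groups."""
    split = median_split(table)
    hi = table.df[table.df["id"].isin(split.high_group)][column].to_numpy(float)
    lo = table.df[table.df["id"].isin(split.low_group)][column].to_numpy(float)
    return one_way_anova(hi, lo)


def compare_sessions(
    table: CohortTable, column_pair: tuple[str, str] = ("rest_alpha", "iq_alpha")
) -> AnovaResult:
    """ANOVA treating the two sessions' values as two groups of n subjects."""
    a = table.df[column_pair[0]].to_numpy(dtype=float)
    b = table.df[column_pair[1]].to_numpy(dtype=float)
    return one_way_anova(a, b)
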