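"""Nonparametric cohort statistics for femoral angle studies.

Continuous variables are summarized as medians with interquartile ranges;
group comparisons use the Mann–Whitney U test (independent groups) or the
Wilcoxon signed-rank test (paired), and monotone associations use Spearman
rank correlation — the standard toolkit when angle distributions are
non-normal. All p-values are two-sided and no multiple-testing correction
is applied; missing covariates are dropped pairwise per analysis.

The cohort table is a pandas DataFrame with (at least) the columns
``sex, age, bmi, ethnicity, neck_shaft_angle_deg, torsion_deg``; the
:class:`SubjectRecord` dataclass is the row-level view of the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SubjectRecord",
    "GroupSummary",
    "TestResult",
    "summarize",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "subgroup_table",
    "retroversion_analysis",
    "age_group_comparison",
    "correlation_analyses",
    "records_to_frame",
]

ANGLE_COLUMNS = ("neck_shaft_angle_deg", "torsion_deg")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: covariates joined to the femur measurement."""

    id: str
    sex: str  # female | male
    neck_shaft_angle_deg: float
    torsion_deg: float
    age: float | None = None
    bmi: float | None = None
    ethnicity: str | None = None  # Caucasian | Asian | African | MiddleEastern
    side: str = "left"

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be female|male, got {self.sex!r}")
        if self.age is not None and not 0 <= self.age <= 130:
            raise ValueError(f"age {self.age} outside [0, 130]")
        if self.bmi is not None and not 5 < self.bmi < 80:
            raise ValueError(f"bmi {self.bmi} outside (5, 80)")


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


class GroupSummary(NamedTuple):
    """Median (IQR) summary of one group, plus range and size."""

    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def __str__(self) -> str:  # matches the conventional reporting style
        return (
            f"{self.median:.1f} (range {self.min:.1f}–{self.max:.1f}, "
            f"IQR {self.q1:.1f}–{self.q3:.1f}, n={self.n})"
        )


class TestResult(NamedTuple):
    statistic: float
    p_value: float
    note: str = ""


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def summarize(values) -> GroupSummary:
    """Median and quartiles (linear interpolation between order statistics)."""
    arr = _clean(values)
    if len(arr) == 0:
        raise ValueError("summarize: empty input")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return GroupSummary(
        n=len(arr), median=float(med), q1=float(q1), q3=float(q3),
        min=float(arr.min()), max=float(arr.max()),
    )


def mann_whitney_u(x, y, method: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney U with midrank ties.

    By default exact enumeration is used when the pooled sample has at most
    12 observations and no ties, and otherwise the normal approximation with
    tie and continuity corrections; ``method`` ('exact'/'asymptotic') forces
    one path.
    """
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney_u: empty group")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if method == "auto":
        method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(float(res.statistic), float(res.pvalue), method)


def wilcoxon_signed_rank(pairs, method: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; the exact null distribution is used for up
    to 12 nonzero pairs, the corrected normal approximation beyond that
    (``method`` 'exact'/'approx' forces one path). A degenerate input (all
    differences zero) is returned flagged with p = 1 rather than raised,
    since it carries a valid 'no shift' answer.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) == 0:
        raise ValueError("wilcoxon_signed_rank: need a non-empty (n, 2) array of pairs")
    d = arr[:, 0] - arr[:, 1]
    d = d[np.isfinite(d)]
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return TestResult(0.0, 1.0, "degenerate: all differences zero")
    if method == "auto":
        method = "exact" if len(nonzero) <= 12 else "approx"
    res = sps.wilcoxon(
        nonzero, zero_method="wilcox", correction=True, alternative="two-sided",
        method=method,
    )
    return TestResult(float(res.statistic), float(res.pvalue), method)


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks, p by the
    t approximation. Pairs with a missing value are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("spearman_rho: x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("spearman_rho: need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman_rho: constant input, correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), f"n={len(x)}")


# ---------------------------------------------------------------------------
# cohort reports
# ---------------------------------------------------------------------------

def subgroup_table(
    frame: pd.DataFrame,
    group_floor: int = 30,
    ethnic_levels: tuple[str, ...] = ("Asian", "Caucasian", "African", "MiddleEastern"),
) -> dict:
    """Summary-table report: both angles for all femurs, by sex, and by
    ethnicity, with between-group Mann–Whitney p-values.

    Ethnic groups smaller than ``group_floor`` are excluded from the
    sub-analysis and listed under ``excluded`` (with their sizes), mirroring
    the usual practice of dropping under-represented groups.
    """
    if len(frame) == 0:
        raise ValueError("subgroup_table: empty cohort")
    if "ethnicity" in frame.columns:
        unknown = set(frame["ethnicity"].dropna()) - set(ethnic_levels)
        if unknown:
            raise ValueError(f"subgroup_table: unknown ethnicity levels {sorted(unknown)}")

    cells: dict[str, dict[str, GroupSummary]] = {}

    def add(name: str, sub: pd.DataFrame) -> None:
        if len(sub):
            cells[name] = {col: summarize(sub[col]) for col in ANGLE_COLUMNS}

    add("all", frame)
    for sex in ("female", "male"):
        add(sex, frame[frame["sex"] == sex])

    excluded: dict[str, int] = {}
    included_eth: list[str] = []
    if "ethnicity" in frame.columns:
        sizes = frame["ethnicity"].value_counts()
        for eth in ethnic_levels:
            n = int(sizes.get(eth, 0))
            if n == 0:
                continue
            if n < group_floor:
                excluded[eth] = n
            else:
                included_eth.append(eth)
                add(eth, frame[frame["ethnicity"] == eth])

    tests: dict[str, TestResult] = {}
    f, m = frame[frame["sex"] == "female"], frame[frame["sex"] == "male"]
    if len(f) and len(m):
        for col in ANGLE_COLUMNS:
            tests[f"female_vs_male:{col}"] = mann_whitney_u(f[col], m[col])
    if "Asian" in included_eth and "Caucasian" in included_eth:
        a = frame[frame["ethnicity"] == "Asian"]
        c = frame[frame["ethnicity"] == "Caucasian"]
        for col in ANGLE_COLUMNS:
            tests[f"Asian_vs_Caucasian:{col}"] = mann_whitney_u(a[col], c[col])

    n_excluded = sum(excluded.values())
    return {
        "cells": cells,
        "tests": tests,
        "excluded": excluded,
        "n_total": int(len(frame)),
        "n_in_ethnic_analysis": int(len(frame) - n_excluded),
    }


def retroversion_analysis(frame: pd.DataFrame) -> dict:
    """Retroversion report: count and share of retroverted femurs (signed
    torsion < 0), their sex split and torsion summary, and a Mann–Whitney
    comparison of BMI between retroverted and non-retroverted subjects."""
    retro_mask = frame["torsion_deg"] < 0
    retro = frame[retro_mask]
    out: dict = {
        "n_total": int(len(frame)),
        "n_retroverted": int(len(retro)),
        "percent_retroverted": 100.0 * len(retro) / len(frame) if len(frame) else 0.0,
    }
    if len(retro):
        out["torsion_summary"] = summarize(retro["torsion_deg"])
        male = int((retro["sex"] == "male").sum())
        out["n_male"] = male
        out["percent_male"] = 100.0 * male / len(retro)
        if "ethnicity" in frame.columns:
            out["ethnicity_split"] = retro["ethnicity"].value_counts().to_dict()
    if "bmi" in frame.columns and len(retro):
        bmi_r = _clean(retro["bmi"])
        bmi_n = _clean(frame.loc[~retro_mask, "bmi"])
        if len(bmi_r) and len(bmi_n):
            out["bmi_retroverted"] = summarize(bmi_r)
            out["bmi_normal"] = summarize(bmi_n)
            out["bmi_test"] = mann_whitney_u(bmi_r, bmi_n)
    return out


def age_group_comparison(
    frame: pd.DataFrame,
    young: tuple[float, float] = (19.0, 50.0),
    old: tuple[float, float] = (75.0, 109.0),
    column: str = "torsion_deg",
) -> dict:
    """Compare an angle between a young and an old age band (inclusive
    bounds), Mann–Whitney two-sided."""
    if "age" not in frame.columns:
        raise ValueError("age_group_comparison: no age column")
    age = frame["age"]
    lo_y, hi_y = min(young), max(young)
    lo_o, hi_o = min(old), max(old)
    y = frame[(age >= lo_y) & (age <= hi_y)]
    o = frame[(age >= lo_o) & (age <= hi_o)]
    if len(y) == 0 or len(o) == 0:
        raise ValueError("age_group_comparison: empty age band")
    return {
        "young": summarize(y[column]),
        "old": summarize(o[column]),
        "test": mann_whitney_u(y[column], o[column]),
        "column": column,
    }


def correlation_analyses(frame: pd.DataFrame) -> dict[str, TestResult]:
    """Spearman correlations of each angle with age and BMI (pairwise
    deletion of missing covariates)."""
    out: dict[str, TestResult] = {}
    for covar in ("age", "bmi"):
        if covar not in frame.columns:
            continue
        for col in ANGLE_COLUMNS:
            try:
                out[f"{covar}_vs_{col}"] = spearman_rho(frame[covar], frame[col])
            except ValueError:
                pass
    return out
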