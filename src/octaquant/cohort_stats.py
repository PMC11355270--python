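"""Cohort-level statistics: eligibility filtering, random eye selection,
group tests from raw or summary data, and covariate-adjusted comparisons.

Eyes with signal strength below 6 or any grader quality flag (motion,
floater, misalignment, segmentation) are excluded; when both of a
participant's eyes survive, one is chosen by a seeded uniform draw.

Group comparisons follow the conventions of a standard two-group
observational analysis: pooled-variance (Student) independent t-tests for
continuous variables, Pearson chi-square without continuity correction for
2 x 2 categorical tables, and ordinary least squares for the
covariate-adjusted group difference in each OCTA metric (adjusters: age,
diabetes, hypertension, signal strength, spherical equivalent, intraocular
pressure, axial length). Welch's t is available via ``equal_var=False``.
No multiple-testing correction is applied; each metric is tested at
alpha = 0.05.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError, SingularDesignError, ValidationError

#: Default covariates of the adjusted linear model.
DEFAULT_ADJUSTERS = [
    "age",
    "diabetes",
    "hypertension",
    "signal_strength",
    "spherical_equivalent",
    "iop_mmHg",
    "axial_length_mm",
]

#: Signal-strength values strictly below this are excluded.
SIGNAL_STRENGTH_CUTOFF = 6

QUALITY_FLAGS = ["motion", "floater", "misalignment", "segmentation"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one group for a continuous variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")

    @classmethod
    def from_raw(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: Literal["pooled_t", "welch_t", "chi_square", "ols_coefficient"]
    estimate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


def spherical_equivalent(sphere_D: float, cylinder_D: float) -> float:
    """Spherical equivalent in diopters: sphere + cylinder / 2."""
    return sphere_D + cylinder_D / 2.0


def apply_exclusions(
    records: pd.DataFrame, scan_quality_flags: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split eye records into kept and excluded, with one reason per exclusion.

    An eye is excluded if its ``signal_strength`` is below 6 or any of the
    boolean grader flags (motion, floater, misalignment, segmentation) is
    set. Flags may live in ``records`` itself or in a parallel
    ``scan_quality_flags`` frame sharing the index. The first matching rule
    (signal strength, then flags in fixed order) is recorded as the reason.
    """
    flags = scan_quality_flags if scan_quality_flags is not None else records
    reasons = pd.Series("", index=records.index, dtype=object)
    low_signal = records["signal_strength"] < SIGNAL_STRENGTH_CUTOFF
    reasons[low_signal] = "signal_strength"
    for flag in QUALITY_FLAGS:
        if flag in flags.columns:
            hit = flags[flag].astype(bool) & (reasons == "")
            reasons[hit] = flag
    excluded = records[reasons != ""].copy()
    excluded["exclusion_reason"] = reasons[reasons != ""]
    return records[reasons == ""].copy(), excluded


def select_random_eye(
    participant_eyes: Sequence[str], participant_id: str, seed: int
) -> str | None:
    """Choose one eligible eye per participant, reproducibly.

    A single eligible eye is returned as-is; with two, a uniform draw from a
    generator seeded by ``(seed, participant_id)`` decides, so the same seed
    always yields the same choice while choices vary across participants.
    Zero eligible eyes drops the participant (returns ``None``).
    """
    eyes = list(participant_eyes)
    if len(eyes) == 0:
        return None
    if len(eyes) == 1:
        return eyes[0]
    if len(eyes) > 2:
        raise ValidationError(f"at most 2 eyes per participant, got {len(eyes)}")
    rng = np.random.default_rng([seed, zlib.crc32(str(participant_id).encode())])
    return eyes[int(rng.integers(2))]


def t_test_from_summary(
    g1: GroupSummary, g2: GroupSummary, equal_var: bool = True
) -> TestResult:
    """Two-sample t-test from group summaries (pooled by default).

    The pooled form uses df = n1 + n2 - 2 and a two-sided p from the t
    distribution. Zero pooled variance with unequal means reports p = 0 with
    a warning; with equal means the test is degenerate and reports t = 0,
    p = 1.
    """
    method = "pooled_t" if equal_var else "welch_t"
    estimate = g1.mean - g2.mean
    if g1.sd == 0 and g2.sd == 0:
        if estimate != 0:
            warnings.warn("zero pooled variance with unequal means; p = 0", stacklevel=2)
            return TestResult(float("inf") * np.sign(estimate), g1.n + g2.n - 2, 0.0,
                              method, estimate)
        return TestResult(0.0, g1.n + g2.n - 2, 1.0, method, 0.0)
    t, p = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=equal_var
    )
    if equal_var:
        df = g1.n + g2.n - 2
    else:  # Welch-Satterthwaite
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return TestResult(float(t), float(df), float(p), method, estimate)


def t_test_from_raw(
    values1: Sequence[float], values2: Sequence[float], equal_var: bool = True
) -> TestResult:
    """Raw-vector path: reduces to :class:`GroupSummary` first, so the two
    paths agree to machine precision."""
    return t_test_from_summary(
        GroupSummary.from_raw(values1), GroupSummary.from_raw(values2), equal_var
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on the 2 x 2 table [[a, b], [c, d]], df = 1,
    without continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("chi-square table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(float(chi2), float(dof), float(p), "chi_square", float(chi2))


def adjusted_group_difference(
    table: pd.DataFrame,
    outcome_column: str,
    group_column: str,
    covariate_columns: Sequence[str],
) -> TestResult:
    """Covariate-adjusted group difference by ordinary least squares.

    Regresses the outcome on the binary group indicator plus the covariates
    and returns the group coefficient, its two-sided p-value and the
    residual degrees of freedom. Exact collinearity (including zero-variance
    columns) raises :class:`SingularDesignError` naming the offenders.
    """
    cols = [group_column, *covariate_columns]
    X = table[cols].astype(float)
    y = table[outcome_column].astype(float)
    if len(table) <= len(cols) + 1:
        raise ValidationError("not enough rows for the number of predictors")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        degenerate = [c for c in cols if table[c].astype(float).std() == 0]
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {design.shape[1]}); "
            f"zero-variance or collinear columns: {degenerate or cols}"
        )
    fit = sm.OLS(y, design).fit()
    return TestResult(
        statistic=float(fit.tvalues[group_column]),
        df=float(fit.df_resid),
        p_value=float(fit.pvalues[group_column]),
        method="ols_coefficient",
        estimate=float(fit.params[group_column]),
    )


# ---------------------------------------------------------------------------
# whole-cohort tables

#: Continuous characteristics row spec: column -> pretty label.
_TABLE1_CONTINUOUS = {
    "age": "Age",
    "axial_length_mm": "Axial length, mm",
    "spherical_equivalent": "Spherical equivalent, diopters",
    "iop_mmHg": "Intraocular pressure, mmHg",
    "signal_strength": "Signal strength, out of 10",
}

#: Categorical rows: column -> (pretty label, level counted as "event").
_TABLE1_CATEGORICAL = {
    "sex": ("Gender, female", "F"),
    "diabetes": ("Diabetes, no", False),
    "hypertension": ("Hypertension, no", False),
}

from .image_io import METRIC_COLUMNS  # 13 metric column names


def build_comparison_tables(
    records: pd.DataFrame,
    group_column: str = "ethnicity",
    adjusters: Sequence[str] = tuple(DEFAULT_ADJUSTERS),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the cohort characteristics table and the adjusted metrics table.

    The first table reports mean +- SD (with unadjusted pooled-t p) or
    n (%) (with chi-square p) per characteristic; the second reports
    mean +- SD per group for each of the 13 OCTA metrics with the
    OLS-adjusted group p-value.
    """
    groups = sorted(records[group_column].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValidationError(f"exactly two groups required, found {groups}")
    g1, g2 = groups
    df1 = records[records[group_column] == g1]
    df2 = records[records[group_column] == g2]

    rows1 = []
    for col, label in _TABLE1_CONTINUOUS.items():
        if col not in records.columns:
            continue
        s1, s2 = GroupSummary.from_raw(df1[col]), GroupSummary.from_raw(df2[col])
        res = t_test_from_summary(s1, s2)
        rows1.append(
            dict(characteristic=label, mean_g1=s1.mean, sd_g1=s1.sd, mean_g2=s2.mean,
                 sd_g2=s2.sd, estimate=res.estimate, p_value=res.p_value, method=res.method)
        )
    for col, (label, level) in _TABLE1_CATEGORICAL.items():
        if col not in records.columns:
            continue
        a = int((df1[col] == level).sum())
        c = int((df2[col] == level).sum())
        try:
            res = chi_square_2x2(a, len(df1) - a, c, len(df2) - c)
            estimate, p = res.estimate, res.p_value
        except DegenerateInputError:
            # a level absent from both groups carries no information
            estimate, p = float("nan"), float("nan")
        rows1.append(
            dict(characteristic=label, mean_g1=a, sd_g1=float("nan"), mean_g2=c,
                 sd_g2=float("nan"), estimate=estimate, p_value=p,
                 method="chi_square")
        )
    table1 = pd.DataFrame(rows1)

    missing = [m for m in METRIC_COLUMNS if m not in records.columns]
    if missing:
        raise ValidationError(f"records lack metric columns {missing}")
    work = records.copy()
    work["_group"] = (work[group_column] == g1).astype(float)
    usable = []
    for col in adjusters:
        if col not in work.columns:
            raise ValidationError(f"missing adjuster column {col!r}")
        work[col] = work[col].astype(float)
        # a constant covariate carries no information; keeping it would only
        # make the design singular
        if work[col].std() == 0:
            warnings.warn(f"dropping zero-variance adjuster {col!r}", stacklevel=2)
        else:
            usable.append(col)
    rows2 = []
    for metric in METRIC_COLUMNS:
        s1, s2 = GroupSummary.from_raw(df1[metric]), GroupSummary.from_raw(df2[metric])
        res = adjusted_group_difference(work, metric, "_group", usable)
        rows2.append(
            dict(metric=metric, mean_g1=s1.mean, sd_g1=s1.sd, mean_g2=s2.mean,
                 sd_g2=s2.sd, estimate=res.estimate, p_value=res.p_value, method=res.method)
        )
    table2 = pd.DataFrame(rows2)
    return table1, table2
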