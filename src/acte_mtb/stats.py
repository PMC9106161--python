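"""Cohort statistics: stratified summaries, pooled t-test, dispersion.

The known-groups comparison stratifies molecular tumor boards into academic
(academic medical centers) vs. non-academic (community, specialized and
private institutions), summarizes each group as mean +/- standard error
(sample sd over sqrt(n)), and tests group differences with a two-sided
two-sample Student's t-test with pooled variance (Welch available via flag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import CohortError, ScoringError
from .rubric import Rubric

ACADEMIC = "academic"
NON_ACADEMIC = "non-academic"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at 1 dp), the reporting convention."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    label: str
    n: int
    mean: float
    se: Optional[float]  # None when n < 2
    min: float
    max: float


@dataclass(frozen=True)
class ComparisonResult:
    group1: CohortSummary
    group2: CohortSummary
    t: float
    df: int
    p: float
    pooled_var: float
    welch: bool = False


@dataclass(frozen=True)
class StratificationRule:
    """Total mapping of the four institution types onto two strata."""

    mapping: dict[str, str]

    def stratum(self, institution_type: str) -> str:
        try:
            return self.mapping[institution_type]
        except KeyError:
            raise CohortError(f"unknown institution type {institution_type!r}") from None


#: academic medical centers vs. everything else
DEFAULT_STRATIFICATION = StratificationRule(
    {
        "academic_medical_center": ACADEMIC,
        "community_hospital": NON_ACADEMIC,
        "specialized_cancer_clinic": NON_ACADEMIC,
        "private_practice": NON_ACADEMIC,
    }
)


def stratify(
    items: Iterable,
    rule: StratificationRule = DEFAULT_STRATIFICATION,
    key: Callable = lambda item: item.institution_type,
) -> dict[str, list]:
    """Partition items (assessments, fixture rows, ...) by stratum.

    The partition is disjoint and exhaustive; an item whose institution type
    is missing or unmapped raises :class:`CohortError` naming it.
    """
    out: dict[str, list] = {}
    for item in items:
        itype = key(item)
        if itype is None:
            raise CohortError(f"item {item!r} has no institution type")
        try:
            stratum = rule.stratum(itype)
        except CohortError as exc:
            rid = getattr(item, "respondent_id", None) or getattr(item, "country", item)
            raise CohortError(f"{exc} (item {rid!r})") from None
        out.setdefault(stratum, []).append(item)
    return out


def cohort_summary(values: Sequence[float], label: str = "") -> CohortSummary:
    """Mean +/- standard error (sd_{n-1}/sqrt(n)) at full precision."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise CohortError(f"cohort {label!r} is empty")
    if np.isnan(vals).any():
        raise CohortError(f"cohort {label!r} contains NaN values")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else None
    return CohortSummary(label, int(vals.size), mean, se, float(vals.min()), float(vals.max()))


def students_t_test(
    group1: Sequence[float],
    group2: Sequence[float],
    *,
    labels: tuple[str, str] = ("group1", "group2"),
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample t-test, pooled variance by default.

    Degenerate zero pooled variance: equal means give t = 0, p = 1; unequal
    means would give an infinite statistic and raise instead.
    """
    s1 = cohort_summary(group1, labels[0])
    s2 = cohort_summary(group2, labels[1])
    if s1.n < 2 or s2.n < 2:
        raise CohortError("t-test needs at least 2 observations per group")
    a = np.asarray(list(group1), dtype=float)
    b = np.asarray(list(group2), dtype=float)
    pooled = float(
        ((s1.n - 1) * a.var(ddof=1) + (s2.n - 1) * b.var(ddof=1)) / (s1.n + s2.n - 2)
    )
    df = s1.n + s2.n - 2
    if pooled == 0 and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if s1.mean == s2.mean:
            return ComparisonResult(s1, s2, 0.0, df, 1.0, 0.0, welch)
        raise CohortError("zero variance with unequal means: t statistic is infinite")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df_out = df if not welch else int(res.df)
    return ComparisonResult(s1, s2, float(res.statistic), df_out, float(res.pvalue), pooled, welch)


def impute_implementation_rate(
    code: str, rubric: Rubric, question_id: str = "implementation_rate"
) -> float:
    """Representative therapy-implementation percentage for an answer code.

    Band options carry their representative value (25/50/75/100) in the
    rubric's ``numeric_value`` map; an "I'm not sure" answer is imputed at
    25%, the rubric's declared value for that option.
    """
    question = rubric.question(question_id)
    try:
        opt = question.option(code)
    except KeyError:
        raise ScoringError(
            f"question {question_id!r}: unknown option code {code!r}"
        ) from None
    if opt.numeric_value is None:
        raise ScoringError(
            f"question {question_id!r}: option {code!r} has no numeric value"
        )
    return float(opt.numeric_value)


@dataclass(frozen=True)
class DispersionResult:
    """Per-value normalized squared deviations, in percent of their mean."""

    pct: Optional[tuple[float, ...]]  # None when all values are equal
    all_equal: bool
    mean_pct: Optional[float]

    @property
    def flagged_zero_variance(self) -> bool:
        return self.all_equal


def dispersion_pct(values: Sequence[float]) -> DispersionResult:
    """Percent variance-from-the-mean per value.

    Each value's squared deviation is expressed as a percentage of the mean
    squared deviation (population convention), so the per-category average
    is 100% by construction. Constant input is flagged rather than divided
    by zero.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise CohortError("dispersion needs at least 2 values")
    dev2 = (vals - vals.mean()) ** 2
    msd = dev2.mean()
    if msd == 0:
        return DispersionResult(None, True, None)
    pct = dev2 / msd * 100.0
    return DispersionResult(tuple(float(x) for x in pct), False, float(pct.mean()))


def dispersion_summary(per_category: dict[str, Sequence[float]]) -> CohortSummary:
    """Pooled per-value dispersion percentages across categories, mean +/- SE."""
    pooled: list[float] = []
    for label, values in per_category.items():
        res = dispersion_pct(values)
        if res.all_equal:
            raise CohortError(f"category {label!r} has zero variance")
        pooled.extend(res.pct)
    return cohort_summary(pooled, "dispersion")
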