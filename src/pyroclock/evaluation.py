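"""Stratified accuracy evaluation, group comparisons and error dynamics.

The study design this supports validates a clock on a cross-sectional
cohort, summarising errors separately by age group (young 0-17, adult
18-80, old 81+) and by sex, testing whether delta age (predicted minus
chronological) differs between strata, and tracing how MAD/SEE change as
the upper end of the evaluated age range grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import DegenerateInputError, PredictionRecord, Sex, ValidationError
from . import metrics as M
from .metrics import PairedAges

__all__ = [
    "AgeGroupScheme",
    "DEFAULT_SCHEME",
    "DEFAULT_THRESHOLDS",
    "GroupComparison",
    "DynamicsPoint",
    "DynamicsCurve",
    "assign_age_group",
    "evaluate_strata",
    "compare_delta_age",
    "metric_dynamics",
]

#: PCP thresholds (years) reported by convention for small-panel clocks.
DEFAULT_THRESHOLDS: tuple[float, ...] = (5.0, 7.5, 10.0)

#: Pooled-stratum label used alongside group and sex labels.
ALL = "all"


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered, non-overlapping integer-year age bands covering [0, max].

    Bounds are inclusive and compared against floor(age), so a band
    ``(lo, hi)`` holds every age in ``[lo, hi + 1)``.  Ages beyond the last
    band's upper bound fall into the last band (an open-ended oldest group).
    """

    groups: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("AgeGroupScheme needs at least one group")
        prev_hi = -1
        for label, lo, hi in self.groups:
            if lo > hi:
                raise ValidationError(f"group {label!r}: lo {lo} > hi {hi}")
            if lo != prev_hi + 1:
                raise ValidationError(
                    f"group {label!r}: bands must tile the age axis without gaps"
                )
            prev_hi = hi

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.groups)


DEFAULT_SCHEME = AgeGroupScheme(
    groups=(("young", 0, 17), ("adult", 18, 80), ("old", 81, 101))
)


def assign_age_group(age: float, scheme: AgeGroupScheme = DEFAULT_SCHEME) -> str:
    """Label whose inclusive [lo, hi] band contains floor(age)."""
    if age < 0 or not math.isfinite(age):
        raise ValidationError(f"age must be non-negative and finite, got {age}")
    yr = math.floor(age)
    for label, lo, hi in scheme.groups:
        if lo <= yr <= hi:
            return label
    return scheme.groups[-1][0]


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample rank-sum comparison of delta age between strata."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class DynamicsPoint:
    upper_age: float
    n: int
    value: Optional[float]


@dataclass(frozen=True)
class DynamicsCurve:
    """A metric recomputed over cumulative age ranges [min_age, t]."""

    metric: str
    points: tuple[DynamicsPoint, ...]

    @property
    def final_value(self) -> Optional[float]:
        return self.points[-1].value


def _paired(records: Sequence[PredictionRecord]) -> PairedAges:
    return PairedAges(
        [r.age for r in records], [r.predicted_age for r in records]
    )


def _report(
    model_id: str,
    age_group: str,
    sex: str,
    records: Sequence[PredictionRecord],
    thresholds: Sequence[float],
):
    from .datamodel import AccuracyReport

    p = _paired(records)
    flags: list[str] = []
    see_val = r2_val = None
    if p.n >= 3:
        see_val = M.see(p)
    else:
        flags.append("see_omitted_n_lt_3")
    if p.n >= 2 and np.ptp(p.x) > 0 and np.ptp(p.x_pred) > 0:
        r2_val = M.r_squared(p)
    else:
        flags.append("r2_omitted_degenerate")
    return AccuracyReport(
        model_id=model_id,
        age_group=age_group,
        sex=sex,
        n=p.n,
        mad=M.mad(p),
        pcp={t: M.pcp(p, t) for t in thresholds},
        see=see_val,
        r2=r2_val,
        flags=flags,
    )


def evaluate_strata(
    records: Sequence[PredictionRecord],
    scheme: AgeGroupScheme = DEFAULT_SCHEME,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
):
    """One :class:`AccuracyReport` per (age group + pooled) x (sex + pooled).

    Records with unknown sex contribute to pooled ("all") strata only.
    Empty strata are omitted.  Records from multiple models are evaluated
    per model.
    """
    if not records:
        raise DegenerateInputError("evaluate_strata needs at least one record")
    reports = []
    model_ids = sorted({r.model_id for r in records})
    for model_id in model_ids:
        model_recs = [r for r in records if r.model_id == model_id]
        labelled = [
            (r, r.age_group if r.age_group else assign_age_group(r.age, scheme))
            for r in model_recs
        ]
        for group in (*scheme.labels, ALL):
            in_group = [
                r for r, g in labelled if group == ALL or g == group
            ]
            for sex in (Sex.FEMALE.value, Sex.MALE.value, ALL):
                strat = [
                    r
                    for r in in_group
                    if sex == ALL or r.sex.value == sex
                ]
                if strat:
                    reports.append(
                        _report(model_id, group, sex, strat, thresholds)
                    )
    return reports


def compare_delta_age(
    records_a: Sequence[PredictionRecord],
    records_b: Sequence[PredictionRecord],
    label_a: str = "a",
    label_b: str = "b",
    paired: bool = False,
) -> GroupComparison:
    """Two-sided Wilcoxon comparison of delta age between two strata.

    The default is the two-sample rank-sum (Mann-Whitney U) test, the
    appropriate "Wilcoxon test" for independent groups of individuals:
    exact null distribution when n_a + n_b <= 20 with no ties, otherwise
    the normal approximation with midranks and tie correction.  Set
    ``paired=True`` for the signed-rank variant on matched samples.
    """
    if not records_a or not records_b:
        raise DegenerateInputError("compare_delta_age: both groups must be non-empty")
    da = np.array([r.delta_age for r in records_a])
    db = np.array([r.delta_age for r in records_b])
    if paired:
        if len(da) != len(db):
            raise DegenerateInputError("paired comparison needs equal-length groups")
        res = stats.wilcoxon(da, db)
        method = "wilcoxon-signed-rank"
    else:
        pooled = np.concatenate([da, db])
        no_ties = len(np.unique(pooled)) == len(pooled)
        exact = (len(da) + len(db) <= 20) and no_ties
        res = stats.mannwhitneyu(
            da, db, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        method = "mann-whitney-exact" if exact else "mann-whitney-normal"
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        n_a=len(da),
        n_b=len(db),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )


_MIN_N = {"mad": 1, "see": 3}


def metric_dynamics(
    records: Sequence[PredictionRecord],
    metric: str = "mad",
    step: float = 1.0,
) -> DynamicsCurve:
    """Recompute MAD or SEE over cumulative age ranges [min_age, t].

    The lower bound stays at the cohort minimum; the upper bound t walks a
    grid of ``step`` years up to the cohort maximum (which is always
    included as the final point, so the curve ends at the global metric).
    Points whose cumulative n is below the metric's minimum carry
    ``value=None``.
    """
    if not records:
        raise DegenerateInputError("metric_dynamics needs at least one record")
    if metric not in _MIN_N:
        raise ValidationError(f"metric must be one of {sorted(_MIN_N)}, got {metric!r}")
    if step <= 0:
        raise ValidationError(f"step must be positive, got {step}")
    ages = np.array([r.age for r in records])
    lo, hi = float(ages.min()), float(ages.max())
    grid = list(np.arange(lo + step, hi, step))
    grid.append(hi)
    fn = M.mad if metric == "mad" else M.see
    pts = []
    for t in grid:
        sub = [r for r in records if r.age <= t]
        value = fn(_paired(sub)) if len(sub) >= _MIN_N[metric] else None
        pts.append(DynamicsPoint(upper_age=float(t), n=len(sub), value=value))
    return DynamicsCurve(metric=metric, points=tuple(pts))
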