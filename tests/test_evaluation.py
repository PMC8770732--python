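"""Stratified evaluation, rank-sum comparisons and dynamics tests."""

import itertools

import numpy as np
import pytest

from pyroclock import (
    AgeGroupScheme,
    Sex,
    assign_age_group,
    compare_delta_age,
    evaluate_strata,
    metric_dynamics,
)
from pyroclock.datamodel import DegenerateInputError, ValidationError
from pyroclock.evaluation import DEFAULT_SCHEME
from pyroclock.metrics import PairedAges, mad, see

from conftest import make_records


# ---- age-group assignment --------------------------------------------------

@pytest.mark.parametrize(
    "age,label",
    [
        (0, "young"), (17, "young"), (17.9, "young"),
        (18, "adult"), (80, "adult"), (80.99, "adult"),
        (81, "old"), (101, "old"), (120, "old"),  # beyond last bound -> last group
    ],
)
def test_assign_age_group_boundaries(age, label):
    assert assign_age_group(age) == label


def test_assign_age_group_rejects_negative():
    with pytest.raises(ValidationError):
        assign_age_group(-0.5)


def test_scheme_must_tile_without_gaps():
    with pytest.raises(ValidationError):
        AgeGroupScheme(groups=(("a", 0, 10), ("b", 12, 20)))
    with pytest.raises(ValidationError):
        AgeGroupScheme(groups=(("a", 5, 10),))


# ---- stratified evaluation -------------------------------------------------

def test_single_stratum_collapse():
    """All records adult + female: the four containing strata agree exactly."""
    recs = make_records([30, 40, 50, 60], [32, 38, 53, 61], groups=["adult"] * 4)
    reports = {(r.age_group, r.sex): r for r in evaluate_strata(recs)}
    assert set(reports) == {
        ("adult", "female"), ("adult", "all"), ("all", "female"), ("all", "all"),
    }
    vals = [(r.mad, r.see, r.r2, tuple(sorted(r.pcp.items()))) for r in reports.values()]
    assert all(v == vals[0] for v in vals)


def test_perfect_predictions_all_strata():
    ages = [5, 30, 90, 16, 70, 85]
    sexes = [Sex.FEMALE, Sex.MALE] * 3
    groups = [assign_age_group(a) for a in ages]
    reports = evaluate_strata(make_records(ages, ages, sexes=sexes, groups=groups))
    for r in reports:
        assert r.mad == 0.0
        assert all(v == 100.0 for v in r.pcp.values())
        if r.see is not None:
            assert r.see == 0.0
        if r.r2 is not None:
            assert r.r2 == pytest.approx(1.0, abs=1e-12)


def test_per_group_mads_hand_computed():
    ages = [10, 12, 14, 30, 40, 50]
    preds = [11, 14, 17, 29, 44, 55]  # errors 1,2,3 and 1,4,5
    groups = ["young"] * 3 + ["adult"] * 3
    reports = {(r.age_group, r.sex): r for r in evaluate_strata(make_records(ages, preds, groups=groups))}
    assert reports[("young", "all")].mad == pytest.approx(2.0)
    assert reports[("adult", "all")].mad == pytest.approx(10.0 / 3.0)
    assert reports[("all", "all")].mad == pytest.approx(16.0 / 6.0)


def test_small_strata_omit_see_and_r2_with_flags():
    recs = make_records([30, 90], [31, 80], groups=["adult", "old"])
    reports = {(r.age_group, r.sex): r for r in evaluate_strata(recs)}
    adult = reports[("adult", "all")]
    assert adult.n == 1 and adult.see is None and adult.r2 is None
    assert "see_omitted_n_lt_3" in adult.flags
    assert "r2_omitted_degenerate" in adult.flags


def test_unknown_sex_only_in_pooled_strata():
    recs = make_records(
        [30, 40, 50], [30, 40, 50],
        sexes=[Sex.FEMALE, Sex.UNKNOWN, Sex.MALE],
        groups=["adult"] * 3,
    )
    reports = {(r.age_group, r.sex): r for r in evaluate_strata(recs)}
    assert reports[("adult", "all")].n == 3
    assert reports[("adult", "female")].n == 1
    assert reports[("adult", "male")].n == 1


def test_stratum_n_summation_invariants(rng):
    ages = rng.uniform(0, 101, 120)
    preds = ages + rng.normal(0, 8, 120)
    sexes = [Sex.FEMALE if u < 0.6 else Sex.MALE for u in rng.random(120)]
    groups = [assign_age_group(a) for a in ages]
    reports = {(r.age_group, r.sex): r for r in evaluate_strata(make_records(ages, preds, sexes=sexes, groups=groups))}
    for sex in ("female", "male", "all"):
        group_sum = sum(
            reports[(g, sex)].n for g in DEFAULT_SCHEME.labels if (g, sex) in reports
        )
        assert group_sum == reports[("all", sex)].n
    for g in (*DEFAULT_SCHEME.labels, "all"):
        by_sex = sum(
            reports[(g, s)].n for s in ("female", "male") if (g, s) in reports
        )
        assert by_sex <= reports[(g, "all")].n


def test_evaluate_strata_empty_errors():
    with pytest.raises(DegenerateInputError):
        evaluate_strata([])


# ---- delta-age comparisons -------------------------------------------------

def exact_ranksum_p(a, b):
    """Exhaustive-enumeration two-sided rank-sum p-value (no ties assumed)."""
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in a)
    n = len(a)
    stats = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = len(a) * (len(pooled) + 1) / 2
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(observed - mean) - 1e-9)
    return extreme / len(stats)


def test_identical_groups_p_near_one():
    recs = make_records(range(10), [a + 1 for a in range(10)])
    cmp = compare_delta_age(recs, recs)
    assert cmp.p_value >= 0.99


def test_extreme_separation_matches_enumeration_oracle():
    a = make_records([0, 0, 0], [1, 2, 3])       # deltas 1,2,3
    b = make_records([0, 0, 0], [101, 102, 103])  # deltas 101,102,103
    cmp = compare_delta_age(a, b, "a", "b")
    assert cmp.method == "mann-whitney-exact"
    assert cmp.p_value == pytest.approx(0.1, abs=1e-12)
    assert exact_ranksum_p([1, 2, 3], [101, 102, 103]) == pytest.approx(0.1, abs=1e-12)


def test_exact_path_agrees_with_enumeration_on_random_small_samples(rng):
    for _ in range(20):
        da = list(np.round(rng.normal(0, 5, 4), 3))
        db = list(np.round(rng.normal(1, 5, 5), 3))
        if len(set(da + db)) < 9:
            continue
        a = make_records([0] * 4, da)
        b = make_records([0] * 5, db)
        cmp = compare_delta_age(a, b)
        assert cmp.p_value == pytest.approx(exact_ranksum_p(da, db), abs=1e-9)


def test_compare_empty_group_errors():
    recs = make_records([1], [2])
    with pytest.raises(DegenerateInputError):
        compare_delta_age(recs, [])


# ---- dynamics --------------------------------------------------------------

def test_dynamics_constant_errors_flat_curve():
    ages = list(range(10, 60, 5))
    preds = [a + 3 for a in ages]
    curve = metric_dynamics(make_records(ages, preds), metric="mad", step=5)
    for p in curve.points:
        if p.value is not None:
            assert p.value == pytest.approx(3.0)


def test_dynamics_piecewise_growth_after_knot():
    ages = [20, 40, 60, 80, 90, 100]
    preds = [20, 40, 60, 80, 70, 80]  # exact below 80, -20 above
    curve = metric_dynamics(make_records(ages, preds), metric="mad", step=10)
    by_t = {p.upper_age: p.value for p in curve.points}
    assert by_t[80.0] == 0.0
    assert by_t[90.0] == pytest.approx(4.0)   # one error of 20 over 5 records
    assert by_t[100.0] == pytest.approx(40.0 / 6.0)
    vals = [p.value for p in curve.points if p.upper_age >= 80]
    assert all(b > a - 1e-12 for a, b in zip(vals, vals[1:]))


@pytest.mark.parametrize("metric,fn", [("mad", mad), ("see", see)])
def test_dynamics_final_point_equals_global_metric(rng, metric, fn):
    ages = rng.uniform(0, 101, 80)
    preds = ages + rng.normal(0, 6, 80)
    recs = make_records(ages, preds)
    curve = metric_dynamics(recs, metric=metric, step=1.0)
    assert curve.points[-1].upper_age == pytest.approx(float(ages.max()))
    assert curve.points[-1].n == 80
    assert curve.final_value == pytest.approx(fn(PairedAges(ages, preds)), abs=1e-12)
    ns = [p.n for p in curve.points]
    assert ns == sorted(ns)


def test_dynamics_small_n_points_flagged_null():
    recs = make_records([0, 50, 100], [1, 52, 98])
    curve = metric_dynamics(recs, metric="see", step=1.0)
    assert curve.points[0].value is None  # n=1 below SEE's minimum of 3
    assert curve.points[-1].value is not None


def test_dynamics_rejects_bad_args():
    recs = make_records([1, 2], [1, 2])
    with pytest.raises(ValidationError):
        metric_dynamics(recs, metric="rmse")
    with pytest.raises(ValidationError):
        metric_dynamics(recs, metric="mad", step=0)
    with pytest.raises(DegenerateInputError):
        metric_dynamics([], metric="mad")
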