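"""Synthetic-cohort generator tests: determinism, calibration, inversion."""

import math

import numpy as np
import pytest

from pyroclock import (
    BandedAges,
    CohortConfig,
    PairedAges,
    SiteModel,
    UniformAges,
    default_bands,
    default_config,
    default_panel,
    mad,
    matched_clock,
    noise_sd_for_correlation,
    predict_cohort,
    regress_site_on_age,
    simulate_cohort,
)
from pyroclock.datamodel import ValidationError
from pyroclock.simulate import age_sampler_sd


def _single_site_config(n=100, noise=0.0, knot=None, lam=1.0, seed=7,
                        lo=18.0, hi=80.0, baseline=10.0, slope=0.5):
    return CohortConfig(
        n=n,
        sites=(
            SiteModel(
                "S1", baseline=baseline, slope=slope, noise_sd=noise,
                attenuation_knot=knot, attenuation_factor=lam,
            ),
        ),
        age_sampler=UniformAges(lo, hi),
        seed=seed,
    )


def test_noiseless_methylation_is_exact_linear_function_of_age():
    cohort = simulate_cohort(_single_site_config(n=50, noise=0.0))
    for s in cohort:
        assert s.methylation["S1"] == pytest.approx(10.0 + 0.5 * s.age, abs=1e-9)


def test_attenuation_bends_mean_trajectory():
    site = SiteModel("S1", baseline=10, slope=0.5, noise_sd=0,
                     attenuation_knot=80, attenuation_factor=0.3)
    assert site.mean_methylation(80.0) == pytest.approx(50.0)
    assert site.mean_methylation(100.0) == pytest.approx(50.0 + 0.3 * 0.5 * 20)


def test_seed_reproducibility_contract():
    cfg = default_config(n=40, seed=11)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    c = simulate_cohort(cfg, seed=12)
    assert [(s.age, s.methylation) for s in a] == [(s.age, s.methylation) for s in b]
    assert [s.age for s in a] != [s.age for s in c]


def test_invalid_parameters_rejected():
    with pytest.raises(ValidationError):
        SiteModel("S1", baseline=0, slope=1, noise_sd=-1)
    with pytest.raises(ValidationError):
        SiteModel("S1", baseline=0, slope=1, noise_sd=1, attenuation_factor=1.5)
    with pytest.raises(ValidationError):
        UniformAges(50, 20)
    with pytest.raises(ValidationError):
        CohortConfig(n=0, sites=default_panel(), age_sampler=UniformAges(0, 10))


def test_matched_clock_single_site_inverts_generator_exactly():
    cfg = _single_site_config(n=60, noise=0.0)
    clk = matched_clock(cfg)
    assert clk.intercept == pytest.approx(-10.0 / 0.5)
    assert clk.terms[0].coefficient == pytest.approx(2.0)
    recs, _ = predict_cohort(clk, simulate_cohort(cfg))
    for r in recs:
        assert r.delta_age == pytest.approx(0.0, abs=1e-9)


def test_matched_clock_two_site_average_inversion():
    cfg = CohortConfig(
        n=40,
        sites=(
            SiteModel("A", baseline=10, slope=0.5, noise_sd=0),
            SiteModel("B", baseline=80, slope=-0.25, noise_sd=0),
        ),
        age_sampler=UniformAges(0, 100),
        seed=3,
    )
    clk = matched_clock(cfg)
    recs, _ = predict_cohort(clk, simulate_cohort(cfg))
    for r in recs:
        assert r.delta_age == pytest.approx(0.0, abs=1e-9)


def test_matched_clock_zero_slope_rejected():
    cfg = CohortConfig(
        n=5,
        sites=(SiteModel("A", baseline=10, slope=0.0, noise_sd=0),),
        age_sampler=UniformAges(0, 10),
    )
    with pytest.raises(ValidationError):
        matched_clock(cfg)


def test_clipping_counted_when_forced():
    cfg = _single_site_config(n=500, noise=30.0, baseline=2.0, slope=0.01, lo=0, hi=5)
    cohort = simulate_cohort(cfg)
    assert cohort.n_clipped > 0
    assert all(0 <= s.methylation["S1"] <= 100 for s in cohort)


def test_default_panel_clipping_negligible():
    cohort = simulate_cohort(default_config(n=2000, seed=5))
    assert cohort.clip_fraction < 0.001


def test_noise_calibration_closed_form():
    # target r, then verify the forward correlation formula round-trips
    sd_age = age_sampler_sd(BandedAges(default_bands()))
    for slope, r in [(0.55, 0.94), (-0.15, -0.79)]:
        sigma = noise_sd_for_correlation(slope, r, sd_age)
        implied = slope * sd_age / math.sqrt(slope**2 * sd_age**2 + sigma**2)
        assert implied == pytest.approx(r, abs=1e-12)


def test_age_sampler_sd_matches_empirical(rng):
    sampler = BandedAges(default_bands())
    ages, _ = sampler.draw(200_000, rng)
    assert age_sampler_sd(sampler) == pytest.approx(float(np.std(ages)), rel=0.01)
    uni = UniformAges(18, 80)
    assert age_sampler_sd(uni) == pytest.approx((80 - 18) / math.sqrt(12), abs=1e-12)


def test_default_cohort_correlations_near_targets():
    """Single-site age correlations land near their calibration targets."""
    cohort = simulate_cohort(default_config(n=4000, seed=9))
    targets = {"ASPA_1": -0.79, "EDARADD_1": -0.84, "ELOVL2_6": 0.94, "PDE4C_1": 0.88}
    for sid, r in targets.items():
        got = regress_site_on_age(cohort, sid).pearson_r
        assert got == pytest.approx(r, abs=0.03)


def test_folded_normal_mad_closed_form():
    """Matched single-site clock error is N(0, (sigma/|b|)^2); its absolute
    mean is sigma/|b| * sqrt(2/pi)."""
    sigma_over_b = 5.0
    cfg = _single_site_config(n=20_000, noise=0.5 * sigma_over_b, seed=21, lo=0, hi=80)
    recs, _ = predict_cohort(matched_clock(cfg), simulate_cohort(cfg))
    observed = mad(PairedAges([r.age for r in recs], [r.predicted_age for r in recs]))
    expected = sigma_over_b * math.sqrt(2 / math.pi)
    assert observed == pytest.approx(expected, rel=0.03)


def test_banded_sampler_expected_counts():
    """Band membership proportions follow the design cells (24,24,25,25,55)/153."""
    cohort = simulate_cohort(default_config(n=153 * 40, seed=13))
    bands = default_bands()
    counts = [0] * len(bands)
    n_female = 0
    for s in cohort:
        for i, b in enumerate(bands):
            if b.lo <= math.floor(s.age) <= b.hi:
                counts[i] += 1
        n_female += s.sex.value == "female"
    total = len(cohort)
    expected = [b.total / 153 for b in bands]
    for c, e in zip(counts, expected):
        assert c / total == pytest.approx(e, abs=0.02)
    assert n_female / total == pytest.approx(96 / 153, abs=0.02)


def test_attenuation_scenario_power_and_effect_direction():
    """Slowed drift past age 80 makes the clock under-predict the old group:
    the old-vs-adult comparison has high power and the effect direction is
    essentially certain (per-replicate error sd ~9 y vs a ~-7 y mean shift)."""
    from pyroclock.scenarios import attenuation_replicates

    out = attenuation_replicates(n_reps=100, seed=3)
    assert out["frac_old_delta_lower"] >= 0.99
    assert out["frac_reject"] >= 0.80
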