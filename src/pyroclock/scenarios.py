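"""Reusable simulation studies over the full pipeline.

Each function here wires generator -> clock -> metrics/evaluation into one
named experiment: exact parameter recovery in the noiseless limit, the
closed-form folded-normal error law, type-I error control of the delta-age
rank-sum comparison, the old-age attenuation effect, and the calibration of
the banded cohort design.  They are consumed by the analysis drivers and
the acceptance checks alike.

All randomness flows from a single integer seed; replicate seeds are
spawned deterministically, so every result is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sstats

from .clocks import predict_cohort
from .datamodel import PredictionRecord
from .evaluation import compare_delta_age, metric_dynamics
from .metrics import PairedAges, mad, pcp, r_squared, see
from .simulate import (
    CohortConfig,
    SiteModel,
    UniformAges,
    default_bands,
    default_config,
    default_panel,
    matched_clock,
    simulate_cohort,
)

__all__ = [
    "degenerate_recovery",
    "folded_normal_check",
    "TwoGroupTrial",
    "two_group_trial",
    "type_one_error_rate",
    "attenuation_replicates",
    "band_count_calibration",
]


def _paired(records: list[PredictionRecord]) -> PairedAges:
    return PairedAges([r.age for r in records], [r.predicted_age for r in records])


def _child_seeds(seed: int, k: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(k)


def degenerate_recovery(n: int = 153, seed: int = 0) -> dict[str, float]:
    """Noise-free cohort + matched clock: the pipeline must recover age exactly.

    Returns MAD, SEE, PCP at 5/7.5/10 y and R² for the banded-design cohort
    with every site's noise set to zero and no attenuation.
    """
    cfg = default_config(n=n, seed=seed)
    cfg = replace(cfg, sites=tuple(replace(s, noise_sd=0.0) for s in cfg.sites))
    records, _ = predict_cohort(matched_clock(cfg), simulate_cohort(cfg))
    p = _paired(records)
    return {
        "mad": mad(p),
        "see": see(p),
        "pcp5": pcp(p, 5.0),
        "pcp7.5": pcp(p, 7.5),
        "pcp10": pcp(p, 10.0),
        "r2": r_squared(p),
    }


def folded_normal_check(
    n: int = 20_000, sigma_over_slope: float = 5.0, seed: int = 0
) -> dict[str, float]:
    """Single-site matched clock under Gaussian noise.

    The prediction error is N(0, (sigma/|b|)^2), so MAD converges to
    ``sigma/|b| * sqrt(2/pi)`` (the folded-normal mean) and SEE to
    ``sigma/|b| * sqrt(n/(n-2))``.  Returns observed and expected values.
    """
    slope = 0.5
    cfg = CohortConfig(
        n=n,
        sites=(
            # noise expressed through sigma/|b| so the error scale is explicit
            SiteModel(
                "S1", baseline=10.0, slope=slope, noise_sd=sigma_over_slope * abs(slope)
            ),
        ),
        age_sampler=UniformAges(0.0, 80.0),
        seed=seed,
    )
    records, _ = predict_cohort(matched_clock(cfg), simulate_cohort(cfg))
    p = _paired(records)
    return {
        "mad": mad(p),
        "see": see(p),
        "expected_mad": sigma_over_slope * math.sqrt(2.0 / math.pi),
        "expected_see": sigma_over_slope * math.sqrt(n / (n - 2)),
        "n": n,
    }


@dataclass(frozen=True)
class TwoGroupTrial:
    """One adult-vs-old replicate of the delta-age comparison."""

    p_value: float
    mean_delta_adult: float
    mean_delta_old: float
    mad_full_range: float
    mad_to_80: float


def two_group_trial(
    seed: int,
    n_adult: int = 50,
    n_old: int = 50,
    attenuation: bool = False,
    attenuation_factor: float = 0.3,
) -> TwoGroupTrial:
    """Simulate adult (18-80) and old (81-101) groups and compare delta age.

    The clock is always the matched inverse of the *linear* (below-knot)
    generator; with ``attenuation`` the old group's methylation drift slows
    beyond age 80, so the clock under-predicts there — the mechanism behind
    old-age "younger" epigenetic age.
    """
    knot = 80.0 if attenuation else None
    lam = attenuation_factor if attenuation else 1.0
    seeds = _child_seeds(seed, 2)
    panel = default_panel(attenuation_knot=knot, attenuation_factor=lam)
    adult_cfg = CohortConfig(
        n=n_adult, sites=panel, age_sampler=UniformAges(18.0, 81.0),
        seed=int(seeds[0].generate_state(1)[0] % 2**31), id_prefix="A",
    )
    old_cfg = CohortConfig(
        n=n_old, sites=panel, age_sampler=UniformAges(81.0, 102.0),
        seed=int(seeds[1].generate_state(1)[0] % 2**31), id_prefix="O",
    )
    clock = matched_clock(adult_cfg)
    adult_recs, _ = predict_cohort(clock, simulate_cohort(adult_cfg))
    old_recs, _ = predict_cohort(clock, simulate_cohort(old_cfg))
    cmp = compare_delta_age(adult_recs, old_recs, "adult", "old")
    combined = adult_recs + old_recs
    curve = metric_dynamics(combined, metric="mad", step=1.0)
    # cumulative MAD over [min_age, 80]: every record with age <= 80
    to_80 = [r for r in combined if r.age <= 80.0]
    return TwoGroupTrial(
        p_value=cmp.p_value,
        mean_delta_adult=float(np.mean([r.delta_age for r in adult_recs])),
        mean_delta_old=float(np.mean([r.delta_age for r in old_recs])),
        mad_full_range=float(curve.final_value),
        mad_to_80=float(mad(_paired(to_80))),
    )


def type_one_error_rate(
    n_reps: int = 200, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the adult-vs-old comparison when no effect exists.

    With no attenuation and no sex offset, both groups' delta ages are iid
    zero-mean noise, so p-values are uniform and the rate should sit near
    ``alpha``.
    """
    seeds = _child_seeds(seed, n_reps)
    rejections = sum(
        two_group_trial(int(s.generate_state(1)[0] % 2**31)).p_value < alpha
        for s in seeds
    )
    return rejections / n_reps


def attenuation_replicates(
    n_reps: int = 200, seed: int = 0, alpha: float = 0.01
) -> dict[str, float]:
    """Replicate the old-age under-prediction scenario.

    Returns the fraction of replicates in which (a) mean delta age of the
    old group is below the adult group's, (b) the rank-sum comparison
    rejects at ``alpha``, and (c) the cumulative MAD curve grows from the
    0-80 range to the full range.
    """
    seeds = _child_seeds(seed, n_reps)
    lower = reject = mad_grows = 0
    for s in seeds:
        t = two_group_trial(int(s.generate_state(1)[0] % 2**31), attenuation=True)
        lower += t.mean_delta_old < t.mean_delta_adult
        reject += t.p_value < alpha
        mad_grows += t.mad_full_range > t.mad_to_80
    return {
        "frac_old_delta_lower": lower / n_reps,
        "frac_reject": reject / n_reps,
        "frac_mad_grows": mad_grows / n_reps,
    }


def band_count_calibration(
    n_reps: int = 500, n: int = 153, seed: int = 0
) -> dict[str, float]:
    """Check the banded age sampler against its design cell proportions.

    Each replicate draws a cohort and computes the chi-square statistic of
    its age-band counts against the design proportions (24,24,25,25,55)/153;
    returns the fraction of replicates outside the statistic's 99% region
    (expected: about 1%) and the mean observed counts.
    """
    bands = default_bands()
    probs = np.array([b.total for b in bands], dtype=float)
    expected = n * probs / probs.sum()
    crit = sstats.chi2.ppf(0.99, df=len(bands) - 1)
    seeds = _child_seeds(seed, n_reps)
    exceed = 0
    count_sum = np.zeros(len(bands))
    for s in seeds:
        cfg = default_config(n=n, seed=int(s.generate_state(1)[0] % 2**31))
        cohort = simulate_cohort(cfg)
        counts = np.zeros(len(bands))
        for sample in cohort:
            yr = math.floor(sample.age)
            for i, b in enumerate(bands):
                if b.lo <= yr <= b.hi:
                    counts[i] += 1
                    break
        count_sum += counts
        stat = float(np.sum((counts - expected) ** 2 / expected))
        exceed += stat > crit
    return {
        "frac_outside_99pct": exceed / n_reps,
        "mean_counts": (count_sum / n_reps).tolist(),
        "expected_counts": expected.tolist(),
    }
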