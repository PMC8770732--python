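"""Applying clock models and per-site age regressions."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    ClockModel,
    DegenerateInputError,
    MissingDataError,
    PredictionRecord,
    Sample,
)

__all__ = [
    "SiteRegressionResult",
    "predict_age",
    "predict_cohort",
    "regress_site_on_age",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteRegressionResult:
    """OLS of percent methylation (response) on age (predictor) at one site.

    ``slope`` is in %-methylation per year under this direction convention;
    ``pearson_r`` keeps its sign and ``r_squared == pearson_r ** 2``.
    """

    site_id: str
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n: int


def predict_age(
    model: ClockModel, sample: Sample, age_group: str = ""
) -> PredictionRecord:
    """Apply one clock model to one sample.

    Raises :class:`MissingDataError` if the sample lacks any site the model
    requires.  If the model declares a ``valid_age_range`` and the sample's
    chronological age falls outside it, the prediction is still returned
    unmodified — a warning is logged rather than the value clipped.
    """
    predicted = model.predict(sample.methylation)
    if model.valid_age_range is not None:
        lo, hi = model.valid_age_range
        if not (lo <= sample.age <= hi):
            log.warning(
                "sample %s: age %.1f outside model %s valid range [%g, %g]",
                sample.sample_id, sample.age, model.model_id, lo, hi,
            )
    return PredictionRecord.build(
        sample_id=sample.sample_id,
        sex=sample.sex,
        age=sample.age,
        predicted_age=predicted,
        age_group=age_group,
        model_id=model.model_id,
    )


def predict_cohort(
    model: ClockModel, samples: list[Sample], scheme=None
) -> tuple[list[PredictionRecord], int]:
    """Apply a model to every sample that carries its sites.

    Samples missing any required site are excluded from that model's
    predictions rather than imputed; the exclusion count is returned and
    logged so it cannot pass silently.  With an age-group ``scheme`` each
    record is labelled with its group.
    """
    if scheme is not None:
        from .evaluation import assign_age_group

        group = lambda age: assign_age_group(age, scheme)  # noqa: E731
    else:
        group = lambda age: ""  # noqa: E731
    records: list[PredictionRecord] = []
    n_excluded = 0
    for s in samples:
        try:
            records.append(predict_age(model, s, age_group=group(s.age)))
        except MissingDataError:
            n_excluded += 1
    if n_excluded:
        log.warning(
            "model %s: excluded %d/%d samples with missing sites",
            model.model_id, n_excluded, len(samples),
        )
    return records, n_excluded


def regress_site_on_age(samples: list[Sample], site_id: str) -> SiteRegressionResult:
    """Ordinary least squares of methylation at ``site_id`` on age.

    Uses only samples with the site measured; requires at least three such
    samples and non-constant age.
    """
    pts = [(s.age, s.methylation[site_id]) for s in samples if site_id in s.methylation]
    if len(pts) < 3:
        raise DegenerateInputError(
            f"site {site_id!r}: need >= 3 samples with this site measured, got {len(pts)}"
        )
    age = np.array([p[0] for p in pts])
    meth = np.array([p[1] for p in pts])
    if np.ptp(age) == 0:
        raise DegenerateInputError(f"site {site_id!r}: age is constant")
    fit = stats.linregress(age, meth)
    r = float(fit.rvalue) if np.ptp(meth) > 0 else 0.0
    return SiteRegressionResult(
        site_id=site_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=r,
        r_squared=r * r,
        n=len(pts),
    )
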