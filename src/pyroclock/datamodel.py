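"""Core domain types for small-panel methylation clocks.

The package works with per-sample percent-methylation measurements at a
handful of named CpG sites (pyrosequencing output), chronological age and
sex.  A clock model maps a methylation profile to a predicted age; the
remaining types carry predictions and stratified accuracy summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

__all__ = [
    "Direction",
    "Sex",
    "CpGSite",
    "Sample",
    "ClockTerm",
    "ClockModel",
    "PredictionRecord",
    "AccuracyReport",
    "PyroclockError",
    "FormatError",
    "ValidationError",
    "MissingDataError",
    "DegenerateInputError",
    "parse_sex",
    "MAX_VALID_AGE",
]

#: Upper validation bound on chronological age, years.  Generous relative to
#: any realistic human cohort (the supported study design spans 0-101).
MAX_VALID_AGE = 130.0


class PyroclockError(Exception):
    """Base class for all package errors."""


class FormatError(PyroclockError):
    """A file is structurally malformed (missing column, non-numeric field)."""


class ValidationError(PyroclockError):
    """Input parsed but violates a domain invariant (bounds, duplicates)."""


class MissingDataError(PyroclockError):
    """A required methylation measurement is absent from a sample."""


class DegenerateInputError(PyroclockError):
    """Too few or degenerate observations for the requested statistic."""


class Direction(str, Enum):
    """Expected direction of age-related methylation drift at a site."""

    INCREASES = "increases_with_age"
    DECREASES = "decreases_with_age"
    UNKNOWN = "unknown"


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


def parse_sex(raw: str) -> Sex:
    """Parse a free-form sex label.

    Accepts ``F``/``female`` and ``M``/``male`` case-insensitively; anything
    else maps to :attr:`Sex.UNKNOWN` (kept in pooled strata, excluded from
    per-sex strata).
    """
    s = str(raw).strip().lower()
    if s in {"f", "female"}:
        return Sex.FEMALE
    if s in {"m", "male"}:
        return Sex.MALE
    return Sex.UNKNOWN


@dataclass(frozen=True)
class CpGSite:
    """A named assay position, e.g. ``ELOVL2_6`` (gene + ordinal).

    ``aliases`` admits the concatenated spellings that appear in the
    literature ("ELOVL26") so panels can be matched against loosely
    formatted column headers.
    """

    site_id: str
    gene: str = ""
    expected_direction: Direction = Direction.UNKNOWN
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.site_id:
            raise ValidationError("CpGSite.site_id must be non-empty")

    def matches(self, name: str) -> bool:
        return name == self.site_id or name in self.aliases


@dataclass
class Sample:
    """One individual: identity, sex, chronological age and methylation.

    ``methylation`` maps site_id -> percent methylation in [0, 100].
    Sites absent from the mapping are treated as missing (allowed, but any
    clock requiring them will exclude the sample).
    """

    sample_id: str
    sex: Sex
    age: float
    methylation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.age <= MAX_VALID_AGE) or not math.isfinite(self.age):
            raise ValidationError(
                f"sample {self.sample_id!r}: age {self.age} outside [0, {MAX_VALID_AGE}]"
            )
        for site, value in self.methylation.items():
            if not (math.isfinite(value) and 0.0 <= value <= 100.0):
                raise ValidationError(
                    f"sample {self.sample_id!r}: methylation {value} at {site!r} "
                    "outside [0, 100]"
                )

    def has_sites(self, site_ids: Sequence[str]) -> bool:
        return all(s in self.methylation for s in site_ids)


@dataclass(frozen=True)
class ClockTerm:
    """One weighted, optionally powered, per-site term of a clock."""

    site_id: str
    coefficient: float
    power: int = 1

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValidationError(f"term {self.site_id!r}: power must be >= 1")
        if not math.isfinite(self.coefficient):
            raise ValidationError(f"term {self.site_id!r}: non-finite coefficient")


@dataclass(frozen=True)
class ClockModel:
    """An age predictor of the form ``intercept + sum c_i * m_i ** p_i``.

    ``m_i`` is percent methylation at the term's site.  ``valid_age_range``
    is advisory: predictions outside it are flagged, never clipped, so
    systematic out-of-range behaviour (e.g. old-age under-prediction)
    remains visible.
    """

    model_id: str
    intercept: float
    terms: tuple[ClockTerm, ...]
    valid_age_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.model_id:
            raise ValidationError("ClockModel.model_id must be non-empty")
        if len(self.terms) == 0:
            raise ValidationError(f"model {self.model_id!r}: needs at least one term")
        keys = [(t.site_id, t.power) for t in self.terms]
        if len(set(keys)) != len(keys):
            raise ValidationError(
                f"model {self.model_id!r}: duplicate (site, power) term"
            )

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(t.site_id for t in self.terms)

    def predict(self, methylation: Mapping[str, float]) -> float:
        """Predicted age for one methylation profile.

        Raises :class:`MissingDataError` naming the first absent site.
        """
        total = self.intercept
        for t in self.terms:
            if t.site_id not in methylation:
                raise MissingDataError(
                    f"model {self.model_id!r}: sample lacks site {t.site_id!r}"
                )
            total += t.coefficient * methylation[t.site_id] ** t.power
        return total


@dataclass(frozen=True)
class PredictionRecord:
    """Chronological age X, predicted age X', their difference, and labels."""

    sample_id: str
    sex: Sex
    age: float
    predicted_age: float
    delta_age: float
    age_group: str
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.delta_age != self.predicted_age - self.age:
            raise ValidationError(
                f"record {self.sample_id!r}: delta_age must equal predicted_age - age"
            )

    @staticmethod
    def build(
        sample_id: str,
        sex: Sex,
        age: float,
        predicted_age: float,
        age_group: str = "",
        model_id: str = "",
    ) -> "PredictionRecord":
        return PredictionRecord(
            sample_id=sample_id,
            sex=sex,
            age=age,
            predicted_age=predicted_age,
            delta_age=predicted_age - age,
            age_group=age_group,
            model_id=model_id,
        )


@dataclass
class AccuracyReport:
    """Accuracy metrics for one (model, age-group, sex) stratum.

    ``see`` requires n >= 3 (its denominator is n - 2) and ``r2`` requires
    n >= 2 with non-constant ages and predictions; when undefined they are
    ``None`` and a note is appended to ``flags``.
    """

    model_id: str
    age_group: str
    sex: str
    n: int
    mad: float
    pcp: dict[float, float]
    see: Optional[float] = None
    r2: Optional[float] = None
    flags: list[str] = field(default_factory=list)
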