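"""Accuracy statistics for age predictors.

All statistics operate on a pair of equal-length vectors: chronological
ages ``x`` and predicted ages ``x_pred``.  Conventions:

* MAD is the **mean** absolute difference ``sum |x_i - x'_i| / n`` — the
  usual epigenetic-clock error summary.  A median-based alternative is
  exposed separately as :func:`median_absolute_error` to avoid the
  perennial mean/median naming confusion.
* SEE is ``sqrt(sum (x_i - x'_i)^2 / (n - 2))``, the standard error of the
  estimate with the two-parameter degrees-of-freedom correction; it needs
  n >= 3.
* PCP at threshold ``t`` is ``100 * k / n`` where ``k`` counts pairs with
  ``|x_i - x'_i| <= t`` — the boundary is included.
* R² is the squared Pearson correlation between x and x', hence always in
  [0, 1] (not the identity-line residual R², which can be negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import DegenerateInputError

__all__ = [
    "PairedAges",
    "mad",
    "see",
    "pcp",
    "r_squared",
    "delta_ages",
    "median_absolute_error",
]


@dataclass(frozen=True)
class PairedAges:
    """Equal-length chronological (x) and predicted (x_pred) age vectors."""

    x: np.ndarray
    x_pred: np.ndarray

    def __init__(self, x: Sequence[float], x_pred: Sequence[float]):
        xa = np.asarray(x, dtype=float)
        pa = np.asarray(x_pred, dtype=float)
        if xa.ndim != 1 or pa.ndim != 1:
            raise DegenerateInputError("PairedAges expects 1-D vectors")
        if xa.shape != pa.shape:
            raise DegenerateInputError(
                f"length mismatch: {xa.shape[0]} ages vs {pa.shape[0]} predictions"
            )
        if xa.shape[0] == 0:
            raise DegenerateInputError("PairedAges needs at least one pair")
        if not (np.all(np.isfinite(xa)) and np.all(np.isfinite(pa))):
            raise DegenerateInputError("PairedAges values must be finite")
        object.__setattr__(self, "x", xa)
        object.__setattr__(self, "x_pred", pa)

    @property
    def n(self) -> int:
        return int(self.x.shape[0])

    @property
    def errors(self) -> np.ndarray:
        """Signed errors x - x_pred (sign is irrelevant to every metric here)."""
        return self.x - self.x_pred


def mad(p: PairedAges) -> float:
    """Mean absolute difference between predicted and chronological age, years."""
    return float(np.mean(np.abs(p.errors)))


def see(p: PairedAges) -> float:
    """Standard error of the estimate, years; denominator n - 2 requires n >= 3."""
    if p.n < 3:
        raise DegenerateInputError(f"SEE needs n >= 3 (denominator n - 2); got n={p.n}")
    return float(np.sqrt(np.sum(p.errors**2) / (p.n - 2)))


def pcp(p: PairedAges, threshold: float) -> float:
    """Percent of predictions with absolute error <= threshold (inclusive)."""
    if threshold <= 0:
        raise DegenerateInputError(f"PCP threshold must be positive; got {threshold}")
    k = int(np.count_nonzero(np.abs(p.errors) <= threshold))
    return 100.0 * k / p.n


def r_squared(p: PairedAges) -> float:
    """Squared Pearson correlation between chronological and predicted age.

    Bounded in [0, 1] by construction.  Undefined when either vector is
    constant (zero variance) or n < 2.
    """
    if p.n < 2:
        raise DegenerateInputError(f"R^2 needs n >= 2; got n={p.n}")
    if np.ptp(p.x) == 0 or np.ptp(p.x_pred) == 0:
        raise DegenerateInputError("R^2 undefined for a constant age vector")
    r = np.corrcoef(p.x, p.x_pred)[0, 1]
    return float(min(r * r, 1.0))


def delta_ages(p: PairedAges) -> np.ndarray:
    """Elementwise delta age x_pred - x, order preserving.

    Negative values mean the clock under-predicts ("younger" epigenetic age).
    """
    return p.x_pred - p.x


def median_absolute_error(p: PairedAges) -> float:
    """Median of |x - x_pred| — the median-based cousin of :func:`mad`."""
    return float(np.median(np.abs(p.errors)))
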