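"""Uncertainty bookkeeping: bias, quadrature combination, intervals.

The generalization bias is characterized as the mean of the absolute
relative errors seen in evaluation; independent fractional error sources
are combined in quadrature (square root of the sum of squares); and 95%
confidence intervals around a central death estimate are the central
value times (1 +/- combined fraction), rounded to a configurable
granularity (nearest 1,000 deaths for national totals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "UncertaintySpec",
    "mean_absolute_bias",
    "combine_quadrature",
    "as_percent",
    "confidence_interval",
]


def _round_half_up(x: float) -> float:
    return float(np.floor(x + 0.5))


def mean_absolute_bias(relative_errors: Sequence[float]) -> float:
    """Mean of absolute relative errors (fractions)."""
    errs = np.asarray(list(relative_errors), dtype=float)
    if errs.size == 0:
        raise ValueError("need at least one relative error")
    return float(np.abs(errs).mean())


def combine_quadrature(components: Sequence[float]) -> float:
    """Combine independent fractional uncertainties in quadrature."""
    comps = np.asarray(list(components), dtype=float)
    if comps.size == 0:
        raise ValueError("need at least one component")
    if np.any(comps < 0):
        raise ValueError("uncertainty components must be non-negative")
    return float(np.sqrt(np.sum(comps * comps)))


def as_percent(fraction: float) -> int:
    """Report a fraction as a whole percent (half rounds up)."""
    return int(_round_half_up(100.0 * fraction))


def confidence_interval(
    central: float, combined: float, rounding: float = 1000.0
) -> tuple[float, float]:
    """Symmetric interval ``central x (1 -/+ combined)``, each bound
    rounded to the nearest ``rounding`` deaths."""
    if central <= 0:
        raise ValueError("central estimate must be positive")
    if not 0 <= combined < 1:
        raise ValueError("combined fraction must lie in [0, 1)")
    if rounding <= 0:
        raise ValueError("rounding granularity must be positive")
    low = _round_half_up(central * (1.0 - combined) / rounding) * rounding
    high = _round_half_up(central * (1.0 + combined) / rounding) * rounding
    return (low, high)


@dataclass
class UncertaintySpec:
    """Named fractional error sources and reporting granularity.

    Defaults carry the two standard components: the generalization bias
    (0.14) and the ERF-plus-temperature uncertainty of summed city
    estimates (0.35), combining to 0.38.
    """

    components: dict[str, float] = field(
        default_factory=lambda: {"generalization": 0.14, "erf_and_temperature": 0.35}
    )
    ci_rounding: float = 1000.0

    def __post_init__(self):
        for name, frac in self.components.items():
            if not 0 <= frac < 1:
                raise ValueError(f"component {name!r} must lie in [0, 1)")

    @property
    def combined(self) -> float:
        return combine_quadrature(list(self.components.values()))

    def interval(self, central: float) -> tuple[float, float]:
        return confidence_interval(central, self.combined, self.ci_rounding)
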