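"""Generalized temperature-mortality exposure-response functions.

An exposure-response function (ERF) gives the relative risk (RR) of
all-cause death as a function of daily mean temperature for one location,
normalized so that RR = 1 at the local optimal temperature (OT), the
temperature of minimum observed mortality.  City-level ERFs derived from
epidemiological studies are only available for a handful of large cities,
so this module builds a *generalized* ERF usable anywhere:

1. each city's observed curve is fit with a quadratic in
   ``T = daily temperature - OT`` restricted to the hot side (``T >= 0``)::

       RR = 1 + a T^2 + b T

2. the fitted coefficients ``a`` and ``b`` are regressed linearly on each
   city's summer (June-August) mean temperature (SMT), capturing the
   observation that cooler climates have steeper risk curves; and

3. the generalized RR at any location is evaluated from its own OT and SMT::

       RR = 1 + slope_a (SMT - xint_a) T^2 + slope_b (SMT - xint_b) T

   clamped below at 1, since for cool SMT the opposite-signed linear term
   can dip the unclamped curve under 1 at small T.

Two fitting variants are supported.  Variant A fits a free constant per
city and discards the (small) offset; variant B forces each city fit
through RR = 1 at T = 0.  Both yield similar generalizations; the
published parameter sets for both are shipped as presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, NonIdentifiableError

__all__ = [
    "Variant",
    "ERFCurve",
    "PolyCoef",
    "GenERFParams",
    "RunCounters",
    "PRESETS",
    "fit_city_polynomial",
    "regress_coefficients",
    "relative_risk",
    "loo_sensitivity",
    "LooSensitivity",
]


class Variant(str, Enum):
    """City-fit variant: free offset at T=0 (A) or forced through RR=1 (B)."""

    A_FREE_OFFSET = "A"
    B_FORCED_THROUGH_ONE = "B"

    @classmethod
    def parse(cls, value: "str | Variant") -> "Variant":
        if isinstance(value, cls):
            return value
        v = str(value).strip().upper()
        for member in cls:
            if v in (member.value, member.name):
                return member
        raise ValueError(f"unknown ERF variant {value!r}; expected 'A' or 'B'")


@dataclass(frozen=True)
class ERFCurve:
    """One location's observed RR-vs-temperature table.

    Samples are at 0.1 degC increments.  ``ot`` is the optimal temperature
    (RR defined to be 1 there) and ``smt`` the local summer mean
    temperature, the covariate the generalization uses.
    """

    city_id: str
    smt: float
    ot: float
    temp: np.ndarray
    rr: np.ndarray

    def __post_init__(self):
        temp = np.asarray(self.temp, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "temp", temp)
        object.__setattr__(self, "rr", rr)
        if temp.ndim != 1 or temp.shape != rr.shape:
            raise ValueError("temp and rr must be parallel 1-D arrays")
        if temp.size >= 2:
            steps = np.diff(temp)
            if np.any(steps <= 0):
                raise ValueError("temperatures must be strictly increasing")
            if not np.allclose(steps, 0.1, atol=1e-6):
                raise ValueError("samples must be at 0.1 degC increments")
        if np.any(rr < 0):
            raise ValueError("relative risk cannot be negative")
        if not (np.isfinite(self.smt) and np.isfinite(self.ot)):
            raise ValueError("smt and ot must be finite")
        # Observed curves are normalized to RR = 1 at OT; tolerate noise.
        if temp.size and temp[0] - 1e-9 <= self.ot <= temp[-1] + 1e-9:
            i = int(np.argmin(np.abs(temp - self.ot)))
            if abs(rr[i] - 1.0) > 0.05:
                raise ValueError(
                    f"curve {self.city_id!r}: RR at OT is {rr[i]:.3f}, "
                    "expected 1 within 0.05"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"city_id": self.city_id, "temp_c": self.temp, "rr": self.rr}
        )


@dataclass(frozen=True)
class PolyCoef:
    """Quadratic fit ``RR = 1 + a T^2 + b T`` for one city.

    ``offset`` is the fitted constant minus one (diagnostic; identically 0
    for variant B, which forces the curve through RR = 1 at T = 0).
    """

    a: float
    b: float
    offset: float
    variant: Variant

    def __post_init__(self):
        if self.variant is Variant.B_FORCED_THROUGH_ONE and self.offset != 0.0:
            raise ValueError("variant B has no free offset")


@dataclass(frozen=True)
class GenERFParams:
    """Parameters of the generalized ERF.

    Each coefficient of the city quadratic is modelled as a line in SMT,
    stored as (slope, x-intercept) and always evaluated as
    ``slope * (SMT - x_intercept)``.  ``corr_a``/``corr_b`` are the
    correlation coefficients of the two coefficient-vs-SMT regressions
    when the parameters came from a fit (NaN for hand-set presets).
    """

    slope_a: float
    xint_a: float
    slope_b: float
    xint_b: float
    variant: Variant = Variant.A_FREE_OFFSET
    corr_a: float = float("nan")
    corr_b: float = float("nan")

    def coef_a(self, smt):
        """Quadratic-term coefficient at the given SMT."""
        return self.slope_a * (np.asarray(smt, dtype=float) - self.xint_a)

    def coef_b(self, smt):
        """Linear-term coefficient at the given SMT."""
        return self.slope_b * (np.asarray(smt, dtype=float) - self.xint_b)

    def as_dict(self) -> dict:
        return {
            "slope_a": self.slope_a,
            "xint_a": self.xint_a,
            "slope_b": self.slope_b,
            "xint_b": self.xint_b,
            "variant": self.variant.value,
            "corr_a": self.corr_a,
            "corr_b": self.corr_b,
        }


#: Published generalized-ERF parameter sets.
PRESETS: dict[str, GenERFParams] = {
    # free-offset city fits (primary parameterization)
    "variant_a": GenERFParams(-0.0014, 30.9, 0.005, 26.7, Variant.A_FREE_OFFSET),
    # city fits forced through RR = 1 at T = 0
    "variant_b": GenERFParams(-0.0011, 32.3, 0.0032, 26.6, Variant.B_FORCED_THROUGH_ONE),
}


@dataclass
class RunCounters:
    """Auditing counters propagated through RR evaluation and lookups.

    ``smt_above_quad_xint`` counts hot-side evaluations in the regime where
    the quadratic coefficient turns negative (SMT above its x-intercept),
    where the generalized curve bends downward at large T.
    ``erf_lookup_above_range`` counts observed-curve lookups beyond the
    tabulated range (held flat at the last sample).
    """

    smt_above_quad_xint: int = 0
    erf_lookup_above_range: int = 0

    def merge(self, other: "RunCounters") -> "RunCounters":
        self.smt_above_quad_xint += other.smt_above_quad_xint
        self.erf_lookup_above_range += other.erf_lookup_above_range
        return self

    def as_dict(self) -> dict:
        return {
            "smt_above_quad_xint": self.smt_above_quad_xint,
            "erf_lookup_above_range": self.erf_lookup_above_range,
        }


def fit_city_polynomial(curve: ERFCurve, variant=Variant.A_FREE_OFFSET) -> PolyCoef:
    """Least-squares quadratic fit of one city's curve on the hot side.

    Only samples with ``temp >= ot`` enter the fit (the generalization is
    for heat above the optimal temperature; the cold side is ignored).

    Raises
    ------
    DegenerateInputError
        Fewer than three usable samples, or a singular design (all T equal).
    """
    variant = Variant.parse(variant)
    mask = curve.temp >= curve.ot - 1e-9
    T = curve.temp[mask] - curve.ot
    y = curve.rr[mask]
    if T.size < 3:
        raise DegenerateInputError(
            f"curve {curve.city_id!r}: {T.size} samples at or above OT; need >= 3"
        )
    n_distinct = np.unique(np.round(T, 9)).size
    if n_distinct < 3:
        raise DegenerateInputError(
            f"curve {curve.city_id!r}: design is singular ({n_distinct} distinct T)"
        )
    if variant is Variant.A_FREE_OFFSET:
        X = np.column_stack([np.ones_like(T), T, T * T])
        c0, c1, c2 = np.linalg.lstsq(X, y, rcond=None)[0]
        coef = PolyCoef(a=float(c2), b=float(c1), offset=float(c0 - 1.0), variant=variant)
    else:
        X = np.column_stack([T, T * T])
        c1, c2 = np.linalg.lstsq(X, y - 1.0, rcond=None)[0]
        coef = PolyCoef(a=float(c2), b=float(c1), offset=0.0, variant=variant)
    if not (np.isfinite(coef.a) and np.isfinite(coef.b)):
        raise DegenerateInputError(f"curve {curve.city_id!r}: non-finite fit")
    return coef


def regress_coefficients(
    points: Sequence[tuple[float, PolyCoef]],
) -> GenERFParams:
    """Ordinary least squares of city coefficients on city SMT.

    ``points`` pairs each city's SMT with its fitted :class:`PolyCoef`.
    Slopes are reported directly; x-intercepts as ``-intercept/slope``.

    Raises
    ------
    DegenerateInputError
        Fewer than three points with distinct SMT.
    NonIdentifiableError
        Either regression slope is zero within tolerance, so its
        x-intercept is undefined.
    """
    if len(points) < 3:
        raise DegenerateInputError("need at least 3 (smt, coefficient) points")
    smt = np.array([float(s) for s, _ in points])
    if np.unique(smt).size < 3:
        raise DegenerateInputError("need at least 3 distinct SMT values")
    variants = {c.variant for _, c in points}
    if len(variants) > 1:
        raise ValueError("mixed fit variants in coefficient regression")
    a = np.array([c.a for _, c in points])
    b = np.array([c.b for _, c in points])

    fit_a = stats.linregress(smt, a)
    fit_b = stats.linregress(smt, b)
    out = {}
    for name, fit in (("a", fit_a), ("b", fit_b)):
        scale = max(1.0, abs(fit.intercept))
        if abs(fit.slope) < 1e-12 * scale:
            raise NonIdentifiableError(
                f"coefficient-{name} regression slope is ~0; x-intercept undefined"
            )
        out[name] = (float(fit.slope), float(-fit.intercept / fit.slope))
    return GenERFParams(
        slope_a=out["a"][0],
        xint_a=out["a"][1],
        slope_b=out["b"][0],
        xint_b=out["b"][1],
        variant=variants.pop(),
        corr_a=float(fit_a.rvalue),
        corr_b=float(fit_b.rvalue),
    )


def relative_risk(t_day, ot, smt, params: GenERFParams, counters: RunCounters | None = None,
                  clamp: bool = True):
    """Generalized relative risk at daily temperature ``t_day``.

    ``T = t_day - ot``; for ``T <= 0`` RR is 1 (no excess heat risk below
    the optimal temperature).  On the hot side the generalized quadratic is
    evaluated and, if ``clamp`` (the default), limited below at 1.
    Inputs broadcast, so gridded fields can be passed directly.

    Evaluations with SMT above the quadratic-term x-intercept (where the
    curve turns concave) are counted in ``counters`` when given.
    """
    t_day = np.asarray(t_day, dtype=float)
    ot = np.asarray(ot, dtype=float)
    smt = np.asarray(smt, dtype=float)
    for name, arr in (("t_day", t_day), ("ot", ot), ("smt", smt)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    T = t_day - ot
    raw = 1.0 + (params.coef_a(smt) * T + params.coef_b(smt)) * T
    hot = T > 0
    if clamp:
        raw = np.maximum(raw, 1.0)
    rr = np.where(hot, raw, 1.0)
    if counters is not None:
        counters.smt_above_quad_xint += int(
            np.count_nonzero(hot & np.broadcast_to(smt > params.xint_a, hot.shape))
        )
    return float(rr) if rr.ndim == 0 else rr


@dataclass(frozen=True)
class LooSensitivity:
    """Leave-one-out sensitivity of the coefficient-regression slopes."""

    full: GenERFParams
    slopes_a: np.ndarray
    slopes_b: np.ndarray
    #: per-left-out-city deviation relative to the all-points slope
    rel_dev_a: np.ndarray
    rel_dev_b: np.ndarray
    sd_rel_a: float
    sd_rel_b: float
    max_rel_dev_a: float
    max_rel_dev_b: float


def loo_sensitivity(points: Sequence[tuple[float, PolyCoef]]) -> LooSensitivity:
    """Re-fit the coefficient regression leaving out one city at a time.

    With only a handful of cities the generalization is sensitive to
    individual data points; this quantifies that spread as the standard
    deviation and maximum of the per-left-out slopes relative to the
    all-points slopes.
    """
    if len(points) < 4:
        raise DegenerateInputError("leave-one-out needs at least 4 points")
    full = regress_coefficients(points)
    slopes_a, slopes_b = [], []
    for i in range(len(points)):
        reduced = [p for j, p in enumerate(points) if j != i]
        fit = regress_coefficients(reduced)
        slopes_a.append(fit.slope_a)
        slopes_b.append(fit.slope_b)
    slopes_a = np.array(slopes_a)
    slopes_b = np.array(slopes_b)
    rel_a = (slopes_a - full.slope_a) / full.slope_a
    rel_b = (slopes_b - full.slope_b) / full.slope_b
    return LooSensitivity(
        full=full,
        slopes_a=slopes_a,
        slopes_b=slopes_b,
        rel_dev_a=rel_a,
        rel_dev_b=rel_b,
        sd_rel_a=float(np.std(rel_a)),
        sd_rel_b=float(np.std(rel_b)),
        max_rel_dev_a=float(np.max(np.abs(rel_a))),
        max_rel_dev_b=float(np.max(np.abs(rel_b))),
    )
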