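"""Heat-attributable deaths: the core accounting engine.

Attributable deaths in a cell on a day are::

    deaths = population x daily baseline rate x attributable fraction

where the attributable fraction is ``RR - 1`` (the default convention
here; the textbook alternative ``(RR - 1)/RR`` is available for
sensitivity runs) and RR comes from the generalized exposure-response
function evaluated at that day's temperature with the cell's OT and SMT.
The daily baseline rate distributes an annual all-cause mortality rate
across months by fixed monthly shares, with deaths spread evenly within
each month.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from ._calendar import DAYS_PER_YEAR, MONTH_LENGTHS, month_of_doy
from .erf import ERFCurve, GenERFParams, RunCounters, relative_risk
from .errors import AlignmentError, MaskError
from .exposure import ExposureFields

__all__ = [
    "BaselineMortality",
    "MortalityResult",
    "CitySeries",
    "daily_baseline_rate",
    "daily_rate_profile",
    "attributable_deaths",
    "project_scenario",
    "aggregate_regions",
    "observed_relative_risk",
    "evaluation_report",
    "totals_row",
]

AF_CONVENTIONS = ("rr_minus_1", "rr_minus_1_over_rr")


@dataclass(frozen=True)
class BaselineMortality:
    """Annual all-cause mortality rate plus monthly weighting."""

    annual_rate: float
    monthly_shares: np.ndarray

    def __post_init__(self):
        shares = np.asarray(self.monthly_shares, dtype=float)
        object.__setattr__(self, "monthly_shares", shares)
        if self.annual_rate <= 0:
            raise ValueError("annual_rate must be positive")
        if shares.shape != (12,) or np.any(shares <= 0):
            raise ValueError("monthly_shares must be 12 positive fractions")
        if abs(shares.sum() - 1.0) > 1e-9:
            raise ValueError("monthly_shares must sum to 1")

    @classmethod
    def uniform(cls, annual_rate: float) -> "BaselineMortality":
        """Shares proportional to month lengths (no seasonality)."""
        return cls(annual_rate, MONTH_LENGTHS / DAYS_PER_YEAR)


def daily_baseline_rate(bm: BaselineMortality, doy: int) -> float:
    """Deaths per person on one day (1-based day-of-year, no-leap):
    ``annual_rate x share(month) / days_in_month``."""
    m = month_of_doy(doy)
    return bm.annual_rate * float(bm.monthly_shares[m - 1]) / float(MONTH_LENGTHS[m - 1])


def daily_rate_profile(bm: BaselineMortality) -> np.ndarray:
    """365-vector of daily baseline rates; sums exactly to annual_rate."""
    per_month = bm.annual_rate * bm.monthly_shares / MONTH_LENGTHS
    return np.repeat(per_month, MONTH_LENGTHS)


def attributable_deaths(pop, daily_rate, rr, af_convention: str = "rr_minus_1"):
    """Deaths attributable to heat for aligned pop/rate/RR arrays."""
    if af_convention not in AF_CONVENTIONS:
        raise ValueError(f"unknown af_convention {af_convention!r}")
    pop = np.asarray(pop, dtype=float)
    daily_rate = np.asarray(daily_rate, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if np.any(pop < 0):
        raise ValueError("negative population")
    if np.any(daily_rate < 0):
        raise ValueError("negative baseline rate")
    af = rr - 1.0
    if af_convention == "rr_minus_1_over_rr":
        af = af / rr
    out = pop * daily_rate * af
    return float(out) if out.ndim == 0 else out


@dataclass
class MortalityResult:
    """Per-cell, per-year attributable deaths with aggregations.

    ``deaths_cell_year`` has shape (n_years, n_lat, n_lon); regional
    aggregations are filled in by :func:`aggregate_regions`.
    """

    deaths_cell_year: np.ndarray
    years: np.ndarray
    national_by_year: np.ndarray
    national_annual_mean: float
    scenario: str = ""
    adaptation: str = ""
    pop_scale: float = 1.0
    counters: RunCounters = field(default_factory=RunCounters)
    per_capita_by_state: "pd.Series | None" = None
    city_box_totals: "pd.Series | None" = None


def _check_grid(name, shape, ref_shape):
    for dim, (got, want) in zip(("lat", "lon"), zip(shape, ref_shape)):
        if got != want:
            raise AlignmentError(
                f"{name}: {dim} size {got} does not match temperature grid {want}"
            )


def project_scenario(
    temps: xr.DataArray,
    pop: np.ndarray,
    bm: BaselineMortality,
    exposure: ExposureFields,
    params: GenERFParams,
    pop_scale: float = 1.0,
    af_convention: str = "rr_minus_1",
    counters: "RunCounters | None" = None,
    scenario: str = "",
    adaptation: str = "",
) -> MortalityResult:
    """Accumulate attributable deaths over a multi-year daily series.

    ``pop`` is multiplied by ``pop_scale`` (a national per-decade
    population projection factor) before accumulation.  The temperature
    series must cover whole no-leap years.
    """
    counters = counters if counters is not None else RunCounters()
    vals = temps.values
    n_time, n_lat, n_lon = vals.shape
    pop = np.asarray(pop, dtype=float)
    _check_grid("population", pop.shape, (n_lat, n_lon))
    _check_grid("exposure", np.asarray(exposure.ot).shape, (n_lat, n_lon))
    if n_time % DAYS_PER_YEAR:
        raise ValueError("temperature series must cover whole 365-day years")
    n_years = n_time // DAYS_PER_YEAR
    years = temps.coords["year"].values.reshape(n_years, DAYS_PER_YEAR)
    if not (years == years[:, :1]).all():
        raise ValueError("time axis must be ordered year-by-year")
    doy = temps.coords["doy"].values

    rr = relative_risk(
        vals,
        np.asarray(exposure.ot)[None, :, :],
        np.asarray(exposure.smt)[None, :, :],
        params,
        counters=counters,
    )
    rate = daily_rate_profile(bm)[doy - 1]
    deaths_day = attributable_deaths(
        (pop * pop_scale)[None, :, :], rate[:, None, None], rr, af_convention
    )
    cell_year = deaths_day.reshape(n_years, DAYS_PER_YEAR, n_lat, n_lon).sum(axis=1)
    national = cell_year.sum(axis=(1, 2))
    return MortalityResult(
        deaths_cell_year=cell_year,
        years=years[:, 0].copy(),
        national_by_year=national,
        national_annual_mean=float(national.mean()),
        scenario=scenario,
        adaptation=adaptation,
        pop_scale=pop_scale,
        counters=counters,
    )


def aggregate_regions(
    result: MortalityResult,
    pop: np.ndarray,
    state_mask: np.ndarray,
    city_boxes: "dict[str, list[tuple[int, int]]] | None" = None,
) -> MortalityResult:
    """Fill in per-state per-capita rates and city-box totals.

    ``state_mask`` holds an integer state id per cell (negative = no
    assignment; only allowed where population is zero).  Per-capita rates
    are annual-mean deaths per million persons, using the same population
    scaling as the projection run.
    """
    pop = np.asarray(pop, dtype=float) * result.pop_scale
    state_mask = np.asarray(state_mask)
    annual = result.deaths_cell_year.mean(axis=0)
    unassigned = (state_mask < 0) & (pop > 0)
    if unassigned.any():
        cells = [tuple(int(i) for i in c) for c in np.argwhere(unassigned)]
        raise MaskError(f"populated cells with no state assignment: {cells[:10]}")
    rates = {}
    for s in np.unique(state_mask[state_mask >= 0]):
        sel = state_mask == s
        p = pop[sel].sum()
        rates[int(s)] = float(annual[sel].sum() / p * 1e6) if p > 0 else float("nan")
    result.per_capita_by_state = pd.Series(rates, name="deaths_per_year_per_million")
    if city_boxes is not None:
        totals = {
            name: float(sum(annual[i, j] for i, j in cells))
            for name, cells in city_boxes.items()
        }
        result.city_box_totals = pd.Series(totals, name="deaths_per_year")
    return result


# ---------------------------------------------------------------------------
# Evaluation against observed city curves


def observed_relative_risk(curve: ERFCurve, t_day, counters: "RunCounters | None" = None):
    """RR by lookup into an observed city table.

    Linear interpolation between the 0.1 degC samples; temperatures below
    the tabulated range (the cold side) give RR = 1, temperatures above it
    hold the last tabulated value (flat extrapolation, counted).  Values
    are clamped at RR >= 1 to match the generalized evaluation.
    """
    t_day = np.asarray(t_day, dtype=float)
    rr = np.interp(t_day, curve.temp, curve.rr, left=1.0, right=float(curve.rr[-1]))
    if counters is not None:
        counters.erf_lookup_above_range += int(np.count_nonzero(t_day > curve.temp[-1]))
    rr = np.maximum(rr, 1.0)
    return float(rr) if rr.ndim == 0 else rr


@dataclass
class CitySeries:
    """One city's inputs for the generalized-vs-observed evaluation."""

    curve: ERFCurve
    temps: np.ndarray  # daily means, whole years
    doy: np.ndarray  # parallel 1-based day-of-year
    population: float


def evaluation_report(
    cities: Sequence[CitySeries],
    params: GenERFParams,
    bm: BaselineMortality,
    af_convention: str = "rr_minus_1",
    counters: "RunCounters | None" = None,
) -> pd.DataFrame:
    """Annual-average deaths per city under generalized vs observed ERF.

    Returns a table indexed by city with columns ``generalized``,
    ``observed``, ``abs_error`` (generalized - observed) and
    ``rel_error_pct`` (rounded percent), plus a ``Total`` row whose
    errors are recomputed from the column sums.
    """
    counters = counters if counters is not None else RunCounters()
    rows = {}
    for cs in cities:
        t = np.asarray(cs.temps, dtype=float)
        doy = np.asarray(cs.doy)
        if t.size % DAYS_PER_YEAR:
            raise ValueError(f"{cs.curve.city_id}: series must cover whole years")
        n_years = t.size // DAYS_PER_YEAR
        rate = daily_rate_profile(bm)[doy - 1]
        rr_gen = relative_risk(t, cs.curve.ot, cs.curve.smt, params, counters=counters)
        rr_obs = observed_relative_risk(cs.curve, t, counters=counters)
        d_gen = attributable_deaths(cs.population, rate, rr_gen, af_convention).sum() / n_years
        d_obs = attributable_deaths(cs.population, rate, rr_obs, af_convention).sum() / n_years
        rows[cs.curve.city_id] = (d_gen, d_obs)
    frame = pd.DataFrame(rows, index=["generalized", "observed"]).T
    gen_total, obs_total = frame["generalized"].sum(), frame["observed"].sum()
    frame.loc["Total"] = (gen_total, obs_total)
    frame["abs_error"] = frame["generalized"] - frame["observed"]
    frame["rel_error_pct"] = _round_half_up(
        100.0 * frame["abs_error"] / frame["observed"]
    )
    return frame


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


def totals_row(generalized: Sequence[float], observed: Sequence[float]) -> dict:
    """Totals-row arithmetic for an evaluation table: sum both columns,
    then recompute absolute and (rounded percent) relative error from
    the sums."""
    g = float(np.sum(generalized))
    o = float(np.sum(observed))
    abs_err = g - o
    return {
        "generalized": g,
        "observed": o,
        "abs_error": abs_err,
        "rel_error_pct": int(_round_half_up(100.0 * abs_err / o)),
    }
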