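"""Synthetic inputs with known ground truth.

Everything the projection pipeline consumes can be generated here:
gridded daily temperatures (seasonal sinusoid + AR(1) weather noise +
an optional warming trend), a gridded population, monthly baseline-
mortality weights, state/city region masks, and city exposure-response
curves sampled from a known generalized quadratic plus noise.  All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import xarray as xr

from ._calendar import DAYS_PER_YEAR, MID_JULY_DOY, MONTH_LENGTHS, MONTH_STARTS
from .erf import ERFCurve, GenERFParams, PRESETS
from .errors import ConfigurationError

__all__ = [
    "ClimateSpec",
    "SyntheticCitySpec",
    "CITY_SMT",
    "default_climate_spec",
    "gen_temperature_grid",
    "gen_city_erf",
    "gen_city_curves",
    "gen_population_grid",
    "gen_monthly_weights",
    "gen_state_mask",
    "gen_city_boxes",
]

#: Summer (June-August) mean temperatures, degC, for the ten benchmark
#: U.S. cities whose observed exposure-response curves anchor the
#: generalization.  Used as defaults when generating synthetic curves.
CITY_SMT: dict[str, float] = {
    "Atlanta": 25.7,
    "Boston": 21.2,
    "Chicago": 22.5,
    "Dallas": 28.9,
    "Houston": 28.4,
    "Los Angeles": 21.8,
    "Miami": 28.4,
    "New York": 23.1,
    "Philadelphia": 23.9,
    "Washington DC": 24.4,
}


@dataclass
class ClimateSpec:
    """Recipe for a gridded daily-temperature series.

    The generated temperature at a cell is::

        mean(cell) + amplitude * cos(2 pi (doy - peak_doy)/365)
        + trend * elapsed_years / 10 + AR(1) noise

    ``annual_mean`` may be a scalar or an (n_lat, n_lon) array; ``trend``
    is degC per decade, measured from ``ref_year`` (default: first year
    generated) so that disjoint periods generated from the same spec sit
    on one consistent warming trajectory.  ``smt_band`` documents the
    plausible range of summer means the defaults are designed to span;
    it is checked by the test-suite, not enforced by the generator.
    """

    n_lat: int
    n_lon: int
    years: Sequence[int]
    annual_mean: "float | np.ndarray" = 16.0
    seasonal_amplitude: float = 9.0
    ar1_coef: float = 0.7
    daily_sd: float = 3.0
    trend: float = 0.0
    peak_doy: int = MID_JULY_DOY
    ref_year: "int | None" = None
    smt_band: tuple[float, float] = (18.0, 32.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ConfigurationError("grid dimensions must be positive")
        years = list(self.years)
        if not years:
            raise ConfigurationError("years must be non-empty")
        if any(b - a != 1 for a, b in zip(years, years[1:])):
            raise ConfigurationError("years must be contiguous")
        if self.daily_sd < 0:
            raise ConfigurationError("daily_sd must be non-negative")
        if not abs(self.ar1_coef) < 1:
            raise ConfigurationError("|ar1_coef| must be < 1")
        mean = np.asarray(self.annual_mean, dtype=float)
        if mean.ndim not in (0, 2):
            raise ConfigurationError("annual_mean must be scalar or 2-D")
        if mean.ndim == 2 and mean.shape != (self.n_lat, self.n_lon):
            raise ConfigurationError("annual_mean shape does not match grid")


def default_climate_spec(
    n_lat: int,
    n_lon: int,
    years: Sequence[int],
    seed: int = 0,
    trend: float = 0.0,
    mean_north: float = 12.0,
    mean_south: float = 19.0,
    ref_year: "int | None" = None,
) -> ClimateSpec:
    """A realistic default grid: annual means grade from a warm south row
    to a cool north row so summer means span roughly 20-28 degC."""
    means = np.linspace(mean_south, mean_north, n_lat)[:, None]
    return ClimateSpec(
        n_lat=n_lat,
        n_lon=n_lon,
        years=list(years),
        annual_mean=np.broadcast_to(means, (n_lat, n_lon)).copy(),
        trend=trend,
        ref_year=ref_year,
        seed=seed,
    )


def _ar1_noise(rng, n_time, shape, phi, sd):
    """AR(1) series with stationary marginal standard deviation ``sd``."""
    out = np.empty((n_time, *shape))
    if sd == 0:
        out.fill(0.0)
        return out
    out[0] = sd * rng.standard_normal(shape)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    for t in range(1, n_time):
        out[t] = phi * out[t - 1] + innov_sd * rng.standard_normal(shape)
    return out


def gen_temperature_grid(spec: ClimateSpec) -> xr.DataArray:
    """Generate daily mean temperature with dims (time, lat, lon).

    The returned array carries ``year`` and ``doy`` auxiliary coordinates
    on the time axis (365-day no-leap calendar) and a ``units: degC``
    attribute.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    years = np.asarray(list(spec.years), dtype=int)
    n_years = years.size
    n_time = n_years * DAYS_PER_YEAR
    doy = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    year = np.repeat(years, DAYS_PER_YEAR)

    mean = np.broadcast_to(
        np.asarray(spec.annual_mean, dtype=float), (spec.n_lat, spec.n_lon)
    )
    seasonal = spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - spec.peak_doy) / DAYS_PER_YEAR
    )
    ref_year = spec.ref_year if spec.ref_year is not None else int(years[0])
    elapsed = (year - ref_year) + (doy - 1) / DAYS_PER_YEAR
    trend = spec.trend * elapsed / 10.0
    noise = _ar1_noise(
        rng, n_time, (spec.n_lat, spec.n_lon), spec.ar1_coef, spec.daily_sd
    )
    data = mean[None, :, :] + (seasonal + trend)[:, None, None] + noise

    lat = 25.25 + 0.5 * np.arange(spec.n_lat)
    lon = -124.75 + 0.5 * np.arange(spec.n_lon)
    return xr.DataArray(
        data,
        dims=("time", "lat", "lon"),
        coords={
            "time": np.arange(n_time),
            "lat": lat,
            "lon": lon,
            "year": ("time", year.astype("int32")),
            "doy": ("time", doy.astype("int32")),
        },
        name="temperature",
        attrs={"units": "degC", "calendar": "noleap"},
    )


@dataclass
class SyntheticCitySpec:
    """Recipe for one synthetic city exposure-response curve.

    The curve is sampled at 0.1 degC increments from OT to OT + t_range::

        RR = 1 + a_true T^2 + b_true T + noise,   clipped at RR >= 0

    with ``a_true = slope_a_true (smt_true - xint_a_true)`` and
    ``b_true = slope_b_true (smt_true - xint_b_true)``, i.e. the truth is
    itself a generalized quadratic, so downstream fits have a known
    target.  Defaults reproduce the primary published parameter set.
    ``ot`` defaults to ``smt_true + 2`` (the optimal temperature sits a
    little above the summer mean in most climates); for fitting purposes
    only ``temp - ot`` matters, so the choice is inert.
    """

    smt_true: float
    slope_a_true: float = -0.0014
    xint_a_true: float = 30.9
    slope_b_true: float = 0.005
    xint_b_true: float = 26.7
    noise_sd: float = 0.0
    t_range: float = 10.0
    ot: "float | None" = None
    city_id: str = "city"
    seed: int = 0

    def validate(self) -> None:
        if self.t_range <= 0:
            raise ConfigurationError("t_range must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    @property
    def a_true(self) -> float:
        return self.slope_a_true * (self.smt_true - self.xint_a_true)

    @property
    def b_true(self) -> float:
        return self.slope_b_true * (self.smt_true - self.xint_b_true)


def gen_city_erf(spec: SyntheticCitySpec) -> ERFCurve:
    """Sample one synthetic city curve from its generating quadratic."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ot = spec.ot if spec.ot is not None else spec.smt_true + 2.0
    n = int(round(spec.t_range * 10)) + 1
    T = np.arange(n) * 0.1
    rr = 1.0 + spec.a_true * T * T + spec.b_true * T
    if spec.noise_sd > 0:
        rr = rr + spec.noise_sd * rng.standard_normal(n)
    rr = np.maximum(rr, 0.0)
    return ERFCurve(
        city_id=spec.city_id, smt=spec.smt_true, ot=ot, temp=ot + T, rr=rr
    )


def gen_city_curves(
    smts: "dict[str, float] | None" = None,
    truth: GenERFParams = PRESETS["variant_a"],
    noise_sd: float = 0.0,
    t_range: float = 10.0,
    seed: int = 0,
) -> list[ERFCurve]:
    """Curves for a set of cities (default: the ten benchmark SMTs)."""
    smts = smts if smts is not None else CITY_SMT
    rng = np.random.default_rng(seed)
    curves = []
    for name, smt in smts.items():
        curves.append(
            gen_city_erf(
                SyntheticCitySpec(
                    smt_true=smt,
                    slope_a_true=truth.slope_a,
                    xint_a_true=truth.xint_a,
                    slope_b_true=truth.slope_b,
                    xint_b_true=truth.xint_b,
                    noise_sd=noise_sd,
                    t_range=t_range,
                    city_id=name,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
        )
    return curves


def gen_population_grid(n_lat: int, n_lon: int, total_persons: int, seed: int = 0) -> np.ndarray:
    """Nonnegative integer population per cell summing to ``total_persons``.

    Cell weights are lognormal (cities are much denser than countryside);
    integer counts are apportioned by largest remainder so the grid total
    matches the request exactly.
    """
    if total_persons <= 0:
        raise ConfigurationError("total_persons must be positive")
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=1.0, size=(n_lat, n_lon))
    shares = (w / w.sum()).ravel() * total_persons
    base = np.floor(shares).astype(np.int64)
    short = int(total_persons - base.sum())
    if short:
        order = np.argsort(-(shares - base))
        base[order[:short]] += 1
    return base.reshape(n_lat, n_lon)


def gen_monthly_weights(winter_excess: float = 0.15) -> np.ndarray:
    """Twelve monthly mortality shares summing to one.

    A cosine annual cycle peaking mid-January scales each month's day
    count; ``winter_excess`` is the fractional amplitude of the cycle
    (0 gives shares exactly proportional to month lengths).  This is a
    stylized stand-in for observed Northern-Hemisphere monthly mortality.
    """
    if not 0 <= winter_excess < 1:
        raise ConfigurationError("winter_excess must lie in [0, 1)")
    mid = MONTH_STARTS + (MONTH_LENGTHS - 1) / 2.0
    shape = 1.0 + winter_excess * np.cos(2.0 * np.pi * (mid - 15.0) / DAYS_PER_YEAR)
    w = MONTH_LENGTHS * shape
    return w / w.sum()


def gen_state_mask(n_lat: int, n_lon: int, n_states: int) -> np.ndarray:
    """Integer state id per cell: contiguous latitude bands, 0..n_states-1."""
    if not 1 <= n_states <= n_lat:
        raise ConfigurationError("need 1 <= n_states <= n_lat")
    rows = (np.arange(n_lat) * n_states) // n_lat
    return np.broadcast_to(rows[:, None], (n_lat, n_lon)).copy()


def gen_city_boxes(
    n_lat: int, n_lon: int, city_ids: Sequence[str], seed: int = 0
) -> dict[str, list[tuple[int, int]]]:
    """Assign each city a distinct single-cell grid box."""
    n = len(city_ids)
    if n > n_lat * n_lon:
        raise ConfigurationError("more cities than grid cells")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_lat * n_lon, size=n, replace=False)
    return {
        cid: [(int(f // n_lon), int(f % n_lon))]
        for cid, f in zip(city_ids, flat)
    }
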