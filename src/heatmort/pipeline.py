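"""End-to-end orchestration: config, stages, artifacts, manifest.

A run is described by a :class:`RunConfig` (YAML on disk).  The pipeline
generates synthetic inputs from the config's seeds, derives the
generalized ERF (by fitting synthetic city curves, or from a shipped
preset), computes reference- and future-period exposure fields, projects
heat-attributable deaths under the configured adaptation scenarios, and
writes tidy CSV tables plus a JSON summary and a reproducibility
manifest.  Everything is deterministic given the config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .adaptation import Adaptation, adaptation_attenuation, run_adaptation
from .erf import (
    PRESETS,
    GenERFParams,
    RunCounters,
    Variant,
    fit_city_polynomial,
    regress_coefficients,
)
from .errors import ConfigurationError
from .exposure import derive_exposure
from .mortality import BaselineMortality, aggregate_regions, project_scenario
from .synth import (
    CITY_SMT,
    default_climate_spec,
    gen_city_boxes,
    gen_city_curves,
    gen_monthly_weights,
    gen_population_grid,
    gen_state_mask,
    gen_temperature_grid,
)
from .uncertainty import UncertaintySpec, confidence_interval, combine_quadrature
from . import io

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end run."""

    n_lat: int = 10
    n_lon: int = 10
    years_ref: tuple[int, int] = (2010, 2019)
    years_future: tuple[int, int] = (2090, 2099)
    scenario_label: str = "synthetic-warming"
    # climate generator
    seasonal_amplitude: float = 9.0
    ar1_coef: float = 0.7
    daily_sd: float = 3.0
    trend_per_decade: float = 0.5
    mean_north: float = 12.0
    mean_south: float = 19.0
    # exposure-response
    erf_variant: str = "A"
    erf_source: str = "fit"  # "fit" or a preset name, e.g. "variant_a"
    erf_noise_sd: float = 0.0
    erf_t_range: float = 10.0
    percentile: float = 84.0
    af_convention: str = "rr_minus_1"
    # population and mortality
    population_total: int = 320_000_000
    pop_scale_ref: float = 1.0
    pop_scale_future: float = 1.4
    annual_mortality_rate: float = 0.0083
    winter_excess: float = 0.15
    # scenarios and uncertainty
    adaptation: tuple[str, ...] = (
        "none", "smt", "lagged_ot", "both_lagged", "both_nonlagged"
    )
    lag_fraction: float = 0.5
    uncertainty_components: dict = field(
        default_factory=lambda: {"generalization": 0.14, "erf_and_temperature": 0.35}
    )
    ci_rounding: float = 1000.0
    n_states: int = 5
    seed: int = 0

    def validate(self) -> None:
        for name in ("years_ref", "years_future"):
            first, last = getattr(self, name)
            if last < first:
                raise ConfigurationError(f"{name}: decade window reversed")
        r0, r1 = self.years_ref
        f0, f1 = self.years_future
        if (r0, r1) != (f0, f1) and not (r1 < f0 or f1 < r0):
            raise ConfigurationError("decade windows overlap partially")
        Variant.parse(self.erf_variant)
        for s in self.adaptation:
            Adaptation.parse(s)
        if self.erf_source != "fit" and self.erf_source not in PRESETS:
            raise ConfigurationError(f"unknown erf_source {self.erf_source!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("years_ref", "years_future", "adaptation"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["years_ref"] = list(self.years_ref)
        d["years_future"] = list(self.years_future)
        d["adaptation"] = list(self.adaptation)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _years(window: tuple[int, int]) -> list[int]:
    return list(range(int(window[0]), int(window[1]) + 1))


def simulate_inputs(config: RunConfig) -> dict:
    """Generate every input the projection needs, keyed by name."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31 - 1))
             for k in ("climate", "pop", "curves", "boxes")}

    def climate_spec(years):
        spec = default_climate_spec(
            config.n_lat, config.n_lon, years,
            seed=seeds["climate"],
            trend=config.trend_per_decade,
            mean_north=config.mean_north,
            mean_south=config.mean_south,
            ref_year=config.years_ref[0],
        )
        spec.seasonal_amplitude = config.seasonal_amplitude
        spec.ar1_coef = config.ar1_coef
        spec.daily_sd = config.daily_sd
        return spec

    temps_ref = gen_temperature_grid(climate_spec(_years(config.years_ref)))
    if tuple(config.years_future) == tuple(config.years_ref):
        temps_future = temps_ref
    else:
        # distinct seed so future weather is a fresh draw on the trend
        spec = climate_spec(_years(config.years_future))
        spec.seed = seeds["climate"] + 1
        temps_future = gen_temperature_grid(spec)

    curves = gen_city_curves(
        CITY_SMT,
        truth=PRESETS["variant_a"],
        noise_sd=config.erf_noise_sd,
        t_range=config.erf_t_range,
        seed=seeds["curves"],
    )
    return {
        "temps_ref": temps_ref,
        "temps_future": temps_future,
        "population": gen_population_grid(
            config.n_lat, config.n_lon, config.population_total, seed=seeds["pop"]
        ),
        "weights": gen_monthly_weights(config.winter_excess),
        "state_mask": gen_state_mask(config.n_lat, config.n_lon, config.n_states),
        "city_boxes": gen_city_boxes(
            config.n_lat, config.n_lon, list(CITY_SMT), seed=seeds["boxes"]
        ),
        "curves": curves,
    }


def derive_params(curves, variant) -> GenERFParams:
    """Fit each city quadratic and regress coefficients on SMT."""
    variant = Variant.parse(variant)
    points = [(c.smt, fit_city_polynomial(c, variant)) for c in curves]
    return regress_coefficients(points)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages and write artifacts under ``outdir``.

    Returns the JSON-serializable run summary.
    """
    t0 = time.perf_counter()
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = simulate_inputs(config)
    pop = inputs["population"]
    bm = BaselineMortality(config.annual_mortality_rate, inputs["weights"])

    if config.erf_source == "fit":
        params = derive_params(inputs["curves"], config.erf_variant)
    else:
        params = PRESETS[config.erf_source]
    io.write_params(params, outdir / "gen_erf_params.json")

    exp_ref = derive_exposure(
        inputs["temps_ref"], config.years_ref,
        scenario_label=config.scenario_label, percentile=config.percentile,
    )
    exp_future = derive_exposure(
        inputs["temps_future"], config.years_future,
        scenario_label=config.scenario_label, percentile=config.percentile,
    )
    io.write_field(exp_ref.ot, outdir / "ot_ref.nc", "ot")
    io.write_field(exp_ref.smt, outdir / "smt_ref.nc", "smt")
    io.write_field(exp_future.ot, outdir / "ot_future.nc", "ot")
    io.write_field(exp_future.smt, outdir / "smt_future.nc", "smt")

    counters = RunCounters()
    baseline = project_scenario(
        inputs["temps_ref"], pop, bm, exp_ref, params,
        pop_scale=config.pop_scale_ref, af_convention=config.af_convention,
        counters=counters, scenario=config.scenario_label, adaptation="baseline",
    )
    baseline = aggregate_regions(
        baseline, pop, inputs["state_mask"], inputs["city_boxes"]
    )
    baseline.per_capita_by_state.rename_axis("state").to_csv(
        outdir / "per_capita_by_state_baseline.csv"
    )
    baseline.city_box_totals.rename_axis("city").to_csv(
        outdir / "city_box_totals_baseline.csv"
    )

    uspec = UncertaintySpec(dict(config.uncertainty_components), config.ci_rounding)
    combined = uspec.combined

    projections = {}
    increase_none = None
    for name in config.adaptation:
        scen = Adaptation.parse(name)
        result = run_adaptation(
            inputs["temps_future"], pop, bm, exp_ref, exp_future, params,
            scenario=scen, lag_fraction=config.lag_fraction,
            pop_scale=config.pop_scale_future,
            af_convention=config.af_convention,
            scenario_label=config.scenario_label,
        )
        counters.merge(result.counters)
        increase = result.national_annual_mean - baseline.national_annual_mean
        entry = {
            "national_annual_mean": result.national_annual_mean,
            "increase_over_baseline": increase,
            "increase_ci": list(confidence_interval(increase, combined,
                                                    config.ci_rounding))
            if increase > 0 else None,
        }
        if scen is Adaptation.NONE:
            increase_none = increase
        entry["attenuation_pct"] = (
            adaptation_attenuation(increase_none, increase)
            if (increase_none is not None and increase_none > 0
                and scen is not Adaptation.NONE)
            else None
        )
        projections[scen.value] = entry
        log.info("scenario %s: %.1f deaths/yr (increase %.1f)",
                 scen.value, result.national_annual_mean, increase)

    summary = {
        "scenario": config.scenario_label,
        "variant": Variant.parse(config.erf_variant).value,
        "params": params.as_dict(),
        "baseline": {
            "decade": list(config.years_ref),
            "national_annual_mean": baseline.national_annual_mean,
            "ci": list(uspec.interval(baseline.national_annual_mean)),
        },
        "future_decade": list(config.years_future),
        "projections": projections,
        "uncertainty": {
            "components": dict(config.uncertainty_components),
            "combined": combined,
        },
        "counters": counters.as_dict(),
    }
    io.write_json(summary, outdir / "summary.json")
    manifest = {
        "package": "heatmort",
        "version": __version__,
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "counters": counters.as_dict(),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    io.write_json(manifest, outdir / "manifest.json")
    return summary
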