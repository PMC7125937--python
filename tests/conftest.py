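import numpy as np
import pytest

import heatmort as hm


@pytest.fixture(scope="session")
def ten_city_curves():
    """Noise-free curves for the ten benchmark cities, generated from the
    primary published generalized parameters."""
    return hm.gen_city_curves(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def published_params():
    return hm.PRESETS["variant_a"]


@pytest.fixture(scope="session")
def baseline_mortality():
    return hm.BaselineMortality(0.0083, hm.gen_monthly_weights(0.15))


@pytest.fixture(scope="session")
def warming_fixture():
    """Small grid with a uniform +4 degC warming between a reference and a
    future decade (trend 0.5 degC/decade over 80 years), plus population."""
    kwargs = dict(seed=11, trend=0.5, ref_year=2010)
    spec_ref = hm.default_climate_spec(6, 6, range(2010, 2015), **kwargs)
    spec_fut = hm.default_climate_spec(6, 6, range(2090, 2095), **kwargs)
    spec_fut.seed = 12
    temps_ref = hm.gen_temperature_grid(spec_ref)
    temps_fut = hm.gen_temperature_grid(spec_fut)
    pop = hm.gen_population_grid(6, 6, 1_000_000, seed=3)
    exp_ref = hm.derive_exposure(temps_ref, (2010, 2014), "ref")
    exp_fut = hm.derive_exposure(temps_fut, (2090, 2094), "future")
    return {
        "temps_ref": temps_ref,
        "temps_future": temps_fut,
        "pop": pop,
        "exp_ref": exp_ref,
        "exp_future": exp_fut,
    }
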