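"""File formats: NetCDF grids, CSV tables, JSON summaries.

Gridded fields travel as classic NetCDF (written through xarray's scipy
backend, so integer coordinates are stored as 32-bit).  Tabular data are
plain CSV; run summaries and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .erf import ERFCurve, GenERFParams, Variant

__all__ = [
    "write_grid", "read_grid",
    "write_field", "read_field",
    "write_curves", "read_curves",
    "write_population", "read_population",
    "write_weights", "read_weights",
    "write_mask", "read_mask",
    "write_params", "read_params",
    "write_json", "read_json",
]


def _int32_coords(ds: xr.Dataset) -> xr.Dataset:
    for name in list(ds.coords):
        if ds[name].dtype.kind in "iu":
            ds[name] = ds[name].astype("int32")
    return ds


def write_grid(da: xr.DataArray, path) -> None:
    """Daily temperature (time, lat, lon) to classic NetCDF."""
    ds = _int32_coords(da.astype("float64").to_dataset(name=da.name or "temperature"))
    ds.to_netcdf(path, engine="scipy")


def read_grid(path, var: "str | None" = None) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        name = var or next(iter(ds.data_vars))
        return ds[name].load()


def write_field(arr: np.ndarray, path, name: str = "field") -> None:
    """2-D (lat, lon) field to classic NetCDF."""
    da = xr.DataArray(np.asarray(arr, dtype=float), dims=("lat", "lon"), name=name)
    da.to_dataset(name=name).to_netcdf(path, engine="scipy")


def read_field(path, name: "str | None" = None) -> np.ndarray:
    with xr.open_dataset(path, engine="scipy") as ds:
        key = name or next(iter(ds.data_vars))
        return ds[key].load().values


def write_curves(curves: Sequence[ERFCurve], curves_path, cities_path) -> None:
    """Curves as (city_id, temp_c, rr) rows plus a per-city sidecar
    table carrying each city's SMT and OT."""
    pd.concat([c.to_frame() for c in curves]).to_csv(curves_path, index=False)
    pd.DataFrame(
        {
            "city_id": [c.city_id for c in curves],
            "smt_c": [c.smt for c in curves],
            "ot_c": [c.ot for c in curves],
        }
    ).to_csv(cities_path, index=False)


def read_curves(curves_path, cities_path) -> list[ERFCurve]:
    samples = pd.read_csv(curves_path)
    cities = pd.read_csv(cities_path).set_index("city_id")
    out = []
    for city_id, grp in samples.groupby("city_id", sort=False):
        meta = cities.loc[city_id]
        out.append(
            ERFCurve(
                city_id=str(city_id),
                smt=float(meta["smt_c"]),
                ot=float(meta["ot_c"]),
                temp=grp["temp_c"].to_numpy(),
                rr=grp["rr"].to_numpy(),
            )
        )
    return out


def write_population(pop: np.ndarray, path) -> None:
    n_lat, n_lon = pop.shape
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    pd.DataFrame(
        {"lat_idx": ii.ravel(), "lon_idx": jj.ravel(), "persons": pop.ravel()}
    ).to_csv(path, index=False)


def read_population(path) -> np.ndarray:
    df = pd.read_csv(path)
    n_lat = int(df["lat_idx"].max()) + 1
    n_lon = int(df["lon_idx"].max()) + 1
    out = np.zeros((n_lat, n_lon))
    out[df["lat_idx"], df["lon_idx"]] = df["persons"]
    return out


def write_weights(shares: np.ndarray, path) -> None:
    pd.DataFrame({"month": np.arange(1, 13), "share": shares}).to_csv(path, index=False)


def read_weights(path) -> np.ndarray:
    return pd.read_csv(path).sort_values("month")["share"].to_numpy()


def write_mask(mask: np.ndarray, path, column: str = "state") -> None:
    n_lat, n_lon = mask.shape
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    pd.DataFrame(
        {"lat_idx": ii.ravel(), "lon_idx": jj.ravel(), column: mask.ravel()}
    ).to_csv(path, index=False)


def read_mask(path, column: str = "state") -> np.ndarray:
    df = pd.read_csv(path)
    n_lat = int(df["lat_idx"].max()) + 1
    n_lon = int(df["lon_idx"].max()) + 1
    out = np.full((n_lat, n_lon), -1, dtype=int)
    out[df["lat_idx"], df["lon_idx"]] = df[column]
    return out


def write_params(params: GenERFParams, path) -> None:
    write_json(params.as_dict(), path)


def read_params(path) -> GenERFParams:
    d = read_json(path)
    return GenERFParams(
        slope_a=d["slope_a"],
        xint_a=d["xint_a"],
        slope_b=d["slope_b"],
        xint_b=d["xint_b"],
        variant=Variant.parse(d.get("variant", "A")),
        corr_a=d.get("corr_a", float("nan")),
        corr_b=d.get("corr_b", float("nan")),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
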