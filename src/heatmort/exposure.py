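"""Per-cell exposure fields: optimal temperature and summer mean.

The generalized risk function needs two local climate covariates at every
grid cell: the optimal temperature (OT), taken as the 84th percentile of
the full daily temperature distribution over a reference period, and the
summer mean temperature (SMT), the mean over June-August days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from ._calendar import DAYS_PER_YEAR, is_jja
from .errors import DataQualityError

__all__ = ["ExposureFields", "compute_ot", "compute_smt", "derive_exposure"]

#: default percentile of the daily distribution taken as OT
OT_PERCENTILE = 84.0


@dataclass
class ExposureFields:
    """OT and SMT fields (degC) for one period and scenario."""

    ot: np.ndarray
    smt: np.ndarray
    period: tuple[int, int]
    scenario_label: str = ""

    def validate(self, populated: "np.ndarray | None" = None) -> None:
        """Check finiteness (on populated cells if a mask is given) and
        that SMT lies within loose physical bounds."""
        ot = np.asarray(self.ot, dtype=float)
        smt = np.asarray(self.smt, dtype=float)
        if ot.shape != smt.shape:
            raise ValueError("ot and smt must share a grid")
        sel = populated if populated is not None else np.ones(ot.shape, bool)
        if not np.all(np.isfinite(ot[sel])) or not np.all(np.isfinite(smt[sel])):
            raise ValueError("non-finite exposure values on populated cells")
        if np.any(smt[sel] < -90) or np.any(smt[sel] > 60):
            raise ValueError("SMT outside [-90, 60] degC sanity bounds")


def _values_and_doy(temps, doy):
    if isinstance(temps, xr.DataArray):
        values = temps.values
        if doy is None and "doy" in temps.coords:
            doy = temps.coords["doy"].values
    else:
        values = np.asarray(temps, dtype=float)
    return values, doy


def compute_ot(temps, percentile: float = OT_PERCENTILE,
               max_missing_frac: float = 0.05) -> np.ndarray:
    """Per-cell percentile of daily temperature (time axis first).

    Uses linear interpolation between closest order statistics.  Cells
    whose missing-value fraction exceeds ``max_missing_frac`` raise a
    :class:`DataQualityError` listing the offending cells.
    """
    values, _ = _values_and_doy(temps, None)
    if values.shape[0] < DAYS_PER_YEAR:
        raise ValueError("need at least one full year (365 daily values) per cell")
    missing = np.isnan(values).mean(axis=0)
    bad = np.argwhere(missing > max_missing_frac)
    if bad.size:
        cells = [tuple(int(i) for i in idx) for idx in bad]
        raise DataQualityError(
            f"{len(cells)} cell(s) exceed the {max_missing_frac:.0%} "
            f"missing-data threshold: {cells[:10]}",
            cells=cells,
        )
    return np.nanpercentile(values, percentile, axis=0, method="linear")


def compute_smt(temps, doy=None) -> np.ndarray:
    """Per-cell mean over all June-August days (time axis first).

    ``doy`` (1-based day-of-year, no-leap) may be omitted when ``temps``
    is a DataArray carrying a ``doy`` coordinate.
    """
    values, doy = _values_and_doy(temps, doy)
    if doy is None:
        raise ValueError("day-of-year information required to select JJA days")
    doy = np.asarray(doy)
    if doy.shape[0] != values.shape[0]:
        raise ValueError("doy must parallel the time axis")
    sel = is_jja(doy)
    if not sel.any():
        raise ValueError("period contains no June-August days")
    return np.nanmean(values[sel], axis=0)


def derive_exposure(temps: xr.DataArray, period: tuple[int, int],
                    scenario_label: str = "",
                    percentile: float = OT_PERCENTILE) -> ExposureFields:
    """OT and SMT fields for the years ``period[0]..period[1]`` of a
    daily temperature DataArray (coords ``year`` and ``doy`` required)."""
    first, last = int(period[0]), int(period[1])
    years = temps.coords["year"].values
    sel = (years >= first) & (years <= last)
    if not sel.any():
        raise ValueError(f"no data in period {first}-{last}")
    sub = temps.isel(time=np.flatnonzero(sel))
    fields = ExposureFields(
        ot=compute_ot(sub, percentile=percentile),
        smt=compute_smt(sub),
        period=(first, last),
        scenario_label=scenario_label,
    )
    fields.validate()
    return fields
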