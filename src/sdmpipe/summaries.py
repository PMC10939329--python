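"""Geospatial summaries: quality-weighted habitat area, change maps,
refugia maps, 5 km -> 1 km resampling, and tabular consolidation.

Quality-weighted habitat area (qwHA) treats each 1-km cell's suitability
p ∈ [0, 1] as an area weight: a cell at p = 1 contributes 1 km², at p = 0.3
it contributes 0.3 km², so

    qwHA = Σ_cells p   [km² at 1-km resolution].

Maps on coarser grids are first subdivided value-preservingly (a 5-km cell
becomes 25 identical 1-km cells).  Change maps difference future and
historical percent-scale suitability (positive = improvement by default);
refugia maps are the scaled product p_hist x p_future / 100, accentuating
cells suitable in both periods.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .grids import Grid, SuitabilityMap
from .projection import ENSEMBLE_STATS, SuitabilityCube


@dataclass
class ChangeMap:
    """Per-cell suitability change in percent points, in [-100, 100]."""

    values: np.ndarray
    grid: Grid
    nodata_mask: np.ndarray
    key: object = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        valid = self.values[~self.nodata_mask]
        if valid.size and (np.abs(valid) > 100.0 + 1e-9).any():
            raise ValueError("change values must lie in [-100, 100]")


def resample_to_1km(map_: SuitabilityMap) -> SuitabilityMap:
    """Subdivide each cell into 1-km cells carrying the same value.

    Value-preserving nearest resampling: a 5-km cell becomes a 5x5 block of
    identical 1-km cells, so qwHA is conserved exactly (x cell-count).  The
    cell size must be an integer number of km.
    """
    f = map_.grid.cell_size_km
    factor = int(round(f))
    if abs(f - factor) > 1e-9 or factor < 1:
        raise ValueError(f"cell size {f} km does not subdivide into whole 1-km cells")
    if factor == 1:
        return map_
    block = np.ones((factor, factor))
    values = np.kron(map_.values, block)
    mask = np.kron(map_.nodata_mask.astype(int), block.astype(int)).astype(bool)
    grid = Grid(
        rows=map_.grid.rows * factor,
        cols=map_.grid.cols * factor,
        cell_size_km=1.0,
        origin=map_.grid.origin,
    )
    return SuitabilityMap(
        values=values,
        grid=grid,
        nodata_mask=mask,
        scale=map_.scale,
        key=map_.key,
        clamp_fraction=map_.clamp_fraction,
    )


def qwha(map_: SuitabilityMap) -> float:
    """Quality-weighted habitat area in km² of a unit-scale 1-km map."""
    if map_.scale != "unit":
        raise ValueError("qwha requires a unit-scale (0-1) map; convert percent maps first")
    if abs(map_.grid.cell_size_km - 1.0) > 1e-9:
        raise ValueError("qwha requires a 1-km grid; resample first")
    return float(map_.valid_values.sum())


def qwha_km2(map_: SuitabilityMap) -> float:
    """qwHA of any suitability map: convert to unit scale, resample to 1 km, sum."""
    m = map_.to_unit() if map_.scale == "percent" else map_
    return qwha(resample_to_1km(m))


def _check_pair(a, b) -> None:
    if a.grid != b.grid:
        raise ValueError("maps must share a grid")
    if a.scale != b.scale:
        raise ValueError("maps must share a scale")


def change_map(
    historical: SuitabilityMap,
    future: SuitabilityMap,
    sign_convention: str = "as_stated",
) -> ChangeMap:
    """Suitability change between the historical and a future map.

    ``as_stated`` (default): future − historical, so positive values mark
    areas that improve.  ``as_printed``: historical − future (the opposite
    sign convention).
    """
    _check_pair(historical, future)
    if historical.scale != "percent":
        raise ValueError("change maps are computed on percent-scale maps")
    if sign_convention == "as_stated":
        values = future.values - historical.values
    elif sign_convention == "as_printed":
        values = historical.values - future.values
    else:
        raise ValueError("sign_convention must be 'as_stated' or 'as_printed'")
    mask = historical.nodata_mask | future.nodata_mask
    return ChangeMap(values=np.where(mask, 0.0, values), grid=historical.grid, nodata_mask=mask, key=future.key)


def refugia_map(historical: SuitabilityMap, future: SuitabilityMap) -> SuitabilityMap:
    """Climate-refugia map: p_hist x p_future / 100, percent scale.

    High values mark cells suitable both historically and in the future;
    r <= min(p_hist, p_future) everywhere.
    """
    _check_pair(historical, future)
    if historical.scale != "percent":
        raise ValueError("refugia maps are computed on percent-scale maps")
    mask = historical.nodata_mask | future.nodata_mask
    values = historical.values * future.values / 100.0
    return SuitabilityMap(
        values=np.where(mask, 0.0, values),
        grid=historical.grid,
        nodata_mask=mask,
        scale="percent",
        key=future.key,
    )


def summarize_species(cube: SuitabilityCube, stats: tuple = ENSEMBLE_STATS) -> pd.DataFrame:
    """Per-species qwHA table across scenarios, periods and ensemble stats.

    One historical row plus one row per (scenario, period, stat), each with
    the qwHA in km² and the absolute (km²) and proportional change relative
    to the historical area.  A zero historical area leaves the proportional
    change as NaN (undefined, not infinite).
    """
    hist_area = qwha_km2(cube.historical_map)
    rows = [
        {
            "species": cube.species_id,
            "scenario": "historical",
            "period": None,
            "stat": "mean",
            "qwha_km2": hist_area,
            "delta_abs_km2": 0.0,
            "delta_prop": 0.0 if hist_area > 0 else float("nan"),
        }
    ]
    for key in sorted(k for k in cube.maps if k[1] in stats):
        scenario, stat, period = key
        area = qwha_km2(cube.maps[key])
        delta = area - hist_area
        rows.append(
            {
                "species": cube.species_id,
                "scenario": scenario,
                "period": period,
                "stat": stat,
                "qwha_km2": area,
                "delta_abs_km2": delta,
                "delta_prop": delta / hist_area if hist_area > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def consolidate(
    per_species: list, bin_width: float = 0.10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate species summary tables and bin proportional changes.

    Returns (table, histogram).  The histogram counts species-rows of the
    ensemble-mean maps per proportional-change bin (default width 10
    percentage points), per scenario and period — the ingredients of a
    change-in-habitat-area histogram.
    """
    if not per_species:
        raise ValueError("no species tables to consolidate")
    table = pd.concat(per_species, ignore_index=True)
    fut = table[(table["scenario"] != "historical") & (table["stat"] == "mean")].copy()
    fut = fut[np.isfinite(fut["delta_prop"])]
    if len(fut):
        lo = np.floor(fut["delta_prop"].min() / bin_width) * bin_width
        hi = np.ceil(fut["delta_prop"].max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_width])
        fut["bin"] = pd.cut(fut["delta_prop"], edges, include_lowest=True)
        hist = (
            fut.groupby(["scenario", "period", "bin"], observed=True)
            .size()
            .rename("n_species")
            .reset_index()
        )
        hist["bin_left"] = hist["bin"].map(lambda b: float(b.left))
        hist["bin_right"] = hist["bin"].map(lambda b: float(b.right))
        hist = hist.drop(columns=["bin"])
    else:
        hist = pd.DataFrame(columns=["scenario", "period", "n_species", "bin_left", "bin_right"])
    return table, hist
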