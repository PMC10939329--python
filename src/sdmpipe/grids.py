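"""Raster containers shared across the pipeline.

A :class:`Grid` describes a regular raster lattice (rows, columns, square
cell size in km, origin of the upper-left corner).  An :class:`EnvStack`
holds named, aligned environmental layers on one grid with a common nodata
mask; a :class:`SuitabilityMap` holds one habitat-suitability surface on
either the unit (0-1) or percent (0-100) scale.

Rasters are written as single-band TIFF files (LZW compression) with a JSON
sidecar carrying the georeferencing (origin, cell size) and nodata metadata,
so every product remains self-describing without a GIS dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import tifffile

NODATA = -9999.0

HistoricalKey = "historical"


@dataclass(frozen=True)
class Grid:
    """Regular raster lattice with square cells.

    ``origin`` is the (x, y) map coordinate of the upper-left corner, in km.
    Row index increases southwards (decreasing y), column index eastwards.
    """

    rows: int
    cols: int
    cell_size_km: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def cell_center(self, row: np.ndarray, col: np.ndarray):
        """Map coordinates (x, y) of cell centres."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size_km
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size_km
        return x, y

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "cell_size_km": self.cell_size_km,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Grid":
        return cls(
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            cell_size_km=float(d["cell_size_km"]),
            origin=tuple(d["origin"]),
        )


def _check_layer(values: np.ndarray, grid: Grid, name: str) -> None:
    if values.shape != (grid.rows, grid.cols):
        raise ValueError(
            f"layer {name!r} has shape {values.shape}, expected {(grid.rows, grid.cols)}"
        )


@dataclass
class EnvStack:
    """Named, aligned environmental layers on one grid.

    ``values`` has shape (n_layers, rows, cols); ``nodata_mask`` is True where
    cells carry no data (shared by every layer).  ``categorical`` names the
    layers holding integer class codes (e.g. a biogeographic-region layer).
    ``key`` is ``"historical"`` or a ``(scenario, gcm, period)`` triple for a
    future stack.
    """

    layer_names: list[str]
    grid: Grid
    values: np.ndarray
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    categorical: frozenset = frozenset()
    key: object = HistoricalKey

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.layer_names):
            raise ValueError("values must be (n_layers, rows, cols) matching layer_names")
        if self.values.shape[1:] != (self.grid.rows, self.grid.cols):
            raise ValueError("layer shape does not match grid")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("duplicate layer names")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros((self.grid.rows, self.grid.cols), dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != (self.grid.rows, self.grid.cols):
            raise ValueError("nodata_mask shape does not match grid")
        if self.nodata_mask.all():
            raise ValueError("stack has no valid cells (all nodata)")
        self.categorical = frozenset(self.categorical)
        for name in self.categorical:
            if name not in self.layer_names:
                raise ValueError(f"categorical layer {name!r} not in layer_names")

    @property
    def n_layers(self) -> int:
        return len(self.layer_names)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def valid_cells(self) -> np.ndarray:
        """Flat indices (row * cols + col) of non-nodata cells."""
        return np.flatnonzero(self.valid_mask.ravel())

    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None
        return self.values[i]

    def values_at_cells(self, cells: np.ndarray, layers: Iterable[str] | None = None) -> np.ndarray:
        """Environmental values at flat cell indices; shape (n_cells, n_layers)."""
        names = list(layers) if layers is not None else self.layer_names
        flat = self.values.reshape(self.n_layers, -1)
        idx = [self.layer_names.index(n) for n in names]
        return flat[idx][:, np.asarray(cells, dtype=int)].T

    def with_values(self, values: np.ndarray, key: object = None) -> "EnvStack":
        return EnvStack(
            layer_names=list(self.layer_names),
            grid=self.grid,
            values=np.asarray(values, dtype=float).copy(),
            nodata_mask=self.nodata_mask.copy(),
            categorical=self.categorical,
            key=self.key if key is None else key,
        )

    # -- persistence ------------------------------------------------------

    def write(self, directory: str | Path) -> Path:
        """Write one TIFF per layer plus a JSON sidecar manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, name in enumerate(self.layer_names):
            write_raster(directory / f"{name}.tif", self.values[i], self.nodata_mask)
        sidecar = {
            "grid": self.grid.to_dict(),
            "layers": self.layer_names,
            "categorical": sorted(self.categorical),
            "key": list(self.key) if isinstance(self.key, tuple) else self.key,
            "nodata": NODATA,
        }
        path = directory / "stack.json"
        path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return path

    @classmethod
    def read(cls, directory: str | Path) -> "EnvStack":
        directory = Path(directory)
        sidecar = json.loads((directory / "stack.json").read_text())
        grid = Grid.from_dict(sidecar["grid"])
        names = sidecar["layers"]
        values = np.empty((len(names), grid.rows, grid.cols))
        mask = None
        for i, name in enumerate(names):
            values[i], mask = read_raster(directory / f"{name}.tif")
        key = sidecar["key"]
        if isinstance(key, list):
            key = tuple(key)
        return cls(
            layer_names=names,
            grid=grid,
            values=values,
            nodata_mask=mask,
            categorical=frozenset(sidecar.get("categorical", ())),
            key=key,
        )


@dataclass
class SuitabilityMap:
    """One habitat-suitability surface.

    ``scale`` is ``"unit"`` (values in [0, 1]) or ``"percent"`` (values in
    [0, 100]); stored data products use the percent scale.  ``clamp_fraction``
    records the fraction of valid cells where at least one predictor was
    clamped to its training range during projection.
    """

    values: np.ndarray
    grid: Grid
    nodata_mask: np.ndarray = None  # type: ignore[assignment]
    scale: str = "unit"
    key: object = None
    clamp_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.rows, self.grid.cols):
            raise ValueError("values shape does not match grid")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros_like(self.values, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.scale not in ("unit", "percent", "density"):
            raise ValueError("scale must be 'unit', 'percent' or 'density'")
        if self.scale != "density":  # Gibbs densities are unbounded above
            valid = self.values[~self.nodata_mask]
            hi = 1.0 if self.scale == "unit" else 100.0
            if valid.size and (valid.min() < -1e-9 or valid.max() > hi + 1e-9):
                raise ValueError(f"values outside [0, {hi}] for scale={self.scale!r}")

    def to_percent(self) -> "SuitabilityMap":
        if self.scale == "percent":
            return self
        if self.scale != "unit":
            raise ValueError("only unit-scale maps convert to percent")
        return replace(self, values=self.values * 100.0, scale="percent")

    def to_unit(self) -> "SuitabilityMap":
        if self.scale == "unit":
            return self
        if self.scale != "percent":
            raise ValueError("only percent-scale maps convert to unit")
        return replace(self, values=self.values / 100.0, scale="unit")

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        write_raster(path, self.values, self.nodata_mask)
        sidecar = {
            "grid": self.grid.to_dict(),
            "scale": self.scale,
            "key": list(self.key) if isinstance(self.key, tuple) else self.key,
            "clamp_fraction": self.clamp_fraction,
            "nodata": NODATA,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "SuitabilityMap":
        path = Path(path)
        values, mask = read_raster(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        key = sidecar.get("key")
        if isinstance(key, list):
            key = tuple(key)
        return cls(
            values=values,
            grid=Grid.from_dict(sidecar["grid"]),
            nodata_mask=mask,
            scale=sidecar["scale"],
            key=key,
            clamp_fraction=float(sidecar.get("clamp_fraction", 0.0)),
        )


def write_raster(path: str | Path, values: np.ndarray, nodata_mask: np.ndarray) -> None:
    data = np.asarray(values, dtype=np.float32).copy()
    data[np.asarray(nodata_mask, dtype=bool)] = NODATA
    tifffile.imwrite(str(path), data, compression="lzw")


def read_raster(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = tifffile.imread(str(path)).astype(float)
    mask = data == NODATA
    data[mask] = 0.0
    return data, mask
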