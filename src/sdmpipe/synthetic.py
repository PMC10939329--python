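"""Synthetic landscapes, climate futures, virtual species and occurrences.

This module generates everything the modelling pipeline consumes, with the
statistical structure of the real inputs: a candidate-predictor stack of 19
bioclimatic-like layers, 15 soil/landscape-like layers and one categorical
region layer (35 candidates in total); future stacks on a scenario x GCM x
period grid with scenario-graded climate drift and per-GCM jitter; virtual
species with known niches (the ground truth against which niche recovery is
judged); biased presence sampling; and pooled taxon-group occurrence sets
from which target-group backgrounds are subsampled.

Continuous layers are smoothed Gaussian white noise (kernel width =
``spatial_correlation_length`` cells) plus a deterministic north-south
gradient, so nearby cells are correlated the way real climate surfaces are.
Temperature-like layers drift additively under warming scenarios;
precipitation-like layers are scaled multiplicatively (drying), soil and
region layers are time-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grids import EnvStack, Grid, HistoricalKey

DEFAULT_SCENARIOS = ("RCP2.6-SSP1", "RCP4.5-SSP2", "RCP7.0-SSP3", "RCP8.5-SSP5")
# severity weight of each scenario, used to grade climate drift
DEFAULT_SEVERITIES = (0.25, 0.5, 0.75, 1.0)
DEFAULT_GCMS = (
    "BCC-CSM2-MR",
    "CNRM-CM6-1",
    "CNRM-ESM2-1",
    "CanESM5",
    "IPSL-CM6A-LR",
    "MIROC-ES2L",
    "MIROC6",
    "MRI-ESM2-0",
)
DEFAULT_PERIODS = (1990, 2030, 2050, 2070, 2090)

TAXON_GROUPS = ("mammal", "bird", "reptile", "amphibian", "vascular_plant")


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of a synthetic candidate-predictor landscape.

    Defaults give 19 bioclimatic + 15 soil + 1 categorical region layer,
    i.e. 35 candidate predictors on a 5-km grid.
    """

    grid_rows: int = 40
    grid_cols: int = 40
    cell_size_km: float = 5.0
    n_bioclim: int = 19
    n_soil: int = 15
    include_categorical: bool = True
    n_regions: int = 6
    spatial_correlation_length: float = 4.0
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 4 or self.grid_cols < 4:
            raise ValueError("grid must be at least 4x4")
        if self.n_bioclim < 1 or self.n_soil < 0:
            raise ValueError("need at least one bioclimatic layer")
        if not (0.0 <= self.nodata_fraction < 0.5):
            raise ValueError("nodata_fraction must be in [0, 0.5)")

    @property
    def n_layers(self) -> int:
        return self.n_bioclim + self.n_soil + (1 if self.include_categorical else 0)

    @property
    def layer_names(self) -> list[str]:
        names = [f"bio{i:02d}" for i in range(1, self.n_bioclim + 1)]
        names += [f"soil{i:02d}" for i in range(1, self.n_soil + 1)]
        if self.include_categorical:
            names.append("region")
        return names


def is_temperature_layer(name: str) -> bool:
    """Bioclim layers 1-11 summarise temperature; 12-19 precipitation."""
    return name.startswith("bio") and int(name[3:]) <= 11


def is_precipitation_layer(name: str) -> bool:
    return name.startswith("bio") and int(name[3:]) >= 12


def is_soil_layer(name: str) -> bool:
    return name.startswith("soil")


def _smooth_field(rng: np.random.Generator, rows: int, cols: int, corr: float) -> np.ndarray:
    """Unit-variance smooth random field (Gaussian-kernel-smoothed noise)."""
    noise = rng.standard_normal((rows, cols))
    if corr > 0:
        noise = ndimage.gaussian_filter(noise, sigma=corr, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    return noise


def make_landscape(spec: LandscapeSpec) -> EnvStack:
    """Generate the historical candidate-predictor stack.

    Temperature-like layers are centred near 20 (degrees C) with a
    north-south gradient; precipitation-like layers are positive (mm) so the
    multiplicative drying drift keeps them physical; soil layers are
    dimensionless smooth fields; the region layer codes nearest-seed
    (Voronoi) biogeographic regions.
    """
    rng = np.random.default_rng(spec.seed)
    grid = Grid(spec.grid_rows, spec.grid_cols, spec.cell_size_km)
    rows, cols = spec.grid_rows, spec.grid_cols
    lat = np.linspace(1.0, -1.0, rows)[:, None] * np.ones((1, cols))  # +1 north

    layers = []
    for i in range(1, spec.n_bioclim + 1):
        z = _smooth_field(rng, rows, cols, spec.spatial_correlation_length)
        if i <= 11:  # temperature-like: degrees C, warmer in the "north"
            layers.append(20.0 + 6.0 * lat + 3.0 * z)
        else:  # precipitation-like: mm, strictly positive
            layers.append(600.0 * np.exp(0.4 * z + 0.2 * lat))
    for _ in range(spec.n_soil):
        z = _smooth_field(rng, rows, cols, spec.spatial_correlation_length)
        layers.append(50.0 + 15.0 * z)
    if spec.include_categorical:
        rr, cc = np.mgrid[0:rows, 0:cols]
        seeds_r = rng.uniform(0, rows, spec.n_regions)
        seeds_c = rng.uniform(0, cols, spec.n_regions)
        d2 = (rr[..., None] - seeds_r) ** 2 + (cc[..., None] - seeds_c) ** 2
        layers.append(np.argmin(d2, axis=-1).astype(float))

    mask = np.zeros((rows, cols), dtype=bool)
    if spec.nodata_fraction > 0:
        # carve a contiguous "ocean" where a smooth field is lowest
        sea = _smooth_field(rng, rows, cols, max(spec.spatial_correlation_length, 2.0))
        cut = np.quantile(sea, spec.nodata_fraction)
        mask = sea <= cut

    return EnvStack(
        layer_names=spec.layer_names,
        grid=grid,
        values=np.stack(layers),
        nodata_mask=mask,
        categorical=frozenset({"region"}) if spec.include_categorical else frozenset(),
        key=HistoricalKey,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Climate-future grid: scenarios x GCMs x periods, with graded drift.

    ``temp_drift_c`` is the additive temperature shift (degrees C) reached at
    the final period under the most severe scenario; ``precip_drift_frac`` the
    corresponding proportional precipitation change (negative = drying).
    Each GCM perturbs the drift with its own smooth jitter of standard
    deviation ``gcm_jitter_sd`` (degrees C for temperature layers; the same
    number is read as a proportional sd for precipitation layers).
    """

    scenarios: tuple = DEFAULT_SCENARIOS
    severities: tuple = DEFAULT_SEVERITIES
    gcms: tuple = DEFAULT_GCMS
    periods: tuple = DEFAULT_PERIODS
    temp_drift_c: float = 4.0
    precip_drift_frac: float = -0.3
    gcm_jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.scenarios) != len(self.severities):
            raise ValueError("scenarios and severities must align")
        if len(self.periods) < 2:
            raise ValueError("need a historical period plus at least one future period")
        if sorted(self.periods) != list(self.periods):
            raise ValueError("periods must be increasing")

    @property
    def historical_period(self) -> int:
        return self.periods[0]

    @property
    def future_periods(self) -> tuple:
        return tuple(self.periods[1:])

    def severity(self, scenario: str) -> float:
        try:
            return self.severities[self.scenarios.index(scenario)]
        except ValueError:
            raise KeyError(f"unknown scenario {scenario!r}") from None

    def progress(self, period: int) -> float:
        """Fraction of the full drift realised by ``period`` (0 at historical)."""
        span = self.periods[-1] - self.periods[0]
        return (period - self.periods[0]) / span


def make_future_stacks(base: EnvStack, scen: ScenarioSpec) -> dict:
    """Project the historical stack onto every (scenario, gcm, period) key.

    Temperature-like layers get ``severity x progress x temp_drift_c`` added;
    precipitation-like layers are multiplied by
    ``1 + severity x progress x precip_drift_frac``; soil and categorical
    layers are copied untouched.  The per-GCM jitter is a fixed draw per
    (gcm, layer), so a given GCM is consistently warm or cool.
    """
    if base.key != HistoricalKey:
        raise ValueError("base stack must be historical")
    rng = np.random.default_rng(scen.seed)
    # one jitter scalar per (gcm, layer), drawn once in a fixed order
    jitter = {
        (g, name): rng.normal(0.0, scen.gcm_jitter_sd)
        for g in scen.gcms
        for name in base.layer_names
    }
    out: dict = {}
    for scenario in scen.scenarios:
        sev = scen.severity(scenario)
        for gcm in scen.gcms:
            for period in scen.future_periods:
                prog = scen.progress(period)
                vals = base.values.copy()
                for i, name in enumerate(base.layer_names):
                    j = jitter[(gcm, name)]
                    if is_temperature_layer(name):
                        vals[i] = vals[i] + sev * prog * (scen.temp_drift_c + j)
                    elif is_precipitation_layer(name):
                        factor = 1.0 + sev * prog * (scen.precip_drift_frac + j)
                        vals[i] = vals[i] * max(factor, 0.0)
                    # soil-like and categorical layers are time-invariant
                key = (scenario, gcm, period)
                out[key] = base.with_values(vals, key=key)
    return out


# ---------------------------------------------------------------------------
# virtual species


@dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped response: exp(-(v - center)^2 / (2 width^2)), peak 1."""

    center: float
    width: float

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((v - self.center) / self.width) ** 2)


@dataclass(frozen=True)
class LogisticResponse:
    """Sigmoid response: 1 / (1 + exp(-slope (v - midpoint))), 0.5 at midpoint."""

    midpoint: float
    slope: float

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.slope * (v - self.midpoint)))


@dataclass(frozen=True)
class ConstantResponse:
    """Flat response (useful for degenerate-case tests)."""

    value: float

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(v, dtype=float), self.value)


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a known suitability function over named predictors.

    ``niche`` maps predictor name -> response; per-cell responses are combined
    by product (default) or by a weighted geometric mean, either of which
    keeps the true suitability in [0, 1].
    """

    species_id: str
    group: str = "mammal"
    niche: Mapping[str, object] = field(default_factory=dict)
    combination: str = "product"
    weights: Mapping[str, float] | None = None
    prevalence_target: float | None = None

    def __post_init__(self) -> None:
        if not self.niche:
            raise ValueError("niche must name at least one predictor")
        if self.combination not in ("product", "geometric"):
            raise ValueError("combination must be 'product' or 'geometric'")
        if self.group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {self.group!r}")


def true_suitability(vs: VirtualSpecies, stack: EnvStack):
    """Evaluate the species' known suitability surface on a stack (unit scale)."""
    from .grids import SuitabilityMap

    missing = [v for v in vs.niche if v not in stack.layer_names]
    if missing:
        raise KeyError(f"niche variables missing from stack: {missing}")
    parts = {v: np.clip(resp(stack.layer(v)), 0.0, 1.0) for v, resp in vs.niche.items()}
    if vs.combination == "product":
        suit = np.prod(np.stack(list(parts.values())), axis=0)
    else:
        w = {v: (vs.weights or {}).get(v, 1.0) for v in parts}
        total = sum(w.values())
        logs = sum(w[v] * np.log(np.maximum(parts[v], 1e-300)) for v in parts)
        suit = np.exp(logs / total)
    suit = np.where(stack.nodata_mask, 0.0, suit)
    return SuitabilityMap(
        values=suit,
        grid=stack.grid,
        nodata_mask=stack.nodata_mask.copy(),
        scale="unit",
        key=(vs.species_id, "true", HistoricalKey),
    )


# ---------------------------------------------------------------------------
# occurrences and backgrounds


@dataclass
class OccurrenceSet:
    """Presence points of one species: map coordinates plus flat cell index."""

    species_id: str
    x: np.ndarray
    y: np.ndarray
    cell_index: np.ndarray
    group: str = "mammal"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cell_index = np.asarray(self.cell_index, dtype=int)
        if not (len(self.x) == len(self.y) == len(self.cell_index)):
            raise ValueError("x, y, cell_index must have equal length")
        if len(self.cell_index) < 1:
            raise ValueError("an occurrence set needs at least one point")

    @property
    def n(self) -> int:
        return len(self.cell_index)


def roadside_bias(grid: Grid, strength: float = 3.0) -> np.ndarray:
    """East-west sampling-effort gradient (highest along the west edge).

    Emulates accessibility bias: effort decays exponentially with distance
    from a north-south 'road' at column 0.
    """
    cols = np.arange(grid.cols) / max(grid.cols - 1, 1)
    return np.exp(-strength * cols)[None, :] * np.ones((grid.rows, 1))


def sample_occurrences(
    vs: VirtualSpecies,
    stack: EnvStack,
    n: int,
    bias: np.ndarray | None = None,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw ``n`` presence points with cell probability ∝ suitability x bias.

    Points may repeat cells (real occurrence records do); coordinates are
    jittered uniformly within the cell.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit = true_suitability(vs, stack).values.ravel().copy()
    suit[stack.nodata_mask.ravel()] = 0.0
    if bias is not None:
        b = np.asarray(bias, dtype=float).ravel()
        if b.shape != suit.shape:
            raise ValueError("bias surface must match the grid")
        suit = suit * b
    total = suit.sum()
    if total <= 0:
        raise ValueError("suitability x bias is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    cells = rng.choice(suit.size, size=n, replace=True, p=suit / total)
    rows, cols = np.divmod(cells, stack.grid.cols)
    cx, cy = stack.grid.cell_center(rows, cols)
    half = stack.grid.cell_size_km / 2.0
    x = cx + rng.uniform(-half, half, size=n)
    y = cy + rng.uniform(-half, half, size=n)
    return OccurrenceSet(
        species_id=vs.species_id, x=x, y=y, cell_index=cells, group=vs.group, seed=seed
    )


@dataclass
class BackgroundSet:
    """Target-group background: pooled group occurrences plus a subsample.

    The pool is the union of all occurrence records of every species in the
    taxonomic group; the working sample is a uniform without-replacement
    subsample (capped at the pool size) used as pseudo-absences, so the
    background carries the same survey bias as the presences.
    """

    group: str
    pool_cells: np.ndarray
    pool_x: np.ndarray
    pool_y: np.ndarray
    sample_idx: np.ndarray  # indices into the pool
    seed: int | None = None

    def __post_init__(self) -> None:
        self.pool_cells = np.asarray(self.pool_cells, dtype=int)
        self.sample_idx = np.asarray(self.sample_idx, dtype=int)
        if len(self.sample_idx) > len(self.pool_cells):
            raise ValueError("sample cannot exceed pool")
        if len(np.unique(self.sample_idx)) != len(self.sample_idx):
            raise ValueError("sample must be drawn without replacement")

    @property
    def pool_size(self) -> int:
        return len(self.pool_cells)

    @property
    def sample_cells(self) -> np.ndarray:
        return self.pool_cells[self.sample_idx]

    @property
    def sample_size(self) -> int:
        return len(self.sample_idx)


def build_target_group_background(
    groups: Mapping[str, Sequence[OccurrenceSet]],
    sample_size: int = 10_000,
    seed: int = 0,
) -> dict:
    """Pool each group's occurrences and subsample background points.

    The sample is uniform without replacement of size
    ``min(sample_size, pool size)``.
    """
    out = {}
    for gi, (group, occs) in enumerate(sorted(groups.items())):
        if not occs:
            raise ValueError(f"group {group!r} has no occurrence sets")
        cells = np.concatenate([o.cell_index for o in occs])
        x = np.concatenate([o.x for o in occs])
        y = np.concatenate([o.y for o in occs])
        rng = np.random.default_rng(seed + gi)
        k = min(sample_size, len(cells))
        idx = rng.choice(len(cells), size=k, replace=False)
        out[group] = BackgroundSet(
            group=group, pool_cells=cells, pool_x=x, pool_y=y, sample_idx=idx, seed=seed + gi
        )
    return out


def landscape_background(
    stack: EnvStack, group: str = "all", sample_size: int = 10_000, seed: int = 0
) -> BackgroundSet:
    """Background drawn uniformly from valid landscape cells (no survey bias).

    The alternative to a target-group background when a group's pooled
    occurrences are too few or too narrow to span environmental space.
    """
    cells = stack.valid_cells
    rows, cols = np.divmod(cells, stack.grid.cols)
    x, y = stack.grid.cell_center(rows, cols)
    rng = np.random.default_rng(seed)
    k = min(sample_size, len(cells))
    idx = rng.choice(len(cells), size=k, replace=False)
    return BackgroundSet(
        group=group, pool_cells=cells, pool_x=x, pool_y=y, sample_idx=idx, seed=seed
    )


def morans_i(values: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Moran's I spatial autocorrelation with rook (4-neighbour) weights.

    Straightforward vectorised pair sum; used to characterise how smooth a
    generated layer is.
    """
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = np.where(mask, np.nan, v)
    z = v - np.nanmean(v)
    num = 0.0
    w_sum = 0.0
    for dr, dc in ((0, 1), (1, 0)):
        a = z[: v.shape[0] - dr, : v.shape[1] - dc]
        b = z[dr:, dc:]
        ok = ~np.isnan(a) & ~np.isnan(b)
        num += 2.0 * np.sum(a[ok] * b[ok])  # both directions
        w_sum += 2.0 * ok.sum()
    denom = np.nansum(z**2)
    n = np.sum(~np.isnan(z))
    if denom == 0 or w_sum == 0:
        return 0.0
    return (n / w_sum) * (num / denom)
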