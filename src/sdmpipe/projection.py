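"""Projection of fitted models across the scenario x GCM x period grid,
linear time-interpolation of missing climate stacks, and GCM ensembles.

Projection applies the lambdas-file model to every future predictor stack
with clamping on by default (2090 conditions routinely leave the training
range; the clamped-cell fraction is recorded per map).  Ensembling takes the
per-cell minimum, arithmetic mean and maximum of the suitability maps across
the GCMs of each (scenario, period) — computed on the transformed percent
maps, matching the stored data products.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import EnvStack, HistoricalKey, SuitabilityMap
from .maxent import LambdaModel, predict

ENSEMBLE_STATS = ("min", "mean", "max")


@dataclass
class SuitabilityCube:
    """Per-species suitability maps keyed (scenario, gcm-or-stat, period).

    ``historical_map`` anchors change and refugia calculations.  Stored maps
    use the percent (0-100) scale.
    """

    species_id: str
    historical_map: SuitabilityMap
    maps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = self.historical_map.grid
        for key, m in self.maps.items():
            if m.grid != grid:
                raise ValueError(f"map {key} is not on the historical grid")

    def scenarios(self) -> list:
        return sorted({k[0] for k in self.maps})

    def periods(self) -> list:
        return sorted({k[2] for k in self.maps})

    def gcms(self) -> list:
        return sorted({k[1] for k in self.maps if k[1] not in ENSEMBLE_STATS})


def project_all(
    model: LambdaModel,
    stacks: dict,
    historical: EnvStack,
    clamp: bool = True,
    output: str = "cloglog",
) -> SuitabilityCube:
    """Project a model onto the historical stack and every keyed future stack.

    Returns a cube of percent-scale maps; each map carries the fraction of
    cells clamped during its projection.
    """
    hist = predict(model, historical, clamp=clamp, output=output).to_percent()
    hist = replace(hist, key=(model.species_id, HistoricalKey))
    maps = {}
    for key, stack in stacks.items():
        if not (isinstance(key, tuple) and len(key) == 3):
            raise ValueError(f"future stack key must be (scenario, gcm, period); got {key!r}")
        m = predict(model, stack, clamp=clamp, output=output).to_percent()
        maps[key] = replace(m, key=(model.species_id, *key))
    return SuitabilityCube(species_id=model.species_id, historical_map=hist, maps=maps)


def interpolate_missing_layer(
    stacks: dict,
    missing_key: tuple,
    historical: EnvStack | None = None,
    historical_period: int | None = None,
) -> EnvStack:
    """Fill a missing (scenario, gcm, period) stack by linear interpolation
    in time between the nearest bracketing periods of the same scenario and
    GCM.

    The historical stack, when given, acts as the ``historical_period``
    endpoint for every (scenario, gcm).  Weights follow year distance: a
    2030 stack between 1990 and 2050 is (1/3) x 1990 + (2/3) x 2050.
    """
    scenario, gcm, period = missing_key
    if missing_key in stacks:
        return stacks[missing_key]
    available: dict[int, EnvStack] = {
        k[2]: s for k, s in stacks.items() if k[0] == scenario and k[1] == gcm
    }
    if historical is not None:
        if historical_period is None:
            raise ValueError("historical_period required with a historical stack")
        available.setdefault(historical_period, historical)
    earlier = [y for y in available if y < period]
    later = [y for y in available if y > period]
    if not earlier or not later:
        raise ValueError(
            f"cannot interpolate {missing_key}: need one earlier and one later period "
            f"(have {sorted(available)})"
        )
    y0, y1 = max(earlier), min(later)
    w = (period - y0) / (y1 - y0)
    v0, v1 = available[y0].values, available[y1].values
    vals = (1.0 - w) * v0 + w * v1
    # categorical layers cannot be averaged; carry the earlier period's codes
    base = available[y0]
    for i, name in enumerate(base.layer_names):
        if name in base.categorical:
            vals[i] = v0[i]
    return base.with_values(vals, key=missing_key)


def ensemble_stats(cube: SuitabilityCube, gcms: list | None = None) -> SuitabilityCube:
    """Augment a cube with per-cell min/mean/max maps across GCMs.

    Every listed GCM must be present for each (scenario, period); the
    ensemble is computed on the percent-scale suitability maps.
    """
    gcms = list(gcms) if gcms is not None else cube.gcms()
    if not gcms:
        raise ValueError("no GCM maps to ensemble")
    combos = sorted({(k[0], k[2]) for k in cube.maps if k[1] not in ENSEMBLE_STATS})
    new_maps = dict(cube.maps)
    for scenario, period in combos:
        stack_vals = []
        for g in gcms:
            key = (scenario, g, period)
            if key not in cube.maps:
                raise ValueError(f"missing GCM map {key} for ensemble")
            stack_vals.append(cube.maps[key].values)
        arr = np.stack(stack_vals)
        template = cube.maps[(scenario, gcms[0], period)]
        for stat, vals in (
            ("min", arr.min(axis=0)),
            ("mean", arr.mean(axis=0)),
            ("max", arr.max(axis=0)),
        ):
            new_maps[(scenario, stat, period)] = replace(
                template,
                values=vals,
                key=(cube.species_id, scenario, stat, period),
                clamp_fraction=float(
                    np.mean([cube.maps[(scenario, g, period)].clamp_fraction for g in gcms])
                ),
            )
    return SuitabilityCube(
        species_id=cube.species_id, historical_map=cube.historical_map, maps=new_maps
    )
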