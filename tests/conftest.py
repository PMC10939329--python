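"""Shared fixtures: small synthetic landscapes, species and helper builders."""

from pathlib import Path

import numpy as np
import pytest

from sdmpipe import (
    EnvStack,
    GaussianResponse,
    Grid,
    LandscapeSpec,
    VirtualSpecies,
    make_landscape,
)

DATA_DIR = Path(__file__).parent / "data"


def make_stack(named_layers: dict, cell_size_km: float = 5.0, mask=None, categorical=()) -> EnvStack:
    """Build an EnvStack from a dict of 2-D arrays."""
    names = list(named_layers)
    values = np.stack([np.asarray(named_layers[n], dtype=float) for n in names])
    grid = Grid(values.shape[1], values.shape[2], cell_size_km)
    return EnvStack(
        layer_names=names,
        grid=grid,
        values=values,
        nodata_mask=mask,
        categorical=frozenset(categorical),
    )


@pytest.fixture(scope="session")
def landscape() -> EnvStack:
    """Default 20x20 candidate-predictor stack (35 layers)."""
    return make_landscape(LandscapeSpec(grid_rows=20, grid_cols=20, seed=1))


@pytest.fixture(scope="session")
def recovery_landscape() -> EnvStack:
    """The 40x40 landscape used by the niche-recovery checks."""
    return make_landscape(LandscapeSpec(seed=7))


@pytest.fixture
def gaussian_species(landscape) -> VirtualSpecies:
    tv = landscape.layer("bio01")
    pv = landscape.layer("bio12")
    return VirtualSpecies(
        species_id="vsp_test",
        group="mammal",
        niche={
            "bio01": GaussianResponse(float(np.quantile(tv, 0.4)), float(tv.std() * 0.7)),
            "bio12": GaussianResponse(float(np.quantile(pv, 0.6)), float(pv.std())),
        },
    )
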