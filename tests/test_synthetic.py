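"""Generator behaviour: determinism, landscape structure, climate drift,
virtual species, occurrence sampling and target-group backgrounds."""

import numpy as np
import pytest
from scipy import stats

from sdmpipe import (
    GaussianResponse,
    LandscapeSpec,
    LogisticResponse,
    ScenarioSpec,
    VirtualSpecies,
    build_target_group_background,
    make_future_stacks,
    make_landscape,
    morans_i,
    sample_occurrences,
    true_suitability,
)
from sdmpipe.synthetic import (
    ConstantResponse,
    is_precipitation_layer,
    is_soil_layer,
    is_temperature_layer,
    landscape_background,
)

from conftest import make_stack


def morans_i_double_loop(v: np.ndarray) -> float:
    """Independent Moran's I oracle: explicit loop over rook-neighbour pairs."""
    rows, cols = v.shape
    z = v - v.mean()
    num = w = 0.0
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    num += z[r, c] * z[rr, cc]
                    w += 1
    return (v.size / w) * (num / (z**2).sum())


class TestLandscape:
    def test_seeded_determinism(self):
        spec = LandscapeSpec(grid_rows=20, grid_cols=20, seed=1)
        a, b = make_landscape(spec), make_landscape(spec)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.nodata_mask, b.nodata_mask)

    def test_default_candidate_count_is_35(self, landscape):
        assert landscape.n_layers == 35
        assert "region" in landscape.categorical

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="4x4"):
            LandscapeSpec(grid_rows=3, grid_cols=10)

    def test_correlation_length_orders_morans_i(self):
        smooth = make_landscape(LandscapeSpec(grid_rows=24, grid_cols=24, spatial_correlation_length=8, seed=5))
        rough = make_landscape(LandscapeSpec(grid_rows=24, grid_cols=24, spatial_correlation_length=1, seed=5))
        i_smooth = morans_i_double_loop(smooth.values[0])
        i_rough = morans_i_double_loop(rough.values[0])
        assert i_smooth > i_rough
        # package statistic agrees with the loop oracle
        assert morans_i(smooth.values[0]) == pytest.approx(i_smooth, abs=1e-10)

    def test_nodata_carved_when_requested(self):
        st = make_landscape(LandscapeSpec(grid_rows=20, grid_cols=20, nodata_fraction=0.2, seed=2))
        frac = st.nodata_mask.mean()
        assert 0.1 < frac < 0.3
        assert not st.nodata_mask.all()


class TestFutureStacks:
    def test_default_grid_gives_128_future_stacks(self, landscape):
        stacks = make_future_stacks(landscape, ScenarioSpec())
        assert len(stacks) == 4 * 8 * 4

    def test_zero_drift_zero_jitter_is_identity(self, landscape):
        scen = ScenarioSpec(temp_drift_c=0.0, precip_drift_frac=0.0, gcm_jitter_sd=0.0)
        stacks = make_future_stacks(landscape, scen)
        for st in stacks.values():
            assert np.allclose(st.values, landscape.values)

    def test_drift_monotone_in_scenario_severity(self, landscape):
        stacks = make_future_stacks(landscape, ScenarioSpec())
        gcm = "CanESM5"
        hot = stacks[("RCP8.5-SSP5", gcm, 2090)].layer("bio01").mean()
        mild = stacks[("RCP2.6-SSP1", gcm, 2090)].layer("bio01").mean()
        assert hot > mild

    def test_soil_layers_time_invariant(self, landscape):
        stacks = make_future_stacks(landscape, ScenarioSpec())
        soils = [n for n in landscape.layer_names if is_soil_layer(n)]
        for st in stacks.values():
            for n in soils + ["region"]:
                assert np.array_equal(st.layer(n), landscape.layer(n))

    def test_layer_names_conserved(self, landscape):
        stacks = make_future_stacks(landscape, ScenarioSpec())
        for st in stacks.values():
            assert st.layer_names == landscape.layer_names

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError):
            ScenarioSpec().severity("RCP9.9")

    def test_layer_classification(self):
        assert is_temperature_layer("bio01") and is_temperature_layer("bio11")
        assert is_precipitation_layer("bio12") and is_precipitation_layer("bio19")
        assert not is_temperature_layer("soil01")


class TestTrueSuitability:
    def test_gaussian_peaks_at_one_at_center(self):
        stack = make_stack({"t": np.linspace(0, 10, 25).reshape(5, 5)})
        vs = VirtualSpecies("s", "bird", niche={"t": GaussianResponse(center=5.0, width=2.0)})
        suit = true_suitability(vs, stack)
        assert suit.values.max() == pytest.approx(1.0, abs=1e-6)

    def test_product_of_constant_halves_is_quarter(self):
        stack = make_stack({"a": np.ones((4, 4)), "b": np.ones((4, 4))})
        vs = VirtualSpecies(
            "s", "bird", niche={"a": ConstantResponse(0.5), "b": ConstantResponse(0.5)}
        )
        assert np.allclose(true_suitability(vs, stack).values, 0.25)

    def test_logistic_midpoint_is_half(self):
        stack = make_stack({"t": np.full((4, 4), 3.0)})
        vs = VirtualSpecies("s", "bird", niche={"t": LogisticResponse(midpoint=3.0, slope=2.0)})
        assert np.allclose(true_suitability(vs, stack).values, 0.5)

    def test_missing_niche_variable_rejected(self, landscape):
        vs = VirtualSpecies("s", "bird", niche={"absent": GaussianResponse(0, 1)})
        with pytest.raises(KeyError, match="absent"):
            true_suitability(vs, landscape)

    def test_bounded_in_unit_interval(self, landscape, gaussian_species):
        suit = true_suitability(gaussian_species, landscape)
        assert suit.values.min() >= 0.0 and suit.values.max() <= 1.0


class TestSampleOccurrences:
    def test_seeded_determinism(self, landscape, gaussian_species):
        a = sample_occurrences(gaussian_species, landscape, 123, seed=9)
        b = sample_occurrences(gaussian_species, landscape, 123, seed=9)
        assert np.array_equal(a.cell_index, b.cell_index)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_uniform_suitability_gives_uniform_occupancy(self):
        stack = make_stack({"t": np.zeros((20, 20))})
        vs = VirtualSpecies("s", "bird", niche={"t": ConstantResponse(0.5)})
        occ = sample_occurrences(vs, stack, 10_000, seed=1)
        counts = np.bincount(occ.cell_index, minlength=400)
        res = stats.chisquare(counts)
        assert res.pvalue > 1e-3

    def test_support_restriction(self):
        t = np.zeros((5, 5))
        t[2, 3] = 1.0
        stack = make_stack({"t": t})
        vs = VirtualSpecies("s", "bird", niche={"t": LogisticResponse(midpoint=0.5, slope=200.0)})
        occ = sample_occurrences(vs, stack, 50, seed=0)
        assert set(occ.cell_index) == {2 * 5 + 3}

    def test_all_zero_suitability_rejected(self):
        stack = make_stack({"t": np.zeros((5, 5))})
        vs = VirtualSpecies("s", "bird", niche={"t": ConstantResponse(0.0)})
        with pytest.raises(ValueError, match="zero everywhere"):
            sample_occurrences(vs, stack, 10, seed=0)

    def test_bias_shifts_sampling(self, landscape):
        from sdmpipe import roadside_bias

        vs = VirtualSpecies("s", "bird", niche={"bio01": ConstantResponse(1.0)})
        bias = roadside_bias(landscape.grid, strength=5.0)
        occ = sample_occurrences(vs, landscape, 2000, bias=bias, seed=4)
        cols = occ.cell_index % landscape.grid.cols
        assert cols.mean() < landscape.grid.cols / 2 - 2  # pulled towards the "road"


class TestTargetGroupBackground:
    def _occ(self, species, n, seed, group="mammal"):
        rng = np.random.default_rng(seed)
        cells = rng.integers(0, 400, n)
        from sdmpipe import OccurrenceSet

        return OccurrenceSet(species, rng.random(n), rng.random(n), cells, group=group)

    def test_pool_union_and_subsample_size(self):
        occs = {"mammal": [self._occ("a", 6000, 1), self._occ("b", 5000, 2)]}
        bg = build_target_group_background(occs, sample_size=10_000, seed=0)["mammal"]
        assert bg.pool_size == 11_000
        assert bg.sample_size == 10_000

    def test_small_pool_clamps_to_pool(self):
        occs = {"mammal": [self._occ("a", 40, 1)]}
        bg = build_target_group_background(occs, sample_size=100, seed=0)["mammal"]
        assert bg.sample_size == 40

    def test_sample_without_replacement(self):
        occs = {"mammal": [self._occ("a", 500, 3)]}
        bg = build_target_group_background(occs, sample_size=400, seed=0)["mammal"]
        assert len(np.unique(bg.sample_idx)) == bg.sample_size

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no occurrence sets"):
            build_target_group_background({"mammal": []})

    def test_landscape_background_on_valid_cells(self, landscape):
        bg = landscape_background(landscape, sample_size=150, seed=1)
        assert bg.sample_size == 150
        assert not landscape.nodata_mask.ravel()[bg.sample_cells].any()
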