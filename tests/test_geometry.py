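import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dermaplex.geometry import (
    GeometryError,
    GeometryParams,
    GridResolutionError,
    Label,
    build_unit_cell,
    classify_nodes,
    place_pores,
)


class TestGeometryParams:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"plexus_top_depth": 780.0}, "plexus_top_depth"),
            ({"loop_apex_depth": 450.0}, "loop_apex_depth"),
            ({"arteriole_layer_thickness": 30.0}, "arteriole_layer_thickness"),
            ({"pore_density": 1.5}, "pore_density"),
            ({"pore_density": -0.1}, "pore_density"),
            ({"loop_width": -1.0}, "loop_width"),
        ],
    )
    def test_invalid_parameters_name_the_field(self, kwargs, field):
        with pytest.raises(GeometryError, match=field):
            GeometryParams(**kwargs)


class TestUnitCell:
    def test_standard_cell_extent_is_loop_width_plus_spacing(self):
        geom = build_unit_cell(GeometryParams())
        assert geom.cell_length == pytest.approx(240.0)
        assert geom.cell_width == pytest.approx(240.0)

    def test_centerline_apex_depth(self):
        geom = build_unit_cell(GeometryParams())
        assert geom.centerline_min_depth == pytest.approx(150.0)

    def test_centerline_starts_and_ends_at_plexus_top(self):
        geom = build_unit_cell(GeometryParams())
        assert geom.loop_centerline[0, 2] == pytest.approx(400.0)
        assert geom.loop_centerline[-1, 2] == pytest.approx(400.0)

    def test_plexus_layers_venule_on_top(self):
        geom = build_unit_cell(GeometryParams())
        assert geom.venule_layer == (400.0, 425.0)
        assert geom.arteriole_layer == (425.0, 450.0)

    def test_construction_is_pure(self):
        a = build_unit_cell(GeometryParams())
        b = build_unit_cell(GeometryParams())
        assert a.pore_footprints == b.pore_footprints
        np.testing.assert_array_equal(a.loop_centerline, b.loop_centerline)


class TestPores:
    def test_zero_density_gives_no_pores(self):
        geom = build_unit_cell(GeometryParams(pore_density=0.0))
        assert geom.pore_footprints == ()

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_standard_density_area_fraction(self, seed):
        geom = build_unit_cell(GeometryParams(pore_density=0.11, pore_seed=seed))
        assert geom.pore_area_fraction == pytest.approx(0.11, abs=0.005)

    def test_determinism(self):
        g = build_unit_cell(GeometryParams())
        a = place_pores(g, 0.2, seed=7)
        b = place_pores(g, 0.2, seed=7)
        assert a.pore_footprints == b.pore_footprints

    def test_out_of_range_density_rejected(self):
        g = build_unit_cell(GeometryParams())
        with pytest.raises(GeometryError):
            place_pores(g, 1.2, seed=0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        d1=st.floats(0.0, 1.0),
        d2=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_pore_count_monotone_in_density(self, d1, d2, seed):
        lo, hi = sorted((d1, d2))
        g = build_unit_cell(GeometryParams())
        a = place_pores(g, lo, seed)
        b = place_pores(g, hi, seed)
        assert len(b.pore_footprints) >= len(a.pore_footprints)
        # nested: the sparser layout is a subset of the denser one
        assert set(a.pore_footprints) <= set(b.pore_footprints)


class TestClassifyNodes:
    def test_label_partition_counts_standard_grid(self):
        grid = classify_nodes(build_unit_cell(GeometryParams()), 10.0)
        counts = grid.label_counts()
        assert grid.shape == (24, 24, 80)
        assert sum(counts.values()) == 24 * 24 * 80

    def test_no_pore_labels_when_density_zero(self):
        grid = classify_nodes(build_unit_cell(GeometryParams(pore_density=0.0)), 10.0)
        assert np.count_nonzero(grid.labels == Label.PORE) == 0

    def test_pore_node_fraction_matches_density(self):
        grid = classify_nodes(build_unit_cell(GeometryParams(pore_density=0.25)), 10.0)
        layer = np.isin(grid.labels, Label.PLEXUS + (Label.PORE,))
        pore = grid.labels == Label.PORE
        frac = pore.sum() / layer.sum()
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_coarse_grid_cannot_resolve_lumen(self):
        with pytest.raises(GridResolutionError, match="fine"):
            classify_nodes(build_unit_cell(GeometryParams(lumen_diameter=10.0)), 20.0)

    def test_non_dividing_resolution_rejected(self):
        with pytest.raises(GridResolutionError):
            classify_nodes(build_unit_cell(GeometryParams()), 7.0)

    def test_no_lumen_above_apex(self):
        grid = classify_nodes(build_unit_cell(GeometryParams()), 10.0)
        zc = grid.z_centers()
        lum = np.isin(grid.labels, Label.LUMEN)
        min_depth = zc[np.where(lum.any(axis=(0, 1)))[0]].min()
        assert min_depth >= 150.0 - grid.dz

    def test_plexus_and_pore_labels_only_inside_layer_bounds(self):
        grid = classify_nodes(build_unit_cell(GeometryParams()), 10.0)
        zc = grid.z_centers()
        special = np.isin(grid.labels, Label.PLEXUS + (Label.PORE,))
        depths = zc[np.where(special.any(axis=(0, 1)))[0]]
        assert depths.min() >= 400.0 and depths.max() < 450.0

    def test_every_station_has_a_node(self):
        grid = classify_nodes(build_unit_cell(GeometryParams()), 10.0)
        assert all(len(nodes) >= 1 for nodes in grid.station_nodes)
        assert grid.n_stations == len(grid.lumen_s) == len(grid.lumen_ds)

    def test_station_chain_spans_both_limbs(self):
        grid = classify_nodes(build_unit_cell(GeometryParams()), 10.0)
        assert grid.station_is_arteriole[0]
        assert not grid.station_is_arteriole[-1]
        # arclength covers roughly two limbs plus the apex run
        total = grid.lumen_ds.sum()
        assert total == pytest.approx(2 * 250 + 170, rel=0.1)

    def test_unit_cell_volume_exact(self):
        geom = build_unit_cell(GeometryParams())
        grid = classify_nodes(geom, 10.0)
        vol = np.prod(grid.shape) * grid.dx * grid.dy * grid.dz
        assert vol == geom.cell_length * geom.cell_width * geom.params.slab_depth
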