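import numpy as np
import pytest

from dermaplex.geometry import GeometryParams, Label
from dermaplex.sensitivity import (
    STANDARD_VELOCITY_FRACTIONS,
    DepthProfile,
    band_ratio_sensitivity,
    depth_profile,
    plexus_mean_concentration,
    run_sweep,
    top_bottom_ratio,
)
from dermaplex.transport import SimState, TransportParams, simulate

COARSE_GEO = GeometryParams(lumen_diameter=20.0)


def uniform_state(grid, c=2.5):
    s = SimState.zeros(grid)
    s.C_vs[np.isin(grid.labels, Label.DIFFUSIVE)] = c
    s.C_b = np.full(grid.n_stations, c)
    s.C_vp = s.C_ap = c
    return s


class TestDepthProfile:
    def test_uniform_field_gives_constant_profile(self, coarse_grid):
        s = uniform_state(coarse_grid)
        for tag in ("arteriole_adjacent", "venule_adjacent", "lateral_mean"):
            p = depth_profile(s, coarse_grid, tag)
            np.testing.assert_allclose(p.concentrations, 2.5, rtol=1e-12)

    def test_unknown_tag_rejected(self, coarse_grid):
        with pytest.raises(ValueError, match="tag"):
            depth_profile(SimState.zeros(coarse_grid), coarse_grid, "sideways")

    def test_profile_reports_compartments_inside_layers(self, coarse_grid):
        s = uniform_state(coarse_grid, 1.0)
        s.C_vp, s.C_ap = 5.0, 7.0
        p = depth_profile(s, coarse_grid, "arteriole_adjacent")
        z = p.depths_um
        assert np.all(p.concentrations[(z > 400) & (z < 425)] == 5.0)
        assert np.all(p.concentrations[(z > 425) & (z < 450)] == 7.0)

    def test_monotone_depth_axis_required(self):
        with pytest.raises(ValueError, match="increasing"):
            DepthProfile(np.array([0.0, 10.0, 10.0]), np.zeros(3), "lateral_mean")


class TestPlexusMean:
    def test_equal_compartments(self, coarse_steady):
        cpl = coarse_steady.coupling
        s = SimState(0.0, np.zeros((1, 1, 1)), np.zeros(0), 4.2, 4.2)
        assert plexus_mean_concentration(s, cpl) == pytest.approx(4.2)

    def test_volume_weighting(self, coarse_steady):
        cpl = coarse_steady.coupling  # equal 25 um layers -> equal volumes
        s = SimState(0.0, np.zeros((1, 1, 1)), np.zeros(0), 2.0, 0.0)
        assert plexus_mean_concentration(s, cpl) == pytest.approx(1.0)

    def test_exchange_switched_off_starves_the_plexus(self, coarse_steady):
        # transient oracle: with k_p = 0 nothing ever reaches the vessels
        traj = simulate(
            None,
            TransportParams(k_p=0.0),
            20.0,
            t_end=1000.0,
            scheme="implicit",
            dt=50.0,
            grid=coarse_steady.grid,
        )
        off = plexus_mean_concentration(traj.final, traj.ops.coupling)
        on = plexus_mean_concentration(coarse_steady.state, coarse_steady.coupling)
        assert on > off
        assert off == 0.0


class TestTopBottomRatio:
    def test_uniform_profile_ratio_one(self):
        p = DepthProfile(np.arange(5.0, 800.0, 10.0), np.ones(80), "lateral_mean")
        assert top_bottom_ratio(p, 450.0) == pytest.approx(1.0)

    def test_zero_top_concentration_rejected(self):
        p = DepthProfile(np.arange(5.0, 800.0, 10.0), np.zeros(80), "lateral_mean")
        with pytest.raises(ValueError, match="zero"):
            top_bottom_ratio(p, 450.0)

    def test_diffusion_only_matches_linear_closed_form(self):
        # C(z) = J (L - z) / D  =>  band mean over [450, 500) vs top value
        z = np.arange(5.0, 800.0, 10.0)
        c = (800.0 - z) / 800.0
        p = DepthProfile(z, c, "lateral_mean")
        expected = np.mean((800.0 - z[(z >= 450) & (z < 500)]) / 800.0) / c[0]
        assert top_bottom_ratio(p, 450.0) == pytest.approx(expected)

    def test_band_choice_sensitivity_reported(self, coarse_steady):
        p = depth_profile(coarse_steady.state, coarse_steady.grid, "lateral_mean")
        rep = band_ratio_sensitivity(p, 450.0)
        assert set(rep) == {25.0, 50.0, 75.0, 100.0}
        assert all(r > 0 for r in rep.values())


class TestRunSweep:
    def test_single_value_sweep_equals_standalone_run(self, coarse_steady):
        sw = run_sweep("velocity", [6.5e-4], geometry=COARSE_GEO, resolution=20.0)
        standalone = plexus_mean_concentration(coarse_steady.state, coarse_steady.coupling)
        assert sw.C_plex[0] == standalone

    def test_sweep_is_reproducible(self):
        a = run_sweep("pore_density", [0.11, 0.25], geometry=COARSE_GEO, resolution=20.0)
        b = run_sweep("pore_density", [0.11, 0.25], geometry=COARSE_GEO, resolution=20.0)
        assert a.C_plex == b.C_plex
        assert a.summary_frame().equals(b.summary_frame())

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="sweep"):
            run_sweep("temperature", [1.0], geometry=COARSE_GEO, resolution=20.0)

    def test_plexus_size_sweep_keeps_mid_depth(self):
        sw = run_sweep("plexus_size", [30.0, 50.0], geometry=COARSE_GEO, resolution=20.0)
        assert not sw.partial
        # both runs share the 425 um plexus mid-depth by construction
        assert len(sw.C_plex) == 2 and all(c > 0 for c in sw.C_plex)

    def test_long_frame_layout(self):
        sw = run_sweep("velocity", [6.5e-4], geometry=COARSE_GEO, resolution=20.0)
        df = sw.long_frame()
        assert set(df["line_tag"]) == {"arteriole_adjacent", "venule_adjacent", "lateral_mean"}
        assert {"parameter", "value", "depth_um", "concentration_per_m3"} <= set(df.columns)


class TestTrendsCoarse:
    """Qualitative shape of the steady profiles at the coarse study resolution."""

    def test_pore_density_increases_plexus_concentration(self):
        sw = run_sweep("pore_density", [0.11, 0.19, 0.25], geometry=COARSE_GEO, resolution=20.0)
        assert np.all(np.diff(sw.C_plex) > 0)

    def test_above_plexus_concentration_decreases_with_velocity(self):
        vals = [6.5e-4 * f for f in STANDARD_VELOCITY_FRACTIONS]
        sw = run_sweep("velocity", vals, geometry=COARSE_GEO, resolution=20.0)
        above = [p["lateral_mean"].at_depth(200.0) for p in sw.profiles]
        assert np.all(np.diff(above) < 0)

    def test_venule_side_richer_than_arteriole_side(self, coarse_steady):
        ven = depth_profile(coarse_steady.state, coarse_steady.grid, "venule_adjacent")
        art = depth_profile(coarse_steady.state, coarse_steady.grid, "arteriole_adjacent")
        # stop one cell above the plexus top: the fat 20 um lumen's outlet row
        # locally depresses the venule-side tissue at this resolution
        m = (ven.depths_um >= 350) & (ven.depths_um <= 380)
        assert np.all(ven.concentrations[m] >= art.concentrations[m])

    def test_minimum_near_plexus_with_rise_below(self, coarse_steady):
        art = depth_profile(coarse_steady.state, coarse_steady.grid, "arteriole_adjacent")
        z, c = art.depths_um, art.concentrations
        imin = int(np.argmin(c))
        assert 350.0 <= z[imin] <= 460.0
        assert np.mean(c[z > 460.0]) > c[imin]
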