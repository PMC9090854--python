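import warnings

import numpy as np
import pytest

from dermaplex.geometry import GeometryParams, Label, build_unit_cell, classify_nodes
from dermaplex.plexus import UM
from dermaplex.transport import (
    ConvergenceWarning,
    SimState,
    SolverError,
    TransportParams,
    assemble_operators,
    simulate,
    steady_state,
    step,
)


def all_tissue_grid(h=20.0):
    geom = build_unit_cell(
        GeometryParams(pore_density=1.0)  # fully porous band: slab is one region
    )
    return geom, classify_nodes(geom, h, include_loop=False)


class TestParams:
    def test_nonpositive_diffusivity_rejected(self):
        with pytest.raises(ValueError, match="D_vs"):
            TransportParams(D_vs=0.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError, match="k_p"):
            TransportParams(k_p=-1.0)

    def test_defaults_resolve_from_geometry(self):
        geom = build_unit_cell(GeometryParams())
        p = TransportParams().resolve(geom)
        assert p.D_p == p.D_vs
        assert p.k_pcl == p.v_b
        # inter-layer diffusion estimate D_p / (half plexus thickness)
        assert p.k1 == pytest.approx(1e-10 / 25e-6)
        assert p.k2 == p.k1


class TestOperators:
    def test_uniform_field_has_zero_diffusion_rate(self):
        geom, grid = all_tissue_grid()
        ops = assemble_operators(grid, TransportParams(J_sc=0.0))
        u = np.ones(ops.n)
        rate = ops.A_diff @ u
        # entries are O(D/h^2) ~ 0.25/s; a constant field cancels to roundoff
        assert np.max(np.abs(rate)) < 1e-12

    def test_equal_tissue_and_blood_gives_zero_exchange(self, coarse_grid):
        # C_vs = C_b = C_vp = C_ap everywhere, no flux, no advection: fixed point
        ops = assemble_operators(grid=coarse_grid, params=TransportParams(J_sc=0.0, v_b=0.0))
        u = np.ones(ops.n)
        assert np.max(np.abs(ops.A @ u)) < 1e-12

    def test_exchange_rate_scales_with_permeability_and_area(self, coarse_grid):
        # tissue at 1, blood at 0: lumen gains k_p * (total lumen surface)
        ops = assemble_operators(
            grid=coarse_grid, params=TransportParams(J_sc=0.0, v_b=0.0, k1=0.0, k2=0.0)
        )
        u = np.zeros(ops.n)
        u[: ops.n_t] = 1.0
        gain = ops.V * (ops.A @ u)
        ns = len(ops.ds_m)
        lumen_gain = float(np.sum(gain[ops.n_t : ops.n_t + ns]))
        d = coarse_grid.geom.params.lumen_diameter * UM
        surface = np.pi * d * float(np.sum(ops.ds_m))
        assert lumen_gain == pytest.approx(1e-6 * surface, rel=1e-12)

    def test_periodic_closure_commutes_with_lateral_shift(self, rng):
        geom, grid = all_tissue_grid()
        ops = assemble_operators(grid, TransportParams(J_sc=0.0))
        c = rng.uniform(0.0, 1.0, grid.shape)
        state = SimState(0.0, c, np.zeros(0), 0.0, 0.0)
        rolled = SimState(0.0, np.roll(c, 3, axis=0), np.zeros(0), 0.0, 0.0)
        r1 = ops.unpack(ops.A @ ops.pack(state), 0.0).C_vs
        r2 = ops.unpack(ops.A @ ops.pack(rolled), 0.0).C_vs
        np.testing.assert_allclose(np.roll(r1, 3, axis=0), r2, rtol=0, atol=1e-12)


class TestStep:
    def test_zero_state_stays_zero_without_flux(self, coarse_grid):
        ops = assemble_operators(coarse_grid, TransportParams(J_sc=0.0))
        s = SimState.zeros(coarse_grid)
        for scheme in ("explicit", "imex", "implicit"):
            out = step(s, 1e-3, ops, scheme=scheme)
            assert np.all(out.C_vs == 0) and np.all(out.C_b == 0)
            assert out.C_vp == 0 and out.C_ap == 0

    def test_influx_is_local_to_top_layer_after_one_step(self, coarse_grid):
        ops = assemble_operators(coarse_grid, TransportParams())
        s1 = step(SimState.zeros(coarse_grid), 1e-3, ops, scheme="explicit")
        assert s1.C_vs[:, :, 0].min() > 0
        assert np.all(s1.C_vs[:, :, 1:] == 0)

    def test_advective_cfl_violation_flagged_at_step_time(self, coarse_grid):
        ops = assemble_operators(coarse_grid, TransportParams())
        with pytest.raises(SolverError, match="CFL"):
            step(SimState.zeros(coarse_grid), 10.0, ops, scheme="imex")

    def test_eigenmode_decays_at_analytic_rate(self):
        # manufactured solution: lateral cosine eigenmode of the periodic box
        geom, grid = all_tissue_grid(h=20.0)
        D = 1e-10
        ops = assemble_operators(grid, TransportParams(D_vs=D, J_sc=0.0))
        kx = 2 * np.pi / (geom.cell_length * UM)
        lam = D * kx**2
        x = grid.x_centers()[:, None, None] * UM
        mode = np.cos(kx * x) * np.ones(grid.shape)
        s = SimState(0.0, 2.0 + mode, np.zeros(0), 0.0, 0.0)
        t_f, n = 20.0, 200
        for _ in range(n):
            s = step(s, t_f / n, ops, scheme="imex")
        exact = 2.0 + mode * np.exp(-lam * t_f)
        # bound: spatial eigenvalue error (kx h)^2/12 ~ 2.3% of the decay
        assert np.max(np.abs(s.C_vs - exact)) < 2e-2


class TestSimulate:
    def test_zero_horizon_returns_initial_state_only(self, coarse_geometry):
        traj = simulate(coarse_geometry, TransportParams(), 20.0, t_end=0.0)
        assert len(traj.states) == 1
        assert traj.final.time == 0.0
        assert np.all(traj.final.C_vs == 0)

    @pytest.mark.parametrize("scheme", ["imex", "implicit"])
    def test_mass_balance_closes(self, coarse_geometry, coarse_grid, scheme):
        traj = simulate(
            coarse_geometry,
            TransportParams(),
            20.0,
            t_end=60.0,
            output_times=[20.0, 60.0],
            scheme=scheme,
            dt=None if scheme == "imex" else 3.0,
            grid=coarse_grid,
        )
        assert traj.log["mass_residual_rel_influx"].max() < 1e-3

    def test_positivity_preserved(self, coarse_geometry, coarse_grid):
        traj = simulate(
            coarse_geometry, TransportParams(), 20.0, t_end=30.0, grid=coarse_grid
        )
        s = traj.final
        assert s.C_vs.min() >= 0 and s.C_b.min() >= 0
        assert s.C_vp >= 0 and s.C_ap >= 0

    def test_profile_difference_shrinks_under_refinement(self):
        # self-consistency: successive refinements move the solution less
        geom = build_unit_cell(GeometryParams(lumen_diameter=40.0))
        profs = {}
        for h in (40.0, 20.0, 10.0):
            traj = simulate(geom, TransportParams(), h, t_end=100.0, scheme="implicit", dt=10.0)
            lab = traj.ops.grid.labels
            c = traj.final.C_vs
            prof = np.array(
                [
                    c[:, :, iz][np.isin(lab[:, :, iz], Label.DIFFUSIVE)].mean()
                    if np.isin(lab[:, :, iz], Label.DIFFUSIVE).any()
                    else np.nan
                    for iz in range(lab.shape[2])
                ]
            )
            z = traj.ops.grid.z_centers()
            profs[h] = (z, prof)
        zs = np.arange(25.0, 800.0, 50.0)

        def interp(h):
            z, p = profs[h]
            m = ~np.isnan(p)
            return np.interp(zs, z[m], p[m])

        d1 = np.nanmax(np.abs(interp(40.0) - interp(20.0)))
        d2 = np.nanmax(np.abs(interp(20.0) - interp(10.0)))
        assert d2 < d1


class TestSteadyState:
    def test_diffusion_only_matches_linear_closed_form(self):
        geom, grid = all_tissue_grid(h=20.0)
        res = steady_state(
            geom, TransportParams(k_p=0.0, v_b=0.0), 20.0, bottom_bc="sink", grid=grid
        )
        assert res.converged
        z = grid.z_centers() * UM
        exact = 1.0 * (800e-6 - z) / 1e-10
        err = np.abs(res.state.C_vs[0, 0, :] - exact) / exact[0]
        assert err.max() < 1e-6

    def test_pure_accumulation_flagged_non_converged(self):
        geom, grid = all_tissue_grid(h=20.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = steady_state(
                geom, TransportParams(k_p=0.0, v_b=0.0), 20.0, bottom_bc="no_flux", grid=grid
            )
        assert not res.converged

    def test_standard_steady_satisfies_rate_criterion(self, coarse_steady):
        assert coarse_steady.converged
        assert coarse_steady.criterion < coarse_steady.tol

    def test_steady_removal_balances_influx(self, coarse_steady):
        ops = coarse_steady.ops
        u = ops.pack(coarse_steady.state)
        assert ops.removal_rate(u) == pytest.approx(ops.influx_rate(), rel=1e-6)

    def test_steady_concentrations_nonnegative(self, coarse_steady):
        s = coarse_steady.state
        assert s.C_vs.min() >= 0 and s.C_b.min() >= 0
        assert s.C_vp > 0 and s.C_ap > 0
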