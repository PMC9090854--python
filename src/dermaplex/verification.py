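"""Independent verification machinery: brute-force solver and manufactured solutions.

This module re-implements the continuous transport equations by direct
array accumulation (rolls, pads and per-station loops) with no shared
discretization code with :mod:`dermaplex.transport`, so the two can be
cross-checked; and it runs manufactured-solution grid-refinement studies to
measure the observed convergence order of the main solver. It is intended for
tests and the ``verify`` command, not for production runs — it is deliberately
naive and may be orders of magnitude slower.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GeometryParams, Label, LabeledGrid, SkinGeometry, build_unit_cell, classify_nodes
from .plexus import UM, PlexusCoupling, build_coupling
from .transport import (
    ResolvedParams,
    SimState,
    TransportParams,
    assemble_operators,
    step,
)

__all__ = [
    "brute_force_rhs",
    "brute_force_step",
    "brute_force_mass",
    "ConvergenceReport",
    "manufactured_convergence",
]

MAX_BRUTE_NODES = 20 * 20 * 50


def _resolved(params, geom):
    return params.resolve(geom) if isinstance(params, TransportParams) else params


def brute_force_rhs(
    state: SimState,
    grid: LabeledGrid,
    params: TransportParams | ResolvedParams,
    coupling: PlexusCoupling | None = None,
    bottom_bc: str = "no_flux",
):
    """Time derivatives of all state components by naive accumulation.

    Returns ``(dC_vs, dC_b, dC_vp, dC_ap)``. Small grids only
    (≤ 20×20×50 nodes).
    """
    if int(np.prod(grid.shape)) > MAX_BRUTE_NODES:
        raise ValueError(
            f"brute-force oracle refuses grids larger than {MAX_BRUTE_NODES} nodes"
        )
    p = _resolved(params, grid.geom)
    if coupling is None and grid.n_stations > 0:
        coupling = build_coupling(grid, p.v_b)

    lab = grid.labels
    diff = np.isin(lab, Label.DIFFUSIVE)
    dcoef = np.where(lab == Label.PORE, p.D_p, p.D_vs)
    hx, hy, hz = grid.dx * UM, grid.dy * UM, grid.dz * UM
    v_cell = hx * hy * hz
    C = np.where(diff, state.C_vs, 0.0)
    rate = np.zeros_like(C)

    # diffusion: face fluxes by harmonic-mean conductance
    for axis, h in ((0, hx), (1, hy)):
        Cn = np.roll(C, -1, axis=axis)
        dn = np.roll(dcoef, -1, axis=axis)
        mn = np.roll(diff, -1, axis=axis)
        g = 2.0 * dcoef * dn / (dcoef + dn) / h**2
        F = np.where(diff & mn, g * (Cn - C), 0.0)
        rate += F
        rate -= np.roll(F, 1, axis=axis)
    gz = 2.0 * dcoef[:, :, :-1] * dcoef[:, :, 1:] / (dcoef[:, :, :-1] + dcoef[:, :, 1:]) / hz**2
    Fz = np.where(
        diff[:, :, :-1] & diff[:, :, 1:], gz * (C[:, :, 1:] - C[:, :, :-1]), 0.0
    )
    rate[:, :, :-1] += Fz
    rate[:, :, 1:] -= Fz

    # boundary closures
    if p.J_sc != 0:
        rate[:, :, 0] += np.where(diff[:, :, 0], p.J_sc / hz, 0.0)
    if bottom_bc == "sink":
        rate[:, :, -1] -= np.where(diff[:, :, -1], 2.0 * dcoef[:, :, -1] / hz**2 * C[:, :, -1], 0.0)

    ns = grid.n_stations
    dC_b = np.zeros(ns)
    dvp = 0.0
    dap = 0.0
    if ns:
        ds = grid.lumen_ds * UM
        a_cl = coupling.A_cl
        # advection (upwind; inlet fed by the arteriole plexus)
        if p.v_b > 0:
            for i in range(ns):
                up = state.C_ap if i == 0 else state.C_b[i - 1]
                dC_b[i] += p.v_b * (up - state.C_b[i]) / ds[i]
        # endothelial exchange, equal split over each station's neighbours
        if p.k_p > 0:
            d_lum = grid.geom.params.lumen_diameter * UM
            nx, ny, nz = grid.shape
            for i in range(ns):
                nbrs = set()
                for (ix, iy, iz) in grid.station_nodes[i]:
                    for o in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        jx, jy, jz = (ix + o[0]) % nx, (iy + o[1]) % ny, iz + o[2]
                        if 0 <= jz < nz and lab[jx, jy, jz] in Label.DIFFUSIVE:
                            nbrs.add((jx, jy, jz))
                if not nbrs:
                    continue
                a_per = np.pi * d_lum * ds[i] / len(nbrs)
                for nb in sorted(nbrs):
                    j_flux = p.k_p * a_per * (state.C_b[i] - C[nb])
                    rate[nb] += j_flux / v_cell
                    dC_b[i] -= j_flux / (a_cl * ds[i])

    if coupling is not None:
        cpl = coupling
        fa = cpl.face_area
        sum_vp = 0.0
        for nb in cpl.vp_tissue_nodes:
            f = p.k_p * fa * (state.C_vp - C[nb])
            rate[nb] += f / v_cell
            sum_vp -= f
        sum_ap = 0.0
        for nb in cpl.ap_tissue_nodes:
            f = p.k_p * fa * (state.C_ap - C[nb])
            rate[nb] += f / v_cell
            sum_ap -= f
        dvp = (
            sum_vp
            + cpl.A_int * (p.k2 * state.C_ap - p.k1 * state.C_vp)
            + (p.k_pcl * cpl.A_cl * state.C_b[-1] if ns else 0.0)
        ) / cpl.V_vp
        dap = (
            sum_ap
            + cpl.A_int * (p.k1 * state.C_vp - p.k2 * state.C_ap)
            - (p.v_b * cpl.A_cl * state.C_ap if ns else 0.0)
            - cpl.k_e * state.C_ap
        ) / cpl.V_ap

    rate = np.where(diff, rate, 0.0)
    return rate, dC_b, dvp, dap


def brute_force_step(
    state: SimState,
    dt: float,
    grid: LabeledGrid,
    params: TransportParams | ResolvedParams,
    coupling: PlexusCoupling | None = None,
    bottom_bc: str = "no_flux",
) -> SimState:
    """One fully explicit Euler step of the naive reference implementation."""
    dvs, dcb, dvp, dap = brute_force_rhs(state, grid, params, coupling, bottom_bc)
    return SimState(
        time=state.time + dt,
        C_vs=state.C_vs + dt * dvs,
        C_b=state.C_b + dt * dcb,
        C_vp=state.C_vp + dt * dvp,
        C_ap=state.C_ap + dt * dap,
    )


def brute_force_mass(state: SimState, grid: LabeledGrid, coupling: PlexusCoupling | None):
    """Total solute amount, integrating each compartment independently."""
    diff = np.isin(grid.labels, Label.DIFFUSIVE)
    v_cell = grid.dx * grid.dy * grid.dz * UM**3
    m = float(np.sum(state.C_vs[diff])) * v_cell
    if grid.n_stations and coupling is not None:
        m += float(np.sum(state.C_b * grid.lumen_ds * UM)) * coupling.A_cl
    if coupling is not None:
        m += coupling.V_vp * state.C_vp + coupling.V_ap * state.C_ap
    return m


# ---------------------------------------------------------------------------
# manufactured-solution convergence studies


@dataclass
class ConvergenceReport:
    """Grid-refinement study result.

    ``orders[i]`` is the observed order between ``resolutions[i]`` and
    ``resolutions[i+1]`` (log2 error ratio for 2× refinement); ``monotone`` is
    False when errors fail to decrease under refinement.
    """

    case: str
    resolutions: list[float]
    errors: list[float]
    orders: list[float]
    monotone: bool

    @property
    def min_order(self) -> float:
        return min(self.orders) if self.orders else np.nan

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (h, e) in enumerate(zip(self.resolutions, self.errors)):
            rows.append(
                {
                    "case": self.case,
                    "resolution_um": h,
                    "l2_error": e,
                    "observed_order": self.orders[i - 1] if i > 0 else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _diffusion_case_geom(slab: float = 240.0) -> SkinGeometry:
    # fully porous plexus band -> the entire slab is one diffusive region
    return build_unit_cell(
        GeometryParams(
            slab_depth=slab,
            loop_apex_depth=100.0,
            plexus_top_depth=200.0,
            plexus_total_thickness=20.0,
            arteriole_layer_thickness=10.0,
            venule_layer_thickness=10.0,
            pore_density=1.0,
        )
    )


def _run_diffusion_case(h: float, t_f: float, n0: int, full_params: bool) -> float:
    geom = _diffusion_case_geom()
    grid = classify_nodes(geom, (h, 60.0, h), include_loop=False)
    D = 1e-10
    tp = (
        TransportParams(D_vs=D, J_sc=0.0)
        if not full_params
        else TransportParams(D_vs=D, J_sc=0.0, k_p=0.0, v_b=6.5e-4)
    )
    ops = assemble_operators(grid, tp)
    Lx = geom.cell_length * UM
    Lz = geom.params.slab_depth * UM
    kx, kz = 2 * np.pi / Lx, np.pi / Lz
    lam = D * (kx**2 + kz**2)
    x = grid.x_centers()[:, None, None] * UM
    z = grid.z_centers()[None, None, :] * UM
    u0 = np.cos(kx * x) * np.cos(kz * z) * np.ones((1, grid.shape[1], 1))
    state = SimState.zeros(grid)
    state.C_vs = u0 + 2.0  # shifted positive; the constant mode is invariant
    n_steps = max(1, int(round(n0 * (20.0 / h) ** 2)))
    dt = t_f / n_steps
    for _ in range(n_steps):
        state = step(state, dt, ops, scheme="imex")
    exact = (u0 * np.exp(-lam * t_f)) + 2.0
    err = state.C_vs - exact
    return float(np.sqrt(np.mean(err**2)))


def _run_advection_case(h: float, cfl: float = 0.5) -> float:
    geom = build_unit_cell(GeometryParams(lumen_diameter=20.0))
    grid = classify_nodes(geom, h)
    v = 6.5e-4
    s_tot = float(np.sum(grid.lumen_ds)) * UM

    def g(xi):
        return 2.0 + np.sin(2 * np.pi * xi / s_tot)

    tp = TransportParams(v_b=v, k_p=0.0, J_sc=0.0)
    ops = assemble_operators(
        grid, tp, inlet_func=lambda t: float(g(-v * t))
    )
    s = grid.lumen_s * UM
    state = SimState.zeros(grid)
    state.C_b = g(s)
    t_f = 0.4 * s_tot / v
    ds_min = float(np.min(grid.lumen_ds)) * UM
    dt = cfl * ds_min / v
    n = int(np.ceil(t_f / dt))
    dt = t_f / n
    # explicit scheme: identical upwind advection operator, and with k_p = 0
    # the (inert) tissue block needs no implicit factorization
    for _ in range(n):
        state = step(state, dt, ops, scheme="explicit")
    exact = g(s - v * t_f)
    return float(np.sqrt(np.mean((state.C_b - exact) ** 2)))


def manufactured_convergence(
    case: str,
    resolutions: list[float] | None = None,
    t_f: float = 10.0,
    n0_steps: int = 8,
) -> ConvergenceReport:
    """Observed convergence order of the main solver on analytic solutions.

    Cases: ``diffusion_only`` — a separable cosine eigenmode of the periodic/
    no-flux box, decaying at its analytic rate (expected order 2);
    ``advection_only`` — a travelling wave along the lumen chain with the
    matching inlet history (expected order 1, upwind); ``coupled`` — the
    diffusion study run through the fully coupled assembly with the coupling
    coefficients at zero, which must reduce to the diffusion orders.
    """
    if resolutions is None:
        resolutions = [20.0, 10.0, 5.0]
    if len(resolutions) < 3:
        raise ValueError("need at least 3 resolutions for an order estimate")
    if case == "diffusion_only":
        errs = [_run_diffusion_case(h, t_f, n0_steps, full_params=False) for h in resolutions]
    elif case == "coupled":
        errs = [_run_diffusion_case(h, t_f, n0_steps, full_params=True) for h in resolutions]
    elif case == "advection_only":
        errs = [_run_advection_case(h) for h in resolutions]
    else:
        raise ValueError(f"unknown case {case!r}")
    orders = []
    for i in range(len(errs) - 1):
        ratio = resolutions[i] / resolutions[i + 1]
        orders.append(float(np.log(errs[i] / errs[i + 1]) / np.log(ratio)))
    monotone = all(errs[i] > errs[i + 1] for i in range(len(errs) - 1))
    return ConvergenceReport(
        case=case,
        resolutions=list(resolutions),
        errors=errs,
        orders=orders,
        monotone=monotone,
    )
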