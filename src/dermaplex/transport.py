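"""Coupled dermal transport solver.

Discretizes and integrates the coupled system on the periodic unit cell:

* diffusion of the solute through viable tissue and plexus pores
  (``∂C/∂t = D ∇²C``, 7-point stencil, periodic lateral closure, constant
  applied flux ``J_sc`` at the top, zero-flux — or optionally sink — bottom);
* 1-D conservative upwind advection of the capillary-loop blood concentration
  along the centerline arclength at speed ``v_b`` (arteriole inlet → apex →
  venule outlet), exchanging with adjacent tissue through the endothelial
  permeability ``k_p`` over the lumen surface;
* the two well-stirred plexus compartment balances (see
  :mod:`dermaplex.plexus`), fed by the loop outlet and drained by the loop
  inlet and the systemic circulation.

Because every coupling is linear, the semi-discrete system is ``du/dt = A u + b``
for the stacked unknown vector ``u = [C_vs(tissue+pore), C_b(stations), C_vp,
C_ap]``. Time integration offers an IMEX scheme (implicit diffusion via a
cached sparse factorization, explicit upwind advection and exchange), a fully
explicit scheme (used for oracle cross-checks), and a fully implicit backward
Euler scheme for long transients. Steady states are obtained directly from
``A u = -b`` and verified against the operational rate-of-change criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import GeometryParams, Label, LabeledGrid, SkinGeometry, build_unit_cell, classify_nodes
from .plexus import UM, PlexusCoupling, build_coupling

__all__ = [
    "TransportParams",
    "ResolvedParams",
    "SimState",
    "SolverError",
    "ConvergenceWarning",
    "Operators",
    "assemble_operators",
    "step",
    "simulate",
    "steady_state",
    "SteadyResult",
    "Trajectory",
]


class SolverError(RuntimeError):
    """Numerical failure during time stepping or the steady solve."""


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class TransportParams:
    """Physical transport constants (SI units).

    ``D_vs`` — solute diffusivity in viable skin (m²/s); ``D_p`` — diffusivity
    in the plexus pores (defaults to ``D_vs``); ``v_b`` — blood speed along the
    capillary-loop centerline (m/s, physiological 0.65 ± 0.3 mm/s); ``k_p`` —
    endothelial permeability of the loop wall (m/s); ``J_sc`` — constant applied
    flux from the stratum corneum at z = 0 (amount·m⁻²·s⁻¹, normalized to 1);
    ``k1``/``k2`` — venule→arteriole / arteriole→venule plexus exchange
    velocities (default: the inter-layer diffusion estimate
    ``D_p / (plexus_total_thickness / 2)``); ``k_pcl`` — loop-outlet→venule
    plexus transfer velocity (default: ``v_b``, convective delivery).
    """

    D_vs: float = 1e-10
    D_p: float | None = None
    v_b: float = 6.5e-4
    k_p: float = 1e-6
    J_sc: float = 1.0
    k1: float | None = None
    k2: float | None = None
    k_pcl: float | None = None

    def __post_init__(self) -> None:
        if self.D_vs <= 0:
            raise ValueError(f"D_vs must be positive, got {self.D_vs}")
        for name in ("D_p", "v_b", "k_p", "J_sc", "k1", "k2", "k_pcl"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")

    def resolve(self, geom: SkinGeometry) -> "ResolvedParams":
        d_p = self.D_vs if self.D_p is None else self.D_p
        half = 0.5 * geom.params.plexus_total_thickness * UM
        k_diff = d_p / half if half > 0 else 0.0
        return ResolvedParams(
            D_vs=self.D_vs,
            D_p=d_p,
            v_b=self.v_b,
            k_p=self.k_p,
            J_sc=self.J_sc,
            k1=k_diff if self.k1 is None else self.k1,
            k2=k_diff if self.k2 is None else self.k2,
            k_pcl=self.v_b if self.k_pcl is None else self.k_pcl,
        )


@dataclass(frozen=True)
class ResolvedParams:
    D_vs: float
    D_p: float
    v_b: float
    k_p: float
    J_sc: float
    k1: float
    k2: float
    k_pcl: float


@dataclass
class SimState:
    """Concentrations at one time point.

    ``C_vs`` is the full (nx, ny, nz) tissue field (zeros at lumen/plexus
    nodes), ``C_b`` the lumen concentration per centerline station, and
    ``C_vp``/``C_ap`` the two plexus compartment scalars. Units are
    amount·m⁻³ with time in seconds.
    """

    time: float
    C_vs: np.ndarray
    C_b: np.ndarray
    C_vp: float
    C_ap: float

    @classmethod
    def zeros(cls, grid: LabeledGrid) -> "SimState":
        return cls(
            time=0.0,
            C_vs=np.zeros(grid.shape),
            C_b=np.zeros(grid.n_stations),
            C_vp=0.0,
            C_ap=0.0,
        )


@dataclass
class Operators:
    """Assembled discrete system du/dt = A u + b with bookkeeping vectors."""

    grid: LabeledGrid
    params: ResolvedParams
    coupling: PlexusCoupling | None
    bottom_bc: str
    n_t: int
    unknown_index: np.ndarray  # (nx,ny,nz) int, -1 at non-diffusive nodes
    A: sp.csr_matrix
    A_diff: sp.csr_matrix
    b: np.ndarray
    V: np.ndarray  # per-unknown volume (m³)
    removal: np.ndarray  # removal rate = removal @ u (amount/s)
    ds_m: np.ndarray  # station arclength (m)
    inlet_func: Callable[[float], float] | None = None
    _lu: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def i_vp(self) -> int:
        return self.n - 2

    @property
    def i_ap(self) -> int:
        return self.n - 1

    def pack(self, state: SimState) -> np.ndarray:
        u = np.empty(self.n)
        u[: self.n_t] = state.C_vs[self.unknown_index >= 0]
        ns = len(self.ds_m)
        u[self.n_t : self.n_t + ns] = state.C_b
        u[self.i_vp] = state.C_vp
        u[self.i_ap] = state.C_ap
        return u

    def unpack(self, u: np.ndarray, time: float) -> SimState:
        c_vs = np.zeros(self.grid.shape)
        c_vs[self.unknown_index >= 0] = u[: self.n_t]
        ns = len(self.ds_m)
        return SimState(
            time=time,
            C_vs=c_vs,
            C_b=u[self.n_t : self.n_t + ns].copy(),
            C_vp=float(u[self.i_vp]),
            C_ap=float(u[self.i_ap]),
        )

    def total_mass(self, u: np.ndarray) -> float:
        return float(self.V @ u)

    def influx_rate(self) -> float:
        return float(self.V @ self.b)

    def removal_rate(self, u: np.ndarray) -> float:
        return float(self.removal @ u)

    def rhs(self, u: np.ndarray, t: float = 0.0) -> np.ndarray:
        return self.A @ u + self._b_t(t)

    def _b_t(self, t: float) -> np.ndarray:
        if self.inlet_func is None or len(self.ds_m) == 0 or self.params.v_b == 0:
            return self.b
        b = self.b.copy()
        b[self.n_t] += self.params.v_b / self.ds_m[0] * self.inlet_func(t)
        return b

    def advective_cfl_dt(self) -> float:
        if len(self.ds_m) == 0 or self.params.v_b == 0:
            return np.inf
        return float(np.min(self.ds_m) / self.params.v_b)

    def explicit_diffusion_dt(self) -> float:
        g = self.grid
        d = max(self.params.D_vs, self.params.D_p)
        s = sum(1.0 / (h * UM) ** 2 for h in (g.dx, g.dy, g.dz))
        return 1.0 / (2.0 * d * s)

    def default_dt(self, scheme: str = "imex") -> float:
        """Automatic step: half the advective CFL bound, capped by the fastest
        explicit coupling rate (and the diffusion bound for the explicit
        scheme)."""
        dt = 0.5 * self.advective_cfl_dt()
        A_rest = self.A - self.A_diff
        diag = -A_rest.diagonal()
        rate = float(np.max(diag)) if diag.size else 0.0
        if rate > 0:
            dt = min(dt, 0.5 / rate)
        if scheme == "explicit":
            dt = min(dt, 0.5 * self.explicit_diffusion_dt())
        if not np.isfinite(dt):
            dt = 0.5 * self.explicit_diffusion_dt()
        return dt


def _diffusion_entries(grid: LabeledGrid, params: ResolvedParams, unknown_index, bottom_bc):
    """COO entries of the 7-point diffusion operator (rate units, 1/s)."""
    lab = grid.labels
    U = unknown_index
    dcoef = np.where(lab == Label.PORE, params.D_p, params.D_vs)
    hx, hy, hz = grid.dx * UM, grid.dy * UM, grid.dz * UM
    rows, cols, vals = [], [], []

    def add_pairs(ui, uj, gij):
        m = (ui >= 0) & (uj >= 0)
        i, j, g = ui[m], uj[m], gij[m]
        rows.extend([i, i, j, j])
        cols.extend([j, i, i, j])
        vals.extend([g, -g, g, -g])

    for axis, h in ((0, hx), (1, hy)):
        Un = np.roll(U, -1, axis=axis)
        dn = np.roll(dcoef, -1, axis=axis)
        g = 2.0 * dcoef * dn / (dcoef + dn) / h**2
        add_pairs(U, Un, g)
    # z axis: non-periodic
    Ui = U[:, :, :-1]
    Uj = U[:, :, 1:]
    di = dcoef[:, :, :-1]
    dj = dcoef[:, :, 1:]
    g = 2.0 * di * dj / (di + dj) / hz**2
    add_pairs(Ui, Uj, g)

    if bottom_bc == "sink":
        Ub = U[:, :, -1]
        db = dcoef[:, :, -1]
        m = Ub >= 0
        rows.append(Ub[m])
        cols.append(Ub[m])
        vals.append(-2.0 * db[m] / hz**2)
    elif bottom_bc != "no_flux":
        raise ValueError(f"unknown bottom_bc {bottom_bc!r}")

    rows = np.concatenate([np.ravel(r) for r in rows]) if rows else np.array([], int)
    cols = np.concatenate([np.ravel(c) for c in cols]) if cols else np.array([], int)
    vals = np.concatenate([np.ravel(v) for v in vals]) if vals else np.array([])
    return rows, cols, vals


def _station_neighbors(grid: LabeledGrid, nodes) -> list[tuple[int, int, int]]:
    """Diffusive 6-neighbours of a station's lumen cells (periodic laterally)."""
    nx, ny, nz = grid.shape
    lab = grid.labels
    out = set()
    for (ix, iy, iz) in nodes:
        for dxi, dyi, dzi in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            jx, jy, jz = (ix + dxi) % nx, (iy + dyi) % ny, iz + dzi
            if not 0 <= jz < nz:
                continue
            if lab[jx, jy, jz] in Label.DIFFUSIVE:
                out.add((jx, jy, jz))
    return sorted(out)


def assemble_operators(
    grid: LabeledGrid,
    params: TransportParams | ResolvedParams,
    coupling: PlexusCoupling | None = None,
    bottom_bc: str = "no_flux",
    inlet_func: Callable[[float], float] | None = None,
) -> Operators:
    """Assemble the coupled linear system for a labelled grid.

    ``coupling`` may be omitted for lumen-free verification grids, in which
    case the compartment unknowns are carried but decoupled. Requesting a
    ``dt`` that violates the advective CFL bound is flagged at step time, not
    here.
    """
    if isinstance(params, TransportParams):
        params = params.resolve(grid.geom)
    if coupling is None and grid.n_stations > 0:
        coupling = build_coupling(grid, params.v_b)

    lab = grid.labels
    diffusive = np.isin(lab, Label.DIFFUSIVE)
    n_t = int(np.count_nonzero(diffusive))
    U = np.full(grid.shape, -1, dtype=np.int64)
    U[diffusive] = np.arange(n_t)

    ns = grid.n_stations
    n = n_t + ns + 2
    i_vp, i_ap = n - 2, n - 1
    hx, hy, hz = grid.dx * UM, grid.dy * UM, grid.dz * UM
    v_cell = hx * hy * hz
    ds_m = grid.lumen_ds * UM

    rows, cols, vals = _diffusion_entries(grid, params, U, bottom_bc)
    A_diff = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    r2, c2, v2 = [], [], []

    def add(i, j, g):
        r2.append(i)
        c2.append(j)
        v2.append(g)

    a_cl = coupling.A_cl if coupling is not None else 0.0
    v_lum = a_cl * ds_m if ns else np.array([])

    # lumen advection (conservative first-order upwind) and endothelial exchange
    if ns and params.v_b > 0:
        for i in range(ns):
            add(n_t + i, n_t + i, -params.v_b / ds_m[i])
            if i > 0:
                add(n_t + i, n_t + i - 1, params.v_b / ds_m[i])
            elif inlet_func is None:
                add(n_t, i_ap, params.v_b / ds_m[0])
    if ns and params.k_p > 0:
        d_lum = grid.geom.params.lumen_diameter * UM
        for i in range(ns):
            nbrs = _station_neighbors(grid, grid.station_nodes[i])
            if not nbrs:
                continue
            a_per = np.pi * d_lum * ds_m[i] / len(nbrs)
            for node in nbrs:
                j = int(U[node])
                add(j, n_t + i, params.k_p * a_per / v_cell)
                add(j, j, -params.k_p * a_per / v_cell)
                add(n_t + i, j, params.k_p * a_per / v_lum[i])
                add(n_t + i, n_t + i, -params.k_p * a_per / v_lum[i])

    removal = np.zeros(n)
    if coupling is not None:
        cpl = coupling
        fa = cpl.face_area
        # tissue <-> compartment exchange across the horizontal interfaces
        for node in cpl.vp_tissue_nodes:
            j = int(U[node])
            add(j, i_vp, params.k_p * fa / v_cell)
            add(j, j, -params.k_p * fa / v_cell)
            add(i_vp, j, params.k_p * fa / cpl.V_vp)
            add(i_vp, i_vp, -params.k_p * fa / cpl.V_vp)
        for node in cpl.ap_tissue_nodes:
            j = int(U[node])
            add(j, i_ap, params.k_p * fa / v_cell)
            add(j, j, -params.k_p * fa / v_cell)
            add(i_ap, j, params.k_p * fa / cpl.V_ap)
            add(i_ap, i_ap, -params.k_p * fa / cpl.V_ap)
        # inter-compartment capillary exchange
        add(i_vp, i_ap, params.k2 * cpl.A_int / cpl.V_vp)
        add(i_vp, i_vp, -params.k1 * cpl.A_int / cpl.V_vp)
        add(i_ap, i_vp, params.k1 * cpl.A_int / cpl.V_ap)
        add(i_ap, i_ap, -params.k2 * cpl.A_int / cpl.V_ap)
        if ns:
            # loop outlet delivers to the venule plexus; inlet draws from the
            # arteriole plexus (the advective inflow assembled above); k_e
            # removes to the systemic circulation
            add(i_vp, n_t + ns - 1, params.k_pcl * cpl.A_cl / cpl.V_vp)
            add(i_ap, i_ap, -(params.v_b * cpl.A_cl + cpl.k_e) / cpl.V_ap)
            removal[i_ap] = cpl.k_e
            removal[n_t + ns - 1] = (params.v_b - params.k_pcl) * cpl.A_cl
        else:
            add(i_ap, i_ap, -cpl.k_e / cpl.V_ap)
            removal[i_ap] = cpl.k_e

    A_rest = sp.coo_matrix((v2, (r2, c2)), shape=(n, n)).tocsr()
    A = (A_diff + A_rest).tocsr()

    b = np.zeros(n)
    if params.J_sc != 0:
        top = U[:, :, 0]
        b[top[top >= 0]] = params.J_sc / hz

    V = np.empty(n)
    V[:n_t] = v_cell
    if ns:
        V[n_t : n_t + ns] = v_lum
    V[i_vp] = coupling.V_vp if coupling is not None else v_cell
    V[i_ap] = coupling.V_ap if coupling is not None else v_cell

    return Operators(
        grid=grid,
        params=params,
        coupling=coupling,
        bottom_bc=bottom_bc,
        n_t=n_t,
        unknown_index=U,
        A=A,
        A_diff=A_diff,
        b=b,
        V=V,
        removal=removal,
        ds_m=ds_m,
        inlet_func=inlet_func,
    )


def _factorize(ops: Operators, key: str, dt: float, mat: sp.spmatrix):
    tag = (key, float(dt))
    if tag not in ops._lu:
        ops._lu[tag] = spla.splu((sp.identity(ops.n, format="csc") - dt * mat.tocsc()))
    return ops._lu[tag]


def step(state: SimState, dt: float, ops: Operators, scheme: str = "imex") -> SimState:
    """Advance one time step.

    Schemes: ``imex`` (implicit diffusion, explicit advection/exchange;
    default), ``explicit`` (forward Euler throughout; used for verification),
    ``implicit`` (backward Euler on the full coupled operator; unconditionally
    stable and positivity-preserving, for long transients).
    """
    if dt <= 0:
        raise SolverError(f"dt must be positive, got {dt}")
    if scheme in ("imex", "explicit"):
        cfl = ops.advective_cfl_dt()
        if dt > cfl * (1 + 1e-12):
            raise SolverError(
                f"dt={dt:g} s violates the advective CFL bound {cfl:g} s "
                f"(v_b={ops.params.v_b:g} m/s, min ds={np.min(ops.ds_m):g} m)"
            )
    if scheme == "explicit" and dt > ops.explicit_diffusion_dt() * (1 + 1e-12):
        raise SolverError(
            f"dt={dt:g} s violates the explicit diffusion stability bound "
            f"{ops.explicit_diffusion_dt():g} s"
        )

    u = ops.pack(state)
    b_t = ops._b_t(state.time)
    if scheme == "explicit":
        u1 = u + dt * (ops.A @ u + b_t)
    elif scheme == "imex":
        rhs = u + dt * ((ops.A - ops.A_diff) @ u + b_t)
        u1 = _factorize(ops, "diff", dt, ops.A_diff).solve(rhs)
    elif scheme == "implicit":
        u1 = _factorize(ops, "full", dt, ops.A).solve(u + dt * b_t)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    if not np.all(np.isfinite(u1)):
        raise SolverError(f"non-finite concentration after step at t={state.time:g} s")
    floor = -1e-9 * max(1.0, float(np.max(np.abs(u1))))
    if np.min(u1) < floor:
        raise SolverError(
            f"negative concentration {np.min(u1):g} after step at t={state.time:g} s; "
            "reduce dt"
        )
    np.clip(u1, 0.0, None, out=u1)
    return ops.unpack(u1, state.time + dt)


@dataclass
class Trajectory:
    """Simulation output: states at the requested times plus a mass-balance log."""

    states: list[SimState]
    log: pd.DataFrame
    ops: Operators

    @property
    def final(self) -> SimState:
        return self.states[-1]


def simulate(
    geom: SkinGeometry,
    params: TransportParams | ResolvedParams,
    resolution: float | Sequence[float],
    t_end: float,
    output_times: Sequence[float] | None = None,
    scheme: str = "imex",
    dt: float | None = None,
    bottom_bc: str = "no_flux",
    grid: LabeledGrid | None = None,
) -> Trajectory:
    """Integrate from the zero initial state to ``t_end``.

    States are recorded at ``output_times`` (default: just 0 and ``t_end``);
    each record logs the running mass balance
    ``total mass - (cumulative influx - cumulative removal)`` relative to the
    cumulative influx.
    """
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    if grid is None:
        grid = classify_nodes(geom, resolution)
    ops = assemble_operators(grid, params, bottom_bc=bottom_bc)
    state = SimState.zeros(grid)

    out_times = sorted(set([t_end] + list(output_times or [])))
    if t_end == 0 or (out_times and out_times[-1] == 0):
        log = _log_row_frame([_log_row(ops, state, 0.0, 0.0)])
        return Trajectory(states=[state], log=log, ops=ops)

    if dt is None:
        dt = ops.default_dt(scheme)
    influx = ops.influx_rate()
    cum_in = 0.0
    cum_out = 0.0
    states = []
    rows = []
    t = 0.0
    for t_out in out_times:
        if t_out <= t:
            states.append(state)
            rows.append(_log_row(ops, state, cum_in, cum_out))
            continue
        n_steps = max(1, int(np.ceil((t_out - t) / dt - 1e-12)))
        dt_local = (t_out - t) / n_steps
        for _ in range(n_steps):
            u_before = ops.pack(state)
            state = step(state, dt_local, ops, scheme=scheme)
            # accumulate the exact discrete budget for the scheme in use
            if scheme == "implicit":
                cum_out += dt_local * ops.removal_rate(ops.pack(state))
            else:
                cum_out += dt_local * ops.removal_rate(u_before)
            cum_in += dt_local * influx
        t = t_out
        states.append(state)
        rows.append(_log_row(ops, state, cum_in, cum_out))
    return Trajectory(states=states, log=_log_row_frame(rows), ops=ops)


def _log_row(ops: Operators, state: SimState, cum_in: float, cum_out: float):
    mass = ops.total_mass(ops.pack(state))
    resid = mass - (cum_in - cum_out)
    rel = abs(resid) / cum_in if cum_in > 0 else abs(resid)
    return {
        "time_s": state.time,
        "total_mass": mass,
        "cumulative_influx": cum_in,
        "cumulative_removal": cum_out,
        "mass_residual": resid,
        "mass_residual_rel_influx": rel,
    }


def _log_row_frame(rows):
    return pd.DataFrame(rows)


@dataclass
class SteadyResult:
    """Steady-state solution plus convergence diagnostics.

    ``criterion`` is the operational steadiness measure: the maximum rate of
    change over the state, scaled by the slab diffusion time and the field
    magnitude. ``converged`` is False when no steady state exists (e.g. pure
    accumulation with no removal pathway) or the solve failed.
    """

    state: SimState
    converged: bool
    criterion: float
    tol: float
    residual_norm: float
    grid: LabeledGrid
    coupling: PlexusCoupling | None
    ops: Operators


def steady_state(
    geom: SkinGeometry,
    params: TransportParams | ResolvedParams,
    resolution: float | Sequence[float],
    tol: float = 1e-6,
    bottom_bc: str = "no_flux",
    grid: LabeledGrid | None = None,
) -> SteadyResult:
    """Solve the steady coupled system ``A u = -b`` directly.

    The solution is verified against the operational criterion: the maximum
    residual rate of change, multiplied by the characteristic slab diffusion
    time ``L²/D_vs`` and divided by the field magnitude, must fall below
    ``tol``. Systems with no removal pathway have no steady state; the result
    is then flagged ``converged=False`` with a warning.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if grid is None:
        grid = classify_nodes(geom, resolution)
    ops = assemble_operators(grid, params, bottom_bc=bottom_bc)
    A = ops.A.tocsr()

    # Unknowns in connectivity components that the applied flux never reaches
    # (e.g. a stagnant impermeable lumen, or compartments decoupled by k_p = 0)
    # stay at their zero initial value; replace their rows by identity so the
    # reachable subsystem decides solvability.
    from scipy.sparse.csgraph import connected_components

    _, comp = connected_components(A + A.T, directed=False)
    live = np.unique(comp[ops.b != 0]) if np.any(ops.b != 0) else np.array([], int)
    dead = ~np.isin(comp, live)
    if dead.any():
        keep = sp.diags((~dead).astype(float))
        A = (keep @ A + sp.diags(-dead.astype(float))).tocsr()

    u = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", spla.MatrixRankWarning)
            u = spla.spsolve(A.tocsc(), -ops.b)
    except RuntimeError:
        u = None
    if u is None or not np.all(np.isfinite(u)):
        warnings.warn("steady solve failed (singular system); no steady state", ConvergenceWarning)
        state = SimState.zeros(grid)
        return SteadyResult(state, False, np.inf, tol, np.inf, grid, ops.coupling, ops)

    resid = ops.A @ u + ops.b
    scale = float(np.max(np.abs(u)))
    tau = (geom.params.slab_depth * UM) ** 2 / ops.params.D_vs
    criterion = float(np.max(np.abs(resid))) * tau / (scale if scale > 0 else 1.0)
    # a true steady state also balances the global mass budget (influx equals
    # the sum of every removal pathway); a singular accumulating system can
    # fake a small pointwise residual at huge field values but not this
    influx = abs(float(ops.V @ ops.b))
    imbalance = abs(float(ops.V @ resid))
    balanced = imbalance <= 1e-8 * influx if influx > 0 else True
    nonneg = float(np.min(u)) >= -1e-9 * max(scale, 1.0)
    converged = bool(criterion < tol and balanced and nonneg)
    if not converged:
        warnings.warn(
            f"no steady state reached (criterion {criterion:g} vs tol {tol:g}, "
            f"mass-rate imbalance {imbalance:g} vs influx {influx:g}); "
            "flagged non-converged",
            ConvergenceWarning,
        )
    u = np.where(np.abs(u) < 1e-14 * max(scale, 1.0), 0.0, u)
    state = ops.unpack(np.clip(u, 0.0, None), time=np.inf)
    return SteadyResult(
        state, converged, criterion, tol, float(np.linalg.norm(resid)), grid, ops.coupling, ops
    )


def standard_geometry(**overrides) -> SkinGeometry:
    """Unit cell at the printed standard parameter set (overridable)."""
    return build_unit_cell(GeometryParams(**overrides))
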