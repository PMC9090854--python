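"""Sensitivity sweeps and depth-profile extraction.

Provides the four physiological sweeps — total plexus size, plexus depth,
capillary blood velocity and plexus pore density — together with the profile
samplers used to read them out: concentration vs depth along vertical lines
adjacent to the arteriole or venule limb of the capillary loop (or laterally
averaged), and the plexus-mean concentration ``C_plex`` that the response
regressions summarize.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import GeometryParams, Label, LabeledGrid, build_unit_cell
from .plexus import UM, PlexusCoupling
from .transport import SimState, TransportParams, simulate, steady_state

__all__ = [
    "DepthProfile",
    "SweepResult",
    "depth_profile",
    "plexus_mean_concentration",
    "top_bottom_ratio",
    "band_ratio_sensitivity",
    "run_sweep",
    "STANDARD_VELOCITY_FRACTIONS",
]

# the velocity sweep uses these multiples of the standard 0.65 mm/s
STANDARD_VELOCITY_FRACTIONS = (0.1, 0.25, 0.5, 0.75, 1.0)

LINE_TAGS = ("arteriole_adjacent", "venule_adjacent", "lateral_mean")


@dataclass
class DepthProfile:
    """Concentration vs depth along one vertical sampling line.

    ``depths_um`` is strictly increasing from the top of the viable skin.
    Within the plexus layers the profile reports the respective compartment
    concentration (C_vp in the venule layer, C_ap in the arteriole layer); at
    nodes inside the capillary lumen it reports the local blood concentration.
    ``line_um`` is the lateral (x, y) position, or None for a lateral mean.
    """

    depths_um: np.ndarray
    concentrations: np.ndarray
    line_tag: str
    line_um: tuple[float, float] | None = None

    def __post_init__(self):
        d = np.asarray(self.depths_um, float)
        c = np.asarray(self.concentrations, float)
        if d.shape != c.shape:
            raise ValueError("depths and concentrations must have equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        self.depths_um = d
        self.concentrations = c

    def at_depth(self, z_um: float) -> float:
        return float(np.interp(z_um, self.depths_um, self.concentrations))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_um": self.depths_um,
                "concentration_per_m3": self.concentrations,
                "line_tag": self.line_tag,
                "x_um": self.line_um[0] if self.line_um else np.nan,
                "y_um": self.line_um[1] if self.line_um else np.nan,
            }
        )


def _adjacent_column(grid: LabeledGrid, tag: str) -> tuple[int, int]:
    """Sampling column one grid cell laterally inward of the named limb."""
    if grid.n_stations == 0:
        raise ValueError("grid has no capillary loop; no limb-adjacent line")
    nx = grid.shape[0]
    if tag == "arteriole_adjacent":
        ix, iy, _ = grid.station_nodes[0][0]
        return (ix + 1) % nx, iy
    ix, iy, _ = grid.station_nodes[-1][0]
    return (ix - 1) % nx, iy


def depth_profile(state: SimState, grid: LabeledGrid, tag: str) -> DepthProfile:
    """Sample a concentration-depth profile from a (near-)steady state.

    ``tag`` is ``arteriole_adjacent`` or ``venule_adjacent`` (vertical line one
    cell laterally from the lumen surface of that limb, on the papilla side) or
    ``lateral_mean`` (area-weighted average per depth: tissue and pore nodes,
    plus the compartment value over the vascular fraction of each plexus
    layer).
    """
    if tag not in LINE_TAGS:
        raise ValueError(f"unknown line tag {tag!r}; expected one of {LINE_TAGS}")
    zc = grid.z_centers()
    lab = grid.labels
    if tag == "lateral_mean":
        geom = grid.geom
        cell_area = geom.cell_length * geom.cell_width
        face = grid.dx * grid.dy
        vals = np.empty(grid.shape[2])
        for iz in range(grid.shape[2]):
            sl = lab[:, :, iz]
            dmask = np.isin(sl, Label.DIFFUSIVE)
            dsum = float(np.sum(state.C_vs[:, :, iz][dmask])) * face
            n_nondiff = sl.size - int(np.count_nonzero(dmask))
            if np.any(sl == Label.PLEXUS_VENULE):
                vals[iz] = (n_nondiff * face * state.C_vp + dsum) / cell_area
            elif np.any(sl == Label.PLEXUS_ARTERIOLE):
                vals[iz] = (n_nondiff * face * state.C_ap + dsum) / cell_area
            else:
                # lumen nodes excluded: mean over the tissue fraction
                n = int(np.count_nonzero(dmask))
                vals[iz] = dsum / (n * face) if n else np.nan
        return DepthProfile(zc, vals, tag, None)

    ix, iy = _adjacent_column(grid, tag)
    station_of = grid.station_of_node()
    vals = np.empty(grid.shape[2])
    for iz in range(grid.shape[2]):
        l = lab[ix, iy, iz]
        if l in Label.DIFFUSIVE:
            vals[iz] = state.C_vs[ix, iy, iz]
        elif l == Label.PLEXUS_VENULE:
            vals[iz] = state.C_vp
        elif l == Label.PLEXUS_ARTERIOLE:
            vals[iz] = state.C_ap
        else:  # lumen node on the sampling line (apex run): local blood value
            vals[iz] = state.C_b[station_of[(ix, iy, iz)]]
    x = (ix + 0.5) * grid.dx
    y = (iy + 0.5) * grid.dy
    return DepthProfile(zc, vals, tag, (x, y))


def plexus_mean_concentration(state: SimState, coupling: PlexusCoupling) -> float:
    """Volume-weighted mean of the two compartment concentrations (C_plex)."""
    return (coupling.V_vp * state.C_vp + coupling.V_ap * state.C_ap) / (
        coupling.V_vp + coupling.V_ap
    )


def top_bottom_ratio(
    profile: DepthProfile, plexus_bottom_um: float, band_um: float = 50.0
) -> float:
    """Below-plexus to top concentration ratio (fraction).

    Mean concentration over the ``band_um``-thick band immediately below the
    arteriole plexus layer, divided by the concentration at the top of the
    viable skin.
    """
    top = profile.concentrations[0]
    if top == 0:
        raise ValueError("top concentration is zero; ratio undefined")
    m = (profile.depths_um >= plexus_bottom_um) & (
        profile.depths_um < plexus_bottom_um + band_um
    )
    if not np.any(m):
        raise ValueError("profile does not cover the below-plexus band")
    return float(np.mean(profile.concentrations[m]) / top)


def band_ratio_sensitivity(
    profile: DepthProfile,
    plexus_bottom_um: float,
    bands_um: Sequence[float] = (25.0, 50.0, 75.0, 100.0),
) -> dict[float, float]:
    """Ratio as a function of the below-plexus band thickness."""
    return {b: top_bottom_ratio(profile, plexus_bottom_um, b) for b in bands_um}


@dataclass
class SweepResult:
    """One sensitivity sweep: per-value C_plex and depth profiles.

    ``parameter_values_si`` are in SI units (m, m/s, or a fraction);
    ``values`` echo the sweep input (μm for lengths). ``partial`` is True when
    any run failed to converge; ``failed_values`` lists the offending inputs.
    """

    parameter_name: str
    values: list[float]
    parameter_values_si: list[float]
    C_plex: list[float]
    profiles: list[dict[str, DepthProfile]]
    converged: list[bool]
    metadata: dict

    @property
    def partial(self) -> bool:
        return not all(self.converged)

    @property
    def failed_values(self) -> list[float]:
        return [v for v, ok in zip(self.values, self.converged) if not ok]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.parameter_name,
                "value": self.values,
                "value_si": self.parameter_values_si,
                "C_plex_per_m3": self.C_plex,
                "converged": self.converged,
            }
        )

    def long_frame(self) -> pd.DataFrame:
        frames = []
        for v, profs in zip(self.values, self.profiles):
            for tag, p in profs.items():
                f = p.to_frame()
                f.insert(0, "parameter", self.parameter_name)
                f.insert(1, "value", v)
                frames.append(f)
        return pd.concat(frames, ignore_index=True)


SWEEP_NAMES = ("plexus_size", "plexus_depth", "velocity", "pore_density")


def _sweep_configs(name, value, geometry: GeometryParams, transport: TransportParams):
    if name == "plexus_size":
        # scale both layers symmetrically about the standard plexus mid-depth
        mid = geometry.plexus_top_depth + 0.5 * geometry.plexus_total_thickness
        g = dc_replace(
            geometry,
            plexus_top_depth=mid - 0.5 * value,
            plexus_total_thickness=value,
            venule_layer_thickness=0.5 * value,
            arteriole_layer_thickness=0.5 * value,
        )
        return g, transport, value * UM
    if name == "plexus_depth":
        return dc_replace(geometry, plexus_top_depth=value), transport, value * UM
    if name == "velocity":
        return geometry, dc_replace(transport, v_b=value), value
    if name == "pore_density":
        return dc_replace(geometry, pore_density=value), transport, value
    raise ValueError(f"unknown sweep name {name!r}; expected one of {SWEEP_NAMES}")


def run_sweep(
    name: str,
    values: Sequence[float],
    geometry: GeometryParams | None = None,
    transport: TransportParams | None = None,
    resolution: float | Sequence[float] = 10.0,
    tol: float = 1e-6,
    protocol: str = "steady",
    t_eval: float = 5000.0,
    n_steps: int = 200,
) -> SweepResult:
    """Run one steady-state (or fixed-horizon) simulation per parameter value.

    All runs share the base configuration except the swept parameter. With
    ``protocol="steady"`` each run is the direct steady solve; with
    ``protocol="horizon"`` each run is a backward-Euler transient evaluated at
    ``t_eval`` seconds, which probes the filling regime of the deep dermis.
    """
    geometry = geometry if geometry is not None else GeometryParams()
    transport = transport if transport is not None else TransportParams()
    if protocol not in ("steady", "horizon"):
        raise ValueError(f"unknown protocol {protocol!r}")
    out_vals_si: list[float] = []
    cplex: list[float] = []
    profiles: list[dict[str, DepthProfile]] = []
    converged: list[bool] = []
    for v in values:
        g_par, t_par, v_si = _sweep_configs(name, v, geometry, transport)
        geom = build_unit_cell(g_par)
        if protocol == "steady":
            res = steady_state(geom, t_par, resolution, tol=tol)
            state, grid, cpl, ok = res.state, res.grid, res.coupling, res.converged
        else:
            tr = simulate(
                geom, t_par, resolution, t_end=t_eval, scheme="implicit", dt=t_eval / n_steps
            )
            state, grid, cpl, ok = tr.final, tr.ops.grid, tr.ops.coupling, True
        out_vals_si.append(v_si)
        cplex.append(plexus_mean_concentration(state, cpl) if cpl else np.nan)
        profiles.append({tag: depth_profile(state, grid, tag) for tag in LINE_TAGS})
        converged.append(bool(ok))
    return SweepResult(
        parameter_name=name,
        values=list(values),
        parameter_values_si=out_vals_si,
        C_plex=cplex,
        profiles=profiles,
        converged=converged,
        metadata={
            "resolution_um": resolution,
            "tol": tol,
            "protocol": protocol,
            "t_eval_s": t_eval if protocol == "horizon" else None,
            "pore_seed": geometry.pore_seed,
        },
    )
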