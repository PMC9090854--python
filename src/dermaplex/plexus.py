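"""Well-stirred venule/arteriole plexus compartments and their couplings.

The subpapillary plexus is represented by two spatially uniform compartments
stacked below the capillary loops: the venule layer (top, receiving the loop
outflow) and the arteriole layer (bottom, feeding the loop inlet and draining
to the systemic circulation). Each obeys a volumetric balance with transfer
velocities (m/s) acting over interface areas:

    V_vp dC_vp/dt =  k_p A_vp (<C_vs>_top - C_vp) + A_int (k2 C_ap - k1 C_vp)
                     + k_pcl A_cl C_b(outlet)
    V_ap dC_ap/dt =  k_p A_ap (<C_vs>_bot - C_ap) + A_int (k1 C_vp - k2 C_ap)
                     - v_b A_cl C_ap - k_e C_ap

with k_e = v_b A_cl. Every transfer term appears with opposite sign in exactly
one donor and one recipient balance; only the systemic removal k_e C_ap (and,
when k_pcl != v_b, the un-captured part of the loop outflow) leaves the system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Label, LabeledGrid

__all__ = [
    "PlexusCoupling",
    "lumen_cross_section",
    "build_coupling",
    "plexus_rhs",
    "plexus_rhs_components",
]

UM = 1e-6  # metre per micrometre


def lumen_cross_section(grid: LabeledGrid) -> float:
    """Discrete cross-sectional area of the capillary loop lumen (m²).

    Counts the lumen nodes in one transverse station slice of the arteriole
    limb and multiplies by the lateral cell area, mirroring the way a
    cross-section is measured by integrating over the rasterized vessel. The
    result is within one cell area of the circular π r² value and converges to
    it under refinement.
    """
    if grid.n_stations == 0 or all(len(n) == 0 for n in grid.station_nodes):
        raise ValueError("grid contains no lumen nodes; cannot measure a cross-section")
    art = [i for i in range(grid.n_stations) if grid.station_is_arteriole[i]]
    mid = art[len(art) // 2]
    n = len(grid.station_nodes[mid])
    return n * (grid.dx * UM) * (grid.dy * UM)


@dataclass(frozen=True)
class PlexusCoupling:
    """Geometric coupling constants and interface node sets (SI units).

    ``vp_tissue_nodes`` are the tissue nodes immediately above the venule
    layer and ``ap_tissue_nodes`` those immediately below the arteriole layer
    (non-pore columns only: pore columns bypass the compartments by straight
    diffusion). ``inlet_station``/``outlet_station`` index the lumen chain ends.
    """

    V_vp: float
    V_ap: float
    A_vp: float
    A_ap: float
    A_int: float
    A_cl: float
    k_e: float
    face_area: float
    vp_tissue_nodes: tuple[tuple[int, int, int], ...]
    ap_tissue_nodes: tuple[tuple[int, int, int], ...]
    inlet_station: int
    outlet_station: int


def build_coupling(grid: LabeledGrid, v_b: float) -> PlexusCoupling:
    """Derive compartment volumes, areas and interface node sets from the grid."""
    geom = grid.geom
    p = geom.params
    cell_area = geom.cell_length * geom.cell_width * UM * UM
    pore_area = geom.pore_area_fraction * cell_area
    a_int = cell_area - pore_area
    v_vp = p.venule_layer_thickness * UM * a_int
    v_ap = p.arteriole_layer_thickness * UM * a_int
    if grid.n_stations == 0:
        raise ValueError("grid has no capillary loop; no lumen coupling to build")
    # geometric circular area: the rasterized count (lumen_cross_section) jumps
    # by whole cells under refinement, and k_e = v_b A_cl must not
    a_cl = np.pi * (0.5 * p.lumen_diameter * UM) ** 2

    zc = grid.z_centers()
    (v0, _), (_, a1) = geom.plexus_layer_bounds
    iz_above = int(np.searchsorted(zc, v0)) - 1  # deepest node above the venule layer
    iz_below = int(np.searchsorted(zc, a1))  # shallowest node below the arteriole layer
    if iz_above < 0 or iz_below >= grid.shape[2]:
        raise ValueError("plexus layers touch the slab boundary; no tissue interface")

    lab = grid.labels
    vp_nodes = []
    ap_nodes = []
    nx, ny, _ = grid.shape
    for ix in range(nx):
        for iy in range(ny):
            if lab[ix, iy, iz_above] in Label.DIFFUSIVE and lab[ix, iy, iz_above + 1] == Label.PLEXUS_VENULE:
                vp_nodes.append((ix, iy, iz_above))
            if lab[ix, iy, iz_below] in Label.DIFFUSIVE and lab[ix, iy, iz_below - 1] == Label.PLEXUS_ARTERIOLE:
                ap_nodes.append((ix, iy, iz_below))

    return PlexusCoupling(
        V_vp=v_vp,
        V_ap=v_ap,
        A_vp=a_int,
        A_ap=a_int,
        A_int=a_int,
        A_cl=a_cl,
        k_e=v_b * a_cl,
        face_area=grid.dx * grid.dy * UM * UM,
        vp_tissue_nodes=tuple(vp_nodes),
        ap_tissue_nodes=tuple(ap_nodes),
        inlet_station=0,
        outlet_station=grid.n_stations - 1,
    )


def plexus_rhs_components(
    c_vs_top: np.ndarray,
    c_vs_bot: np.ndarray,
    c_b_outlet: float,
    c_vp: float,
    c_ap: float,
    k_p: float,
    k1: float,
    k2: float,
    k_pcl: float,
    v_b: float,
    cpl: PlexusCoupling,
) -> dict[str, float]:
    """Individual transfer channels (amount/s) of the two compartment balances.

    Sign convention: a positive value adds mass to the compartment named in the
    key prefix. ``ap_loop_in`` is the convective draw into the loop inlet
    (always a loss to the arteriole plexus); ``ap_systemic`` is the removal to
    the systemic circulation, which leaves the modelled system entirely.
    """
    for name, v in (("k_p", k_p), ("k1", k1), ("k2", k2), ("k_pcl", k_pcl), ("v_b", v_b)):
        if v < 0:
            raise ValueError(f"rate coefficient {name} must be nonnegative, got {v}")
    fa = cpl.face_area
    return {
        "vp_tissue": k_p * fa * float(np.sum(np.asarray(c_vs_top) - c_vp)),
        "vp_inter": cpl.A_int * (k2 * c_ap - k1 * c_vp),
        "vp_loop_out": k_pcl * cpl.A_cl * c_b_outlet,
        "ap_tissue": k_p * fa * float(np.sum(np.asarray(c_vs_bot) - c_ap)),
        "ap_inter": cpl.A_int * (k1 * c_vp - k2 * c_ap),
        "ap_loop_in": -v_b * cpl.A_cl * c_ap,
        "ap_systemic": -cpl.k_e * c_ap,
    }


def plexus_rhs(
    c_vs_top: np.ndarray,
    c_vs_bot: np.ndarray,
    c_b_outlet: float,
    c_vp: float,
    c_ap: float,
    k_p: float,
    k1: float,
    k2: float,
    k_pcl: float,
    v_b: float,
    cpl: PlexusCoupling,
) -> tuple[float, float]:
    """(dC_vp/dt, dC_ap/dt) in amount·m⁻³·s⁻¹."""
    ch = plexus_rhs_components(
        c_vs_top, c_vs_bot, c_b_outlet, c_vp, c_ap, k_p, k1, k2, k_pcl, v_b, cpl
    )
    dvp = (ch["vp_tissue"] + ch["vp_inter"] + ch["vp_loop_out"]) / cpl.V_vp
    dap = (ch["ap_tissue"] + ch["ap_inter"] + ch["ap_loop_in"] + ch["ap_systemic"]) / cpl.V_ap
    return dvp, dap
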