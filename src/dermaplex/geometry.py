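"""Periodic unit-cell geometry of the papillary dermis.

The computational domain is one periodic unit cell of superficial skin: a slab of
viable tissue containing a single hairpin capillary loop (arteriole limb up,
horizontal apex run, venule limb down), two stacked well-stirred plexus layers
(venule layer on top of the arteriole layer), and avascular "pore" columns that
pierce both plexus layers and let solute diffuse past the vessels.

All geometric lengths are in micrometres; z is positive downward with z = 0 at
the top of the viable skin. Grid nodes are cell-centred with 0-based indices and
half-open layer intervals [top, bottom).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "GridResolutionError",
    "GeometryParams",
    "SkinGeometry",
    "LabeledGrid",
    "Label",
    "build_unit_cell",
    "place_pores",
    "classify_nodes",
]


class GeometryError(ValueError):
    """A geometry parameter violates its physical/consistency constraints."""


class GridResolutionError(ValueError):
    """The requested grid resolution cannot resolve the geometry."""


class Label:
    """Integer node labels; every grid node carries exactly one."""

    TISSUE = 0
    LUMEN_ARTERIOLE = 1
    LUMEN_VENULE = 2
    PLEXUS_VENULE = 3
    PLEXUS_ARTERIOLE = 4
    PORE = 5

    NAMES = {
        TISSUE: "tissue",
        LUMEN_ARTERIOLE: "lumen_arteriole_limb",
        LUMEN_VENULE: "lumen_venule_limb",
        PLEXUS_VENULE: "plexus_venule",
        PLEXUS_ARTERIOLE: "plexus_arteriole",
        PORE: "pore",
    }

    LUMEN = (LUMEN_ARTERIOLE, LUMEN_VENULE)
    PLEXUS = (PLEXUS_VENULE, PLEXUS_ARTERIOLE)
    DIFFUSIVE = (TISSUE, PORE)


@dataclass(frozen=True)
class GeometryParams:
    """Physiological geometry of the unit cell (lengths in μm).

    Defaults describe the papillary dermis of human skin: capillary loops
    reaching to 150 μm below the epidermal-dermal junction, 170 μm wide and
    70 μm apart, above a 50 μm subpapillary plexus whose top sits at 400 μm,
    inside an 800 μm slab. ``pore_density`` is the lateral area fraction of
    avascular channels through the plexus.
    """

    slab_depth: float = 800.0
    loop_apex_depth: float = 150.0
    loop_width: float = 170.0
    loop_spacing: float = 70.0
    loop_length: float = 215.0
    lumen_diameter: float = 10.0
    plexus_top_depth: float = 400.0
    plexus_total_thickness: float = 50.0
    arteriole_layer_thickness: float = 25.0
    venule_layer_thickness: float = 25.0
    pore_density: float = 0.11
    pore_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "slab_depth",
            "loop_apex_depth",
            "loop_width",
            "loop_spacing",
            "loop_length",
            "lumen_diameter",
            "plexus_top_depth",
            "plexus_total_thickness",
            "arteriole_layer_thickness",
            "venule_layer_thickness",
        ):
            if getattr(self, name) < 0:
                raise GeometryError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.plexus_top_depth + self.plexus_total_thickness >= self.slab_depth:
            raise GeometryError(
                "plexus_top_depth + plexus_total_thickness must be < slab_depth "
                f"({self.plexus_top_depth} + {self.plexus_total_thickness} >= {self.slab_depth})"
            )
        if self.loop_apex_depth >= self.plexus_top_depth:
            raise GeometryError(
                f"loop_apex_depth ({self.loop_apex_depth}) must be < plexus_top_depth "
                f"({self.plexus_top_depth})"
            )
        if not np.isclose(
            self.arteriole_layer_thickness + self.venule_layer_thickness,
            self.plexus_total_thickness,
        ):
            raise GeometryError(
                "arteriole_layer_thickness + venule_layer_thickness must equal "
                f"plexus_total_thickness ({self.arteriole_layer_thickness} + "
                f"{self.venule_layer_thickness} != {self.plexus_total_thickness})"
            )
        if not 0.0 <= self.pore_density <= 1.0:
            raise GeometryError(f"pore_density must be in [0, 1], got {self.pore_density}")


@dataclass(frozen=True)
class SkinGeometry:
    """Continuous description of the unit cell before discretization.

    ``loop_centerline`` is an arclength-ordered polyline (N×3, μm): it starts at
    the plexus top on the arteriole limb, rises to the apex, runs across, and
    descends the venule limb back to the plexus top. ``pore_footprints`` are
    axis-aligned lateral rectangles (x0, y0, x1, y1), non-overlapping, valid
    through both plexus layers.
    """

    params: GeometryParams
    cell_length: float
    cell_width: float
    loop_centerline: np.ndarray
    pore_footprints: tuple[tuple[float, float, float, float], ...]
    plexus_layer_bounds: tuple[tuple[float, float], tuple[float, float]]

    @property
    def venule_layer(self) -> tuple[float, float]:
        return self.plexus_layer_bounds[0]

    @property
    def arteriole_layer(self) -> tuple[float, float]:
        return self.plexus_layer_bounds[1]

    @property
    def centerline_min_depth(self) -> float:
        return float(np.min(self.loop_centerline[:, 2]))

    @property
    def pore_area_fraction(self) -> float:
        area = sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in self.pore_footprints)
        return area / (self.cell_length * self.cell_width)

    def arclength(self) -> np.ndarray:
        """Cumulative arclength (μm) at each centerline vertex."""
        seg = np.linalg.norm(np.diff(self.loop_centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def summary(self) -> str:
        p = self.params
        lines = [
            f"unit cell: {self.cell_length:g} x {self.cell_width:g} x {p.slab_depth:g} um",
            f"loop: apex {p.loop_apex_depth:g} um, width {p.loop_width:g} um, "
            f"lumen diameter {p.lumen_diameter:g} um, centerline length "
            f"{self.arclength()[-1]:g} um",
            f"venule plexus layer: [{self.venule_layer[0]:g}, {self.venule_layer[1]:g}) um",
            f"arteriole plexus layer: [{self.arteriole_layer[0]:g}, {self.arteriole_layer[1]:g}) um",
            f"pores: {len(self.pore_footprints)} footprints, area fraction "
            f"{self.pore_area_fraction:.4f} (target {p.pore_density:g})",
        ]
        return "\n".join(lines)


def build_unit_cell(params: GeometryParams) -> SkinGeometry:
    """Construct the periodic unit cell for one capillary loop.

    The lateral extent is ``loop_width + loop_spacing`` in both directions
    (square cell). The loop centerline is a planar U-shape at the cell's
    mid-``y`` plane; both limbs span from the plexus top up to the apex depth —
    where the nominal loop length ends short of the plexus, the venule limb is
    treated as extended vertically down to it by the larger vertical venules
    that drain the loop.
    """
    cell = params.loop_width + params.loop_spacing
    if cell <= 0:
        raise GeometryError("loop_width + loop_spacing must be positive")
    if params.loop_width >= cell:
        raise GeometryError("loop_spacing must be positive so limbs stay inside the cell")

    x_a = 0.5 * (cell - params.loop_width)
    x_v = x_a + params.loop_width
    y0 = 0.5 * cell
    z_top = params.loop_apex_depth
    z_plex = params.plexus_top_depth
    centerline = np.array(
        [
            [x_a, y0, z_plex],
            [x_a, y0, z_top],
            [x_v, y0, z_top],
            [x_v, y0, z_plex],
        ]
    )
    ven = (params.plexus_top_depth, params.plexus_top_depth + params.venule_layer_thickness)
    art = (ven[1], ven[1] + params.arteriole_layer_thickness)

    geom = SkinGeometry(
        params=params,
        cell_length=cell,
        cell_width=cell,
        loop_centerline=centerline,
        pore_footprints=(),
        plexus_layer_bounds=(ven, art),
    )
    return place_pores(geom, params.pore_density, params.pore_seed)


def _pore_lattice(cell_length: float, cell_width: float, target_tile: float = 10.0):
    nx = max(1, int(round(cell_length / target_tile)))
    ny = max(1, int(round(cell_width / target_tile)))
    return nx, ny, cell_length / nx, cell_width / ny


def place_pores(geom: SkinGeometry, density: float, seed: int) -> SkinGeometry:
    """Realize avascular pore columns at the requested lateral area fraction.

    Pores are whole tiles of a fixed ~10 μm lattice spanning the cell; a seeded
    permutation of the tiles fixes a priority order, and the first
    ``round(density * n_tiles)`` tiles become pores. This makes placement
    deterministic for a given seed, nested (monotone) in density, and accurate
    to within half a tile of the requested area fraction.
    """
    if not 0.0 <= density <= 1.0:
        raise GeometryError(f"pore density must be in [0, 1], got {density}")
    ntx, nty, tx, ty = _pore_lattice(geom.cell_length, geom.cell_width)
    n_tiles = ntx * nty
    k = int(round(density * n_tiles))
    order = np.random.default_rng(int(seed)).permutation(n_tiles)
    footprints = []
    for t in order[:k]:
        i, j = divmod(int(t), nty)
        footprints.append((i * tx, j * ty, (i + 1) * tx, (j + 1) * ty))
    footprints.sort()
    return replace(geom, pore_footprints=tuple(footprints))


# ---------------------------------------------------------------------------
# Discretization / node classification


@dataclass
class LabeledGrid:
    """Cell-centred structured grid with per-node region labels.

    The capillary lumen is carried as an ordered 1-D chain of "stations" along
    the centerline: ``station_nodes[i]`` is the list of (ix, iy, iz) grid nodes
    belonging to station ``i`` (≥1 node each), ``lumen_s``/``lumen_ds`` give the
    arclength position and length of each station (μm), and
    ``station_is_arteriole`` tags the limb. Station 0 is the arteriole-limb
    inlet at the plexus top; the last station is the venule-limb outlet.
    """

    geom: SkinGeometry
    dx: float
    dy: float
    dz: float
    labels: np.ndarray  # (nx, ny, nz) int8
    station_nodes: list[list[tuple[int, int, int]]]
    lumen_s: np.ndarray
    lumen_ds: np.ndarray
    station_is_arteriole: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_stations(self) -> int:
        return len(self.station_nodes)

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.shape[0]) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.shape[1]) + 0.5) * self.dy

    def z_centers(self) -> np.ndarray:
        return (np.arange(self.shape[2]) + 0.5) * self.dz

    def label_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {Label.NAMES[int(v)]: int(c) for v, c in zip(vals, counts)}

    def station_of_node(self) -> dict[tuple[int, int, int], int]:
        out: dict[tuple[int, int, int], int] = {}
        for i, nodes in enumerate(self.station_nodes):
            for n in nodes:
                out[n] = i
        return out


def _containing_index(coord: float, h: float, n: int) -> int:
    """Index of the cell whose half-open interval [i*h, (i+1)*h) contains coord."""
    return int(np.clip(np.floor(coord / h), 0, n - 1))


def _station_cells(
    axis_point: tuple[float, float],
    perp_axes: tuple[int, int],
    primary: tuple[int, int, int],
    k_extra: int,
    spacings: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> list[tuple[int, int, int]]:
    """Primary node plus the ``k_extra`` nearest perpendicular neighbours.

    Used to thicken the one-node-wide centerline raster so the discrete lumen
    cross-section approximates the circular π r² area. Ties are broken by
    (distance, offset) lexicographic order for determinism.
    """
    cells = [primary]
    if k_extra <= 0:
        return cells
    a1, a2 = perp_axes
    h1, h2 = spacings[a1], spacings[a2]
    cands = []
    for d1 in (-2, -1, 0, 1, 2):
        for d2 in (-2, -1, 0, 1, 2):
            if d1 == 0 and d2 == 0:
                continue
            idx = list(primary)
            idx[a1] += d1
            idx[a2] += d2
            if not (0 <= idx[a1] < shape[a1] and 0 <= idx[a2] < shape[a2]):
                continue
            c1 = (idx[a1] + 0.5) * h1
            c2 = (idx[a2] + 0.5) * h2
            dist = np.hypot(c1 - axis_point[0], c2 - axis_point[1])
            cands.append((dist, d1, d2, tuple(idx)))
    cands.sort()
    cells.extend(c[-1] for c in cands[:k_extra])
    return cells


def classify_nodes(
    geom: SkinGeometry, resolution: float | Sequence[float], include_loop: bool = True
) -> LabeledGrid:
    """Partition the grid nodes of the unit cell into labelled regions.

    ``resolution`` is either a scalar spacing or (dx, dy, dz) in μm; spacings
    must divide the cell extents. The lumen must be resolvable
    (``lumen_diameter >= max(dx, dy)``); each centerline station is rasterized
    to the containing grid node and thickened to ``round(π r² / (dx dy))``
    nodes so the discrete cross-sectional area tracks the circular one.
    ``include_loop=False`` builds an avascular grid (no lumen stations), used
    for closed-form and manufactured-solution verification runs.
    """
    p = geom.params
    if np.isscalar(resolution):
        dx = dy = dz = float(resolution)
    else:
        dx, dy, dz = (float(v) for v in resolution)
    for h, extent, name in (
        (dx, geom.cell_length, "dx"),
        (dy, geom.cell_width, "dy"),
        (dz, p.slab_depth, "dz"),
    ):
        if h <= 0:
            raise GridResolutionError(f"{name} must be positive")
        if abs(extent / h - round(extent / h)) > 1e-9:
            raise GridResolutionError(
                f"{name}={h} does not divide the cell extent {extent} um"
            )
    if include_loop and p.lumen_diameter < max(dx, dy) - 1e-12:
        raise GridResolutionError(
            f"lumen diameter {p.lumen_diameter} um unresolved at lateral spacing "
            f"{max(dx, dy)} um; use a grid at least as fine as the lumen diameter"
        )

    nx = int(round(geom.cell_length / dx))
    ny = int(round(geom.cell_width / dy))
    nz = int(round(p.slab_depth / dz))
    labels = np.full((nx, ny, nz), Label.TISSUE, dtype=np.int8)
    zc = (np.arange(nz) + 0.5) * dz

    # plexus layers, venule on top (loops drain into the venule plexus first)
    (v0, v1), (a0, a1) = geom.plexus_layer_bounds
    ven_mask = (zc >= v0) & (zc < v1)
    art_mask = (zc >= a0) & (zc < a1)
    labels[:, :, ven_mask] = Label.PLEXUS_VENULE
    labels[:, :, art_mask] = Label.PLEXUS_ARTERIOLE

    # pore columns pierce both layers
    xc = (np.arange(nx) + 0.5) * dx
    yc = (np.arange(ny) + 0.5) * dy
    layer_mask = ven_mask | art_mask
    for (fx0, fy0, fx1, fy1) in geom.pore_footprints:
        ix = (xc >= fx0) & (xc < fx1)
        iy = (yc >= fy0) & (yc < fy1)
        labels[np.ix_(ix, iy, layer_mask)] = Label.PORE

    if not include_loop:
        return LabeledGrid(
            geom=geom,
            dx=dx,
            dy=dy,
            dz=dz,
            labels=labels,
            station_nodes=[],
            lumen_s=np.array([]),
            lumen_ds=np.array([]),
            station_is_arteriole=np.array([], dtype=bool),
        )

    # capillary-loop stations: vertical arteriole limb (ascending), horizontal
    # apex run, vertical venule limb (descending); all above the plexus top
    x_a, y0, _ = geom.loop_centerline[0]
    x_v = geom.loop_centerline[-1][0]
    ix_a = _containing_index(x_a, dx, nx)
    ix_v = _containing_index(x_v, dx, nx)
    iy0 = _containing_index(y0, dy, ny)
    iz_apex = _containing_index(p.loop_apex_depth, dz, nz)
    iz_plex_top = int(np.ceil(p.plexus_top_depth / dz - 1e-9)) - 1  # deepest node above plexus
    if iz_plex_top <= iz_apex:
        raise GridResolutionError("grid too coarse to separate loop apex from plexus top")

    r = 0.5 * p.lumen_diameter
    k_total = max(1, int(round(np.pi * r * r / (dx * dy))))
    k_extra = k_total - 1

    stations: list[list[tuple[int, int, int]]] = []
    ds_list: list[float] = []
    # arteriole limb: from plexus top up to just below the apex row
    for iz in range(iz_plex_top, iz_apex, -1):
        stations.append(
            _station_cells((x_a, y0), (0, 1), (ix_a, iy0, iz), k_extra, (dx, dy, dz), (nx, ny, nz))
        )
        ds_list.append(dz)
    # apex run, arteriole corner to venule corner inclusive
    for ix in range(ix_a, ix_v + 1):
        stations.append(
            _station_cells((y0, p.loop_apex_depth), (1, 2), (ix, iy0, iz_apex), k_extra, (dx, dy, dz), (nx, ny, nz))
        )
        ds_list.append(dx)
    # venule limb: back down to the plexus top
    for iz in range(iz_apex + 1, iz_plex_top + 1):
        stations.append(
            _station_cells((x_v, y0), (0, 1), (ix_v, iy0, iz), k_extra, (dx, dy, dz), (nx, ny, nz))
        )
        ds_list.append(dz)

    ds = np.asarray(ds_list)
    s = np.cumsum(ds) - 0.5 * ds
    total = float(np.sum(ds))
    is_art = s < 0.5 * total

    # resolve overlaps: a node claimed by two stations stays with the first
    seen: set[tuple[int, int, int]] = set()
    for i, nodes in enumerate(stations):
        kept = []
        for n in nodes:
            if n in seen:
                continue
            seen.add(n)
            kept.append(n)
        stations[i] = kept
        lab = Label.LUMEN_ARTERIOLE if is_art[i] else Label.LUMEN_VENULE
        for (jx, jy, jz) in kept:
            labels[jx, jy, jz] = lab
    if any(len(n) == 0 for n in stations):
        # merge empty stations into their predecessor's arclength
        keep_idx = [i for i, n in enumerate(stations) if n]
        stations = [stations[i] for i in keep_idx]
        ds = ds[keep_idx]
        s = s[keep_idx]
        is_art = is_art[keep_idx]

    return LabeledGrid(
        geom=geom,
        dx=dx,
        dy=dy,
        dz=dz,
        labels=labels,
        station_nodes=stations,
        lumen_s=s,
        lumen_ds=ds,
        station_is_arteriole=is_art,
    )
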