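"""Hexagonal-cell reach geometry, habitat attributes and hydraulic lookups.

A reach is a honeycomb of equal-area, flat-topped hexagonal cells.  Each
cell carries static habitat attributes (velocity-shelter fraction, hiding
cover fraction, distance to hiding cover, spawning-gravel fraction, reach
end flag) and a hydraulic lookup table mapping discharge to cell-average
depth and velocity.  Depth and velocity at intermediate flows are obtained
by linear interpolation; outside the tabulated flow range values are
clamped to the nearest tabulated flow and a :class:`HydraulicRangeWarning`
is emitted.

The synthetic-reach generator emulates the habitat inputs of a restored
rapids reach below a dam: monotone power-law depth/velocity ratings with
seeded spatial variation, a contiguous spawning-gravel patch, and
upstream/downstream end cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon

from .core_math import ParameterError, ReachParams, default_reach_params

__all__ = [
    "SchemaError",
    "HydraulicRangeWarning",
    "Cell",
    "Reach",
    "build_hex_grid",
    "cell_hydraulics_at_flow",
    "read_cell_files",
    "write_cell_files",
    "generate_synthetic_reach",
    "STANDARD_DISCHARGES",
]

SQRT3 = math.sqrt(3.0)

#: the standard 20-discharge hydraulic lookup grid (m^3/s)
STANDARD_DISCHARGES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0,
                       7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 15.0, 20.0, 25.0, 30.0)


class SchemaError(ValueError):
    """Malformed or inconsistent cell input files."""


class HydraulicRangeWarning(UserWarning):
    """Flow outside the hydraulic lookup range; values clamped to the ends."""


@dataclass
class Cell:
    """One hexagonal habitat cell."""

    cellID: int
    centroid: Tuple[float, float]            # m
    corners: List[Tuple[float, float]]       # six (x, y) in m
    area: float                              # m^2
    cellFracShelter: float = 0.0
    cellFracHidingCover: float = 0.0
    cellDistToHide: float = 0.0              # cm
    cellFracSpawn: float = 0.0
    reachEnd: str = "I"                      # I (inside), U (upstream), D (downstream)
    neighbors: List[int] = field(default_factory=list)
    lookup_flows: np.ndarray = field(default_factory=lambda: np.empty(0))
    lookup_depth: np.ndarray = field(default_factory=lambda: np.empty(0))     # cm
    lookup_velocity: np.ndarray = field(default_factory=lambda: np.empty(0))  # cm/s

    def validate(self) -> None:
        for name in ("cellFracShelter", "cellFracHidingCover", "cellFracSpawn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SchemaError(f"cell {self.cellID}: {name}={v} outside [0, 1]")
        if self.area <= 0:
            raise SchemaError(f"cell {self.cellID}: non-positive area")
        if self.reachEnd not in ("I", "U", "D"):
            raise SchemaError(f"cell {self.cellID}: reachEnd must be I, U or D")
        if self.lookup_flows.size:
            if np.any(np.diff(self.lookup_flows) <= 0):
                raise SchemaError(f"cell {self.cellID}: lookup flows not increasing")
            if np.any(self.lookup_depth < 0) or np.any(self.lookup_velocity < 0):
                raise SchemaError(f"cell {self.cellID}: negative depth/velocity")


class Reach:
    """A collection of cells plus reach parameters, with vectorised access.

    Derived arrays (depth/velocity tables, centroids, habitat fractions,
    neighbour indices) are built once at construction and indexed by cell
    position; ``index_of`` maps cellID to position.
    """

    def __init__(self, cells: Sequence[Cell], params: ReachParams | None = None):
        if not cells:
            raise SchemaError("reach needs at least one cell")
        ids = [c.cellID for c in cells]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate cellID in reach")
        ends = {c.reachEnd for c in cells}
        if len(cells) > 1 and not {"U", "D"} <= ends:
            raise SchemaError("reach needs at least one U and one D cell")
        for c in cells:
            c.validate()

        self.cells = list(cells)
        self.params = params or default_reach_params()
        self.index_of = {c.cellID: i for i, c in enumerate(self.cells)}
        self.ids = np.asarray(ids, dtype=int)
        self.centroids = np.asarray([c.centroid for c in self.cells])          # m
        self.area_m2 = np.asarray([c.area for c in self.cells])
        self.area_cm2 = self.area_m2 * 1e4
        self.frac_shelter = np.asarray([c.cellFracShelter for c in self.cells])
        self.frac_hide = np.asarray([c.cellFracHidingCover for c in self.cells])
        self.dist_to_hide = np.asarray([c.cellDistToHide for c in self.cells])  # cm
        self.frac_spawn = np.asarray([c.cellFracSpawn for c in self.cells])
        self.reach_end = np.asarray([c.reachEnd for c in self.cells])
        self.neighbors_idx = [
            np.asarray([self.index_of[n] for n in c.neighbors if n in self.index_of],
                       dtype=int)
            for c in self.cells
        ]
        self.lookup_flows = np.asarray(self.cells[0].lookup_flows, dtype=float)
        if self.lookup_flows.size:
            self.depth_table = np.vstack([c.lookup_depth for c in self.cells])
            self.velocity_table = np.vstack([c.lookup_velocity for c in self.cells])
        else:
            self.depth_table = np.empty((len(self.cells), 0))
            self.velocity_table = np.empty((len(self.cells), 0))
        self._kdtree = cKDTree(self.centroids)

    def __len__(self) -> int:
        return len(self.cells)

    # hydraulics -----------------------------------------------------------
    def _interp_weights(self, flow: float) -> Tuple[int, int, float]:
        flows = self.lookup_flows
        if flows.size == 0:
            raise ParameterError("reach has no hydraulic lookup")
        if flow < 0:
            raise ParameterError("flow must be non-negative")
        if flow < flows[0] or flow > flows[-1]:
            warnings.warn(
                f"flow {flow} m3/s outside lookup range "
                f"[{flows[0]}, {flows[-1]}]; clamping",
                HydraulicRangeWarning, stacklevel=3)
            flow = min(max(flow, flows[0]), flows[-1])
        j = int(np.searchsorted(flows, flow, side="right")) - 1
        j = min(max(j, 0), flows.size - 2) if flows.size > 1 else 0
        if flows.size == 1:
            return 0, 0, 0.0
        frac = (flow - flows[j]) / (flows[j + 1] - flows[j])
        return j, j + 1, frac

    def depths_at(self, flow: float) -> np.ndarray:
        """Cell-average depth (cm) for every cell at the given flow."""
        j0, j1, w = self._interp_weights(flow)
        return (1 - w) * self.depth_table[:, j0] + w * self.depth_table[:, j1]

    def velocities_at(self, flow: float) -> np.ndarray:
        """Cell-average velocity (cm/s) for every cell at the given flow."""
        j0, j1, w = self._interp_weights(flow)
        return (1 - w) * self.velocity_table[:, j0] + w * self.velocity_table[:, j1]

    def cells_within(self, centroid_m: Tuple[float, float], radius_m: float) -> np.ndarray:
        """Indices of cells whose centroid lies within ``radius_m`` metres."""
        return np.asarray(
            self._kdtree.query_ball_point(centroid_m, radius_m), dtype=int)

    def gravel_area_cm2(self) -> float:
        return float(np.sum(self.frac_spawn * self.area_cm2))


def cell_hydraulics_at_flow(cell: Cell, flow: float) -> Tuple[float, float]:
    """Depth (cm) and velocity (cm/s) of one cell at a flow, interpolated.

    Clamps (with a :class:`HydraulicRangeWarning`) outside the lookup range.
    """
    if cell.lookup_flows.size == 0:
        raise ParameterError("cell has no hydraulic lookup")
    if flow < 0:
        raise ParameterError("flow must be non-negative")
    flows = np.asarray(cell.lookup_flows, dtype=float)
    if flow < flows[0] or flow > flows[-1]:
        warnings.warn(
            f"flow {flow} m3/s outside lookup range [{flows[0]}, {flows[-1]}]; "
            "clamping", HydraulicRangeWarning, stacklevel=2)
    depth = float(np.interp(flow, flows, cell.lookup_depth))
    vel = float(np.interp(flow, flows, cell.lookup_velocity))
    return depth, vel


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _hex_corners(cx: float, cy: float, side: float) -> List[Tuple[float, float]]:
    return [(cx + side * math.cos(math.pi / 3 * k),
             cy + side * math.sin(math.pi / 3 * k)) for k in range(6)]


def build_hex_grid(polygon, ew_spacing: float) -> List[Cell]:
    """Tile a polygon with flat-topped regular hexagons.

    The east-west centre spacing between adjacent columns is ``ew_spacing``
    metres, giving side length ``ew_spacing / 1.5`` and per-cell area
    ``(3*sqrt(3)/2) * (ew_spacing / 1.5)**2``.  Cells whose centroid falls
    inside the polygon are kept whole; adjacency is derived from shared
    edges (centre distance ``sqrt(3) * side``).
    """
    if ew_spacing <= 0:
        raise ParameterError("ew_spacing must be positive")
    if not isinstance(polygon, Polygon):
        try:
            polygon = Polygon(polygon)
        except Exception as exc:
            raise ParameterError(f"invalid polygon: {exc}") from exc
    if polygon.is_empty or polygon.area <= 0:
        raise ParameterError("polygon is degenerate")

    side = ew_spacing / 1.5
    row_h = SQRT3 * side
    area = 1.5 * SQRT3 * side * side

    minx, miny, maxx, maxy = polygon.bounds
    j0 = int(math.floor((minx - side) / ew_spacing))
    j1 = int(math.ceil((maxx + side) / ew_spacing))
    i0 = int(math.floor((miny - row_h) / row_h))
    i1 = int(math.ceil((maxy + row_h) / row_h))

    cells: List[Cell] = []
    keys = {}
    for j in range(j0, j1 + 1):
        yoff = 0.5 * row_h if (j % 2) else 0.0
        for i in range(i0, i1 + 1):
            cx = j * ew_spacing
            cy = i * row_h + yoff
            if polygon.covers(Point(cx, cy)):
                cid = len(cells)
                keys[(j, i)] = cid
                cells.append(Cell(
                    cellID=cid, centroid=(cx, cy),
                    corners=_hex_corners(cx, cy, side), area=area))

    # adjacency: six surrounding (column, row) offsets for flat-top hexes
    for (j, i), cid in keys.items():
        di_diag = 2 * (j % 2) - 1  # -1 for even columns, +1 for odd
        offs = [(0, 1), (0, -1),
                (1, 0), (-1, 0),
                (1, di_diag), (-1, di_diag)]
        for dj, di in offs:
            other = keys.get((j + dj, i + di))
            if other is not None:
                cells[cid].neighbors.append(other)
    for c in cells:
        c.neighbors.sort()
    return cells


# ---------------------------------------------------------------------------
# cell file I/O
# ---------------------------------------------------------------------------

def _polygon_area(corners) -> float:
    x = np.asarray([p[0] for p in corners])
    y = np.asarray([p[1] for p in corners])
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _recompute_adjacency(cells: List[Cell]) -> None:
    if len(cells) < 2:
        return
    c0 = cells[0]
    side = math.dist(c0.corners[0], c0.corners[1])
    thresh = SQRT3 * side * 1.01
    tree = cKDTree([c.centroid for c in cells])
    pairs = tree.query_pairs(thresh)
    for c in cells:
        c.neighbors = []
    for a, b in pairs:
        cells[a].neighbors.append(cells[b].cellID)
        cells[b].neighbors.append(cells[a].cellID)
    for c in cells:
        c.neighbors.sort()


def read_cell_files(geometry_path, habitat_path, hydraulics_path,
                    params: ReachParams | None = None) -> Reach:
    """Assemble a Reach from the three cell input tables.

    ``cellID`` is the join key; a cellID missing from any file, or
    duplicated, raises :class:`SchemaError`.
    """
    geo = pd.read_csv(geometry_path)
    hab = pd.read_csv(habitat_path)
    hyd = pd.read_csv(hydraulics_path)

    for name, df in (("geometry", geo), ("habitat", hab)):
        if df["cellID"].duplicated().any():
            dup = int(df.loc[df["cellID"].duplicated(), "cellID"].iloc[0])
            raise SchemaError(f"duplicate cellID {dup} in {name} file")

    geo_ids = set(geo["cellID"])
    for name, ids in (("habitat", set(hab["cellID"])),
                      ("hydraulics", set(hyd["cellID"]))):
        missing = geo_ids ^ ids if name == "habitat" else geo_ids - ids
        if missing:
            raise SchemaError(
                f"cellID {sorted(missing)[0]} missing/extra in {name} file")

    hab = hab.set_index("cellID")
    cells: List[Cell] = []
    for row in geo.itertuples(index=False):
        cid = int(row.cellID)
        corners = [(getattr(row, f"x{k}"), getattr(row, f"y{k}"))
                   for k in range(1, 7)]
        h = hab.loc[cid]
        sub = hyd[hyd["cellID"] == cid].sort_values("flow_m3s")
        if sub["flow_m3s"].duplicated().any():
            raise SchemaError(f"duplicate lookup flow for cell {cid}")
        cx = float(np.mean([p[0] for p in corners]))
        cy = float(np.mean([p[1] for p in corners]))
        cells.append(Cell(
            cellID=cid, centroid=(cx, cy), corners=corners,
            area=_polygon_area(corners),
            cellFracShelter=float(h["fracShelter"]),
            cellFracHidingCover=float(h["fracHide"]),
            cellDistToHide=float(h["distToHide_cm"]),
            cellFracSpawn=float(h["fracSpawn"]),
            reachEnd=str(h["reachEnd"]),
            lookup_flows=sub["flow_m3s"].to_numpy(float),
            lookup_depth=sub["depth_cm"].to_numpy(float),
            lookup_velocity=sub["velocity_cms"].to_numpy(float),
        ))
    _recompute_adjacency(cells)
    return Reach(cells, params)


def write_cell_files(reach: Reach, geometry_path, habitat_path, hydraulics_path) -> None:
    """Write the three cell tables (counterpart of :func:`read_cell_files`)."""
    geo_rows, hab_rows, hyd_rows = [], [], []
    for c in reach.cells:
        row = {"cellID": c.cellID}
        for k, (x, y) in enumerate(c.corners, start=1):
            row[f"x{k}"] = x
            row[f"y{k}"] = y
        geo_rows.append(row)
        hab_rows.append({
            "cellID": c.cellID, "fracShelter": c.cellFracShelter,
            "distToHide_cm": c.cellDistToHide, "fracSpawn": c.cellFracSpawn,
            "fracHide": c.cellFracHidingCover, "reachEnd": c.reachEnd})
        for q, d, v in zip(c.lookup_flows, c.lookup_depth, c.lookup_velocity):
            hyd_rows.append({"cellID": c.cellID, "flow_m3s": q,
                             "depth_cm": d, "velocity_cms": v})
    pd.DataFrame(geo_rows).to_csv(geometry_path, index=False)
    pd.DataFrame(hab_rows).to_csv(habitat_path, index=False)
    pd.DataFrame(hyd_rows).to_csv(hydraulics_path, index=False)


# ---------------------------------------------------------------------------
# synthetic reach generator
# ---------------------------------------------------------------------------

def generate_synthetic_reach(
    n_cols: int,
    n_rows: int,
    seed: int = 0,
    *,
    ew_spacing: float = 1.5,
    depth_coef: float = 26.0,
    depth_exp: float = 0.42,
    velocity_coef: float = 25.0,
    velocity_exp: float = 0.38,
    cell_sigma: float = 0.25,
    gravel_frac_of_cells: float = 0.1,
    lookup_flows: Sequence[float] = STANDARD_DISCHARGES,
    params: ReachParams | None = None,
) -> Reach:
    """Generate a seeded synthetic reach of ``n_cols`` x ``n_rows`` hex cells.

    Per-cell depth and velocity follow monotone power-law ratings
    ``depth = depth_coef * Q**depth_exp * f_cell`` (cm) with lognormal
    spatial factors ``f_cell``; habitat fractions are drawn from seeded
    Beta/exponential distributions; one contiguous spawning-gravel patch is
    grown from a central cell; the first column of cells is flagged U
    (upstream) and the last column D (downstream).
    """
    if n_cols < 2 or n_rows < 2:
        raise ParameterError("synthetic reach needs at least 2x2 cells")
    rng = np.random.default_rng(seed)
    side = ew_spacing / 1.5
    row_h = SQRT3 * side
    poly = Polygon([
        (-0.1, -0.1),
        (ew_spacing * (n_cols - 1) + 0.1, -0.1),
        (ew_spacing * (n_cols - 1) + 0.1, row_h * (n_rows - 1) + 0.5 * row_h + 0.1),
        (-0.1, row_h * (n_rows - 1) + 0.5 * row_h + 0.1),
    ])
    cells = build_hex_grid(poly, ew_spacing)
    n = len(cells)
    flows = np.asarray(sorted(lookup_flows), dtype=float)

    f_depth = rng.lognormal(mean=0.0, sigma=cell_sigma, size=n)
    f_vel = rng.lognormal(mean=0.0, sigma=cell_sigma, size=n)
    shelter = rng.beta(1.2, 10.0, size=n)
    hide = rng.beta(2.0, 6.0, size=n)
    dist_hide = rng.exponential(scale=200.0, size=n)  # cm

    xs = np.asarray([c.centroid[0] for c in cells])
    min_x, max_x = xs.min(), xs.max()

    for i, c in enumerate(cells):
        c.lookup_flows = flows
        c.lookup_depth = depth_coef * flows ** depth_exp * f_depth[i]
        c.lookup_velocity = velocity_coef * flows ** velocity_exp * f_vel[i]
        c.cellFracShelter = float(shelter[i])
        c.cellFracHidingCover = float(hide[i])
        c.cellDistToHide = float(dist_hide[i])
        if math.isclose(c.centroid[0], min_x, abs_tol=1e-9):
            c.reachEnd = "U"
        elif math.isclose(c.centroid[0], max_x, abs_tol=1e-9):
            c.reachEnd = "D"

    # contiguous spawning-gravel patch grown from a central cell
    n_patch = max(2, int(round(gravel_frac_of_cells * n)))
    center = min(range(n), key=lambda i: math.dist(
        cells[i].centroid, ((min_x + max_x) / 2, float(np.median(
            [c.centroid[1] for c in cells])))))
    patch, frontier, seen = [], [center], {center}
    while frontier and len(patch) < n_patch:
        idx = frontier.pop(0)
        patch.append(idx)
        for nb in cells[idx].neighbors:
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    for idx in patch:
        cells[idx].cellFracSpawn = float(rng.uniform(0.6, 1.0))

    return Reach(cells, params)
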