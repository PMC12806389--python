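"""Planar shared-vertex polygonal tessellations.

A tissue is a simply connected patch of polygonal cells that share vertices
and edges (a "vertex model" mesh).  Cells are stored as counterclockwise
cycles of vertex indices into a single ``(V, 2)`` position array.  Edges are
derived from the cell cycles rather than stored separately, so edge/cell
consistency cannot drift across topological events.

All lengths are measured in units of the reference hexagon edge ``a``; a
regular hexagon with edge ``a`` has area ``A0 = (3*sqrt(3)/2) * a**2``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import LinearRing

from .errors import DegenerateEdgeError, InvalidCellError

__all__ = [
    "TissueMesh",
    "Geometry",
    "IntegrityReport",
    "hexagon_area",
    "polygon_area",
    "polygon_perimeter",
    "edge_lengths",
    "turning_angles",
    "mesh_integrity",
    "make_regular_hexagon",
    "make_hex_patch",
]

#: Edges shorter than this multiple of the reference length are degenerate.
DEGENERATE_TOL = 1e-12


def hexagon_area(a: float) -> float:
    """Area of a regular hexagon with edge length ``a``."""
    return 1.5 * math.sqrt(3.0) * a * a


# ---------------------------------------------------------------------------
# cached combinatorics


class _MeshCache:
    """Flattened index arrays derived from the cell cycles.

    Rebuilt only after topological events; purely positional updates reuse
    the same index arrays.
    """

    def __init__(self, mesh: "TissueMesh"):
        cells = mesh.cells
        V = len(mesh.positions)
        self.n_cells = len(cells)
        counts = np.array([len(c) for c in cells], dtype=np.int64)
        self.counts = counts
        self.offsets = np.concatenate(([0], np.cumsum(counts)))
        if self.n_cells:
            flat = np.concatenate(cells)
            self.flat_v = flat
            F = len(flat)
            starts = self.offsets[:-1]
            ends = self.offsets[1:] - 1
            nv = np.empty(F, dtype=np.int64)
            nv[:-1] = flat[1:]
            nv[ends] = flat[starts]
            self.next_v = nv
            pv = np.empty(F, dtype=np.int64)
            pv[1:] = flat[:-1]
            pv[starts] = flat[ends]
            self.prev_v = pv
            self.cell_of = np.repeat(np.arange(self.n_cells), counts)
        else:  # pragma: no cover - empty meshes are rejected upstream
            self.flat_v = np.empty(0, dtype=np.int64)
            self.next_v = np.empty(0, dtype=np.int64)
            self.prev_v = np.empty(0, dtype=np.int64)
            self.cell_of = np.empty(0, dtype=np.int64)

        # unique undirected edges, encoded as min*2^32 + max
        lo = np.minimum(self.flat_v, self.next_v)
        hi = np.maximum(self.flat_v, self.next_v)
        keys = lo << np.int64(32) | hi
        uniq, first, inv, cnt = np.unique(
            keys, return_index=True, return_inverse=True, return_counts=True
        )
        self.edge_keys = uniq  # sorted undirected keys, for O(log E) lookup
        self.n_edges = len(uniq)
        self.edge_of_slot = inv  # flat slot -> edge id
        self.edge_first_slot = first  # edge id -> one flat slot on it
        self.edge_multiplicity = cnt  # 1 = boundary, 2 = interior (if valid)
        self.edge_u = self.flat_v[first]
        self.edge_v = self.next_v[first]
        self.interior = cnt == 2

        # incident cells per edge (second cell = -1 on boundary edges)
        order = np.argsort(inv, kind="stable")
        self.edge_cell_a = np.full(self.n_edges, -1, dtype=np.int64)
        self.edge_cell_b = np.full(self.n_edges, -1, dtype=np.int64)
        eids = inv[order]
        cids = self.cell_of[order]
        pos = np.concatenate(([0], np.cumsum(cnt)))
        self.edge_cell_a[:] = cids[pos[:-1]]
        two = cnt >= 2
        self.edge_cell_b[two] = cids[pos[:-1][two] + 1]

        # vertex bookkeeping
        self.vertex_ncells = np.bincount(self.flat_v, minlength=V)
        bmask = np.zeros(V, dtype=bool)
        bedges = ~self.interior
        bmask[self.edge_u[bedges]] = True
        bmask[self.edge_v[bedges]] = True
        self.boundary_vertex = bmask
        # cells touching the free boundary (own at least one boundary edge)
        cbound = np.zeros(self.n_cells, dtype=bool)
        cbound[self.edge_cell_a[bedges]] = True
        self.boundary_cell = cbound

        # vertex -> incident cells (CSR-style)
        vorder = np.argsort(self.flat_v, kind="stable")
        self.vcell_data = self.cell_of[vorder]
        self.vcell_offsets = np.concatenate(
            ([0], np.cumsum(self.vertex_ncells))
        )

        # vertex -> incident edge slots (both endpoints), for per-vertex
        # reductions over incident edge lengths
        ends = np.concatenate((self.flat_v, self.next_v))
        self.incident_order = np.argsort(ends, kind="stable")
        deg = np.bincount(ends, minlength=V)
        self.incident_empty = deg == 0
        offs = np.concatenate(([0], np.cumsum(deg)))[:-1]
        # vacated vertex slots have no incident edges; clamp their group
        # starts so reduceat stays in bounds (results are masked out)
        self.incident_offsets = np.minimum(offs, max(len(ends) - 1, 0))

    def edge_cells(self, u: int, v: int) -> tuple[int, ...]:
        """Cells incident to the undirected edge (u, v)."""
        key = (min(u, v) << 32) | max(u, v)
        idx = np.searchsorted(self.edge_keys, key)
        if idx >= len(self.edge_keys) or self.edge_keys[idx] != key:
            return ()
        out = [int(self.edge_cell_a[idx])]
        if self.edge_cell_b[idx] >= 0:
            out.append(int(self.edge_cell_b[idx]))
        return tuple(out)

    def vertex_cells(self, v: int) -> np.ndarray:
        return self.vcell_data[self.vcell_offsets[v]: self.vcell_offsets[v + 1]]


@dataclass
class Geometry:
    """Per-step geometric measures computed from the current positions."""

    edge_vec: np.ndarray      # (F, 2) vector from slot vertex to its successor
    edge_len: np.ndarray      # (F,)   length of that edge
    area: np.ndarray          # (N,)   signed shoelace area per cell
    perimeter: np.ndarray     # (N,)
    angles: np.ndarray        # (F,)   signed turning angle at each slot vertex
    cross: np.ndarray         # (F,)   per-slot shoelace cross term


class TissueMesh:
    """Shared-vertex planar polygonal tessellation.

    Parameters
    ----------
    positions:
        ``(V, 2)`` float array of vertex coordinates.
    cells:
        Iterable of vertex-index cycles, one per cell, counterclockwise.
    """

    def __init__(self, positions, cells):
        self.positions = np.array(positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise InvalidCellError("positions must be an (V, 2) array")
        self.cells: list[np.ndarray] = [
            np.asarray(c, dtype=np.int64) for c in cells
        ]
        for c in self.cells:
            if len(c) < 3:
                raise InvalidCellError("cell cycle needs at least 3 vertices")
        self._cache: _MeshCache | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cache(self) -> _MeshCache:
        if self._cache is None:
            self._cache = _MeshCache(self)
        return self._cache

    @property
    def n_edges(self) -> int:
        return self.cache.n_edges

    def invalidate(self) -> None:
        """Drop derived combinatorial state after a topological change."""
        self._cache = None

    def copy(self) -> "TissueMesh":
        return TissueMesh(self.positions.copy(), [c.copy() for c in self.cells])

    def side_counts(self) -> np.ndarray:
        """Number of polygon vertices n0 per cell."""
        return self.cache.counts.copy()

    def boundary_vertices(self) -> np.ndarray:
        """Boolean mask of vertices lying on the free boundary."""
        return self.cache.boundary_vertex.copy()

    def cell_centroids(self) -> np.ndarray:
        """Arithmetic mean of each cell's vertex positions."""
        c = self.cache
        sums = np.zeros((self.n_cells, 2))
        np.add.at(sums, c.cell_of, self.positions[c.flat_v])
        return sums / c.counts[:, None]

    # -- geometry ----------------------------------------------------------
    def compute_geometry(self) -> Geometry:
        """Vectorized areas, perimeters, edge lengths and turning angles."""
        c = self.cache
        p = self.positions
        r = p[c.flat_v]
        rn = p[c.next_v]
        ev = rn - r
        el = np.hypot(ev[:, 0], ev[:, 1])
        cross = r[:, 0] * rn[:, 1] - rn[:, 0] * r[:, 1]
        area = 0.5 * np.add.reduceat(cross, c.offsets[:-1])
        perim = np.add.reduceat(el, c.offsets[:-1])
        # signed turning angle at the slot vertex: between incoming edge b
        # (prev -> here) and outgoing edge c (here -> next)
        rp = p[c.prev_v]
        b = r - rp
        cx, cy = ev[:, 0], ev[:, 1]
        bx, by = b[:, 0], b[:, 1]
        ang = np.arctan2(bx * cy - by * cx, bx * cx + by * cy)
        return Geometry(ev, el, area, perim, ang, cross)


# ---------------------------------------------------------------------------
# per-cell geometric operations


def _cell_coords(cell_id: int, mesh: TissueMesh) -> np.ndarray:
    cyc = mesh.cells[cell_id]
    if len(cyc) < 3:
        raise InvalidCellError(f"cell {cell_id} has fewer than 3 vertices")
    return mesh.positions[cyc]


def polygon_area(cell_id: int, mesh: TissueMesh) -> float:
    """Shoelace area of one cell; positive for counterclockwise cycles."""
    xy = _cell_coords(cell_id, mesh)
    x, y = xy[:, 0], xy[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(0.5 * np.sum(x * yn - xn * y))


def edge_lengths(cell_id: int, mesh: TissueMesh) -> np.ndarray:
    """Lengths ``l_ij`` of the cell's edges, in cycle order."""
    xy = _cell_coords(cell_id, mesh)
    d = np.roll(xy, -1, axis=0) - xy
    return np.hypot(d[:, 0], d[:, 1])


def polygon_perimeter(cell_id: int, mesh: TissueMesh) -> float:
    """Perimeter of one cell."""
    return float(edge_lengths(cell_id, mesh).sum())


def turning_angles(cell_id: int, mesh: TissueMesh, l0: float = 1.0) -> np.ndarray:
    """Signed exterior (turning) angles at each vertex of the cell.

    The angle at vertex ``j`` is measured between the incoming edge
    ``r_j - r_{j-1}`` and the outgoing edge ``r_{j+1} - r_j``, with the sign
    of the 2-D cross product.  For a simple counterclockwise polygon the
    angles sum to ``2*pi``; concave vertices give negative values.
    """
    xy = _cell_coords(cell_id, mesh)
    b = xy - np.roll(xy, 1, axis=0)
    c = np.roll(xy, -1, axis=0) - xy
    lb = np.hypot(b[:, 0], b[:, 1])
    if np.any(lb < DEGENERATE_TOL * l0):
        raise DegenerateEdgeError(f"cell {cell_id} has a zero-length edge")
    return np.arctan2(
        b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0],
        b[:, 0] * c[:, 0] + b[:, 1] * c[:, 1],
    )


# ---------------------------------------------------------------------------
# integrity


@dataclass
class IntegrityReport:
    """Diagnostic summary of a mesh's structural validity."""

    n_vertices: int
    n_edges: int
    n_cells: int
    euler: int                       # V - E + N; 1 for a simply connected patch
    connected: bool
    edge_violations: list = field(default_factory=list)
    nonsimple_cells: list = field(default_factory=list)
    negative_area_cells: list = field(default_factory=list)
    nonfinite: bool = False

    @property
    def valid(self) -> bool:
        return (
            self.euler == 1
            and self.connected
            and not self.edge_violations
            and not self.nonsimple_cells
            and not self.negative_area_cells
            and not self.nonfinite
        )


def mesh_integrity(mesh: TissueMesh, check_simple: bool = True) -> IntegrityReport:
    """Check the Euler relation, edge consistency and polygon simplicity.

    A valid simply connected tessellation satisfies ``V - E + N = 1``, every
    edge bounds one (boundary) or two (interior) cells with the two incident
    cells traversing it in opposite directions, and every cell is a simple
    counterclockwise polygon.
    """
    c = mesh.cache
    n_used = int(np.count_nonzero(c.vertex_ncells))
    report = IntegrityReport(
        n_vertices=n_used,
        n_edges=c.n_edges,
        n_cells=mesh.n_cells,
        euler=n_used - c.n_edges + mesh.n_cells,
        connected=True,
    )
    if not np.all(np.isfinite(mesh.positions)):
        report.nonfinite = True

    # multiplicity and opposed traversal
    bad = np.nonzero(c.edge_multiplicity > 2)[0]
    for e in bad:
        report.edge_violations.append(
            (int(c.edge_u[e]), int(c.edge_v[e]), "multiplicity>2")
        )
    directed = c.flat_v << np.int64(32) | c.next_v
    _, dcnt = np.unique(directed, return_counts=True)
    if np.any(dcnt > 1):
        # some directed edge is traversed twice => two cells run it the
        # same way (orientation clash)
        dup = np.unique(directed)[dcnt > 1]
        for key in dup:
            report.edge_violations.append(
                (int(key >> 32), int(key & 0xFFFFFFFF), "same-direction")
            )

    geom = mesh.compute_geometry()
    neg = np.nonzero(geom.area <= 0)[0]
    report.negative_area_cells = [int(i) for i in neg]

    if check_simple:
        for i, cyc in enumerate(mesh.cells):
            ring = LinearRing(mesh.positions[cyc])
            if not ring.is_simple:
                report.nonsimple_cells.append(i)

    # connectivity over the vertex adjacency graph
    used = np.unique(c.flat_v)
    if len(used):
        g = coo_matrix(
            (np.ones(len(c.flat_v)), (c.flat_v, c.next_v)),
            shape=(mesh.n_vertices, mesh.n_vertices),
        )
        ncomp, labels = connected_components(g, directed=False)
        report.connected = len(np.unique(labels[used])) == 1
    return report


# ---------------------------------------------------------------------------
# fixtures


def _hexagon_corners(center: np.ndarray, a: float) -> np.ndarray:
    """Flat-top regular hexagon corners, counterclockwise."""
    k = np.arange(6)
    ang = np.pi / 3.0 * k
    return center + a * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def make_regular_hexagon(a: float = 1.0) -> TissueMesh:
    """Single regular hexagonal cell with edge length ``a``."""
    if a <= 0:
        raise ValueError("edge length a must be positive")
    corners = _hexagon_corners(np.zeros(2), a)
    return TissueMesh(corners, [np.arange(6)])


def _spiral_axial(n: int):
    """First ``n`` axial hex-grid coordinates in ring (spiral) order."""
    dirs = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    out = [(0, 0)]
    ring = 1
    while len(out) < n:
        q, r = ring * dirs[4][0], ring * dirs[4][1]  # start below center
        for d in range(6):
            for _ in range(ring):
                out.append((q, r))
                q += dirs[d][0]
                r += dirs[d][1]
                if len(out) >= n:
                    return out[:n]
        ring += 1
    return out[:n]


def make_hex_patch(n_cells: int, a: float = 1.0) -> TissueMesh:
    """Defect-free patch of ``n_cells`` regular hexagons with free boundary.

    Cells are laid out in spiral (ring) order around a central cell; shared
    corners are deduplicated so neighboring cells reference the same vertex.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if a <= 0:
        raise ValueError("edge length a must be positive")
    # flat-top hexagons: axial (q, r) -> cartesian center
    centers = []
    for q, r in _spiral_axial(n_cells):
        centers.append((1.5 * a * q, math.sqrt(3.0) * a * (r + 0.5 * q)))
    vindex: dict[tuple, int] = {}
    positions: list[tuple] = []
    cells = []
    for cx, cy in centers:
        corners = _hexagon_corners(np.array([cx, cy]), a)
        cyc = []
        for x, y in corners:
            key = (round(x / a, 6), round(y / a, 6))
            if key not in vindex:
                vindex[key] = len(positions)
                positions.append((x, y))
            cyc.append(vindex[key])
        cells.append(cyc)
    return TissueMesh(np.array(positions), cells)


# ---------------------------------------------------------------------------
# snapshots

SNAPSHOT_VERSION = 1


def snapshot_dict(
    mesh: TissueMesh,
    time: float = 0.0,
    params_hash: str | None = None,
    concentrations: np.ndarray | None = None,
    per_cell_coeffs: dict | None = None,
) -> dict:
    """JSON-serializable snapshot of mesh + per-cell state."""
    d = {
        "version": SNAPSHOT_VERSION,
        "time": time,
        "params_hash": params_hash,
        "vertices": mesh.positions.tolist(),
        "cells": [c.tolist() for c in mesh.cells],
    }
    if concentrations is not None:
        d["concentrations"] = np.asarray(concentrations).tolist()
    if per_cell_coeffs is not None:
        d["per_cell_coeffs"] = {
            k: np.asarray(v).tolist() for k, v in per_cell_coeffs.items()
        }
    return d


def save_snapshot(path, mesh: TissueMesh, **kwargs) -> None:
    with open(path, "w") as fh:
        json.dump(snapshot_dict(mesh, **kwargs), fh)


def load_snapshot(path) -> tuple[TissueMesh, dict]:
    """Load a snapshot; returns the mesh and the full snapshot dict."""
    with open(path) as fh:
        d = json.load(fh)
    mesh = TissueMesh(np.array(d["vertices"]), d["cells"])
    return mesh, d
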