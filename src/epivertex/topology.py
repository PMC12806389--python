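"""Topological events: stochastic cell division and T1 intercalation.

Division follows the longest-edge rule: the cell's longest edge and the
edge (closest to) opposite it are bisected, the two midpoints are joined by
a new edge, and the cell splits into two daughters.  The division
probability per cell per step is ``p_div = p0 * q**(n0 - 6)``, so
many-sided cells divide more often when ``q > 1``.

Intercalation (a T1 neighbor exchange) fires whenever an interior edge
shrinks below the critical length ``d_int``: the short edge is replaced by
its 90-degree-rotated counterpart, swapping which two of the four incident
cells are adjacent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TopologyEventError
from .mesh import TissueMesh

__all__ = [
    "DivisionParams",
    "IntercalationParams",
    "EventLog",
    "division_probability",
    "divide_cell",
    "attempt_divisions",
    "find_short_edges",
    "t1_swap",
    "attempt_intercalations",
    "merge_edge",
    "repair_short_edges",
    "replay_events",
]

MIN_SIDES = 4  # no topological event may create a polygon below this class


@dataclass
class DivisionParams:
    """Base probability ``p0`` (per cell per step) and side sensitivity ``q``."""

    p0: float = 5e-5
    q: float = 1.4

    def __post_init__(self):
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.q <= 0:
            raise ValueError("q must be positive")


@dataclass
class IntercalationParams:
    """Critical edge length and the length assigned to the rotated edge."""

    d_int: float = 0.15
    post_length_factor: float = 1.5

    def __post_init__(self):
        if self.d_int <= 0:
            raise ValueError("d_int must be positive")
        if self.post_length_factor <= 0:
            raise ValueError("post_length_factor must be positive")


@dataclass
class EventLog:
    """Replayable record of divisions and intercalations."""

    events: list = field(default_factory=list)

    def add(self, event: dict) -> None:
        self.events.append(event)

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


# ---------------------------------------------------------------------------
# division


def division_probability(n0: int | np.ndarray, params: DivisionParams):
    """``p_div = p0 * q**(n0 - 6)`` clamped to [0, 1]."""
    p = params.p0 * params.q ** (np.asarray(n0, dtype=float) - 6.0)
    return np.clip(p, 0.0, 1.0)


def _opposite_edge(lengths: np.ndarray, j_long: int) -> int:
    """Edge opposite ``j_long``: the antipodal edge for even side counts,
    the longer of the two edges flanking the antipodal vertex for odd."""
    n = len(lengths)
    if n % 2 == 0:
        return (j_long + n // 2) % n
    c1 = (j_long + n // 2) % n
    c2 = (j_long + (n + 1) // 2) % n
    if lengths[c2] > lengths[c1]:
        return c2
    return c1  # ties: lower offset wins


def _insert_midpoint_in_neighbor(
    mesh: TissueMesh, cell_id: int, tail: int, head: int, new_v: int
) -> None:
    """Insert ``new_v`` into a neighboring cell that traverses head->tail."""
    cyc = mesh.cells[cell_id]
    n = len(cyc)
    for k in range(n):
        if cyc[k] == head and cyc[(k + 1) % n] == tail:
            mesh.cells[cell_id] = np.insert(cyc, k + 1, new_v)
            return
    raise TopologyEventError(
        f"cell {cell_id} does not traverse edge {head}->{tail}"
    )


def divide_cell(
    mesh: TissueMesh,
    cell_id: int,
    edges: tuple[int, int] | None = None,
    time: float = 0.0,
) -> dict:
    """Split ``cell_id`` across the midpoints of its longest and opposite edges.

    The two midpoints become new vertices (also inserted into the neighbors
    sharing those edges, which each gain one side) and are joined by a new
    edge.  The mother keeps its cell id with one daughter cycle; the other
    daughter is appended to the end of the cell list.  Returns a replayable
    event record.  ``edges`` overrides the (longest, opposite) edge offsets,
    which is used for replay.
    """
    cyc = mesh.cells[cell_id]
    n = len(cyc)
    if n < MIN_SIDES:
        raise TopologyEventError(f"cell {cell_id} has n0 < {MIN_SIDES}")
    pos = mesh.positions
    pts = pos[cyc]
    d = np.roll(pts, -1, axis=0) - pts
    lengths = np.hypot(d[:, 0], d[:, 1])
    if edges is None:
        j1 = int(np.argmax(lengths))  # argmax takes the lowest index on ties
        j2 = _opposite_edge(lengths, j1)
    else:
        j1, j2 = edges
    if j1 == j2:
        raise TopologyEventError("split edges coincide")

    cache = mesh.cache  # neighbor lookups need the pre-event cache
    tails = (int(cyc[j1]), int(cyc[j2]))
    heads = (int(cyc[(j1 + 1) % n]), int(cyc[(j2 + 1) % n]))
    mids = [
        0.5 * (pos[t] + pos[h]) for t, h in zip(tails, heads)
    ]
    w1 = len(pos)
    w2 = w1 + 1
    mesh.positions = np.vstack([pos, mids[0], mids[1]])

    # neighbors sharing the split edges gain the midpoint vertex
    for (t, h), w in zip(zip(tails, heads), (w1, w2)):
        for nb in cache.edge_cells(t, h):
            if nb != cell_id:
                _insert_midpoint_in_neighbor(mesh, nb, t, h, w)

    # mother cycle with both midpoints inserted (keep j1 < j2 bookkeeping
    # implicit by inserting the later offset first)
    aug = list(map(int, cyc))
    for j, w in sorted(zip((j1, j2), (w1, w2)), reverse=True):
        aug.insert(j + 1, w)
    ia, ib = aug.index(w1), aug.index(w2)
    if ia > ib:
        ia, ib = ib, ia
        w1_first = False
    else:
        w1_first = True
    half_a = aug[ia:ib + 1]          # first midpoint ... second midpoint
    half_b = aug[ib:] + aug[:ia + 1]  # second midpoint ... first midpoint
    if len(half_a) < MIN_SIDES or len(half_b) < MIN_SIDES:
        raise TopologyEventError("division would create a cell with n0 < 4")

    daughter_id = mesh.n_cells
    mesh.cells[cell_id] = np.asarray(half_a, dtype=np.int64)
    mesh.cells.append(np.asarray(half_b, dtype=np.int64))
    mesh.invalidate()
    return {
        "t": time,
        "type": "division",
        "cell": int(cell_id),
        "daughter": int(daughter_id),
        "edges": (int(j1), int(j2)),
        "split_edges": [(tails[0], heads[0]), (tails[1], heads[1])],
        "new_vertices": (int(w1), int(w2)),
        "w1_first": bool(w1_first),
    }


def attempt_divisions(
    mesh: TissueMesh,
    params: DivisionParams,
    rng: np.random.Generator,
    time: float = 0.0,
) -> list[dict]:
    """One division round: every existing cell draws one uniform variate.

    Cells whose draw falls below ``p_div(n0)`` divide this step, processed
    in cell-id order; daughters created this step do not divide this step.
    Side counts are taken at the start of the round.
    """
    n_before = mesh.n_cells
    if n_before == 0:
        return []
    draws = rng.random(n_before)
    p = division_probability(mesh.side_counts(), params)
    winners = np.nonzero(draws < p)[0]
    events = []
    for cid in winners:
        try:
            events.append(divide_cell(mesh, int(cid), time=time))
        except TopologyEventError:  # guarded rejection, logged by caller
            continue
    return events


# ---------------------------------------------------------------------------
# intercalation


def find_short_edges(mesh: TissueMesh, d_int: float) -> list[tuple[int, int]]:
    """Interior edges shorter than ``d_int``, ascending by length."""
    c = mesh.cache
    geom = mesh.compute_geometry()
    el = geom.edge_len[c.edge_first_slot]
    mask = c.interior & (el < d_int)
    idx = np.nonzero(mask)[0]
    idx = idx[np.argsort(el[idx], kind="stable")]
    return [
        (min(int(c.edge_u[e]), int(c.edge_v[e])),
         max(int(c.edge_u[e]), int(c.edge_v[e])))
        for e in idx
    ]


def _third_cell(cache, vertex: int, exclude: tuple[int, int]) -> int | None:
    cells = [int(c) for c in cache.vertex_cells(vertex) if c not in exclude]
    if len(cells) != 1:
        return None
    return cells[0]


def t1_swap(
    mesh: TissueMesh,
    edge: tuple[int, int],
    params: IntercalationParams,
    time: float = 0.0,
    _cache=None,
) -> dict:
    """Apply a T1 neighbor exchange across ``edge = (v1, v2)``.

    Requires the generic configuration: the edge is interior and each
    endpoint is shared by exactly three cells.  The two cells sharing the
    edge each lose one side; the two cells incident only at its endpoints
    each gain one side.  Geometrically the edge is rotated 90 degrees about
    its midpoint and assigned length ``post_length_factor * d_int``.
    """
    v1, v2 = int(edge[0]), int(edge[1])
    # _cache: a pre-event cache snapshot, valid when the caller guarantees
    # this edge's neighborhood is untouched since the snapshot (used to
    # batch several swaps per round without intermediate rebuilds)
    cache = _cache if _cache is not None else mesh.cache
    inc = cache.edge_cells(v1, v2)
    if len(inc) != 2:
        raise TopologyEventError("T1 requires an interior edge")
    if cache.vertex_ncells[v1] != 3 or cache.vertex_ncells[v2] != 3:
        raise TopologyEventError("T1 requires valence-3 endpoints")

    # orient: cell A traverses v1 -> v2, cell B traverses v2 -> v1
    def _traverses(cid, a, b):
        cyc = mesh.cells[cid]
        n = len(cyc)
        for k in range(n):
            if cyc[k] == a and cyc[(k + 1) % n] == b:
                return True
        return False

    if _traverses(inc[0], v1, v2):
        A, B = inc
    else:
        B, A = inc
    C = _third_cell(cache, v1, (A, B))
    D = _third_cell(cache, v2, (A, B))
    if C is None or D is None or C == D:
        raise TopologyEventError("non-generic T1 neighborhood")
    if len(mesh.cells[A]) <= MIN_SIDES or len(mesh.cells[B]) <= MIN_SIDES:
        raise TopologyEventError("T1 would create a cell with n0 < 4")

    def _drop(cid, v):
        cyc = mesh.cells[cid]
        mesh.cells[cid] = cyc[cyc != v]

    def _insert_after(cid, anchor, new):
        cyc = list(map(int, mesh.cells[cid]))
        k = cyc.index(anchor)
        cyc.insert(k + 1, new)
        mesh.cells[cid] = np.asarray(cyc, dtype=np.int64)

    # combinatorial rewiring: A keeps v2, B keeps v1, C gains v2 after v1,
    # D gains v1 after v2 (orientations derived from CCW traversal).
    _drop(A, v1)
    _drop(B, v2)
    _insert_after(C, v1, v2)
    _insert_after(D, v2, v1)

    # geometric rotation about the midpoint; the CCW normal points into A,
    # which is the side v2 ends up on (v2 stays incident to A).
    p = mesh.positions
    m = 0.5 * (p[v1] + p[v2])
    d = p[v2] - p[v1]
    norm = np.hypot(d[0], d[1])
    if norm == 0:
        raise TopologyEventError("degenerate edge in T1")
    u = d / norm
    nvec = np.array([-u[1], u[0]])
    # rotated-edge length: post_length_factor * d_int in the generic case,
    # but never more than post_length_factor times the edge being replaced,
    # so a swap deep inside a strongly contracted region stays at the local
    # geometric scale instead of stabbing across neighboring cells
    new_len = params.post_length_factor * min(params.d_int, norm)
    half = 0.5 * new_len
    p[v2] = m + half * nvec
    p[v1] = m - half * nvec
    mesh.invalidate()
    return {
        "t": time,
        "type": "t1",
        "edge": (v1, v2),
        "cells": (int(A), int(B), int(C), int(D)),
    }


def attempt_intercalations(
    mesh: TissueMesh,
    params: IntercalationParams,
    time: float = 0.0,
) -> list[dict]:
    """Swap all currently short interior edges, shortest first.

    Edges touching a vertex already moved by a swap this round are stale
    (both their length and their local topology changed) and are skipped.
    """
    short = find_short_edges(mesh, params.d_int)
    if not short:
        return []
    cache = mesh.cache
    events = []
    touched_v: set[int] = set()
    touched_c: set[int] = set()
    for (u, v) in short:
        if u in touched_v or v in touched_v:
            continue
        inc = cache.edge_cells(u, v)
        if any(c in touched_c for c in inc):
            continue
        try:
            ev = t1_swap(mesh, (u, v), params, time=time, _cache=cache)
        except TopologyEventError:
            continue
        events.append(ev)
        touched_v.update((u, v))
        touched_c.update(ev["cells"])
    return events


# ---------------------------------------------------------------------------
# mesh repair


def merge_edge(mesh: TissueMesh, edge: tuple[int, int], time: float = 0.0) -> dict:
    """Collapse a degenerate edge by merging its endpoints at their midpoint.

    The cells incident to the edge each lose one side (guarded at n0 >= 4);
    other cells meeting the removed endpoint are rewired to the surviving
    vertex.  Removes one vertex and one edge, so the Euler relation
    ``V - E + N = 1`` is preserved.  The vacated vertex slot is left
    unused rather than renumbered.
    """
    u, v = int(edge[0]), int(edge[1])
    cache = mesh.cache
    inc = cache.edge_cells(u, v)
    if not inc:
        raise TopologyEventError(f"({u}, {v}) is not an edge")
    cells_u = set(int(x) for x in cache.vertex_cells(u))
    cells_v = set(int(x) for x in cache.vertex_cells(v))
    for cid in inc:
        if len(mesh.cells[cid]) <= MIN_SIDES:
            raise TopologyEventError("merge would create a cell with n0 < 4")
    for cid in (cells_u & cells_v) - set(inc):
        # cell touches both endpoints away from the edge: merging would
        # pinch it into a non-simple polygon
        raise TopologyEventError("endpoints shared by a non-incident cell")
    mesh.positions[u] = 0.5 * (mesh.positions[u] + mesh.positions[v])
    for cid in cells_v:
        cyc = [int(x) for x in mesh.cells[cid]]
        cyc = [u if x == v else x for x in cyc]
        # drop the consecutive duplicate created in the incident cells
        out = []
        for j, x in enumerate(cyc):
            if x == cyc[j - 1]:
                continue
            out.append(x)
        mesh.cells[cid] = np.asarray(out, dtype=np.int64)
    mesh.invalidate()
    return {"t": time, "type": "merge", "edge": (u, v), "cells": sorted(cells_v | cells_u)}


def repair_short_edges(
    mesh: TissueMesh, min_len: float, time: float = 0.0
) -> list[dict]:
    """Collapse edges shorter than ``min_len`` (mesh repair, shortest first).

    Intended for lengths far below ``d_int``: edges that intercalation
    cannot remove (boundary edges, non-generic junctions) but that are so
    short the polygonal model is meaningless at their scale, and whose
    1/l^2 angle stiffness would otherwise destabilize the integration.
    """
    c = mesh.cache
    geom = mesh.compute_geometry()
    el = geom.edge_len[c.edge_first_slot]
    idx = np.nonzero(el < min_len)[0]
    if not len(idx):
        return []
    idx = idx[np.argsort(el[idx], kind="stable")]
    pairs = [(int(c.edge_u[e]), int(c.edge_v[e])) for e in idx]
    events = []
    touched: set[int] = set()
    for (u, v) in pairs:
        if u in touched or v in touched:
            continue
        try:
            events.append(merge_edge(mesh, (u, v), time=time))
        except TopologyEventError:
            continue
        touched.update((u, v))
    return events


# ---------------------------------------------------------------------------
# replay


def replay_events(mesh: TissueMesh, events, intercalation: IntercalationParams):
    """Re-apply an event log to (a copy of) the initial mesh, in order.

    Divisions are replayed with their recorded edge offsets, so the
    reconstructed topology matches the original run exactly.
    """
    out = mesh.copy()
    for ev in events:
        if ev["type"] == "division":
            divide_cell(out, ev["cell"], edges=tuple(ev["edges"]), time=ev["t"])
        elif ev["type"] == "t1":
            t1_swap(out, tuple(ev["edge"]), intercalation, time=ev["t"])
        elif ev["type"] == "merge":
            merge_edge(out, tuple(ev["edge"]), time=ev["t"])
        else:
            raise TopologyEventError(f"unknown event type {ev['type']!r}")
    return out
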