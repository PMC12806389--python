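import numpy as np
import pytest

from epivertex.errors import TopologyEventError
from epivertex.mesh import make_hex_patch, make_regular_hexagon, mesh_integrity
from epivertex.topology import (
    DivisionParams,
    IntercalationParams,
    attempt_divisions,
    attempt_intercalations,
    divide_cell,
    division_probability,
    find_short_edges,
    merge_edge,
    replay_events,
    t1_swap,
)


def neighbor_graph(mesh):
    """Frozen set of adjacent cell-id pairs (for replay comparison)."""
    c = mesh.cache
    ci = c.edge_cell_a[c.interior]
    cj = c.edge_cell_b[c.interior]
    return {frozenset((int(a), int(b))) for a, b in zip(ci, cj)}


class TestDivisionProbability:
    def test_table_values(self):
        p = DivisionParams(p0=5e-5, q=1.4)
        assert division_probability(6, p) == pytest.approx(5e-5)
        assert division_probability(4, p) == pytest.approx(5e-5 / 1.96)

    def test_q_one_is_flat(self):
        p = DivisionParams(p0=1e-3, q=1.0)
        for n in (4, 5, 6, 9, 12):
            assert division_probability(n, p) == pytest.approx(1e-3)

    def test_clamped_to_unit_interval(self):
        p = DivisionParams(p0=0.9, q=1.4)
        assert division_probability(40, p) == 1.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DivisionParams(p0=1.5)
        with pytest.raises(ValueError):
            DivisionParams(q=0.0)


class TestDivideCell:
    def test_hexagon_splits_into_two_pentagons(self):
        m = make_regular_hexagon(1.0)
        ev = divide_cell(m, 0)
        assert [len(c) for c in m.cells] == [5, 5]
        assert ev["daughter"] == 1
        r = mesh_integrity(m)
        assert r.valid and r.euler == 1
        g = m.compute_geometry()
        assert g.area[0] == pytest.approx(g.area[1], abs=1e-12)

    def test_neighbors_gain_one_side(self):
        p = make_hex_patch(7)
        before = [len(c) for c in p.cells]
        assert before == [6] * 7
        divide_cell(p, 0)  # central cell: both split edges interior
        after = sorted(len(c) for c in p.cells)
        assert after == [5, 5, 6, 6, 6, 6, 7, 7]
        assert mesh_integrity(p).valid

    def test_division_counts(self):
        p = make_hex_patch(7)
        V, E, N = p.n_vertices, p.n_edges, p.n_cells
        divide_cell(p, 3)
        r = mesh_integrity(p)
        assert (r.n_vertices, r.n_edges, r.n_cells) == (V + 2, E + 3, N + 1)

    def test_pentagon_odd_rule_picks_larger_flank(self):
        # pentagon with a clearly longest edge and asymmetric flanks
        from epivertex.mesh import TissueMesh

        pts = np.array(
            [(0, 0), (2.0, 0), (2.6, 1.2), (1.0, 2.2), (-0.6, 1.0)], float
        )
        m = TissueMesh(pts, [[0, 1, 2, 3, 4]])
        lengths = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
        j1 = int(np.argmax(lengths))
        c1, c2 = (j1 + 2) % 5, (j1 + 3) % 5
        expect = c1 if lengths[c1] >= lengths[c2] else c2
        ev = divide_cell(m, 0)
        assert ev["edges"][0] == j1
        assert ev["edges"][1] == expect


class TestAttemptDivisions:
    def test_zero_probability_is_identity(self, patch7, rng):
        cells_before = [c.copy() for c in patch7.cells]
        events = attempt_divisions(patch7, DivisionParams(p0=0.0), rng)
        assert events == []
        assert all(
            np.array_equal(a, b) for a, b in zip(cells_before, patch7.cells)
        )

    def test_certain_division_doubles_cells(self, rng):
        m = make_hex_patch(2)
        events = attempt_divisions(m, DivisionParams(p0=1.0, q=1.0), rng)
        assert len(events) == 2 and m.n_cells == 4
        assert mesh_integrity(m).valid

    def test_division_count_matches_binomial_expectation(self, rng):
        m = make_hex_patch(64)
        params = DivisionParams(p0=2e-3, q=1.0)
        total = 0
        trials = 400
        for _ in range(trials):
            # statistics of the draw scheme only: divide a fresh mesh copy
            total += len(attempt_divisions(m.copy(), params, rng))
        mean = 64 * trials * params.p0
        sd = np.sqrt(mean * (1 - params.p0))
        assert abs(total - mean) < 4 * sd


class TestT1:
    @staticmethod
    def generic_interior_edge(mesh):
        c = mesh.cache
        for e in range(c.n_edges):
            if (
                c.interior[e]
                and c.vertex_ncells[c.edge_u[e]] == 3
                and c.vertex_ncells[c.edge_v[e]] == 3
            ):
                return (int(c.edge_u[e]), int(c.edge_v[e]))
        raise AssertionError("no generic interior edge")

    def test_rosette_side_exchange(self):
        p = make_hex_patch(4)
        edge = self.generic_interior_edge(p)
        ev = t1_swap(p, edge, IntercalationParams())
        assert sorted(len(c) for c in p.cells) == [5, 5, 7, 7]
        assert p.n_cells == 4
        assert mesh_integrity(p).valid
        A, B, C, D = ev["cells"]
        assert len(p.cells[A]) == 5 and len(p.cells[B]) == 5
        assert len(p.cells[C]) == 7 and len(p.cells[D]) == 7

    def test_counts_unchanged(self):
        p = make_hex_patch(7)
        V, E, N = p.n_vertices, p.n_edges, p.n_cells
        t1_swap(p, self.generic_interior_edge(p), IntercalationParams())
        r = mesh_integrity(p)
        assert (r.n_vertices, r.n_edges, r.n_cells) == (V, E, N)

    def test_quadrilateral_guard(self):
        # strip sides off the central cell of a large patch one swap at a
        # time; once it is a quadrilateral the next swap must be rejected
        p = make_hex_patch(19)
        params = IntercalationParams()
        target = 0
        engaged = False
        banned: set = set()
        for _ in range(30):
            c = p.cache
            choices = [
                (int(c.edge_u[e]), int(c.edge_v[e]))
                for e in range(c.n_edges)
                if c.interior[e]
                and target in (c.edge_cell_a[e], c.edge_cell_b[e])
                and c.vertex_ncells[c.edge_u[e]] == 3
                and c.vertex_ncells[c.edge_v[e]] == 3
            ]
            choices = [uv for uv in choices if frozenset(uv) not in banned]
            assert choices, "central cell ran out of generic edges"
            try:
                t1_swap(p, choices[0], params)
                banned.clear()
            except TopologyEventError:
                if len(p.cells[target]) == 4:
                    engaged = True
                    break
                banned.add(frozenset(choices[0]))
                continue
            assert min(len(x) for x in p.cells) >= 4
        assert engaged
        assert min(len(x) for x in p.cells) >= 4

    def test_boundary_edge_rejected(self):
        p = make_hex_patch(4)
        c = p.cache
        e = int(np.nonzero(~c.interior)[0][0])
        with pytest.raises(TopologyEventError):
            t1_swap(p, (int(c.edge_u[e]), int(c.edge_v[e])), IntercalationParams())


class TestShortEdges:
    def test_reference_patch_has_none(self, patch32):
        assert find_short_edges(patch32, 0.15) == []

    def test_contracted_interior_edge_found(self):
        p = make_hex_patch(4)
        u, v = TestT1.generic_interior_edge(p)
        mid = 0.5 * (p.positions[u] + p.positions[v])
        d = p.positions[v] - p.positions[u]
        p.positions[u] = mid - 0.05 * d
        p.positions[v] = mid + 0.05 * d
        assert find_short_edges(p, 0.15) == [(min(u, v), max(u, v))]
        events = attempt_intercalations(p, IntercalationParams())
        assert len(events) == 1
        assert mesh_integrity(p).valid

    def test_short_boundary_edge_excluded(self):
        p = make_hex_patch(2)
        c = p.cache
        e = int(np.nonzero(~c.interior)[0][0])
        u, v = int(c.edge_u[e]), int(c.edge_v[e])
        p.positions[v] = p.positions[u] + 0.05 * (
            p.positions[v] - p.positions[u]
        )
        assert (min(u, v), max(u, v)) not in find_short_edges(p, 0.15)

    def test_no_short_edges_is_identity(self, patch7):
        assert attempt_intercalations(patch7, IntercalationParams()) == []


class TestMergeEdge:
    def test_merge_preserves_euler(self):
        p = make_hex_patch(7)
        c = p.cache
        e = int(np.nonzero(c.interior)[0][0])
        u, v = int(c.edge_u[e]), int(c.edge_v[e])
        merge_edge(p, (u, v))
        r = mesh_integrity(p)
        assert r.euler == 1
        assert not r.negative_area_cells and not r.nonsimple_cells

    def test_merge_guard_on_quads(self):
        m = make_regular_hexagon(1.0)
        divide_cell(m, 0)  # two pentagons
        c = m.cache
        e = int(np.nonzero(c.interior)[0][0])
        merge_edge(m, (int(c.edge_u[e]), int(c.edge_v[e])))  # 4,4 now
        c = m.cache
        e2 = int(np.nonzero(c.interior)[0][0]) if c.interior.any() else None
        if e2 is not None:
            with pytest.raises(TopologyEventError):
                merge_edge(m, (int(c.edge_u[e2]), int(c.edge_v[e2])))


class TestEulerInvariantAndReplay:
    def test_euler_preserved_over_random_event_sequence(self, rng):
        """V - E + N = 1 after every one of ~1000 random division/T1 events."""
        mesh = make_hex_patch(7)
        params = IntercalationParams()
        n_events = 0
        while n_events < 1000:
            if rng.random() < 0.8:
                cid = int(rng.integers(mesh.n_cells))
                try:
                    divide_cell(mesh, cid)
                except TopologyEventError:
                    continue
            else:
                c = mesh.cache
                ok = (
                    c.interior
                    & (c.vertex_ncells[c.edge_u] == 3)
                    & (c.vertex_ncells[c.edge_v] == 3)
                )
                idx = np.nonzero(ok)[0]
                if not len(idx):
                    continue
                e = int(rng.choice(idx))
                try:
                    t1_swap(mesh, (int(c.edge_u[e]), int(c.edge_v[e])), params)
                except TopologyEventError:
                    continue
            n_events += 1
            c = mesh.cache
            n_used = int(np.count_nonzero(c.vertex_ncells))
            assert n_used - c.n_edges + mesh.n_cells == 1
        assert min(len(c) for c in mesh.cells) >= 4

    def test_replay_reproduces_neighbor_graph(self, rng):
        initial = make_hex_patch(7)
        mesh = initial.copy()
        params = IntercalationParams()
        events = []
        for _ in range(60):
            cid = int(rng.integers(mesh.n_cells))
            try:
                events.append(divide_cell(mesh, cid, time=0.0))
            except TopologyEventError:
                continue
        short = find_short_edges(mesh, 0.6)
        for edge in short[:5]:
            try:
                events.append(t1_swap(mesh, edge, params))
            except TopologyEventError:
                continue
        replayed = replay_events(initial, events, params)
        assert [len(c) for c in replayed.cells] == [len(c) for c in mesh.cells]
        assert neighbor_graph(replayed) == neighbor_graph(mesh)
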