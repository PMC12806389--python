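import math

import numpy as np
import pytest

from epivertex.errors import InvalidCellError
from epivertex.mechanics import ElasticCoeffs, ReferenceState
from epivertex.mesh import TissueMesh, make_hex_patch, make_regular_hexagon
from epivertex.observables import (
    RegimeThresholds,
    classify_regime,
    energy_per_cell,
    fields_dataframe,
    mean_area_by_class,
    mean_edge_length,
    mean_sides,
    polygon_class_fractions,
    sample_record,
)
from epivertex.topology import divide_cell


def mixed_mesh():
    """Disconnected toy tessellation: two 5-gons, a 6-gon and a 9-gon."""
    cells = []
    pts = []
    off = 0
    for n, shift in [(5, 0.0), (5, 10.0), (6, 20.0), (9, 30.0)]:
        ang = 2 * np.pi * np.arange(n) / n
        pts.append(np.stack([np.cos(ang) + shift, np.sin(ang)], 1))
        cells.append(list(range(off, off + n)))
        off += n
    return TissueMesh(np.vstack(pts), cells)


class TestClassFractions:
    def test_reference_patch_all_hexagons(self, patch32):
        P = polygon_class_fractions(patch32)
        assert P[6] == 1.0
        assert sum(P.values()) == pytest.approx(1.0)

    def test_mixed_classes_with_pooling(self):
        P = polygon_class_fractions(mixed_mesh())
        assert P[5] == 0.5
        assert P[6] == 0.25
        assert P[8] == 0.25  # the 9-gon pools into 8+
        assert sum(P.values()) == pytest.approx(1.0)

    def test_fractions_sum_to_one_after_divisions(self, rng):
        m = make_hex_patch(7)
        for _ in range(10):
            divide_cell(m, int(rng.integers(m.n_cells)))
        assert sum(polygon_class_fractions(m).values()) == pytest.approx(1.0)


class TestMeanAreaByClass:
    def test_reference_patch(self, patch32, ref):
        R = mean_area_by_class(patch32, ref.A0)
        assert set(R) == {6}
        assert R[6] == pytest.approx(1.0)

    def test_one_shrunken_hexagon(self, ref):
        # disconnected hexagons so the shrink does not drag shared vertices
        pts, cells, off = [], [], 0
        for i in range(8):
            ang = np.pi / 3 * np.arange(6)
            scale = 1.0 / np.sqrt(2) if i == 0 else 1.0
            pts.append(np.stack([scale * np.cos(ang) + 5 * i, scale * np.sin(ang)], 1))
            cells.append(list(range(off, off + 6)))
            off += 6
        m = TissueMesh(np.vstack(pts), cells)
        R = mean_area_by_class(m, ref.A0)
        assert R[6] == pytest.approx((7 + 0.5) / 8)

    def test_absent_classes_missing_not_zero(self, hexagon, ref):
        R = mean_area_by_class(hexagon, ref.A0)
        assert 4 not in R and 6 in R

    def test_empty_mesh_rejected(self, ref):
        m = make_regular_hexagon()
        m.cells = []
        m.invalidate()
        with pytest.raises(InvalidCellError):
            mean_area_by_class(m, ref.A0)


class TestMeanSides:
    def test_single_hexagon(self, hexagon):
        assert mean_sides(hexagon) == 6.0

    def test_balanced_pair(self):
        m = mixed_mesh()
        # 5, 5, 6, 9 -> 6.25
        assert mean_sides(m) == pytest.approx(6.25)

    @pytest.mark.parametrize("n", [37, 91, 169])  # 3, 5 and 7 rings
    def test_interior_mean_is_six_for_defect_free_patches(self, n):
        assert mean_sides(make_hex_patch(n), interior_only=True) == 6.0

    def test_neighbor_weighted_mean_is_biased_upward(self, rng):
        # sampling by adjacency overweights many-sided cells, so the
        # neighbor-weighted mean is >= the plain mean (equal on a
        # defect-free patch)
        m = make_hex_patch(19)
        assert mean_sides(m, weighting="neighbors") == 6.0
        for _ in range(25):
            divide_cell(m, int(rng.integers(m.n_cells)))
        assert mean_sides(m, weighting="neighbors") >= mean_sides(m)

    def test_all_cells_mean_bounded_by_euler(self, rng):
        # conforming tessellation, interior vertices of valence >= 3:
        # the all-cells mean cannot exceed 6 by much more than the
        # boundary contribution
        m = make_hex_patch(19)
        for _ in range(30):
            divide_cell(m, int(rng.integers(m.n_cells)))
        assert mean_sides(m) < 6.5


class TestEnergyAndEdges:
    def test_reference_patch_energy_and_line(self, patch32, ref):
        coeffs = ElasticCoeffs.uniform(32, 0.9, 0.1, 1.0, 1.0)
        u, line = energy_per_cell(patch32, coeffs, ref)
        assert u == pytest.approx(3.6)
        assert line == pytest.approx(3.6)

    def test_zero_contractility_reference_line(self, patch32, ref):
        coeffs = ElasticCoeffs.uniform(32, 0.9, 0.0, 1.0, 1.0)
        _, line = energy_per_cell(patch32, coeffs, ref)
        assert line == 0.0

    def test_perturbation_raises_energy(self, patch32, ref, rng):
        coeffs = ElasticCoeffs.uniform(32, 0.9, 0.0, 1.0, 1.0)
        u0, _ = energy_per_cell(patch32, coeffs, ref)
        patch32.positions += 0.02 * rng.standard_normal(patch32.positions.shape)
        u1, _ = energy_per_cell(patch32, coeffs, ref)
        assert u1 > u0

    def test_mean_edge_length_scaling(self, patch7):
        assert mean_edge_length(patch7) == pytest.approx(1.0)
        patch7.positions *= 2.5
        assert mean_edge_length(patch7) == pytest.approx(2.5)


class TestRecords:
    def test_sample_record_consistency(self, patch32, ref):
        coeffs = ElasticCoeffs.uniform(32, 0.9, 0.1, 1.0, 1.0)
        rec = sample_record(patch32, coeffs, ref, t=1.0)
        assert rec.N == 32
        assert rec.U_per_N == pytest.approx(3.6)
        assert sum(rec.P.values()) == pytest.approx(1.0)
        row = rec.as_row()
        assert row["P6"] == 1.0 and math.isnan(row["R4"])

    def test_fields_dataframe_columns(self, patch7, ref):
        coeffs = ElasticCoeffs.uniform(7, 0.9, 0.1, 1.0, 1.0)
        df = fields_dataframe(patch7, coeffs, ref, conc=np.zeros((7, 1)))
        assert {"cell", "x", "y", "n0", "area", "perimeter", "energy", "phi", "C"} <= set(df.columns)
        assert len(df) == 7
        assert np.allclose(df["energy"], 3.6)


class TestClassifyRegime:
    def test_integrity_failure_is_unstable(self, patch7, ref):
        assert classify_regime(patch7, ref, integrity_ok=False).label == "unstable"

    def test_reference_patch_is_uniform(self, patch32, ref):
        assert classify_regime(patch32, ref).label == "uniform"

    def test_handbuilt_bubble_state(self, ref):
        # one 9-sided cell of area ~10 A0 among 50 near-reference cells
        cells = []
        pts = []
        off = 0
        for i in range(50):
            ang = np.pi / 3 * np.arange(6)
            pts.append(np.stack([np.cos(ang) + 5 * i, np.sin(ang)], 1))
            cells.append(list(range(off, off + 6)))
            off += 6
        big_r = np.sqrt(10 * ref.A0 / (4.5 * np.sin(2 * np.pi / 9)))
        ang = 2 * np.pi * np.arange(9) / 9
        pts.append(np.stack([big_r * np.cos(ang) + 500, big_r * np.sin(ang)], 1))
        cells.append(list(range(off, off + 9)))
        m = TissueMesh(np.vstack(pts), cells)
        label = classify_regime(m, ref)
        assert label.label == "bubble"
        assert label.scores["max_area_ratio"] > 3

    def test_collapsed_filaments_are_thread(self, ref):
        # chains of tiny flat quadrilaterals
        pts = []
        cells = []
        off = 0
        for i in range(40):
            x = 0.3 * i
            quad = [(x, 0), (x + 0.28, 0.0), (x + 0.28, 0.02), (x, 0.02)]
            pts.extend(quad)
            cells.append([off, off + 1, off + 2, off + 3])
            off += 4
        m = TissueMesh(np.array(pts, float), cells)
        assert classify_regime(m, ref).label == "thread"

    def test_deterministic(self, patch32, ref):
        a = classify_regime(patch32, ref)
        b = classify_regime(patch32, ref)
        assert a.label == b.label
        assert set(a.scores) == set(b.scores)
        for k in a.scores:
            np.testing.assert_equal(a.scores[k], b.scores[k])
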