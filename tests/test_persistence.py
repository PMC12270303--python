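"""Rips persistence: worked barcodes, MST identity, oracle agreement, invariants."""

import math

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

from colonytda.persistence import (
    PersistenceBar,
    compute_diagram,
    h0_barcode,
    h1_barcode,
    pairwise_distances,
)

from _oracle import rips_barcode_bruteforce


def finite_deaths(bars, dim):
    return sorted(b.death for b in bars if b.dim == dim and math.isfinite(b.death))


class TestPairwiseDistances:
    def test_three_four_five_triangle(self):
        dm = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert dm[0, 1] == dm[1, 0] == 5.0

    def test_single_point_and_duplicates(self):
        assert pairwise_distances([[2.0, 2.0]]).shape == (1, 1)
        dm = pairwise_distances([[1.0, 1.0], [1.0, 1.0]])
        assert dm[0, 1] == 0.0

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distances([[0.0, np.nan]])


class TestBarValidation:
    def test_death_must_exceed_birth(self):
        with pytest.raises(ValueError):
            PersistenceBar(0, 1.0, 1.0)

    def test_negative_birth_rejected(self):
        with pytest.raises(ValueError):
            PersistenceBar(1, -0.5, 1.0)


class TestH0:
    def test_collinear_points(self):
        dm = pairwise_distances([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        bars = h0_barcode(dm)
        assert finite_deaths(bars, 0) == [1.0, 2.0]
        assert sum(math.isinf(b.death) for b in bars) == 1

    def test_unit_square(self, unit_square):
        bars = h0_barcode(pairwise_distances(unit_square))
        assert finite_deaths(bars, 0) == [1.0, 1.0, 1.0]

    def test_single_point(self):
        bars = h0_barcode(pairwise_distances([[5.0, 5.0]]))
        assert len(bars) == 1 and math.isinf(bars[0].death)

    def test_duplicate_points_drop_zero_bars(self):
        bars = h0_barcode(pairwise_distances([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
        assert finite_deaths(bars, 0) == [1.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_finite_deaths_equal_mst_edges(self, disk_cloud, seed):
        """The multiset of dim-0 deaths is the Euclidean MST edge-weight multiset."""
        pts = disk_cloud(40, 60.0, seed)
        dm = pairwise_distances(pts)
        mst = minimum_spanning_tree(dm).toarray()
        expected = sorted(mst[mst > 0].tolist())
        assert np.allclose(finite_deaths(h0_barcode(dm), 0), expected, atol=1e-9)


class TestH1:
    def test_unit_square_single_bar(self, unit_square):
        bars = h1_barcode(pairwise_distances(unit_square), 3.0)
        assert len(bars) == 1
        assert bars[0].birth == pytest.approx(1.0, abs=1e-12)
        assert bars[0].death == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_three_points_never_have_loops(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.random((3, 2)) * 10
            assert h1_barcode(pairwise_distances(pts), 50.0) == []

    def test_regular_hexagon(self, hexagon):
        bars = h1_barcode(pairwise_distances(hexagon), 3.0)
        assert len(bars) == 1
        assert bars[0].birth == pytest.approx(1.0, abs=1e-9)
        assert bars[0].death == pytest.approx(math.sqrt(3), abs=1e-9)

    def test_loop_open_at_threshold_is_essential(self, hexagon):
        bars = h1_barcode(pairwise_distances(hexagon), 1.2)
        assert len(bars) == 1 and math.isinf(bars[0].death)

    def test_nonpositive_threshold_rejected(self, unit_square):
        with pytest.raises(ValueError):
            h1_barcode(pairwise_distances(unit_square), 0.0)


class TestDiagram:
    def test_unit_square_full_diagram(self, unit_square):
        diag = compute_diagram(unit_square, 3.0)
        assert len(diag.bars_in_dim(0)) == 4
        assert len(diag.bars_in_dim(1)) == 1
        assert diag.threshold == 3.0

    def test_single_point(self):
        assert len(compute_diagram([[0.0, 0.0]], 1.0).bars) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_random_clouds(self, seed):
        """Bar multisets in dims 0 and 1 match the brute-force reduction exactly."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(10, 40))
        pts = rng.random((n, 2)) * 40
        diag = compute_diagram(pts, 150.0)
        oracle = rips_barcode_bruteforce(pts, 150.0)
        for dim in (0, 1):
            mine = sorted((b.birth, b.death) for b in diag.bars_in_dim(dim))
            assert len(mine) == len(oracle[dim])
            for (b1, d1), (b2, d2) in zip(mine, oracle[dim]):
                assert b1 == pytest.approx(b2, abs=1e-9)
                assert (math.isinf(d1) and math.isinf(d2)) or d1 == pytest.approx(d2, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_threshold(self, disk_cloud, seed):
        """Raising the threshold preserves bars born below the old one."""
        pts = disk_cloud(35, 20.0, seed + 50)
        lo, hi = 12.0, 30.0
        bars_lo = compute_diagram(pts, lo).bars_in_dim(1)
        bars_hi = compute_diagram(pts, hi).bars_in_dim(1)
        fin_lo = {(b.birth, b.death) for b in bars_lo if math.isfinite(b.death) and b.death <= lo}
        fin_hi = {(b.birth, b.death) for b in bars_hi if b.birth <= lo and b.death <= lo}
        assert fin_lo == fin_hi
        inf_lo = sorted(b.birth for b in bars_lo if math.isinf(b.death))
        ext_hi = sorted(b.birth for b in bars_hi if b.birth <= lo and b.death > lo)
        assert np.allclose(inf_lo, ext_hi)

    @pytest.mark.parametrize("scale", [0.4, 2.5])
    def test_scale_equivariance(self, disk_cloud, scale):
        """Scaling coordinates by c scales every birth and death by c."""
        pts = disk_cloud(30, 15.0, 9)
        base = compute_diagram(pts, 40.0)
        scaled = compute_diagram(pts * scale, 40.0 * scale)
        for dim in (0, 1):
            b0 = sorted((b.birth, b.death) for b in base.bars_in_dim(dim))
            b1 = sorted((b.birth, b.death) for b in scaled.bars_in_dim(dim))
            assert len(b0) == len(b1)
            for (x0, y0), (x1, y1) in zip(b0, b1):
                assert x1 == pytest.approx(scale * x0, rel=1e-9)
                assert (math.isinf(y0) and math.isinf(y1)) or y1 == pytest.approx(
                    scale * y0, rel=1e-9
                )

    def test_exactly_one_essential_component(self, disk_cloud):
        diag = compute_diagram(disk_cloud(60, 30.0, 2), 60.0)
        essential = [b for b in diag.bars_in_dim(0) if math.isinf(b.death)]
        assert len(essential) == 1
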