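"""Landscape-metric unit and property tests: patches, cover, NNI, greenspace."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canopyreg import (
    BinaryRaster,
    classify_greenspace,
    compute_tract_metrics,
    extract_patches,
    median_patch_size,
    nearest_neighbor_index,
    simulate_partition,
    tree_cover_fraction,
)


def flood_fill_patches(grid: np.ndarray, connectivity: int) -> list[set]:
    """Brute-force connected components by BFS; the independent oracle."""
    nrows, ncols = grid.shape
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = set()
    comps = []
    for r in range(nrows):
        for c in range(ncols):
            if grid[r, c] and (r, c) not in seen:
                comp, queue = set(), [(r, c)]
                seen.add((r, c))
                while queue:
                    cr, cc = queue.pop()
                    comp.add((cr, cc))
                    for dr, dc in steps:
                        nr, nc = cr + dr, cc + dc
                        if (0 <= nr < nrows and 0 <= nc < ncols
                                and grid[nr, nc] and (nr, nc) not in seen):
                            seen.add((nr, nc))
                            queue.append((nr, nc))
                comps.append(comp)
    return comps


class TestExtractPatches:
    def test_single_cell_is_one_patch(self):
        g = np.zeros((5, 5), dtype=np.uint8)
        g[2, 2] = 1
        patches = extract_patches(BinaryRaster(g, 2.0), np.ones((5, 5), bool))
        assert len(patches) == 1
        assert patches[0].area == 4.0  # cell_size^2

    @pytest.mark.parametrize("connectivity,expected", [(4, 2), (8, 1)])
    def test_diagonal_touch_depends_on_connectivity(self, connectivity, expected):
        g = np.zeros((4, 4), dtype=np.uint8)
        g[1, 1] = g[2, 2] = 1
        patches = extract_patches(BinaryRaster(g), np.ones((4, 4), bool),
                                  connectivity=connectivity)
        assert len(patches) == expected

    def test_empty_intersection_gives_empty_list(self):
        g = np.ones((3, 3), dtype=np.uint8)
        assert extract_patches(BinaryRaster(g), np.zeros((3, 3), bool)) == []

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle_on_random_rasters(self, connectivity, rng):
        for _ in range(25):
            g = (rng.random((50, 50)) < 0.4).astype(np.uint8)
            patches = extract_patches(BinaryRaster(g), np.ones((50, 50), bool),
                                      connectivity=connectivity)
            oracle = flood_fill_patches(g, connectivity)
            assert len(patches) == len(oracle)
            got = sorted(frozenset(map(tuple, p.cells)) for p in patches)
            assert got == sorted(map(frozenset, oracle))

    def test_patch_areas_sum_to_canopy_area(self, rng):
        g = (rng.random((30, 30)) < 0.3).astype(np.uint8)
        r = BinaryRaster(g, 3.0)
        patches = extract_patches(r, np.ones((30, 30), bool))
        assert np.isclose(sum(p.area for p in patches), g.sum() * 9.0)


class TestTreeCover:
    def test_extremes_and_checkerboard(self):
        mask = np.ones((6, 6), bool)
        zero = BinaryRaster(np.zeros((6, 6), dtype=np.uint8))
        ones = BinaryRaster(np.ones((6, 6), dtype=np.uint8))
        board = BinaryRaster((np.indices((6, 6)).sum(axis=0) % 2).astype(np.uint8))
        assert tree_cover_fraction(zero, mask) == 0.0
        assert tree_cover_fraction(ones, mask) == 1.0
        assert tree_cover_fraction(board, mask) == 0.5

    def test_monotone_under_adding_canopy(self, rng):
        g = (rng.random((20, 20)) < 0.2).astype(np.uint8)
        mask = np.ones((20, 20), bool)
        base = tree_cover_fraction(BinaryRaster(g), mask)
        g2 = g.copy()
        empty = np.argwhere(g2 == 0)
        g2[tuple(empty[0])] = 1
        assert tree_cover_fraction(BinaryRaster(g2), mask) > base


class TestMedianPatchSize:
    def test_order_statistics(self):
        mk = lambda areas: [
            type("P", (), {"area": a})() for a in areas]
        assert median_patch_size(mk([4])) == 4
        assert median_patch_size(mk([1, 9, 100])) == 9
        assert median_patch_size(mk([1, 3, 5, 100])) == 4  # mid-mean convention

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            median_patch_size([])


class TestNearestNeighborIndex:
    def test_coincident_points_give_zero(self):
        pts = np.zeros((5, 2))
        assert nearest_neighbor_index(pts, 10.0) == 0.0

    def test_two_point_closed_form(self):
        d, A = 3.0, 36.0
        pts = np.array([[0.0, 0.0], [d, 0.0]])
        expected = d / (0.5 * np.sqrt(A / 2))
        assert np.isclose(nearest_neighbor_index(pts, A), expected)

    def test_fewer_than_two_points_is_an_error(self):
        with pytest.raises(ValueError):
            nearest_neighbor_index(np.array([[0.0, 0.0]]), 1.0)

    def test_csr_mean_near_one(self, rng):
        # complete spatial randomness: NNI ~ 1 up to (upward) edge bias
        vals = [nearest_neighbor_index(rng.random((200, 2)), 1.0)
                for _ in range(200)]
        assert 0.95 <= np.mean(vals) <= 1.10

    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-50, 50),
           dy=st.floats(-50, 50), scale=st.floats(0.1, 10))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_invariant_under_rigid_motion_and_rescaling(self, angle, dx, dy, scale):
        rng = np.random.default_rng(7)
        pts = rng.random((12, 2)) * 5
        area = 25.0
        base = nearest_neighbor_index(pts, area)
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        moved = pts @ R.T + [dx, dy]
        assert np.isclose(nearest_neighbor_index(moved, area), base, rtol=1e-9)
        assert np.isclose(
            nearest_neighbor_index(pts * scale, area * scale**2), base, rtol=1e-9)


class TestClassifyGreenspace:
    def test_residential_only_green(self, hand_fixture):
        part, _, landuse, _ = hand_fixture
        mask = part.mask(part.tract_ids[0])
        g = np.zeros((10, 10), dtype=np.uint8)
        g[:6, 0:5] = 1  # 30 green cells, all residential: 30% of the tract
        pg, sg, gr = classify_greenspace(BinaryRaster(g), landuse, mask)
        assert (pg, sg, gr) == (0.30, 0.0, 0.0)

    def test_no_green_gives_zeros(self, hand_fixture):
        part, _, landuse, _ = hand_fixture
        mask = part.mask(part.tract_ids[0])
        g = BinaryRaster(np.zeros((10, 10), dtype=np.uint8))
        assert classify_greenspace(g, landuse, mask) == (0.0, 0.0, 0.0)

    def test_unclassified_land_is_counted_in_neither(self):
        from canopyreg import LandUseMap
        part, _ = simulate_partition(1, 1, 4)
        mask = part.mask(part.tract_ids[0])
        labels = np.full((4, 4), LandUseMap.code("other"), dtype=np.int16)
        g = BinaryRaster(np.ones((4, 4), dtype=np.uint8))
        assert classify_greenspace(g, LandUseMap(labels), mask) == (0.0, 0.0, 0.0)


class TestComputeTractMetrics:
    def test_hand_fixture_all_six_metrics(self, hand_fixture):
        part, canopy, landuse, green = hand_fixture
        table = compute_tract_metrics(canopy, green, landuse, part)
        row = table.iloc[0]
        assert row["TreeCov"] == 8 / 100
        assert row["TreeClus"] == 3.0
        # hand-worked NNI: centroids A=(2, 8), B=(7.5, 8.5), C=(17/6, 11/6);
        # nearest-neighbour distances sqrt(30.5), sqrt(30.5), sqrt(697/18)
        d_obs = (2 * np.sqrt(30.5) + np.sqrt(697 / 18)) / 3
        d_exp = 0.5 * np.sqrt(100 / 3)
        assert np.isclose(row["TreeAgr"], d_obs / d_exp, rtol=1e-12)
        assert row["PrvtGrn"] == 0.06
        assert row["SemiGrn"] == 0.03
        assert row["GrnRec"] == 0.02
        assert row["flags"] == ""

    def test_empty_canopy_flags_undefined_metrics(self, hand_fixture):
        part, _, landuse, green = hand_fixture
        empty = BinaryRaster(np.zeros((10, 10), dtype=np.uint8))
        table = compute_tract_metrics(empty, green, landuse, part)
        row = table.iloc[0]
        assert row["TreeCov"] == 0.0
        assert np.isnan(row["TreeClus"]) and np.isnan(row["TreeAgr"])
        assert "TreeClus" in row["flags"] and "TreeAgr" in row["flags"]

    def test_invariant_under_tract_relabeling(self, rng):
        from canopyreg import LandUseMap, simulate_canopy
        part, _ = simulate_partition(2, 2, 8)
        canopy = simulate_canopy(part, 0.3, patch_intensity=0.05, seed=5)
        labels = np.zeros(canopy.grid.shape, dtype=np.int16)
        landuse = LandUseMap(labels)
        green = BinaryRaster(np.zeros_like(canopy.grid))
        t1 = compute_tract_metrics(canopy, green, landuse, part)
        part2 = type(part)(
            [f"Z{t}" for t in part.tract_ids], part.tract_of_cell,
            part.cell_size, part.origin, {}, part.layout)
        t2 = compute_tract_metrics(canopy, green, landuse, part2)
        np.testing.assert_allclose(
            t1[["TreeCov", "TreeClus", "TreeAgr"]].to_numpy(),
            t2[["TreeCov", "TreeClus", "TreeAgr"]].to_numpy())
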