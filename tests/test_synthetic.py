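"""Synthetic landscape / covariate / outcome generators: determinism,
construction arithmetic, and data-generating-process correctness."""

import numpy as np
import pytest

from canopyreg import (
    SyntheticTruth,
    build_queen_weights,
    classify_greenspace,
    extract_patches,
    make_dataset,
    median_patch_size,
    morans_i,
    row_standardize,
    simulate_canopy,
    simulate_covariates,
    simulate_landuse_and_green,
    simulate_outcome,
    simulate_partition,
)
from canopyreg.synthetic import COVARIATE_COLUMNS


class TestSimulatePartition:
    @pytest.mark.parametrize("args,n_tracts,area", [
        ((2, 2, 10, 1.0), 4, 100.0),
        ((1, 3, 5, 2.0), 3, 100.0),
        ((20, 20, 25, 1.0), 400, 625.0),
    ])
    def test_tract_count_and_areas(self, args, n_tracts, area):
        part, empty = simulate_partition(*args)
        assert part.n_tracts == n_tracts
        assert all(np.isclose(a, area) for a in part.areas().values())
        assert empty.grid.shape == (args[0] * args[2], args[1] * args[2])
        assert empty.grid.sum() == 0

    def test_tiles_grid_without_gaps(self):
        part, _ = simulate_partition(20, 20, 25)
        assert part.tract_of_cell.shape == (500, 500)
        assert part.tract_of_cell.min() == 0
        assert len(np.unique(part.tract_of_cell)) == 400

    @pytest.mark.parametrize("bad", [(0, 2, 5), (2, -1, 5), (2, 2, 0)])
    def test_nonpositive_dimensions_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_partition(*bad)


class TestSimulateCanopy:
    def test_zero_cover_gives_empty_raster(self):
        part, _ = simulate_partition(2, 2, 10)
        r = simulate_canopy(part, 0.0, seed=1)
        assert r.grid.sum() == 0

    def test_deterministic_under_seed(self):
        part, _ = simulate_partition(3, 3, 12)
        a = simulate_canopy(part, 0.25, patch_intensity=0.03, seed=7)
        b = simulate_canopy(part, 0.25, patch_intensity=0.03, seed=7)
        assert np.array_equal(a.grid, b.grid)
        c = simulate_canopy(part, 0.25, patch_intensity=0.03, seed=8)
        assert not np.array_equal(a.grid, c.grid)

    def test_realized_cover_within_rounding_of_target(self):
        part, _ = simulate_partition(3, 3, 20)
        r = simulate_canopy(part, 0.18, patch_intensity=0.02, seed=2)
        for k in range(9):
            mask = part.tract_of_cell == k
            realized = r.grid[mask].mean()
            assert abs(realized - 0.18) <= 1.0 / mask.sum() + 1e-12

    def test_invalid_cover_rejected(self):
        part, _ = simulate_partition(1, 1, 10)
        with pytest.raises(ValueError):
            simulate_canopy(part, 1.0)
        with pytest.raises(ValueError):
            simulate_canopy(part, -0.1)

    def test_fewer_seeds_give_larger_patches(self):
        # Monte-Carlo: same cover, 5 vs 500 expected seeds; patch extraction
        # is the measuring oracle
        part, _ = simulate_partition(1, 1, 50)
        area = 2500.0
        med_few, med_many = [], []
        for rep in range(30):
            few = simulate_canopy(part, 0.2, patch_intensity=5 / area,
                                  patch_growth=6.0, seed=100 + rep)
            many = simulate_canopy(part, 0.2, patch_intensity=500 / area,
                                   patch_growth=6.0, seed=100 + rep)
            mask = np.ones((50, 50), bool)
            med_few.append(median_patch_size(extract_patches(few, mask)))
            med_many.append(median_patch_size(extract_patches(many, mask)))
        assert np.mean(med_few) > np.mean(med_many)


class TestSimulateLanduseAndGreen:
    def test_all_zero_green_shares(self):
        part, _ = simulate_partition(2, 2, 10)
        _, green = simulate_landuse_and_green(
            part, {"residential": 1.0}, {"residential": 0.0}, seed=3)
        assert green.grid.sum() == 0

    def test_single_class_green_fraction(self):
        part, _ = simulate_partition(2, 2, 10)
        lu, green = simulate_landuse_and_green(
            part, {"residential": 1.0}, {"residential": 0.3}, seed=3)
        for k, tid in enumerate(part.tract_ids):
            mask = part.tract_of_cell == k
            pg, sg, gr = classify_greenspace(green, lu, mask)
            assert np.isclose(pg, 0.3, atol=1 / mask.sum())
            assert sg == 0.0 and gr == 0.0

    def test_mixed_shares_round_trip(self):
        shares = {"residential": 0.5, "golf": 0.3, "park_recreation": 0.2}
        gshares = {"residential": 0.2, "golf": 0.8, "park_recreation": 0.5}
        part, _ = simulate_partition(2, 2, 30)
        lu, green = simulate_landuse_and_green(part, shares, gshares, seed=5)
        n_cells = 900
        for k, tid in enumerate(part.tract_ids):
            mask = part.tract_of_cell == k
            pg, sg, gr = classify_greenspace(green, lu, mask)
            # one cell of tolerance per block boundary (3 blocks, 30 rows)
            tol = 2 * 30 / n_cells
            assert abs(pg - 0.5 * 0.2) <= tol
            assert abs(sg - 0.3 * 0.8) <= tol
            assert abs(gr - 0.2 * 0.5) <= tol

    def test_shares_must_sum_to_one(self):
        part, _ = simulate_partition(1, 1, 5)
        with pytest.raises(ValueError):
            simulate_landuse_and_green(part, {"residential": 0.7}, {}, seed=0)

    def test_deterministic_under_seed(self):
        part, _ = simulate_partition(2, 2, 15)
        shares = {"residential": 0.6, "park_recreation": 0.4}
        g = {"residential": 0.3, "park_recreation": 0.6}
        a = simulate_landuse_and_green(part, shares, g, seed=9,
                                       share_concentration=40.0)
        b = simulate_landuse_and_green(part, shares, g, seed=9,
                                       share_concentration=40.0)
        assert np.array_equal(a[0].labels, b[0].labels)
        assert np.array_equal(a[1].grid, b[1].grid)


class TestSimulateCovariates:
    def test_identity_correlation_gives_uncorrelated_columns(self):
        df = simulate_covariates(10_000, correlation=np.eye(7), seed=1)
        r = df.corr().to_numpy()
        off = r[~np.eye(7, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_requested_correlation_is_realized(self):
        C = np.eye(7)
        C[0, 1] = C[1, 0] = 0.6
        df = simulate_covariates(20_000, correlation=C, seed=2)
        got = df[COVARIATE_COLUMNS[0]].corr(df[COVARIATE_COLUMNS[1]])
        assert abs(got - 0.6) < 0.05  # clipping shrinks it slightly

    def test_percentages_within_bounds(self):
        df = simulate_covariates(5000, seed=3)
        for col in ("PovRt", "EduAtn", "EtnGrp", "ChldPop", "SnrPop"):
            assert df[col].between(0, 100).all()

    def test_empty_and_seeded(self):
        with pytest.raises(ValueError):
            simulate_covariates(0)
        a = simulate_covariates(50, seed=4)
        b = simulate_covariates(50, seed=4)
        assert a.equals(b)

    def test_invalid_correlation_rejected(self):
        C = np.eye(7)
        C[0, 1] = C[1, 0] = 1.5  # not PSD
        with pytest.raises(ValueError):
            simulate_covariates(10, correlation=C)


@pytest.fixture(scope="module")
def outcome_setup():
    part, _ = simulate_partition(8, 8, 2)
    W = row_standardize(build_queen_weights(part))
    rng = np.random.default_rng(6)
    X = np.column_stack([np.ones(W.n), rng.standard_normal((W.n, 2))])
    return X, W


class TestSimulateOutcome:

    def test_rho_zero_equals_none_process(self, outcome_setup):
        X, W = outcome_setup
        beta = np.array([1.0, 2.0, -1.0])
        y_lag = simulate_outcome(X, W, SyntheticTruth(
            "lag", beta, 1.0, seed=11, rho=0.0))
        y_none = simulate_outcome(X, W, SyntheticTruth(
            "none", beta, 1.0, seed=11))
        np.testing.assert_allclose(y_lag, y_none, atol=1e-12)

    def test_zero_noise_returns_exact_mean(self, outcome_setup):
        X, W = outcome_setup
        beta = np.array([1.0, 2.0, -1.0])
        y = simulate_outcome(X, W, SyntheticTruth("none", beta, 0.0, seed=1))
        np.testing.assert_allclose(y, X @ beta, atol=1e-14)

    def test_inadmissible_parameter_rejected(self, outcome_setup):
        X, W = outcome_setup
        with pytest.raises(ValueError, match="admissible"):
            simulate_outcome(X, W, SyntheticTruth(
                "lag", np.zeros(3), 1.0, seed=1, rho=1.5))

    def test_lag_mean_matches_analytic_form(self, outcome_setup):
        X, W = outcome_setup
        beta = np.array([1.0, 2.0, -1.0])
        rho = 0.6
        analytic = np.linalg.solve(np.eye(W.n) - rho * W.matrix, X @ beta)
        draws = np.stack([
            simulate_outcome(X, W, SyntheticTruth(
                "lag", beta, 1.0, seed=s, rho=rho)) for s in range(400)])
        mc_se = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - analytic) < 4 * mc_se + 1e-9)

    def test_lag_process_leaves_spatial_signal(self, outcome_setup):
        # structural residuals y - X beta (true beta) carry positive
        # autocorrelation detectable by Moran's I
        X, W = outcome_setup
        beta = np.array([1.0, 2.0, -1.0])
        hits = 0
        for s in range(50):
            y = simulate_outcome(X, W, SyntheticTruth(
                "lag", beta, 1.0, seed=s, rho=0.7))
            e = y - X @ beta
            if morans_i(e - e.mean(), W).z > 2:
                hits += 1
        assert hits >= 48


class TestMakeDataset:
    def test_reproducible_and_truth_recorded(self):
        a = make_dataset(n_rows=4, n_cols=4, tract_cells=10, seed=5)
        b = make_dataset(n_rows=4, n_cols=4, tract_cells=10, seed=5)
        assert a.table.equals(b.table)
        assert np.array_equal(a.canopy.grid, b.canopy.grid)
        assert a.truth.process == "lag" and a.truth.rho == 0.541

    def test_nonresidential_tracts_are_parkland(self):
        ds = make_dataset(n_rows=4, n_cols=4, tract_cells=10,
                          n_nonresidential=3, seed=6)
        share = ds.table["residential_share"].to_numpy()
        assert (share[:3] == 0.0).all()
        assert (share[3:] > 0.2).all()
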