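import math

import numpy as np
import pandas as pd
import pytest

from patchspread.landscape_io import (
    CostRaster,
    GridGeometry,
    SuitabilityRaster,
    make_fishnet,
)
from patchspread.patch_delineation import PatchLandscape
from patchspread.spread_simulator import (
    MovementEngine,
    SimulationConfig,
    density_dependent_rate,
    effective_cost,
    effective_cost_grids,
    init_from_buffer,
    init_from_cells,
    max_dispersal_distance_km,
    patch_carrying_capacity,
    reproduce,
    run_simulation,
    settlement_probability,
    step_weights,
    transfer,
)


def _cost(values, nodata_mask=None, cell_size=100.0):
    values = np.asarray(values, dtype=np.int64)
    geom = GridGeometry(nrows=values.shape[0], ncols=values.shape[1], cell_size=cell_size)
    return CostRaster(values=values, geometry=geom, nodata_mask=nodata_mask)


def _landscape(patch_ids, suit=0.9, cell_size=100.0):
    patch_ids = np.asarray(patch_ids, dtype=np.int64)
    geom = GridGeometry(
        nrows=patch_ids.shape[0], ncols=patch_ids.shape[1], cell_size=cell_size
    )
    records = []
    for pid in np.unique(patch_ids[patch_ids > 0]):
        n = int((patch_ids == pid).sum())
        records.append(
            {
                "id": int(pid),
                "n_cells": n,
                "area_km2": n * geom.cell_area_km2,
                "mean_suit": suit,
            }
        )
    table = pd.DataFrame.from_records(
        records, columns=["id", "n_cells", "area_km2", "mean_suit"]
    )
    return PatchLandscape(patch_ids=patch_ids, table=table, geometry=geom)


def corridor_landscape():
    """1-cell patches A and B joined by a 5-cell unit-cost channel.

    The channel extends one cell past B (so the perceptual ray does not
    penalise approaching it) and the walkable band is bounded by nodata.
    """
    ids = np.zeros((7, 13), dtype=np.int64)
    ids[3, 3] = 1
    ids[3, 9] = 2
    cost = np.full((7, 13), 100, dtype=np.int64)
    cost[3, 3:11] = 1
    nodata = np.ones((7, 13), dtype=bool)
    nodata[2:5, 1:12] = False
    land = _landscape(ids, suit=1.0)
    return land, _cost(cost, nodata_mask=nodata)


class TestClosedForms:
    @pytest.mark.parametrize(
        "n,expected", [(0, 1.0), (1, math.exp(-1)), (3, math.exp(-3))]
    )
    def test_density_dependence(self, n, expected):
        assert density_dependent_rate(1.0, 1.0, n) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            density_dependent_rate(1.0, 1.0, -1)

    @pytest.mark.parametrize(
        "area,suit,k_max,expected",
        [(1.0, 1.0, 1.0, 1), (1.5, 0.8, 10.0, 12), (0.06, 0.56, 1.0, 1)],
    )
    def test_carrying_capacity(self, area, suit, k_max, expected):
        assert patch_carrying_capacity(area, suit, k_max) == expected

    def test_settlement_logistic(self):
        assert settlement_probability(0.5, 1, -100.0, 1.0) == pytest.approx(1.0, abs=1e-20)
        assert settlement_probability(1.0, 1, -100.0, 1.0) == pytest.approx(0.5)
        assert settlement_probability(1.5, 1, -100.0, 1.0) == pytest.approx(0.0, abs=1e-20)

    def test_settlement_bad_capacity(self):
        with pytest.raises(ValueError):
            settlement_probability(1, 0, -100.0, 1.0)

    def test_max_dispersal_distance(self):
        config = SimulationConfig(max_steps=200)
        assert max_dispersal_distance_km(config, 100.0) == 20.0


class TestReproduce:
    def test_no_adults_no_juveniles(self):
        assert reproduce(0, 0, SimulationConfig(), np.random.default_rng(0)) == 0

    def test_monte_carlo_mean_matches_closed_form(self):
        # 1 adult at N=1: expected juveniles e^-1
        config = SimulationConfig()
        rng = np.random.default_rng(12345)
        n = 10_000
        draws = [reproduce(1, 1, config, rng) for _ in range(n)]
        expected = math.exp(-1)
        se = math.sqrt(expected / n)  # Poisson variance = mean
        assert abs(np.mean(draws) - expected) < 3 * se

    def test_no_density_dependence(self):
        config = SimulationConfig(dd_strength_inv=0.0)  # b treated as 0
        rng = np.random.default_rng(7)
        draws = [reproduce(5, 5, config, rng) for _ in range(5000)]
        assert abs(np.mean(draws) - 5.0) < 4 * math.sqrt(5.0 / 5000)


class TestEffectiveCost:
    def test_uniform_cost(self):
        cost = _cost(np.full((9, 9), 7))
        for direction in range(8):
            assert effective_cost(cost, (4, 4), direction, 4) == pytest.approx(7.0)

    def test_hand_computed_ray(self):
        values = np.full((1, 5), 1, dtype=np.int64)
        values[0, 1:5] = [10, 20, 30, 40]
        cost = _cost(values)
        # weights 1, 1/2, 1/3, 1/4 -> 40 / (25/12) = 19.2
        assert effective_cost(cost, (0, 0), 2, 4) == pytest.approx(19.2)

    def test_edge_direction_disallowed(self):
        cost = _cost(np.full((3, 3), 5))
        assert effective_cost(cost, (0, 0), 0, 4) == math.inf  # facing north off-map

    def test_truncation_at_edge(self):
        cost = _cost(np.full((1, 3), 6))
        # east ray from col 0 sees cols 1..2 only
        assert effective_cost(cost, (0, 0), 2, 4) == pytest.approx(6.0)

    def test_nodata_truncates_ray(self):
        mask = np.zeros((1, 5), dtype=bool)
        mask[0, 2] = True
        cost = _cost(np.full((1, 5), 4), nodata_mask=mask)
        assert effective_cost(cost, (0, 0), 2, 4) == pytest.approx(4.0)  # only d=1
        assert effective_cost(cost, (0, 1), 2, 4) == math.inf  # adjacent nodata

    def test_grids_match_scalar(self):
        rng = np.random.default_rng(3)
        values = rng.integers(1, 100, size=(12, 15))
        mask = rng.random((12, 15)) < 0.1
        cost = _cost(values, nodata_mask=mask)
        grids = effective_cost_grids(cost, 4)
        for r in range(12):
            for c in range(15):
                for d in range(8):
                    assert grids[d, r, c] == pytest.approx(
                        effective_cost(cost, (r, c), d, 4)
                    ), (r, c, d)


class TestStepWeights:
    def test_uniform_no_heading(self):
        cost = _cost(np.full((9, 9), 10))
        grids = effective_cost_grids(cost, 4)
        w = step_weights((4, 4), None, grids, 5.0)
        np.testing.assert_allclose(w, np.full(8, 1 / 8))

    def test_heading_persistence_ratio(self):
        cost = _cost(np.full((11, 11), 10))
        grids = effective_cost_grids(cost, 4)
        w = step_weights((5, 5), 2, grids, 5.0)  # heading east
        assert w[2] / w[6] == pytest.approx(5.0)  # east / west = DP^1 / DP^0

    def test_dp_one_pure_cost(self):
        values = np.full((11, 11), 10, dtype=np.int64)
        values[:, 7:] = 50
        cost = _cost(values)
        grids = effective_cost_grids(cost, 4)
        w_heading = step_weights((5, 5), 0, grids, 1.0)
        w_none = step_weights((5, 5), None, grids, 1.0)
        np.testing.assert_allclose(w_heading, w_none)


class TestTransfer:
    def test_corridor_settles_above_95pct(self):
        land, cost = corridor_landscape()
        config = SimulationConfig(seed=0)
        grids = effective_cost_grids(cost, 4)
        engine = MovementEngine(grids, land.patch_ids, config)
        rng = np.random.default_rng(0)
        outcomes = [
            engine.walk((3, 3), 1, [1, 0], [1, 1], rng) for _ in range(1000)
        ]
        assert sum(o == 2 for o in outcomes) > 950

    def test_saturated_destination_kills(self):
        land, cost = corridor_landscape()
        config = SimulationConfig(seed=0)
        grids = effective_cost_grids(cost, 4)
        engine = MovementEngine(grids, land.patch_ids, config)
        rng = np.random.default_rng(1)
        # B at N/K = 1.5
        outcomes = [
            engine.walk((3, 3), 1, [1, 3], [1, 2], rng) for _ in range(200)
        ]
        assert sum(o == 2 for o in outcomes) == 0

    def test_transfer_wrapper_matches_engine(self):
        land, cost = corridor_landscape()
        config = SimulationConfig(seed=0)
        grids = effective_cost_grids(cost, 4)
        a = transfer(
            (3, 3), 1, land.patch_ids, grids,
            np.array([1, 0]), np.array([1, 1]), config, np.random.default_rng(5),
        )
        engine = MovementEngine(grids, land.patch_ids, config)
        b = engine.walk((3, 3), 1, [1, 0], [1, 1], np.random.default_rng(5))
        assert a == b

    def test_enclosed_disperser_dies(self):
        ids = np.array([[1]], dtype=np.int64)
        land = _landscape(ids)
        cost = _cost(np.array([[50]]))
        grids = effective_cost_grids(cost, 4)
        engine = MovementEngine(grids, land.patch_ids, SimulationConfig())
        assert engine.walk((0, 0), 1, [1], [1], np.random.default_rng(0)) == 0


class TestInitialisation:
    def test_buffer_includes_nearby_patch(self):
        ids = np.zeros((10, 10), dtype=np.int64)
        ids[4:6, 4:6] = 1
        land = _landscape(ids, cell_size=1000.0)
        presences = pd.DataFrame({"x": [4500.0], "y": [4500.0], "year": [1960]})
        assert init_from_buffer(land, presences, 10_000.0) == {1}

    def test_distant_patch_excluded(self):
        ids = np.zeros((10, 40), dtype=np.int64)
        ids[5, 1] = 1
        ids[5, 30] = 2  # ~29 km east at 1 km cells
        land = _landscape(ids, cell_size=1000.0)
        presences = pd.DataFrame({"x": [1500.0], "y": [4500.0], "year": [1960]})
        assert init_from_buffer(land, presences, 10_000.0) == {1}

    def test_centroid_of_symmetric_presences(self):
        ids = np.zeros((10, 10), dtype=np.int64)
        ids[4:6, 4:6] = 1
        land = _landscape(ids, cell_size=1000.0)
        presences = pd.DataFrame(
            {"x": [3000.0, 7000.0], "y": [3000.0, 7000.0], "year": [1960, 1961]}
        )
        # centroid (5000, 5000) sits inside the patch
        assert init_from_buffer(land, presences, 2_000.0) == {1}

    def test_no_patch_in_buffer_errors(self):
        ids = np.zeros((10, 40), dtype=np.int64)
        ids[5, 39] = 1
        land = _landscape(ids, cell_size=1000.0)
        presences = pd.DataFrame({"x": [500.0], "y": [5000.0], "year": [1960]})
        with pytest.raises(ValueError, match="no patch within"):
            init_from_buffer(land, presences, 5_000.0)

    def test_cells_init_union(self):
        ids = np.zeros((20, 20), dtype=np.int64)
        ids[2:4, 2:4] = 1
        ids[6:8, 6:8] = 2
        ids[15:17, 15:17] = 3
        land = _landscape(ids, cell_size=1000.0)
        fishnet = make_fishnet(land.geometry.extent, 10_000.0)
        presences = pd.DataFrame(
            {"x": [3000.0, 16_000.0], "y": [17_000.0, 4000.0], "year": [1960, 1961]}
        )
        # first presence in NW fishnet cell (patches 1, 2), second in SE (patch 3)
        assert init_from_cells(land, presences, fishnet) == {1, 2, 3}

    def test_cells_init_empty_errors(self):
        ids = np.zeros((20, 20), dtype=np.int64)
        ids[2:4, 2:4] = 1
        land = _landscape(ids, cell_size=1000.0)
        fishnet = make_fishnet(land.geometry.extent, 10_000.0)
        presences = pd.DataFrame({"x": [19_000.0], "y": [1000.0], "year": [1960]})
        with pytest.raises(ValueError, match="no patch"):
            init_from_cells(land, presences, fishnet)


class TestRunSimulation:
    def test_unknown_init_patch(self):
        land, cost = corridor_landscape()
        with pytest.raises(ValueError, match="not in landscape"):
            run_simulation(land, cost, [99], SimulationConfig(total_years=5))

    def test_empty_init(self):
        land, cost = corridor_landscape()
        with pytest.raises(ValueError, match="non-empty"):
            run_simulation(land, cost, [], SimulationConfig(total_years=5))

    def test_isolated_patch_persists(self):
        ids = np.zeros((9, 9), dtype=np.int64)
        ids[3:6, 3:6] = 1
        land = _landscape(ids)
        cost = _cost(np.full((9, 9), 50))
        config = SimulationConfig(seed=4, total_years=100, replicates=3)
        series = run_simulation(land, cost, [1], config)
        assert (series.occupancy[:, :, 0] == 1).all()

    def test_occupancy_threshold_boundary(self):
        # 7/10 occupied -> mean 0.7 -> occupied; 6/10 -> not
        from patchspread.spread_simulator import OccupancySeries

        occ = np.zeros((10, 1, 2), dtype=np.int8)
        occ[:7, 0, 0] = 1
        occ[:6, 0, 1] = 1
        series = OccupancySeries(
            occupancy=occ,
            checkpoint_years=np.array([10]),
            patch_ids=np.array([1, 2]),
            occupancy_threshold=0.7,
        )
        assert series.occupied_patches(0) == {1}

    def test_determinism_bit_identical(self):
        land, cost = corridor_landscape()
        config = SimulationConfig(seed=33, total_years=40, replicates=4)
        a = run_simulation(land, cost, [1], config)
        b = run_simulation(land, cost, [1], config)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        np.testing.assert_array_equal(a.checkpoint_years, b.checkpoint_years)


class TestSimulatorInvariants:
    def test_occupancy_monotone_corridor(self, corridor_run):
        occ = corridor_run["series"].occupancy
        assert (np.diff(occ.astype(int), axis=1) >= 0).all()

    def test_occupancy_monotone_archipelago(self, archipelago_run):
        occ = archipelago_run["series"].occupancy
        assert (np.diff(occ.astype(int), axis=1) >= 0).all()

    @pytest.mark.parametrize("run_name", ["corridor_run", "archipelago_run"])
    def test_emigrant_conservation(self, run_name, request):
        run = request.getfixturevalue(run_name)
        for rep_stats in run["stats"]:
            for year_stats in rep_stats:
                assert (
                    year_stats.settled + year_stats.died == year_stats.emigrated
                )

    def test_adults_never_decrease_isolated(self, corridor_run):
        # patch A is seeded and never loses adults (unit survival)
        occ = corridor_run["series"].occupancy
        assert (occ[:, :, 0] == 1).all()

    def test_distance_ordering(self, archipelago_run):
        from scipy.stats import spearmanr

        series = archipelago_run["series"]
        landscape = archipelago_run["landscape"]
        truth = archipelago_run["fixture"].truth
        geom = landscape.geometry
        # map each patch to its planted blob by centroid distance
        centers = np.array(truth["centers_km"])
        dists = np.array(truth["distances_km"])
        occ = series.occupancy  # (reps, ts, patches)
        first = np.where(
            occ.any(axis=1),
            occ.argmax(axis=1),
            occ.shape[1],  # never colonised -> beyond last checkpoint
        ).astype(float)
        mean_first = first.mean(axis=0)
        patch_dist = []
        for row in landscape.table.itertuples():
            rows, cols = landscape.patch_cells(row.id)
            cx = (cols.mean() + 0.5) * geom.cell_size / 1000.0
            cy = (geom.nrows - rows.mean() - 0.5) * geom.cell_size / 1000.0
            blob = np.argmin(
                (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2
            )
            patch_dist.append(dists[blob])
        rho, _ = spearmanr(patch_dist, mean_first)
        assert rho > 0.9

    def test_mega_patch_range_overestimation(self):
        """Contiguity's one mega patch implies instant full-range coverage;
        size-constrained sub-patches colonise progressively."""
        from patchspread import landscape_io as lio
        from patchspread import patch_delineation as pdel
        from patchspread import synthetic_landscapes as synth
        from patchspread.evaluation import simulated_range_cells

        values = np.full((80, 80), 0.2)
        values[10:70, 10:70] = 0.9  # 36 km^2 block in an 8 km x 8 km extent
        geom = GridGeometry(nrows=80, ncols=80, cell_size=100.0)
        hsm = SuitabilityRaster(values=values, geometry=geom)
        cost = lio.invert_to_cost(lio.scale_suitability(hsm))
        fishnet = make_fishnet(geom.extent, 2000.0)
        cont = pdel.delineate_contiguity(hsm, 0.56)
        vor = pdel.delineate_vorcon(hsm, 0.56, seed=8)
        config = SimulationConfig(
            seed=17, total_years=40, replicates=5, n_report_timesteps=4
        )
        s_cont = run_simulation(cont, cost, [1], config)
        seed_pid = int(vor.patch_ids[12, 12])
        s_vor = run_simulation(vor, cost, [seed_pid], config)
        early = range(2)  # mid-run checkpoints
        for t in early:
            n_cont = len(simulated_range_cells(s_cont.occupied_patches(t), cont, fishnet))
            n_vor = len(simulated_range_cells(s_vor.occupied_patches(t), vor, fishnet))
            assert n_cont > n_vor
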