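"""Shared fixtures. Heavy simulations are session-scoped so unit,
invariant and acceptance tests reuse the same runs."""

from __future__ import annotations

import pytest

from patchspread import landscape_io as lio
from patchspread import patch_delineation as pdel
from patchspread import synthetic_landscapes as synth
from patchspread.spread_simulator import SimulationConfig, run_simulation

THETA = 0.56


@pytest.fixture(scope="session")
def corridor_fixture():
    return synth.two_patch_corridor()


@pytest.fixture(scope="session")
def archipelago_fixture():
    return synth.archipelago()


@pytest.fixture(scope="session")
def mega_fixture():
    return synth.mega_patch()


def _landscape_and_cost(fixture, method="contiguity", seed=5):
    hsm = fixture.hsm
    if method == "contiguity":
        landscape = pdel.delineate_contiguity(hsm, THETA)
    elif method == "vorcon":
        landscape = pdel.delineate_vorcon(hsm, THETA, seed=seed)
    else:
        raise ValueError(method)
    cost = lio.invert_to_cost(lio.scale_suitability(hsm))
    return landscape, cost


@pytest.fixture(scope="session")
def corridor_run():
    """two_patch_corridor contiguity landscape + a 10-replicate run."""
    fixture = synth.two_patch_corridor()
    landscape, cost = _landscape_and_cost(fixture)
    config = SimulationConfig(seed=11, total_years=100, replicates=10)
    init = [1]
    series, stats = run_simulation(
        landscape, cost, init, config, collect_stats=True
    )
    return {
        "fixture": fixture,
        "landscape": landscape,
        "cost": cost,
        "config": config,
        "init": init,
        "series": series,
        "stats": stats,
    }


@pytest.fixture(scope="session")
def archipelago_run():
    """archipelago contiguity landscape + a 10-replicate, 300-year run."""
    fixture = synth.archipelago()
    landscape, cost = _landscape_and_cost(fixture)
    # seed the patch containing the origin blob (distances radiate from it)
    geom = landscape.geometry
    ox_km, oy_km = fixture.truth["origin_km"]
    row, col = geom.cell_of(ox_km * 1000.0, oy_km * 1000.0)
    seed_patch = int(landscape.patch_ids[row, col])
    assert seed_patch > 0
    config = SimulationConfig(
        seed=21, total_years=300, replicates=10, n_report_timesteps=30
    )
    init = [seed_patch]
    series, stats = run_simulation(
        landscape, cost, init, config, collect_stats=True
    )
    return {
        "fixture": fixture,
        "landscape": landscape,
        "cost": cost,
        "config": config,
        "init": init,
        "series": series,
        "stats": stats,
    }


@pytest.fixture(scope="session")
def mega_benchmark():
    """mega_patch delineated both ways + matched 120-year simulations."""
    fixture = synth.mega_patch()
    hsm = fixture.hsm
    cost = lio.invert_to_cost(lio.scale_suitability(hsm))
    fishnet = lio.make_fishnet(hsm.geometry.extent, 10_000.0)
    contiguity = pdel.delineate_contiguity(hsm, THETA)
    vorcon = pdel.delineate_vorcon(hsm, THETA, seed=5)
    config = SimulationConfig(
        seed=2, total_years=120, replicates=10, n_report_timesteps=6
    )
    block = fixture.truth["block_slices"]
    seed_pid = int(vorcon.patch_ids[block[0].start + 2, block[1].start + 2])
    series_cont = run_simulation(contiguity, cost, [1], config)
    series_vor = run_simulation(vorcon, cost, [seed_pid], config)
    return {
        "fixture": fixture,
        "cost": cost,
        "fishnet": fishnet,
        "contiguity": contiguity,
        "vorcon": vorcon,
        "config": config,
        "series_contiguity": series_cont,
        "series_vorcon": series_vor,
    }


@pytest.fixture(scope="session")
def small_hsm():
    """A small autocorrelated surface with planted blobs for quick tests."""
    spec = synth.SyntheticSpec(
        width_km=6.0,
        height_km=6.0,
        seed=123,
        autocorrelation_length=400.0,
        suitability_mean=0.35,
        suitability_sd=0.2,
        n_blobs=4,
        blob_radius_range=(0.4, 0.7),
    )
    return synth.generate_hsm(spec)
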