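"""Patch-occupancy spread simulation.

Yearly cycle in every occupied patch: density-dependent reproduction,
development of juveniles into dispersers, obligate emigration, stochastic
nearest-neighbour transfer over a cost surface (perceptual range +
directional persistence), and logistic below-capacity settlement.
Settled dispersers join the destination patch as adults the next year.

Occupancy is recorded per replicate at evenly spaced checkpoints and
averaged; patches with mean occupancy at or above the threshold count as
occupied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .landscape_io import CostRaster, Fishnet
from .patch_delineation import PatchLandscape

__all__ = [
    "SimulationConfig",
    "PopulationState",
    "YearStats",
    "OccupancySeries",
    "density_dependent_rate",
    "patch_carrying_capacity",
    "settlement_probability",
    "effective_cost",
    "effective_cost_grids",
    "step_weights",
    "transfer",
    "reproduce",
    "simulate_year",
    "run_simulation",
    "init_from_buffer",
    "init_from_cells",
    "max_dispersal_distance_km",
]

# direction order: N, NE, E, SE, S, SW, W, NW (index 0..7)
DIRECTIONS: tuple[tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Demographic and movement parameters (defaults: standardised set)."""

    fecundity_max: float = 1.0          # offspring per adult per year at N=0
    survival_juvenile: float = 1.0
    survival_disperser: float = 1.0
    survival_adult: float = 1.0
    dd_strength_inv: float = 1.0        # 1/b; b = strength of density dependence
    dd_on_survival: bool = False        # see module docs: fecundity-only default
    max_age: int = 1000
    repro_prob: float = 1.0
    emigration_prob: float = 1.0        # obligate emigration of dispersers
    perceptual_range: float = 400.0     # metres
    directional_persistence: float = 5.0
    settle_slope: float = -100.0        # alpha
    settle_inflexion: float = 1.0       # beta (N/K at p = 0.5)
    max_steps: int = 200
    k_max: float = 1.0                  # individuals per fully suitable km^2
    replicates: int = 10
    occupancy_threshold: float = 0.7
    n_report_timesteps: int = 6
    total_years: int | None = None      # None -> pilot-run auto mode
    max_years_cap: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "survival_juvenile", "survival_disperser", "survival_adult",
            "repro_prob", "emigration_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.perceptual_range <= 0:
            raise ValueError("perceptual_range must be > 0")

    @property
    def b(self) -> float:
        return 1.0 / self.dd_strength_inv if self.dd_strength_inv > 0 else 0.0

    def pr_cells(self, cell_size: float) -> int:
        """Perceptual range quantised to whole cells (>= 1)."""
        return max(1, int(self.perceptual_range // cell_size))

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class PopulationState:
    """Adults per patch (index = patch id - 1) and patch carrying capacities.

    With unit survival and a maximum age far beyond any run length, the
    persistent state reduces to adult counts; juveniles and dispersers
    exist transiently inside a year step.
    """

    adults: np.ndarray
    capacity: np.ndarray

    @classmethod
    def empty(cls, landscape: PatchLandscape, config: SimulationConfig) -> "PopulationState":
        k = np.array(
            [
                patch_carrying_capacity(row.area_km2, row.mean_suit, config.k_max)
                for row in landscape.table.itertuples()
            ],
            dtype=np.int64,
        )
        return cls(adults=np.zeros(len(k), dtype=np.int64), capacity=k)

    @property
    def occupied(self) -> np.ndarray:
        return self.adults > 0


@dataclass
class YearStats:
    """Per-year dispersal bookkeeping for conservation checks."""

    emigrated: int = 0
    settled: int = 0
    died: int = 0


@dataclass
class OccupancySeries:
    """Binary occupancy per replicate/checkpoint/patch, plus the mean."""

    occupancy: np.ndarray           # (replicates, timesteps, n_patches) in {0,1}
    checkpoint_years: np.ndarray    # year index of each checkpoint
    patch_ids: np.ndarray
    occupancy_threshold: float

    @property
    def mean_occupancy(self) -> np.ndarray:
        return self.occupancy.mean(axis=0)

    def occupied_patches(self, timestep: int) -> frozenset[int]:
        """Patches whose mean occupancy clears the threshold at a checkpoint."""
        mean = self.mean_occupancy[timestep]
        return frozenset(
            int(pid) for pid, m in zip(self.patch_ids, mean)
            if m >= self.occupancy_threshold
        )

    @property
    def n_timesteps(self) -> int:
        return self.occupancy.shape[1]

    def to_frame(self) -> pd.DataFrame:
        reps, ts, np_ = self.occupancy.shape
        r, t, p = np.meshgrid(
            np.arange(reps), np.arange(ts), np.arange(np_), indexing="ij"
        )
        return pd.DataFrame(
            {
                "replicate": r.ravel(),
                "timestep": t.ravel() + 1,
                "year": self.checkpoint_years[t.ravel()],
                "patch_id": self.patch_ids[p.ravel()],
                "occupied": self.occupancy.ravel().astype(int),
            }
        )

    def mean_frame(self) -> pd.DataFrame:
        mean = self.mean_occupancy
        ts, np_ = mean.shape
        t, p = np.meshgrid(np.arange(ts), np.arange(np_), indexing="ij")
        return pd.DataFrame(
            {
                "timestep": t.ravel() + 1,
                "year": self.checkpoint_years[t.ravel()],
                "patch_id": self.patch_ids[p.ravel()],
                "mean_occupancy": mean.ravel(),
                "occupied": (mean.ravel() >= self.occupancy_threshold).astype(int),
            }
        )


# ---------------------------------------------------------------------------
# Closed-form pieces


def density_dependent_rate(x0: float, b: float, n: float) -> float:
    """Exponential density dependence: x0 * exp(-b * N)."""
    if x0 < 0 or b < 0 or n < 0:
        raise ValueError("x0, b and N must be non-negative")
    return x0 * math.exp(-b * n)


def patch_carrying_capacity(area_km2: float, mean_suit: float, k_max: float) -> int:
    """K = max(1, round(area * suitability * k_max)): linear in size x quality."""
    k = area_km2 * mean_suit * k_max
    return max(1, int(k + 0.5))


def settlement_probability(n: float, k: float, alpha: float, beta: float) -> float:
    """Logistic settlement in N/K: p = 1 / (1 + exp(-alpha * (N/K - beta))).

    With the conventional negative slope (alpha = -100) this is ~1 below
    capacity, 0.5 at capacity and ~0 above it.
    """
    if k < 1:
        raise ValueError("carrying capacity must be >= 1")
    z = -alpha * (n / k - beta)  # exponent of the logistic denominator
    if z > 700.0:
        return 0.0
    if z < -700.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def max_dispersal_distance_km(config: SimulationConfig, cell_size_m: float) -> float:
    """Maximum Euclidean displacement: a straight cardinal path of
    ``max_steps`` nearest-neighbour steps, one cell each."""
    return config.max_steps * cell_size_m / 1000.0


# ---------------------------------------------------------------------------
# Movement


def effective_cost(
    cost: CostRaster,
    from_cell: tuple[int, int],
    direction: int,
    pr_cells: int,
) -> float:
    """Inverse-distance-weighted mean cost along one directional ray.

    Cells at distance d = 1..pr_cells get weight 1/d; the ray truncates
    at the first off-map or nodata cell.  Returns +inf when even the
    adjacent cell is unavailable (direction disallowed).
    """
    dr, dc = DIRECTIONS[direction]
    r, c = from_cell
    nrows, ncols = cost.values.shape
    wsum = 0.0
    csum = 0.0
    for d in range(1, pr_cells + 1):
        rr, cc = r + d * dr, c + d * dc
        if not (0 <= rr < nrows and 0 <= cc < ncols) or cost.nodata_mask[rr, cc]:
            break
        w = 1.0 / d
        wsum += w
        csum += w * cost.values[rr, cc]
    if wsum == 0.0:
        return math.inf
    return csum / wsum


def effective_cost_grids(cost: CostRaster, pr_cells: int) -> np.ndarray:
    """Vectorised :func:`effective_cost` for every cell and direction.

    Returns an (8, nrows, ncols) array; +inf marks disallowed directions.
    """
    nrows, ncols = cost.values.shape
    valid = cost.valid_mask
    vals = cost.values.astype(float)
    out = np.full((8, nrows, ncols), np.inf)
    for di, (dr, dc) in enumerate(DIRECTIONS):
        wsum = np.zeros((nrows, ncols))
        csum = np.zeros((nrows, ncols))
        alive = np.ones((nrows, ncols), dtype=bool)
        for d in range(1, pr_cells + 1):
            shifted_valid = np.zeros((nrows, ncols), dtype=bool)
            shifted_cost = np.zeros((nrows, ncols))
            r0, r1 = max(0, -d * dr), min(nrows, nrows - d * dr)
            c0, c1 = max(0, -d * dc), min(ncols, ncols - d * dc)
            if r0 < r1 and c0 < c1:
                shifted_valid[r0:r1, c0:c1] = valid[
                    r0 + d * dr : r1 + d * dr, c0 + d * dc : c1 + d * dc
                ]
                shifted_cost[r0:r1, c0:c1] = vals[
                    r0 + d * dr : r1 + d * dr, c0 + d * dc : c1 + d * dc
                ]
            alive = alive & shifted_valid
            w = 1.0 / d
            wsum += np.where(alive, w, 0.0)
            csum += np.where(alive, w * shifted_cost, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            eff = csum / wsum
        out[di] = np.where(wsum > 0, eff, np.inf)
    return out


def _persistence_table(dp: float) -> np.ndarray:
    """pers[heading, direction]: DP^((4-k)/4), k = 45-degree increments
    between direction and heading.  Row 8 = no heading (all ones)."""
    table = np.ones((9, 8))
    for h in range(8):
        for d in range(8):
            k = abs(d - h) % 8
            k = min(k, 8 - k)
            table[h, d] = dp ** ((4 - k) / 4.0)
    return table


def step_weights(
    position: tuple[int, int],
    heading: int | None,
    eff_cost: np.ndarray,
    dp: float,
) -> np.ndarray:
    """Normalised probabilities over the 8 step directions.

    weight = persistence / effective_cost, persistence = DP^((4-k)/4)
    with k the angular offset from the heading in 45-degree increments
    (1 for all directions on a headingless first step); disallowed
    directions (infinite effective cost) get probability 0.
    """
    r, c = position
    costs = eff_cost[:, r, c]
    pers = _persistence_table(dp)[8 if heading is None else heading]
    with np.errstate(divide="ignore"):
        w = np.where(np.isfinite(costs), pers / costs, 0.0)
    total = w.sum()
    if total == 0.0:
        return w
    return w / total


class MovementEngine:
    """Pre-baked movement structures for fast per-step stepping.

    Converts the effective-cost grids, patch-ID raster and persistence
    table to nested Python lists once, so the per-step inner loop avoids
    numpy scalar overhead.
    """

    __slots__ = ("ec", "pids", "pers", "max_steps", "alpha", "beta")

    def __init__(
        self,
        eff_cost: np.ndarray,
        patch_ids: np.ndarray,
        config: SimulationConfig,
        pers_table: np.ndarray | None = None,
    ) -> None:
        if pers_table is None:
            pers_table = _persistence_table(config.directional_persistence)
        self.ec = np.ascontiguousarray(np.moveaxis(eff_cost, 0, -1)).tolist()
        self.pids = patch_ids.tolist()
        self.pers = pers_table.tolist()
        self.max_steps = config.max_steps
        self.alpha = config.settle_slope
        self.beta = config.settle_inflexion

    def walk(
        self,
        start_cell: tuple[int, int],
        natal_patch: int,
        adults: list[int],
        capacity: list[int],
        rng: np.random.Generator,
    ) -> int:
        """Walk one disperser; return settled patch id or 0 on death."""
        r, c = start_cell
        heading = 8  # index of the headingless persistence row
        ec, pids, pers_all = self.ec, self.pids, self.pers
        alpha, beta = self.alpha, self.beta
        rand = rng.random
        w = [0.0] * 8
        for _ in range(self.max_steps):
            row = ec[r][c]
            pers = pers_all[heading]
            total = 0.0
            for i in range(8):
                ci = row[i]
                if ci != math.inf:
                    wi = pers[i] / ci
                else:
                    wi = 0.0
                w[i] = wi
                total += wi
            if total == 0.0:
                return 0  # fully enclosed: dies
            u = rand() * total
            acc = 0.0
            direction = 7
            for i in range(8):
                acc += w[i]
                if u < acc:
                    direction = i
                    break
            dr, dc = DIRECTIONS[direction]
            r += dr
            c += dc
            heading = direction
            pid = pids[r][c]
            if pid != 0 and pid != natal_patch:
                p = settlement_probability(
                    adults[pid - 1], capacity[pid - 1], alpha, beta
                )
                if rand() < p:
                    return pid
        return 0


def transfer(
    start_cell: tuple[int, int],
    natal_patch: int,
    patch_ids: np.ndarray,
    eff_cost: np.ndarray,
    adults: np.ndarray,
    capacity: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    engine: MovementEngine | None = None,
) -> int:
    """Walk one disperser until settlement or death.

    Returns the settled patch id, or 0 if the disperser died (exceeded
    ``max_steps`` or got fully enclosed).  Settlement is evaluated on
    every step taken inside a non-natal patch, against the current
    occupancy of that patch; natal-patch re-entry never triggers
    settlement.
    """
    if engine is None:
        engine = MovementEngine(eff_cost, patch_ids, config)
    return engine.walk(
        start_cell, natal_patch, list(adults), list(capacity), rng
    )


# ---------------------------------------------------------------------------
# Demography


def reproduce(
    adults: int, total_n: int, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Juveniles produced this year in one patch.

    Poisson draw with mean adults * repro_prob * fecundity * exp(-b*N);
    the density-dependent mean is the stated contract, the Poisson the
    count-distribution choice.
    """
    if adults <= 0:
        return 0
    mean = adults * config.repro_prob * density_dependent_rate(
        config.fecundity_max, config.b, total_n
    )
    return int(rng.poisson(mean))


def _survive(n: int, p: float, rng: np.random.Generator) -> int:
    if p >= 1.0:
        return n
    if p <= 0.0 or n == 0:
        return 0
    return int(rng.binomial(n, p))


def simulate_year(
    state: PopulationState,
    landscape: PatchLandscape,
    engine: MovementEngine,
    config: SimulationConfig,
    rng: np.random.Generator,
    patch_cells: list[tuple[np.ndarray, np.ndarray]],
) -> YearStats:
    """Advance the population one year in place.

    Event order: reproduce -> juvenile survival/development -> obligate
    emigration and transfer -> settlement; settlers join the destination
    as adults for the next year.  Returns dispersal bookkeeping.
    """
    adults = state.adults
    capacity = state.capacity
    b = config.b
    stats = YearStats()

    # reproduction + juvenile survival per occupied patch
    dispersers_by_patch: list[tuple[int, int]] = []
    occupied_idx = np.nonzero(adults > 0)[0]
    for i in occupied_idx:
        n_t = int(adults[i])
        juveniles = reproduce(n_t, n_t, config, rng)
        sj = config.survival_juvenile
        if config.dd_on_survival:
            sj = density_dependent_rate(sj, b, n_t)
        survivors = _survive(juveniles, sj, rng)
        if config.emigration_prob < 1.0:
            survivors = _survive(survivors, config.emigration_prob, rng)
        if survivors > 0:
            dispersers_by_patch.append((int(i), survivors))
            stats.emigrated += survivors

    # transfer and settlement; settlers raise destination occupancy
    # immediately so later dispersers see it, but only become reproducing
    # adults next year (they are added to `adults` after the loop)
    settled_counts = [0] * len(adults)
    adults_now = [int(a) for a in adults]
    capacity_list = [int(k) for k in capacity]
    for patch_idx, n_disp in dispersers_by_patch:
        rows, cols = patch_cells[patch_idx]
        starts = rng.integers(0, len(rows), size=n_disp)
        natal = patch_idx + 1
        for s in starts:
            dest = engine.walk(
                (int(rows[s]), int(cols[s])), natal, adults_now, capacity_list, rng
            )
            if dest > 0:
                settled_counts[dest - 1] += 1
                adults_now[dest - 1] += 1
                stats.settled += 1
            else:
                stats.died += 1

    # adult survival (standardised set: certain survival, no ageing within cap)
    if config.survival_adult < 1.0:
        for i in np.nonzero(adults > 0)[0]:
            adults[i] = _survive(int(adults[i]), config.survival_adult, rng)
    settled = np.array(settled_counts, dtype=adults.dtype)
    if config.survival_disperser < 1.0:
        for i in np.nonzero(settled > 0)[0]:
            settled[i] = _survive(int(settled[i]), config.survival_disperser, rng)
    adults += settled
    return stats


# ---------------------------------------------------------------------------
# Initialisation


def init_from_buffer(
    landscape: PatchLandscape,
    presences: pd.DataFrame,
    radius_m: float = 10_000.0,
    first_period: tuple[int, int] | None = None,
) -> frozenset[int]:
    """Patches with any cell centre within ``radius_m`` of the centroid of
    the (first-period) presences."""
    df = presences
    if first_period is not None:
        lo, hi = first_period
        df = df[(df.year >= lo) & (df.year <= hi)]
    if len(df) == 0:
        raise ValueError("no presences available for initialisation")
    cx, cy = float(df.x.mean()), float(df.y.mean())
    geom = landscape.geometry
    ids = set()
    r2 = radius_m * radius_m
    for row in landscape.table.itertuples():
        rows, cols = landscape.patch_cells(row.id)
        x = geom.xll + (cols + 0.5) * geom.cell_size
        y = geom.yll + (geom.nrows - rows - 0.5) * geom.cell_size
        if np.any((x - cx) ** 2 + (y - cy) ** 2 <= r2):
            ids.add(int(row.id))
    if not ids:
        raise ValueError(
            f"no patch within {radius_m} m of presence centroid ({cx:.0f}, {cy:.0f})"
        )
    return frozenset(ids)


def init_from_cells(
    landscape: PatchLandscape,
    presences: pd.DataFrame,
    fishnet: Fishnet,
) -> frozenset[int]:
    """Patches inside fishnet cells that contain at least one presence."""
    if len(presences) == 0:
        raise ValueError("no presences available for initialisation")
    hit_cells = set()
    for x, y in zip(presences.x, presences.y):
        cell = fishnet.cell_of(float(x), float(y))
        if cell is not None:
            hit_cells.add(cell)
    geom = landscape.geometry
    ids = set()
    for row in landscape.table.itertuples():
        rows, cols = landscape.patch_cells(row.id)
        x = geom.xll + (cols + 0.5) * geom.cell_size
        y = geom.yll + (geom.nrows - rows - 0.5) * geom.cell_size
        for xi, yi in zip(x, y):
            if fishnet.cell_of(float(xi), float(yi)) in hit_cells:
                ids.add(int(row.id))
                break
    if not ids:
        raise ValueError("no patch intersects a presence-bearing fishnet cell")
    return frozenset(ids)


# ---------------------------------------------------------------------------
# Replicated runs


def _run_replicate(
    landscape: PatchLandscape,
    engine: MovementEngine,
    init_patches: Iterable[int],
    config: SimulationConfig,
    seed: int,
    total_years: int,
    checkpoint_years: np.ndarray,
    patch_cells: list[tuple[np.ndarray, np.ndarray]],
    collect_stats: bool = False,
) -> tuple[np.ndarray, list[YearStats]]:
    rng = np.random.default_rng(seed)
    state = PopulationState.empty(landscape, config)
    for pid in init_patches:
        state.adults[pid - 1] = state.capacity[pid - 1]
    occ = np.zeros((len(checkpoint_years), len(state.adults)), dtype=np.int8)
    checkpoints = {int(y): i for i, y in enumerate(checkpoint_years)}
    all_stats: list[YearStats] = []
    for year in range(1, total_years + 1):
        stats = simulate_year(state, landscape, engine, config, rng, patch_cells)
        if collect_stats:
            all_stats.append(stats)
        if year in checkpoints:
            occ[checkpoints[year]] = (state.adults > 0).astype(np.int8)
    return occ, all_stats


def _pilot_total_years(
    landscape: PatchLandscape,
    engine: MovementEngine,
    init_patches: Iterable[int],
    config: SimulationConfig,
    patch_cells: list[tuple[np.ndarray, np.ndarray]],
) -> int:
    """Years until a pilot replicate occupies every patch, capped."""
    rng = np.random.default_rng(config.seed)
    state = PopulationState.empty(landscape, config)
    for pid in init_patches:
        state.adults[pid - 1] = state.capacity[pid - 1]
    for year in range(1, config.max_years_cap + 1):
        simulate_year(state, landscape, engine, config, rng, patch_cells)
        if np.all(state.adults > 0):
            return year
    return config.max_years_cap


def run_simulation(
    landscape: PatchLandscape,
    cost: CostRaster,
    init_patches: Iterable[int],
    config: SimulationConfig,
    collect_stats: bool = False,
) -> OccupancySeries | tuple[OccupancySeries, list[list[YearStats]]]:
    """Run replicated spread simulations and average patch occupancy.

    Each replicate uses seed = base seed + replicate index; every initial
    patch starts at carrying capacity.  When ``config.total_years`` is
    None, a pilot replicate determines the horizon (to full occupancy or
    the cap).  Occupancy is recorded at ``n_report_timesteps`` evenly
    spaced checkpoints.
    """
    init_patches = sorted(set(int(p) for p in init_patches))
    if not init_patches:
        raise ValueError("init_patches must be non-empty")
    known = set(landscape.table.id.astype(int))
    unknown = [p for p in init_patches if p not in known]
    if unknown:
        raise ValueError(f"initial patch ids not in landscape: {unknown}")

    pr_cells = config.pr_cells(cost.geometry.cell_size)
    eff_cost = effective_cost_grids(cost, pr_cells)
    engine = MovementEngine(eff_cost, landscape.patch_ids, config)
    # off-patch movement is allowed but patch ids drive settlement
    patch_cells = [
        landscape.patch_cells(int(row.id)) for row in landscape.table.itertuples()
    ]

    total_years = config.total_years
    if total_years is None:
        total_years = _pilot_total_years(
            landscape, engine, init_patches, config, patch_cells
        )
    t = config.n_report_timesteps
    checkpoint_years = np.unique(
        np.maximum(1, np.round(np.arange(1, t + 1) * total_years / t)).astype(int)
    )

    occ = np.zeros(
        (config.replicates, len(checkpoint_years), landscape.n_patches), dtype=np.int8
    )
    stats_by_rep: list[list[YearStats]] = []
    for rep in range(config.replicates):
        occ[rep], stats = _run_replicate(
            landscape,
            engine,
            init_patches,
            config,
            config.seed + rep,
            total_years,
            checkpoint_years,
            patch_cells,
            collect_stats=collect_stats,
        )
        stats_by_rep.append(stats)

    series = OccupancySeries(
        occupancy=occ,
        checkpoint_years=checkpoint_years,
        patch_ids=landscape.table.id.to_numpy(dtype=np.int64),
        occupancy_threshold=config.occupancy_threshold,
    )
    if collect_stats:
        return series, stats_by_rep
    return series
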