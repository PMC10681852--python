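"""Range evaluation against presence records.

Observed ranges are built per timestep as minimum convex polygons around
cumulative presences, rasterised onto a coarse fishnet (ObsRange), with
the presence-bearing subset of those cells as a stricter comparator
(ObsPresences).  Simulated ranges are the fishnet cells touched by
occupied patches.  Agreement is scored with sensitivity, specificity and
the True Skill Statistic, with a maxSSS threshold utility and a +/-10%
parameter-perturbation harness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon, box

from .landscape_io import CostRaster, Fishnet
from .patch_delineation import PatchLandscape
from .spread_simulator import OccupancySeries, SimulationConfig, run_simulation

__all__ = [
    "RangeObservation",
    "ConfusionCounts",
    "EvalResult",
    "DegenerateGeometryError",
    "UndefinedMetricError",
    "minimum_convex_polygon",
    "observed_ranges",
    "simulated_range_cells",
    "true_skill_statistic",
    "evaluate_timeseries",
    "maxsss_threshold",
    "sensitivity_analysis",
    "jaccard",
]

Cell = tuple[int, int]


class DegenerateGeometryError(ValueError):
    """Fewer than three non-collinear points: no convex polygon exists."""


class UndefinedMetricError(ValueError):
    """Sensitivity or specificity has an empty denominator."""


@dataclass
class RangeObservation:
    """Observed range for one timestep."""

    period: tuple[int, int]
    n_presences: int
    mcp: Polygon | None
    obs_range_cells: frozenset[Cell]
    obs_presence_cells: frozenset[Cell]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise UndefinedMetricError("no observed presences: sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise UndefinedMetricError("no observed absences: specificity undefined")
        return self.tn / (self.tn + self.fp)

    @property
    def tss(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class EvalResult:
    """Per-timestep scores and summary statistics per comparator."""

    per_timestep: pd.DataFrame  # timestep, comparator, tp, fp, fn, tn, sens, spec, tss
    summary: pd.DataFrame       # comparator, mean, sd, min, max

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "EvalResult":
        per_ts = pd.DataFrame.from_records(rows)
        summaries = []
        for comparator, grp in per_ts.groupby("comparator", sort=True):
            tss = grp.tss.to_numpy(dtype=float)
            summaries.append(
                {
                    "comparator": comparator,
                    "mean_tss": float(np.mean(tss)),
                    "sd_tss": float(np.std(tss, ddof=1)) if len(tss) > 1 else 0.0,
                    "min_tss": float(np.min(tss)),
                    "max_tss": float(np.max(tss)),
                }
            )
        return cls(per_timestep=per_ts, summary=pd.DataFrame.from_records(summaries))


# ---------------------------------------------------------------------------


def minimum_convex_polygon(points: np.ndarray) -> Polygon:
    """Convex hull of >= 3 non-collinear points."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {len(pts)}")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateGeometryError("points are collinear: hull is degenerate")
    return hull


def _presence_cells(df: pd.DataFrame, fishnet: Fishnet) -> frozenset[Cell]:
    cells = set()
    for x, y in zip(df.x, df.y):
        cell = fishnet.cell_of(float(x), float(y))
        if cell is not None:
            cells.add(cell)
    return frozenset(cells)


def observed_ranges(
    presences: pd.DataFrame,
    periods: list[tuple[int, int]],
    fishnet: Fishnet,
) -> list[RangeObservation]:
    """Per-period observed ranges from cumulative presences.

    For each period the convex hull of all presences up to the period end
    is intersected with the fishnet to give ObsRange; cells containing
    presences (within ObsRange) give ObsPresences.  Periods with no
    presences are skipped with a warning; periods whose cumulative points
    are degenerate fall back to the presence cells as the range.
    """
    out: list[RangeObservation] = []
    for period in periods:
        lo, hi = period
        cum = presences[presences.year <= hi]
        if len(cum) == 0 or len(presences[(presences.year >= lo) & (presences.year <= hi)]) == 0:
            if len(cum) == 0:
                warnings.warn(f"period {period}: no presences, skipping", stacklevel=2)
                continue
        pres_cells = _presence_cells(cum, fishnet)
        pts = cum[["x", "y"]].to_numpy(dtype=float)
        try:
            mcp = minimum_convex_polygon(pts)
        except DegenerateGeometryError:
            warnings.warn(
                f"period {period}: degenerate hull, falling back to presence cells",
                stacklevel=2,
            )
            out.append(
                RangeObservation(
                    period=period,
                    n_presences=len(cum),
                    mcp=None,
                    obs_range_cells=pres_cells,
                    obs_presence_cells=pres_cells,
                )
            )
            continue
        range_cells = set()
        for r, c in fishnet.cells():
            if mcp.intersects(box(*fishnet.cell_bounds(r, c))):
                range_cells.add((r, c))
        range_cells |= pres_cells  # a presence cell is in the range by definition
        out.append(
            RangeObservation(
                period=period,
                n_presences=len(cum),
                mcp=mcp,
                obs_range_cells=frozenset(range_cells),
                obs_presence_cells=pres_cells & frozenset(range_cells),
            )
        )
    return out


def simulated_range_cells(
    occupied_patches: frozenset[int] | set[int],
    landscape: PatchLandscape,
    fishnet: Fishnet,
) -> frozenset[Cell]:
    """Fishnet cells containing at least one cell of an occupied patch."""
    geom = landscape.geometry
    cells: set[Cell] = set()
    for pid in occupied_patches:
        rows, cols = landscape.patch_cells(int(pid))
        x = geom.xll + (cols + 0.5) * geom.cell_size
        y = geom.yll + (geom.nrows - rows - 0.5) * geom.cell_size
        for xi, yi in zip(x, y):
            cell = fishnet.cell_of(float(xi), float(yi))
            if cell is not None:
                cells.add(cell)
    return frozenset(cells)


def true_skill_statistic(
    predicted: frozenset[Cell] | set[Cell],
    observed: frozenset[Cell] | set[Cell],
    region: frozenset[Cell] | set[Cell],
) -> ConfusionCounts:
    """Confusion counts of predicted vs observed cells over a region.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    TSS = sensitivity + specificity - 1.
    """
    predicted, observed, region = set(predicted), set(observed), set(region)
    if not predicted <= region or not observed <= region:
        raise ValueError("predicted and observed cells must lie within the region")
    tp = len(predicted & observed)
    fp = len(predicted - observed)
    fn = len(observed - predicted)
    tn = len(region) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_timeseries(
    occupancy: OccupancySeries,
    landscape: PatchLandscape,
    observations: list[RangeObservation],
    fishnet: Fishnet,
    region_cells: frozenset[Cell] | None = None,
) -> EvalResult:
    """Score simulated vs observed ranges at matched timesteps.

    Requires one observation per simulated checkpoint.  Each timestep is
    scored against both ObsRange and ObsPresences; the summary reports
    mean/sd/min/max TSS per comparator.
    """
    if occupancy.n_timesteps != len(observations):
        raise ValueError(
            f"{occupancy.n_timesteps} simulated timesteps vs "
            f"{len(observations)} observations"
        )
    region = region_cells if region_cells is not None else fishnet.region_cells()
    rows = []
    for t, obs in enumerate(observations):
        predicted = simulated_range_cells(
            occupancy.occupied_patches(t), landscape, fishnet
        ) & region
        for comparator, observed in (
            ("ObsRange", obs.obs_range_cells),
            ("ObsPresences", obs.obs_presence_cells),
        ):
            counts = true_skill_statistic(predicted, observed & region, region)
            rows.append(
                {
                    "timestep": t + 1,
                    "comparator": comparator,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    "tn": counts.tn,
                    "sensitivity": counts.sensitivity,
                    "specificity": counts.specificity,
                    "tss": counts.tss,
                }
            )
    return EvalResult.from_rows(rows)


def maxsss_threshold(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> float:
    """Threshold maximising sensitivity + specificity.

    Candidates are the union of observed scores; sensitivity is the
    fraction of presences at or above the threshold, specificity the
    fraction of background below it.  Ties resolve to the smallest
    candidate.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    candidates = np.unique(np.concatenate([pres, bg]))
    best_t, best_score = None, -np.inf
    for t in candidates:
        sens = float(np.mean(pres >= t))
        spec = float(np.mean(bg < t))
        score = sens + spec
        if score > best_score:
            best_t, best_score = float(t), score
    return best_t


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    """Jaccard similarity of two sets; 1.0 when both are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def sensitivity_analysis(
    base_config: SimulationConfig,
    landscape: PatchLandscape,
    cost: CostRaster,
    init_patches: frozenset[int] | set[int],
    fishnet: Fishnet,
    delta: float = 0.10,
    observations: list[RangeObservation] | None = None,
) -> pd.DataFrame:
    """Perturb movement parameters by +/-delta and compare occupied cells.

    Runs the base config and six perturbations (perceptual range,
    directional persistence, max steps; each x(1-delta) and x(1+delta))
    with common seeds, and reports the final-timestep occupied 10-km cell
    set size and its Jaccard similarity to the base run (plus mean TSS
    when observations are supplied).
    """
    variants: list[tuple[str, SimulationConfig]] = [("base", base_config)]
    for sign, tag in ((1 - delta, "minus"), (1 + delta, "plus")):
        variants.append(
            (f"perceptual_range_{tag}",
             base_config.with_(perceptual_range=base_config.perceptual_range * sign))
        )
        variants.append(
            (f"directional_persistence_{tag}",
             base_config.with_(
                 directional_persistence=base_config.directional_persistence * sign))
        )
        variants.append(
            (f"max_steps_{tag}",
             base_config.with_(max_steps=max(1, round(base_config.max_steps * sign))))
        )
    # fix the horizon so every variant reports at the same years
    if base_config.total_years is None:
        raise ValueError("sensitivity_analysis requires an explicit total_years")

    rows = []
    base_cells: frozenset[Cell] | None = None
    for name, cfg in variants:
        series = run_simulation(landscape, cost, init_patches, cfg)
        final_cells = simulated_range_cells(
            series.occupied_patches(series.n_timesteps - 1), landscape, fishnet
        )
        if base_cells is None:
            base_cells = final_cells
        row = {
            "config": name,
            "perceptual_range": cfg.perceptual_range,
            "directional_persistence": cfg.directional_persistence,
            "max_steps": cfg.max_steps,
            "n_occupied_cells": len(final_cells),
            "jaccard_vs_base": jaccard(final_cells, base_cells),
        }
        if observations is not None:
            result = evaluate_timeseries(series, landscape, observations, fishnet)
            obs_range = result.summary.set_index("comparator")
            row["mean_tss_obsrange"] = float(obs_range.loc["ObsRange", "mean_tss"])
            row["mean_tss_obspresences"] = float(
                obs_range.loc["ObsPresences", "mean_tss"]
            )
        rows.append(row)
    return pd.DataFrame.from_records(rows)
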