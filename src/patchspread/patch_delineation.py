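"""Generalise a suitability raster into a landscape of discrete patches.

Four methods are provided:

* ``grid`` — aggregate to aligned square blocks, keep blocks whose mean
  suitability clears the threshold;
* ``voronoi`` — tessellate the extent around suitability-weighted sample
  points, keep tessera whose mean clears the threshold;
* ``contiguity`` — threshold cells, 8-connected component labelling,
  drop components below the minimum home-range area;
* ``vorcon`` — contiguity patches classified by home-range size; small
  dropped, medium kept, large split by a Voronoi tessellation seeded
  with suitability-weighted points inside the parent patch.

Per-patch mean suitability is always computed from the continuous
surface; integer scaling happens only at export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .landscape_io import (
    GridGeometry,
    ScaledHabitatRaster,
    SuitabilityRaster,
    round_half_away,
    write_raster,
)

__all__ = [
    "SizeClassBounds",
    "BalancedPointSet",
    "PatchLandscape",
    "threshold_mask",
    "label_contiguous",
    "filter_by_area",
    "classify_patch_size",
    "sample_balanced_points",
    "voronoi_assign",
    "delineate_grid",
    "delineate_voronoi",
    "delineate_contiguity",
    "delineate_vorcon",
    "delineate",
]

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SizeClassBounds:
    """Home-range size-class boundaries in km^2."""

    small_max: float = 0.06
    large_min: float = 1.0
    home_range_upper: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.small_max < self.large_min <= self.home_range_upper):
            raise ValueError(f"inconsistent size-class bounds: {self}")


@dataclass
class BalancedPointSet:
    """Suitability-weighted sample points with a minimum spacing."""

    points: np.ndarray  # (n, 2) projected metres
    min_distance: float
    target_n: int
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class PatchLandscape:
    """Patch-ID raster (0 = matrix) plus per-patch attribute table."""

    patch_ids: np.ndarray
    table: pd.DataFrame  # columns: id, n_cells, area_km2, mean_suit[, size_class]
    geometry: GridGeometry
    method: str = ""

    @property
    def n_patches(self) -> int:
        return len(self.table)

    def patch_cells(self, patch_id: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.patch_ids == patch_id)

    def quality_raster(self) -> ScaledHabitatRaster:
        """Integer 0-100 per-cell quality (each cell = its patch mean)."""
        quality = np.zeros(self.patch_ids.shape, dtype=np.int64)
        for row in self.table.itertuples():
            quality[self.patch_ids == row.id] = int(round_half_away(row.mean_suit * 100))
        return ScaledHabitatRaster(values=quality, geometry=self.geometry)

    def write(self, out_dir: str | Path, prefix: str = "patches") -> dict[str, Path]:
        """Export paired patch-ID/quality ASCII rasters and the table CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        id_raster = ScaledHabitatRaster(
            values=self.patch_ids.astype(np.int64), geometry=self.geometry
        )
        paths = {
            "patch_ids": write_raster(id_raster, out_dir / f"{prefix}_ids.asc"),
            "quality": write_raster(self.quality_raster(), out_dir / f"{prefix}_quality.asc"),
        }
        table = self.table.copy()
        table["method"] = self.method
        csv_path = out_dir / f"{prefix}_table.csv"
        table.to_csv(csv_path, index=False)
        paths["table"] = csv_path
        return paths


# ---------------------------------------------------------------------------
# Primitive operations


def threshold_mask(hsm: SuitabilityRaster, theta: float) -> np.ndarray:
    """Binary suitability mask: value >= theta and not nodata."""
    if not (0.0 < theta < 1.0):
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    return (hsm.values >= theta) & hsm.valid_mask


def _relabel_row_major(labels: np.ndarray) -> np.ndarray:
    """Renumber non-zero labels 1..k in row-major first-encounter order."""
    flat = labels.ravel()
    nz = flat[flat > 0]
    if nz.size == 0:
        return labels.astype(np.int64)
    first = pd.unique(nz)  # preserves encounter order
    lut = np.zeros(labels.max() + 1, dtype=np.int64)
    lut[first] = np.arange(1, len(first) + 1)
    return lut[labels]


def label_contiguous(mask: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """8-connected component labelling with deterministic label order.

    Returns the labelled grid (labels 1..k in row-major first-encounter
    order, 0 = background) and a mapping label -> component size.
    """
    raw, _ = ndimage.label(mask, structure=_EIGHT_CONN)
    labels = _relabel_row_major(raw)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    return labels, {int(i): int(n) for i, n in zip(ids, counts)}


def filter_by_area(
    labels: np.ndarray, min_area_km2: float, cell_area_km2: float
) -> np.ndarray:
    """Drop components below ``min_area_km2`` (strictly smaller removed,
    equal retained) and re-index survivors 1..k row-major."""
    if min_area_km2 <= 0:
        return _relabel_row_major(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        return labels.astype(np.int64)
    keep = ids[counts * cell_area_km2 >= min_area_km2 - _AREA_EPS]
    lut = np.zeros(labels.max() + 1, dtype=np.int64)
    lut[keep] = keep
    return _relabel_row_major(lut[labels])


_AREA_EPS = 1e-9  # absorbs float noise in n_cells * cell_area products


def classify_patch_size(area_km2: float, bounds: SizeClassBounds) -> str:
    """small (< small_max), medium (small_max..large_min closed), large (>)."""
    if area_km2 < 0:
        raise ValueError(f"area must be >= 0, got {area_km2}")
    if area_km2 < bounds.small_max - _AREA_EPS:
        return "small"
    if area_km2 <= bounds.large_min + _AREA_EPS:
        return "medium"
    return "large"


def sample_balanced_points(
    weight_raster: SuitabilityRaster,
    mask: np.ndarray,
    density_per_km2: float,
    min_distance: float,
    seed: int | np.random.Generator,
    max_attempts_factor: int = 50,
) -> BalancedPointSet:
    """Sample spatially balanced points biased towards suitable habitat.

    Cells are drawn with probability proportional to their suitability
    within ``mask``; each accepted point is the cell centre plus uniform
    within-cell jitter, and candidates closer than ``min_distance`` to an
    accepted point are rejected.  If the spacing constraint makes the
    target count unreachable within ``max_attempts_factor * n`` draws,
    fewer points are returned with a warning.
    """
    if density_per_km2 <= 0:
        raise ValueError("density must be > 0")
    mask = np.asarray(mask, dtype=bool) & weight_raster.valid_mask
    if not mask.any():
        raise ValueError("sampling mask is empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    geom = weight_raster.geometry
    rows, cols = np.nonzero(mask)
    weights = weight_raster.values[rows, cols].astype(float)
    weights = np.clip(weights, 0.0, None)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)  # uniform fallback on zero-weight masks
    p = weights / weights.sum()

    area_km2 = mask.sum() * geom.cell_area_km2
    n_target = max(1, int(round_half_away(density_per_km2 * area_km2)))

    cs = geom.cell_size
    accepted: list[tuple[float, float]] = []
    # spatial hash with bucket edge = min_distance for O(1) spacing checks
    bucket: dict[tuple[int, int], list[int]] = {}
    bucket_size = max(min_distance, 1e-9)
    min_d2 = min_distance * min_distance

    max_attempts = max_attempts_factor * n_target
    draws = rng.choice(len(rows), size=max_attempts, p=p)
    jitter = rng.uniform(-0.5, 0.5, size=(max_attempts, 2))
    attempt = 0
    while len(accepted) < n_target and attempt < max_attempts:
        i = draws[attempt]
        cx, cy = geom.cell_center(int(rows[i]), int(cols[i]))
        x = cx + jitter[attempt, 0] * cs
        y = cy + jitter[attempt, 1] * cs
        attempt += 1
        if min_distance > 0:
            bx, by = int(x // bucket_size), int(y // bucket_size)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in bucket.get((bx + dx, by + dy), ()):
                        px, py = accepted[j]
                        if (px - x) ** 2 + (py - y) ** 2 < min_d2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                continue
            bucket.setdefault((bx, by), []).append(len(accepted))
        accepted.append((x, y))

    if len(accepted) < n_target:
        warnings.warn(
            f"min-distance constraint reached: placed {len(accepted)} of "
            f"{n_target} requested points",
            stacklevel=2,
        )
    return BalancedPointSet(
        points=np.array(accepted, dtype=float).reshape(-1, 2),
        min_distance=min_distance,
        target_n=n_target,
    )


def voronoi_assign(
    points: BalancedPointSet | np.ndarray,
    mask: np.ndarray,
    geometry: GridGeometry,
) -> np.ndarray:
    """Assign each masked cell to its nearest generating point.

    Euclidean distance between cell centres and points; ties broken
    towards the lower point index.  Equivalent to rasterised Thiessen
    polygons clipped to the mask.
    """
    pts = points.points if isinstance(points, BalancedPointSet) else np.asarray(points)
    if len(pts) == 0:
        raise ValueError("need at least one generating point")
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int64)
    if not mask.any():
        return labels
    rows, cols = np.nonzero(mask)
    cx = geometry.xll + (cols + 0.5) * geometry.cell_size
    cy = geometry.yll + (geometry.nrows - rows - 0.5) * geometry.cell_size
    centers = np.column_stack([cx, cy])
    tree = cKDTree(pts)
    if len(pts) == 1:
        labels[rows, cols] = 1
        return labels
    d, idx = tree.query(centers, k=2)
    nearest = idx[:, 0]
    tie = d[:, 0] == d[:, 1]
    nearest[tie] = np.minimum(idx[tie, 0], idx[tie, 1])
    labels[rows, cols] = nearest + 1
    return labels


# ---------------------------------------------------------------------------
# Table construction


def _build_landscape(
    patch_ids: np.ndarray,
    hsm: SuitabilityRaster,
    method: str,
    bounds: SizeClassBounds | None = None,
) -> PatchLandscape:
    geom = hsm.geometry
    ids = np.unique(patch_ids[patch_ids > 0])
    records = []
    sums = ndimage.sum_labels(hsm.values, patch_ids, ids) if ids.size else []
    counts = ndimage.sum_labels(np.ones_like(hsm.values), patch_ids, ids) if ids.size else []
    for pid, s, n in zip(ids, sums, counts):
        n = int(n)
        area = n * geom.cell_area_km2
        rec = {
            "id": int(pid),
            "n_cells": n,
            "area_km2": area,
            "mean_suit": float(s) / n,
        }
        if bounds is not None:
            rec["size_class"] = classify_patch_size(area, bounds)
        records.append(rec)
    cols = ["id", "n_cells", "area_km2", "mean_suit"] + (
        ["size_class"] if bounds is not None else []
    )
    table = pd.DataFrame.from_records(records, columns=cols)
    return PatchLandscape(
        patch_ids=patch_ids.astype(np.int64), table=table, geometry=geom, method=method
    )


def _drop_patches(landscape: PatchLandscape, drop_ids: set[int]) -> np.ndarray:
    out = landscape.patch_ids.copy()
    if drop_ids:
        out[np.isin(out, list(drop_ids))] = 0
    return _relabel_row_major(out)


# ---------------------------------------------------------------------------
# Delineation methods


def delineate_grid(
    hsm: SuitabilityRaster, theta: float, grid_cell_m: float = 1000.0
) -> PatchLandscape:
    """Aggregate the surface to aligned square blocks (default 1 km^2).

    Block mean suitability is computed over valid member cells; blocks
    with mean strictly below ``theta`` (or no valid cells) are dropped.
    Edge blocks may be partial (ceil covering).
    """
    geom = hsm.geometry
    ratio = grid_cell_m / geom.cell_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"grid cell {grid_cell_m} m is not a multiple of raster cell {geom.cell_size} m"
        )
    b = int(round(ratio))
    n_brows = -(-geom.nrows // b)
    n_bcols = -(-geom.ncols // b)
    patch_ids = np.zeros(geom.shape, dtype=np.int64)
    next_id = 1
    vals = np.where(hsm.valid_mask, hsm.values, 0.0)
    valid = hsm.valid_mask.astype(float)
    for br in range(n_brows):
        for bc in range(n_bcols):
            sl = (slice(br * b, min((br + 1) * b, geom.nrows)),
                  slice(bc * b, min((bc + 1) * b, geom.ncols)))
            n_valid = valid[sl].sum()
            if n_valid == 0:
                continue
            mean = vals[sl].sum() / n_valid
            if mean < theta:
                continue
            block = patch_ids[sl]
            block[hsm.valid_mask[sl]] = next_id
            next_id += 1
    return _build_landscape(patch_ids, hsm, method="grid")


def delineate_voronoi(
    hsm: SuitabilityRaster,
    theta: float,
    density_per_km2: float = 1.0,
    min_distance: float = 150.0,
    seed: int | np.random.Generator = 0,
) -> PatchLandscape:
    """Voronoi tessellation of the full extent around weighted points.

    Point density is computed over the whole (valid) extent; tessera
    means come from the continuous surface and tessera with mean below
    ``theta`` are removed.
    """
    mask = hsm.valid_mask
    pts = sample_balanced_points(hsm, mask, density_per_km2, min_distance, seed)
    labels = voronoi_assign(pts, mask, hsm.geometry)
    landscape = _build_landscape(labels, hsm, method="voronoi")
    drop = set(landscape.table.loc[landscape.table.mean_suit < theta, "id"].astype(int))
    ids = _drop_patches(landscape, drop)
    return _build_landscape(ids, hsm, method="voronoi")


def delineate_contiguity(
    hsm: SuitabilityRaster,
    theta: float,
    bounds: SizeClassBounds | None = None,
) -> PatchLandscape:
    """Threshold cells, label 8-connected components, drop components
    smaller than the minimum home-range area.  No upper size limit."""
    bounds = bounds or SizeClassBounds()
    mask = threshold_mask(hsm, theta)
    labels, _ = label_contiguous(mask)
    labels = filter_by_area(labels, bounds.small_max, hsm.geometry.cell_area_km2)
    return _build_landscape(labels, hsm, method="contiguity", bounds=bounds)


def delineate_vorcon(
    hsm: SuitabilityRaster,
    theta: float,
    bounds: SizeClassBounds | None = None,
    density_per_km2: float = 1.0,
    min_distance: float = 150.0,
    seed: int | np.random.Generator = 0,
) -> PatchLandscape:
    """Contiguity patches with large ones split by in-patch Voronoi.

    Small patches (< small_max km^2) are removed, medium passed through
    unchanged, and each large patch (> large_min km^2) is partitioned by
    a Voronoi tessellation of suitability-weighted points sampled inside
    that patch only (n = max(2, round(parent area km^2))).  Sub-patches
    never span two parents.
    """
    bounds = bounds or SizeClassBounds()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    contiguity = delineate_contiguity(hsm, theta, bounds)  # small already removed
    geom = hsm.geometry
    out = np.zeros(geom.shape, dtype=np.int64)
    next_id = 1
    for row in contiguity.table.itertuples():
        member = contiguity.patch_ids == row.id
        if row.size_class != "large":
            out[member] = next_id
            next_id += 1
            continue
        n_pts = max(2, int(round_half_away(row.area_km2 * density_per_km2)))
        area = member.sum() * geom.cell_area_km2
        pts = sample_balanced_points(
            hsm, member, n_pts / area, min_distance, rng
        )
        sub = voronoi_assign(pts, member, geom)
        sub_ids = np.unique(sub[sub > 0])
        for sid in sub_ids:
            out[sub == sid] = next_id
            next_id += 1
    out = _relabel_row_major(out)
    return _build_landscape(out, hsm, method="vorcon", bounds=bounds)


_METHODS = {
    "grid": delineate_grid,
    "voronoi": delineate_voronoi,
    "contiguity": delineate_contiguity,
    "vorcon": delineate_vorcon,
}


def delineate(
    method: str,
    hsm: SuitabilityRaster,
    theta: float = 0.56,
    density_per_km2: float = 1.0,
    min_distance: float = 150.0,
    seed: int = 0,
    bounds: SizeClassBounds | None = None,
) -> PatchLandscape:
    """Dispatch to one of the four delineation methods by name."""
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if method == "grid":
        return delineate_grid(hsm, theta)
    if method == "contiguity":
        return delineate_contiguity(hsm, theta, bounds)
    if method == "voronoi":
        return delineate_voronoi(hsm, theta, density_per_km2, min_distance, seed)
    return delineate_vorcon(hsm, theta, bounds, density_per_km2, min_distance, seed)
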