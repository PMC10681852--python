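"""Seeded synthetic suitability surfaces, presence histories and fixtures.

All generators are pure functions of their spec (seed included), so
repeated calls are bit-identical.  The canonical fixtures carry planted
ground truth (exact blob footprints) against which delineation can be
verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .landscape_io import GridGeometry, SuitabilityRaster

__all__ = [
    "SyntheticSpec",
    "Fixture",
    "generate_hsm",
    "generate_presences",
    "fixtures",
    "two_patch_corridor",
    "mega_patch",
    "archipelago",
    "uniform_matrix",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic suitability surface."""

    width_km: float
    height_km: float
    seed: int
    cell_size: float = 100.0
    autocorrelation_length: float = 500.0  # metres; Gaussian kernel scale
    suitability_mean: float = 0.3
    suitability_sd: float = 0.15
    n_blobs: int = 0
    blob_radius_range: tuple[float, float] = (0.5, 1.0)  # km
    blob_value: float = 0.9

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for synthetic generation")
        for dim in (self.width_km, self.height_km):
            n = dim * 1000.0 / self.cell_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"extent {dim} km is not divisible by cell size {self.cell_size} m"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.height_km * 1000.0 / self.cell_size)),
            int(round(self.width_km * 1000.0 / self.cell_size)),
        )


@dataclass
class Fixture:
    """A canonical synthetic landscape with documented ground truth."""

    name: str
    hsm: SuitabilityRaster
    truth: dict = field(default_factory=dict)


def generate_hsm(spec: SyntheticSpec) -> SuitabilityRaster:
    """Smoothed-noise suitability surface with optional planted blobs.

    White noise convolved with a Gaussian kernel of the autocorrelation
    length, rescaled to the requested mean/sd and clipped to [0, 1];
    blobs are circular regions set to ``blob_value`` at seeded centres.
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.shape
    geom = GridGeometry(nrows=nrows, ncols=ncols, cell_size=spec.cell_size)

    if spec.suitability_sd == 0:
        values = np.full((nrows, ncols), spec.suitability_mean)
    else:
        noise = rng.standard_normal((nrows, ncols))
        sigma = spec.autocorrelation_length / spec.cell_size
        smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = (smooth - smooth.mean()) / sd
        values = spec.suitability_mean + spec.suitability_sd * smooth

    if spec.n_blobs > 0:
        radii_km = rng.uniform(*spec.blob_radius_range, size=spec.n_blobs)
        centers = np.column_stack(
            [
                rng.uniform(0, nrows, size=spec.n_blobs),
                rng.uniform(0, ncols, size=spec.n_blobs),
            ]
        )
        rr, cc = np.mgrid[0:nrows, 0:ncols]
        for (cr, ccen), radius_km in zip(centers, radii_km):
            r_cells = radius_km * 1000.0 / spec.cell_size
            inside = (rr - cr) ** 2 + (cc - ccen) ** 2 <= r_cells**2
            values[inside] = spec.blob_value

    values = np.clip(values, 0.0, 1.0)
    return SuitabilityRaster(values=values, geometry=geom)


def generate_presences(
    hsm: SuitabilityRaster,
    origin: tuple[float, float],
    n_per_period: list[int],
    spread_rate_km: float,
    seed: int,
    start_year: int = 1960,
    period_years: int = 10,
    initial_radius_km: float = 3.0,
) -> pd.DataFrame:
    """Spatiotemporally clustered presences radiating from an origin.

    Period p samples ``n_per_period[p]`` points within a radius growing
    by ``spread_rate_km`` per period, biased towards suitable cells
    (probability proportional to suitability).  Nodata cells are never
    sampled; output is deterministic under the seed.
    """
    geom = hsm.geometry
    if not geom.contains(*origin):
        raise ValueError(f"origin {origin} is off-map")
    rng = np.random.default_rng(seed)
    ox, oy = origin
    xs, ys = geom.cell_centers()
    d2 = (xs - ox) ** 2 + (ys - oy) ** 2
    weights_all = np.where(hsm.valid_mask, np.clip(hsm.values, 0.0, None), 0.0)

    records = []
    for p, n in enumerate(n_per_period):
        radius_m = (initial_radius_km + spread_rate_km * p) * 1000.0
        inside = (d2 <= radius_m**2) & hsm.valid_mask
        w = np.where(inside, weights_all, 0.0).ravel()
        if w.sum() <= 0:
            w = inside.ravel().astype(float)
        if w.sum() <= 0:
            continue
        idx = rng.choice(w.size, size=n, p=w / w.sum())
        years = rng.integers(
            start_year + p * period_years,
            start_year + (p + 1) * period_years,
            size=n,
        )
        rows, cols = np.unravel_index(idx, geom.shape)
        jit = rng.uniform(-0.45, 0.45, size=(n, 2)) * geom.cell_size
        for r, c, yr, (jx, jy) in zip(rows, cols, years, jit):
            x, y = geom.cell_center(int(r), int(c))
            records.append({"x": x + jx, "y": y + jy, "year": int(yr)})
    df = pd.DataFrame.from_records(records, columns=["x", "y", "year"])
    return df.sort_values("year", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Canonical fixtures


def _blank(width_km: float, height_km: float, background: float,
           cell_size: float = 100.0) -> tuple[np.ndarray, GridGeometry]:
    nrows = int(round(height_km * 1000 / cell_size))
    ncols = int(round(width_km * 1000 / cell_size))
    geom = GridGeometry(nrows=nrows, ncols=ncols, cell_size=cell_size)
    return np.full((nrows, ncols), background), geom


def two_patch_corridor(
    background: float = 0.2,
    patch_value: float = 0.9,
    corridor_value: float = 0.5,
) -> Fixture:
    """Two 1 km^2 suitable blocks linked by a short low-cost strip.

    The 5-cell corridor (0.5) sits below the 0.56 threshold, so it is
    matrix for delineation but cheap to traverse for dispersers.
    """
    values, geom = _blank(4.0, 2.0, background)
    a = (slice(5, 15), slice(5, 15))
    b = (slice(5, 15), slice(20, 30))
    corridor = (slice(9, 11), slice(15, 20))
    values[a] = patch_value
    values[b] = patch_value
    values[corridor] = corridor_value
    hsm = SuitabilityRaster(values=values, geometry=geom)
    return Fixture(
        name="two_patch_corridor",
        hsm=hsm,
        truth={
            "patch_a_slices": a,
            "patch_b_slices": b,
            "corridor_slices": corridor,
            "n_patches": 2,
            "patch_area_km2": 1.0,
        },
    )


def mega_patch(
    block_km: float = 20.0,
    extent_km: float = 24.0,
    background: float = 0.2,
    patch_value: float = 0.9,
) -> Fixture:
    """One large contiguous suitable block in a hostile matrix.

    Under contiguity delineation the block is a single patch; under
    Vor-Con it splits into roughly ``block_km^2`` sub-patches.
    """
    values, geom = _blank(extent_km, extent_km, background)
    off = int(round((extent_km - block_km) * 1000 / geom.cell_size / 2))
    n = int(round(block_km * 1000 / geom.cell_size))
    block = (slice(off, off + n), slice(off, off + n))
    values[block] = patch_value
    hsm = SuitabilityRaster(values=values, geometry=geom)
    return Fixture(
        name="mega_patch",
        hsm=hsm,
        truth={
            "block_slices": block,
            "block_area_km2": block_km * block_km,
            "n_patches_contiguity": 1,
        },
    )


def archipelago(
    n_blobs: int = 20,
    extent_km: float = 16.0,
    blob_radius_km: float = 0.4,
    background: float = 0.2,
    patch_value: float = 0.9,
    seed: int = 42,
) -> Fixture:
    """Medium blobs at graded distances from a seed blob near one corner.

    Blob centres follow a deterministic outward spiral from the origin
    blob, spaced so blobs stay discrete (~0.4 km edge-to-edge gaps) but
    remain reachable by weakly guided dispersers; radius 0.4 km gives
    ~0.5 km^2 medium patches.
    """
    values, geom = _blank(extent_km, extent_km, background)
    rng = np.random.default_rng(seed)
    origin = np.array([3.0, 3.0])  # km from lower-left
    centers = [origin]
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = 0
    while len(centers) < n_blobs and k < 10_000:
        k += 1
        radius = 0.75 * np.sqrt(k) + 0.7
        angle = k * golden + rng.uniform(-0.1, 0.1)
        cand = origin + radius * np.array([np.cos(angle), np.sin(angle)])
        margin = blob_radius_km + 0.2
        if not (margin < cand[0] < extent_km - margin and margin < cand[1] < extent_km - margin):
            continue
        if min(np.hypot(*(cand - c)) for c in centers) < 2 * blob_radius_km + 0.4:
            continue
        centers.append(cand)
    rr, cc = np.mgrid[0 : geom.nrows, 0 : geom.ncols]
    xs = (cc + 0.5) * geom.cell_size / 1000.0
    ys = (geom.nrows - rr - 0.5) * geom.cell_size / 1000.0
    for cx, cy in centers:
        inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= blob_radius_km**2
        values[inside] = patch_value
    hsm = SuitabilityRaster(values=values, geometry=geom)
    dists = [float(np.hypot(*(np.array(c) - origin))) for c in centers]
    return Fixture(
        name="archipelago",
        hsm=hsm,
        truth={
            "centers_km": [tuple(map(float, c)) for c in centers],
            "distances_km": dists,
            "n_blobs": len(centers),
            "origin_km": tuple(origin),
        },
    )


def uniform_matrix(value: float = 0.3, extent_km: float = 5.0) -> Fixture:
    """Featureless sub-threshold surface: zero patches at theta = 0.56."""
    values, geom = _blank(extent_km, extent_km, value)
    return Fixture(
        name="uniform_matrix",
        hsm=SuitabilityRaster(values=values, geometry=geom),
        truth={"n_patches": 0},
    )


def fixtures() -> dict[str, Fixture]:
    """All canonical fixtures keyed by name."""
    return {
        f.name: f
        for f in (
            two_patch_corridor(),
            mega_patch(),
            archipelago(),
            uniform_matrix(),
        )
    }
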