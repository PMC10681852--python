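# patchspread

Patch-based hybrid species distribution modelling. `patchspread`
generalises a continuous habitat-suitability raster into a landscape of
home-range-sized habitat patches, simulates patch-occupancy spread with
simplified density-dependent dynamics and stochastic dispersal over a
cost surface, and evaluates predicted ranges against presence records
with the True Skill Statistic (TSS).

## What it does

1. **Patch delineation** (`patchspread.patch_delineation`) — four methods
   for converting a unit-interval suitability raster into discrete
   patches:
   - `grid`: aggregate to aligned 1 km² blocks, keep blocks with mean
     suitability ≥ θ;
   - `voronoi`: rasterised Thiessen tessellation around
     suitability-weighted sample points (≈1 point/km², ≥150 m apart),
     keep tessera with mean ≥ θ;
   - `contiguity`: threshold at θ, 8-connected component labelling, drop
     components smaller than the minimum home-range area (0.06 km²);
   - `vorcon`: contiguity patches classified by home-range size class
     (small < 0.06 km², medium 0.06–1 km², large > 1 km²); small
     dropped, medium kept, large split by an in-patch Voronoi
     tessellation (~1 point per km² of parent area).

2. **Spread simulation** (`patchspread.spread_simulator`) — yearly cycle
   of density-dependent reproduction (`x0·exp(−b·N)`), obligate juvenile
   emigration, stochastic nearest-neighbour transfer over an inverted
   suitability cost surface (perceptual range 400 m, directional
   persistence 5, ≤200 steps ⇒ ≤20 km), and logistic below-capacity
   settlement. Replicated runs are averaged; patches with mean occupancy
   ≥ 0.7 count as occupied.

3. **Evaluation** (`patchspread.evaluation`) — observed ranges from
   minimum convex polygons around cumulative presences on a 10 km
   fishnet (ObsRange) and their presence-bearing cells (ObsPresences);
   TSS = sensitivity + specificity − 1 per timestep with summary
   statistics; a maxSSS threshold utility; and a ±10% parameter
   sensitivity harness.

4. **Synthetic landscapes** (`patchspread.synthetic_landscapes`) —
   seeded generators for autocorrelated suitability surfaces, radially
   expanding presence histories, and canonical fixtures
   (`two_patch_corridor`, `mega_patch`, `archipelago`,
   `uniform_matrix`) with planted ground truth.

5. **Workflow** (`patchspread.workflow`) — one YAML config drives
   delineate → simulate → evaluate (historic mode) or delineate →
   simulate → colonisation-order prediction (novel-region mode), with
   per-stage seeds and provenance logging.

## CLI

```bash
# write a canonical synthetic fixture (raster + presence CSV)
patchspread synth --preset archipelago --seed 7 --out fixtures/

# delineate patches
patchspread delineate --method vorcon --theta 0.56 --density 1.0 \
    --min-dist 150 --seed 1 --in hsm.asc --out patches/

# simulate spread on a delineated landscape
patchspread simulate --landscape patches/ --prefix vorcon --hsm hsm.asc \
    --presences obs.csv --init buffer --seed 1 --years 300 --out sim/

# full pipeline from YAML
patchspread run --config pipeline.yaml
```

Example `pipeline.yaml`:

```yaml
hsm_path: hsm.asc
presences_path: presences.csv
out_dir: out/
mode: evaluate_historic        # or predict_novel
methods: [grid, voronoi, contiguity, vorcon]
theta: 0.56
density_per_km2: 1.0
min_distance: 150.0
fishnet_cell_m: 10000.0
init_buffer_m: 10000.0
periods: [[1960, 1969], [1970, 1979], [1980, 1989], [1990, 1999],
          [2000, 2009], [2010, 2016]]
simulation:
  replicates: 10
  total_years: 300             # omit for pilot-run auto mode
  occupancy_threshold: 0.7
master_seed: 1
```

## Notes

- All stochastic operations take explicit seeds; identical inputs and
  seeds give bit-identical outputs.
- Patch landscapes export as paired integer rasters (patch IDs +
  0–100 quality) plus a patch table CSV.
- The movement cost surface is `max(1, 100 − scaled suitability)`;
  nodata cells are off-limits to dispersers.
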