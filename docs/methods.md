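# Methods

## The cumulative impact model

`cimnet` implements the additive cumulative impact (CI) model used in
marine cumulative impact mapping: per grid cell, each activity's
intensity is multiplied by the summed vulnerability-weighted presence
of the habitats it overlaps, and the CI score is the sum of these
stressor–habitat impact scores over all activities. Three modelling
choices are deliberate and worth stating:

- **Habitat-summed, not habitat-averaged.** Some CIM variants divide
  each cell's score by the number of habitats present; this package
  does not. Adding habitat layers therefore raises CI scores, which is
  why CI values are treated as relative and only compared within one
  region and layer set.
- **No transformation of intensities.** Input layers are consumed as
  published/generated; any log or quantile transform is the data
  producer's responsibility.
- **Purely local scoring.** No stressor propagation or interaction
  (synergy/antagonism) — distance decay is assumed baked into the
  input layers. Cells with no habitat presence score 0 by construction.

Conservation holds to within additive floating tolerance: total CI =
Σ sector CI = Σ activity impacts, cell-wise (tested at 1e-9 × number of
addends); scoring is monotone in every intensity and weight.

## Synthetic seascapes

The generator produces the study conditions the analysis assumes. Its
defaults were chosen once to mirror published regional CIM inventories
(45–46 stressor layers, 21–38 habitat classes, networks of tens of
MCAs) scaled to a desk-size grid:

| parameter | default | meaning |
|---|---|---|
| grid | 64 × 64 cells of 1 km² | analysis resolution |
| land fraction | 0.25 | thresholded smoothed Gaussian field; sea kept 4-connected |
| stressors | 45 layers: Climate 6 regionwide, Fishing 15 patchy, Marine 6 patchy + 4 corridor, Coastal 8 + Land 6 shore-decay | sector-typical footprints |
| habitats | 24 binary layers, mean coverage 0.25 | union forced to cover every sea cell |
| vulnerability | gamma(2, 1) weights, 30% exact zeros | every stressor keeps ≥1 positive weight |
| MCAs | 20, radii 1–4 cells | one sub-km² record, one multi-zone MCA, governance cycling federal/joint/provincial/private |

Footprint models: region-wide layers are strictly positive smoothed
fields; patchy layers are unions of random discs covering well under
half the sea; corridors are thickened random polylines; shore-decay
layers fall off as `exp(−d/λ)`, λ ∈ [2, 5] cells, with multiplicative
roughness. Every layer is zero on land, rescaled to unit maximum over
sea and multiplied by the sector's `intensity_scale` (clipped to
[0, 1]). Pre-rescaling marginals are uniform by default; a lognormal
option exists for heavier-tailed intensities. Coast distance is a
multi-source 4-neighbour BFS from land-adjacent sea cells (grid-edge
cells when there is no land).

All randomness flows through `numpy.random.default_rng` (PCG64), one
explicitly seeded stream per operation: fixed seeds reproduce outputs
bit-for-bit across runs and platforms.

What the generator does **not** emulate: real coastline geometry,
spatial correlation between sectors (e.g. fishing avoiding shipping
lanes), temporal dynamics, CRS/projection effects, and the empirical
intensity distributions of real activity data. Passing tests therefore
demonstrate the correctness of the computations, not the realism of
any particular regional result.

## MCA overlay

Zone records sharing an `mca_id` are merged (geometric union;
attributes from the first zone, warning on disagreement) before the
registry filters: governance must be in the allowlist (default
{federal, joint}) and the merged footprint area must be ≥ 1 km²;
areas strictly below the threshold are excluded, and the threshold is
applied to the merged total, not per zone. Cell membership is the
cell-centre rule on half-open unit boxes — unambiguous counts, no
partial-cell weighting. Per-MCA summaries report the mean CI and a
t-based 95% confidence half-width `t(0.975, n−1)·sd/√n` (0 when n = 1).

## Classification and comparison

- **Fisher–Jenks breaks** are computed exactly by dynamic programming
  over the sorted values (O(k n²)); cuts are restricted to positions
  between distinct values so reported boundaries (the maximum of each
  lower class) are strictly increasing, and cost ties are broken toward
  the lexicographically smallest boundary vector. Classes are
  right-closed; out-of-range values clamp to the end classes.
- **ANOVA** is the classic two-group fixed-effects F-test (equivalent
  to the pooled t: F = t²), with the regional sample inclusive of the
  MCA's own cells — the comparison the planning literature reports.
  The non-independence of a subset-vs-superset comparison is accepted
  as a descriptive convention, not a design-based inference. α = 0.05,
  no multiple-testing correction. Zero pooled variance with unequal
  means is flagged degenerate (p = 0).
- **Distribution overlap** is `100·∫ min(f_a, f_b)` with Gaussian
  kernels, per-sample nrd0 (Silverman) bandwidths, a 1024-point common
  grid padded 3 bandwidths past each extreme, trapezoidal integration.
  These estimator settings are recorded in the result object because
  overlap percentages carry estimator tolerance (the calibration test
  budgets ±2 points on the closed-form 2Φ(−½) case); zero-variance
  samples fall back to a shared-bin histogram with a warning. Overlap
  is computed on raw CI scores; callers may transform first.

## Scenario analysis

Prohibited activities' impact scores are set to zero on cells inside
any target MCA footprint; everything else is bit-identical, so
CI_after ≤ CI_before everywhere with equality outside the MCAs. No
displacement of removed activity is modelled. Percent declines:

- per cell: `100·(before − after)/before`, 0 at 0/0;
- per MCA (default): percent change of the MCA's **mean** CI, matching
  how per-MCA impact is reported elsewhere in the pipeline; the mean of
  per-cell percentages is available as `method="mean_of_cell_pct"` (the
  two differ whenever decline correlates with cell CI);
- network: unweighted mean over MCAs (not area-weighted), plus the
  range, the count of zero-change MCAs and the count of MCAs containing
  any cell above a 50% decline.

High protection potential requires an MCA's current mean CI **and**
its percent decline to strictly exceed the medians of the same table
being labelled (existing + proposed together); with strict
inequalities an all-equal table labels nothing.

## Numerical and I/O choices

- Grid convention: row-major, origin top-left, cells are half-open
  1 km boxes; GeoJSON coordinates are grid units (x = column,
  y = row). Real-data adapters map projected equal-area grids onto
  this convention.
- Rasters are ESRI ASCII grids written at 17 significant digits, so
  float round-trips are exact to ≤1e-12 relative and integer rasters
  are bit-exact. NaN/NODATA cells are read as 0 with a per-layer
  warning count.
- Each run directory carries a `provenance.json` (canonical-YAML
  config hash, seed, package versions); determinism is tested by
  hashing every output byte-for-byte across reruns.
- Problem sizes: the shipped demo and the acceptance script use the
  64×64 seascape above (≈2 500 sea cells, 45 activities), where the
  full pipeline runs in a few seconds; the Jenks DP is quadratic in the
  number of cells and is the dominant cost on much larger grids.

## Known limitations

- The ANOVA ignores spatial autocorrelation; p-values on gridded data
  are optimistic and should be read as descriptive flags.
- The additive model cannot express stressor interactions, and the
  habitat-summed convention ties CI magnitudes to the layer inventory.
- The cell-centre rule under-counts sub-cell and boundary-hugging
  footprints; sites smaller than one cell are excluded rather than
  approximated.
- Scenario declines assume prohibited activities vanish without
  displacement into adjacent waters.
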