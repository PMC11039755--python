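# Methods

This note documents the models behind `paleowalk`, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not demonstrate about real landscapes.

## Coordinates and grids

All synthetic runs use planar grids in kilometres with cell-centred
registration; row 0 is the northern edge and y decreases southwards.
Geographic (degree) rasters are accepted at I/O but converted semantics are
the caller's responsibility — removing projections from the core keeps every
numerical test free of projection ambiguity. Grids must be at least 8×8 and
all rasters in a run share one geometry.

## Synthetic world

The generator emulates the statistical structure of a late-Pleistocene
continental setting rather than any real geography:

* **Terrain** (`generate_dem`): a radially symmetric platform (constant
  40 m coastal base) whose outer `shelf_fraction` (default 0.3) of area is a
  ramp from −61 m to −84 m — strictly inside the −60…−85 m envelope of the
  sea-level curve, so exposed land shrinks as the sea recovers from the
  lowstand. Interior relief is a Gaussian random field with power spectral
  density ∝ k^−2 (spectral synthesis gives realistic drainage texture;
  exponent configurable), scaled by `relief_amplitude` (default 500 m),
  tapered to zero at the coast, plus a central dome and a Gaussian
  endorheic depression (depth 0.25 × relief) that guarantees closed basins.
* **Climate** (`generate_climate`): precipitation = a fixed north–south
  gradient (1.6× to 0.4× the 1 m/yr mean) plus a temporally AR(1)
  (φ = 0.8 per slice) smooth anomaly field of standard deviation
  0.35 m/yr — bracketing a −0.4…+0.3 m/yr per-site anomaly envelope —
  clamped at zero. The anomaly correlation length (10 cells) is a free
  parameter of the generator, not an inference about any climate model.
  Sea level is piecewise linear through (start, −68 m),
  (start − ¼·span, −85 m), (end, −60 m): for the default 75–35 ka window the
  lowstand falls at 65 ka. NPP is 1 − exp(−P/P₀) normalised to [0, 1] over
  the series — saturating, and monotone in precipitation within every slice.
* **Sites** (`generate_sites`): uniform over land cells without replacement;
  the three dated ages are iid uniforms in the requested bounds sorted into
  (min, mean, max).

Everything is bit-deterministic under a fixed seed.

## Landscape evolution

`route_flow` processes cells in decreasing elevation (ties broken row-major)
and splits each land cell's discharge among all strictly lower D8
neighbours with weights proportional to slope (linear MFD; the partition
exponent is a genuinely open choice and 1 keeps the scheme scale-free).
Ocean cells (z below current sea level) only receive; land cells without a
lower neighbour are endorheic sinks and terminate basins; basin labels are
assigned along steepest-descent paths to each sink or coastal outlet.
Conservation — precipitation over land = flux into the ocean + accumulation
in sinks — holds to machine precision and is asserted at 1e−6 in tests.

`detect_lakes` is a priority-flood fill seeded at the ocean and grid
boundary; lake cells lie above sea level but below their basin's spill
elevation. Submarine depressions belong to the ocean mask.

`evolve_step` applies explicit forward Euler to
∂z/∂t = U + κ∇²z + ε·P^d·(PA)^m·S^n with S the steepest downslope gradient:

* the SPL term erodes land cells outside lakes; eroded flux is routed along
  steepest-descent paths and deposited entirely at the first lake or ocean
  cell reached (or the endorheic sink) — a detachment-limited reading in
  which deposition is bookkeeping, not a transport-capacity law. Sediment
  closure (eroded = deposited) is exact and asserted at 1e−6.
* diffusion uses a five-point Laplacian with edge replication (approximate
  no-flux boundary) on land only; ocean cells change only by deposition.
* the step is rejected (`ConfigurationError`) if dt exceeds half the
  CFL-style bound min(dx²/4κ, dx/max(ε·P^d·(PA)^m·S^(n−1))).

Defaults (κ = 0.1 m²/yr, ε = 1e−7, dt = 1000 yr, U = 0, m = 0.5, n = 1,
d = 0.42) are chosen for stability and realistic mm/kyr-scale denudation on
the synthetic worlds; ε and κ are free parameters, not calibrated values.
`run_history` holds precipitation and sea level from the nearest earlier
climate slice, snapshots at a fixed interval, and accumulates cumulative
erosion/deposition for the prospecting stage.

## Physiographic resistance

* **Slope index**: steepest-descent gradient magnitude normalised by the
  land-wide maximum (scale-invariant; an all-flat grid maps to zero).
* **TPI**: z minus the mean over an annulus, computed at a fine (2–5 km) and
  a coarse (10–15 km) scale — the km equivalents of 0.02–0.05° and
  0.1–0.15° at ~1 km/0.01°; edge cells average available neighbours only.
  Standardisation to mean 0 / sd 100 makes the scales comparable; the
  categorical TPI uses the mean of the two standardised rasters so both
  observation scales inform the landform classes.
* **Categories**: equal-frequency (quantile) class edges fitted over land
  cells — 7 slope, 5 water-flux, 10 TPI_S classes. Quantile edges are
  scale-free across synthetic worlds; the class *counts* are fixed, the
  edges are not.
* **Diversity**: within a disk neighbourhood (default radius 5 km),
  p_k is the proportion of observations of pooled category value k across
  the C = 3 layers; P_DIV = (−Σ p_k ln p_k)/ln C, clipped to [0, 1] (with
  more than C pooled values the printed normalisation can exceed 1; the
  clip honours the declared range while keeping the formula). Empty
  neighbourhoods score 0.
* **Environmental index**: ocean and endorheic lakes cost 1 (barriers);
  channel cells scale 0 → 0.7 with discharge up to the 80 m³/s major-river
  threshold and 0.7 → 0.95 from there to the land-wide maximum (strong but
  not impermeable crossings); bank cells adjacent to rivers above a minimum
  corridor discharge (default 8 m³/s) carry the 0.2 along-river cost —
  crossing costs stay on the channels, travel costs on the banks; cells
  jointly below the lower-quartile precipitation and NPP thresholds with
  slope index < 0.05 cost 0.92 (arid flats). All thresholds are exposed in
  `EnvironmentalConfig`.
* **Combination**: cost = max(slope index, 1 − P_DIV, env, 1 − NPP), then
  coastal cells (a 1-cell land band along the ocean, width configurable)
  and river banks are lowered to 0.2 unless they are barriers; barrier and
  major-river cells retain their environmental values; output clipped to
  [0, 1]. NPP can be excluded as a standalone layer (`npp_as_layer=False`),
  in which case it still acts through the arid-flat rule.

## Movement model

A two-state Markov chain (random ↔ correlated; defaults 0.01 and 0.002, so
the stationary correlated fraction is 5/6) drives heading selection each
step:

* **Candidates from the prior**: `n_candidate_headings` (24) candidate
  directions are *drawn from the state's turning prior* — uniform in the
  random state, wrapped Cauchy centred on the previous heading with
  concentration ρ = 0.95 in the correlated state — then weighted by
  (1 − mean resistance along the ray out to the 10 km perceptual range,
  10 samples/ray) raised to the stringency exponent γ (default 6), and one
  is sampled proportionally to weight. Drawing candidates from the prior
  rather than spacing them on a fixed fan is deliberate: a ρ = 0.95 wrapped
  Cauchy has a ~3° peak half-width, so a 15°-spaced fan weighted by its
  density would concentrate realised turning to ~0.99; sampling from the
  prior reproduces ρ exactly under uniform resistance, which the
  calibration tests assert (0.95 ± 0.01 over 10⁶ steps).
* **Stringency**: γ makes the walker *minimise* perceived resistance rather
  than merely prefer it in proportion. Under uniform resistance weights are
  equal for any γ, so calibrations are unaffected; on structured landscapes
  γ = 6 gives decisive corridor following (visited-cell resistance ~0.28 vs
  0.57 for uniform land on the two-corridor benchmark; γ = 1 yields almost
  no preference). Fully blocked rays have zero weight; if all rays are
  blocked the choice falls back to the prior alone.
* **Advance**: realised step = 1 km × (1 − resistance of the current cell),
  truncated at the last non-barrier point along the segment (sampled every
  quarter cell) and clamped to the grid. Positions are continuous;
  resistance is looked up by containing cell. Barriers (cost ≥ the map's
  barrier threshold, default 1.0) are never entered — asserted exhaustively.
* **Time-varying resistance**: the active map switches every
  `resistance_update_steps` (250,000 by default, i.e. 1 kyr at 250
  walks/yr), held at the last map when the stack is exhausted. If an update
  strands the walker on a new barrier (a drowned shelf), it is relocated to
  the nearest non-barrier cell — the one mechanism that is not part of the
  per-step model.
* **Engines**: a numba kernel and a pure-Python reference implement the
  identical decision sequence and consume the same Mersenne–Twister stream
  in the same order, so their trajectories are bit-identical for a seed —
  a structural cross-check asserted in the tests. Ensembles fan per-walker
  seeds out of a base seed through a counter-based `SeedSequence` scheme.
* A `wrap=True` mode runs the walker on a torus; it exists for calibration
  (no edge effects) and the turning-angle measurement uses minimum-image
  displacements there.

## Analysis products

* **Residential aggregation**: scan forward from the first position,
  accumulating steps while within the knowledge radius (25 or 50 km) of the
  current anchor; the first position beyond it closes the mobility event and
  becomes the next anchor. The trailing partial event is retained so
  per-event distances sum exactly to the trajectory total. Verified against
  a brute-force re-scan oracle on short trajectories.
* **Site access**: all trajectory points within 10 km of a site, with the
  cumulative travelled distance at each.
* **Distinct visits**: 1-D k-means over cumulative distances at access, k
  chosen by silhouette score over k ∈ 2…min(8, n−1); k = 1 is forced when
  the spread is below twice the access radius (points that close together
  in walked distance are one pass, not several). "Percent visited" counts
  realisations with at least one access, not time fraction.
* **Occupation KDE**: a binned kernel density — points histogrammed on the
  analysis grid and smoothed with a Gaussian of bandwidth 2 cells by
  default — rescaled to a maximum of 1. Unnormalised, its integral matches
  the point count to ~1e−3 when the bandwidth is small against the domain.
* **Presence heat map**: raw per-cell point counts over all realisations;
  conservation (sum = point count) is exact under any consistent thinning.
* **Migration speed**: distance/((entry age − site age)·1000 yr) for each of
  a site's min/mean/max ages, from both the mean and the minimum
  first-access distance over realisations; sites not younger than the entry
  age are rejected.
* **Prospecting**: candidates filtered by percent visited > 70 and mean
  in-radius walker count > 200 (both configurable), ranked lexicographically
  by (percent, count) descending, reported with mean walked distances.

## Orchestration and problem sizes

`run_pipeline` chains the stages, persists every artefact (text rasters,
NetCDF stacks via the scipy engine, CSV tables), records SHA-256 hashes and
per-stage timings in a JSON manifest, and is resumable from any stage by
reloading earlier artefacts (a missing prerequisite raises a stage-tagged
error). The analysis stage deliberately consumes the *persisted* trajectory
record rather than the in-memory one, so resumed and fresh runs produce
identical artefacts.

The shipped configurations are desk-scale by design: 64–128² grids at 2 km,
10⁴–10⁵-step walkers in ensembles of tens to a hundred, against the
full-scale study conditions of ~1 km continental grids and 2 × 5000
realisations of 10⁷ steps. The movement defaults themselves (switching
probabilities, ρ, step cap, perceptual range, update cadence, 10⁷ steps)
are the full-scale values; only `n_steps`, grids and ensemble sizes are
scaled down in examples, tests and the acceptance script.

## What the synthetic tests do and do not show

Passing tests demonstrate that the mechanics are implemented correctly —
conservation, closed-form morphometrics, Markov/turning calibration,
barrier exclusion, oracle equivalence, corridor recovery, bit-level
reproducibility. They do not show that the synthetic worlds reproduce any
real region's physiography: the terrain is radially symmetric with one
depression, precipitation has no orographic coupling, NPP is a fixed
transform of rainfall rather than an ecosystem model, and desk-scale
ensembles cannot reproduce headline statistics that depend on real
reconstructions and 10⁷-step, 5000-realisation campaigns (travelled-distance
distributions, per-site speeds of order 6–10 km/yr, denudation-rate maps).
Known limitations: no demography or social decision rules, one-step heading
memory only, no transport-limited sediment law, no marine dynamics, and the
stranded-walker rescue after map updates is a pragmatic device outside the
per-step model.
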