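# Methods

`palmland` models where oil palm is commercially viable on a tropical
floodplain, and what one hectare of plantation is worth over a crop life.
It couples three pieces: a seeded synthetic-floodplain generator, a
decision-rule / CART land-suitability classifier, and a 25-year discounted
cash-flow model, tied together by hectare accounting and error-matrix
accuracy assessment.  Everything below is computed by the package; the
analysis drivers under `analysis/` and the test suite exercise exactly
these procedures.

## The suitability model

Flood inundation is the dominant cause of palm mortality on the floodplain
studied here, so suitability is a function of three biophysical predictors:
Euclidean distance to the main river (m), elevation (m ASL), and an ordinal
soil agricultural-suitability class (1 unsuitable … 4 very suitable).
Aspect and slope are carried as predictors but hold no signal — the
generator derives them from the elevation surface and the reference rules
never read them — mirroring their non-significance in the source analysis.

The reference rule set marks land *commercially redundant* when

1. it lies within 1,504 m of the river at ≤ 22.4 m ASL; or
2. beyond 1,504 m, at ≤ 16 m ASL on marginal (class 2) soil; or
3. beyond 1,947 m, on very suitable (class 4) soil at 9.9–14 m ASL
   (low depressions that pond in wet years);

everything else is *full stand* (suitable).  Rules are interval
conjunctions evaluated first-match-wins with a default class, so
classification is exhaustive and deterministic; since all three rules map
to the same class, ordering affects explanation only.

### CART induction

`palmland.cart` re-derives comparable rules from labelled points with a
from-scratch classification tree: exhaustive midpoint search per predictor,
Gini impurity decrease as the split criterion, ties broken by predictor
declaration order then lower threshold (with stable sorting this makes
growth fully deterministic).  Ordinal soil is split as numeric; a single
named class appears in extracted rules as a pair of cuts (1.5 < soil ≤ 2.5).

Pruning is minimal cost-complexity: the weakest-link subtree sequence is
computed, candidate complexity parameters are the geometric means of
consecutive path alphas, and the parameter is chosen by stratified 10-fold
cross-validated misclassification with the one-standard-error rule, the SE
taken from fold-to-fold variation.  The reference rules were originally
derived with a different CART implementation whose pruning settings are
unknown; the one-SE choice here is declared, not inferred.

Defaults: `min_leaf = 5`, `max_depth = 10`.  A depth-6 tree *can* express
the three reference rules if built by hand, but greedy Gini growth takes a
different split order and needs depth 7–8 before the training set is
perfectly separated; 10 leaves headroom for noisy data.

Two behaviours worth knowing about:

- **Threshold recovery.**  On noise-free rule-labelled samples the grown
  tree recovers every generating threshold to within one value-grid step of
  the training sampler (8 m in distance, 0.2 m in elevation), because with
  data on both sides of a boundary the optimal cut is the midpoint of the
  two straddling values.  The tests assert exactly this.
- **Pruning under pure noise.**  With no signal, CV pruning collapses the
  tree to its root in most seeds and always discards the bulk of the grown
  structure, but not in ≥ 95% of seeds: the minimum of the CV error curve
  over a candidate-rich path dips more than one SE below the root's rate
  often enough that the one-SE rule keeps a few spurious leaves.  R's
  `rpart` behaves the same under identical conditions (we checked; 40–68%
  collapse across settings).  The property test asserts majority collapse
  and strong simplification, which is what the procedure actually
  guarantees.

## The economic model

One hectare is priced over a 25-year crop life.  Revenue is fresh fruit
bunches (FFB) at a constant 178 USD/t (a 2011 regional average; no crude
palm-oil conversion, matching how smallholders and mill-less estates are
paid).  The default full-stand yield curve (t FFB/ha by crop year) is

    years 1–2   0          (immature)
    years 3–7   11.5, 17, 22, 26, 29   (monotone ramp)
    years 8–11  30         (peak plateau)
    years 12–25 linear decline from the plateau to 17 in year 25

which sums to 548.0 t, giving a 25-year mean of exactly 21.92 t.  Palm
capacity c — the standing fraction of the 136 stands/ha full planting
density — scales the whole curve proportionally (yield is assumed directly
proportional to standing palms).

Costs have the minimal structure consistent with the three industry
categories: fixed general charges and field upkeep (USD/ha/yr), harvesting
and transport proportional to yield (USD/t), and a *supplying* (replanting)
charge of S₀·(1−c) USD/ha in years 1–2 only, when estates replace dead
palms.  Net flows are discounted at rate r (default 11%/yr; sensitivity set
5, 8, 14%) and annualized as NPV/25 — the published class table's
magnitudes are only consistent with per-year values, so we adopt that
convention explicitly.

### Cost calibration

Absolute cost levels live in unpublished spreadsheets, so the two free
parameters (total fixed cost F and harvest rate h) are solved in closed
form from two anchor NPVs: the full-stand class endpoints at 11% discount,
A(0.76) = 413 and A(1.00) = 637 USD/ha/yr.  With discount factors d_t,
Y = Σ y_t d_t, D = Σ d_t and E = d₁ + d₂,

    25·A(c) = c·(p − h)·Y − F·D − S₀·(1 − c)·E

is affine in c, so the two anchors pin the line.  A useful consequence: the
calibrated model's NPV at any other capacity is independent of the
supplying base S₀ (it is absorbed into F and h), so the unpublished
supplying values cannot move the class-endpoint predictions.  S₀ defaults
to 15 USD/ha — "relatively small", which is all that is known about it —
and F is split 35/65 between general charges and field upkeep, a
conventional estate ratio with no downstream effect.  Calibration fails
loudly (`CalibrationError`) if the anchors would force a negative cost.

Calibrated at 11%, the model puts the remaining class endpoints at 403.7
(capacity 0.75), 179.7 (0.51), 170.3 (0.50), −53.7 (0.26), −63.0 (0.25) and
−296.3 (0.00) USD/ha/yr — on the two-anchor line by construction, and
within $6/yr of the published endpoints; the residual is the unpublished
per-class supplying adjustment.  Break-even capacity at 11% is c* ≈ 0.318
(≈ 43 of 136 stands/ha), found by bisection to |A(c*)| < 0.01.

Out of scope by design: new-planting capital costs, mill costs, labour
constraints, CPO conversion and price paths — none are modelled upstream
either.

## The synthetic floodplain

`generate_landscape(shape, params, seed)` builds every layer from one
`numpy` Generator, so a (shape, params, seed) triple is bit-reproducible.
Cells default to 100 m (1 ha).  The river is a sinusoidal west–east channel
plus a smoothed random walk, two cells wide.  Distance to river is the
exact Euclidean distance transform (cell-center semantics; equal to the
brute-force minimum, which the tests verify).  Elevation is
`base + gradient·dist/flood_extent + smoothed Gaussian noise`, clipped at
zero: rising in expectation with distance from the channel, with
`flood_extent` as the flood-prone-fringe control (for a fixed seed the
surface decreases pointwise as it grows, so the low-lying near-river
fraction is monotone in it).  Soil is a Gaussian-smoothed latent field cut
at quartiles into the four ordinal classes; the patch-size parameter
(smoothing σ, default 5 cells) is a free choice — no observation
constrains the real layer's autocorrelation.  Forest systems follow the
floodplain logic (mangrove low and river-proximal, seasonally flooded on
the low plain, lowland dry above, degraded patches sprinkled).  Land titles
come from a greedy random rectangle tessellation with Native Title parcels
capped below 40 ha (their legal limit) beside larger commercial leases.
The productivity layer is the reference rules applied to (distance,
elevation, soil), with independent label flips at rate ε emulating mapping
error.

### Training-point sampler

`sample_suitability_points` draws labelled points on value grids (8 m
distance, 0.2 m elevation) stratified over the three rule regions *and*
their full-stand boundary shadows, with extra weight just beyond each
distance threshold.  This emulates training data digitised from mapped
productive and grossly underproductive blocks — which interleave across
flood boundaries — and guarantees each decision boundary has data on both
sides, the premise of grid-precision threshold recovery.  The class mix
comes out near 56:44 full-stand:redundant, close to the 263:211 of the
source training set.  What this generator does *not* emulate: spatial
autocorrelation of mapping error (flips are independent), georeferencing
error, and class imbalance drift — so passing tests say the estimator
recovers a rule structure under clean and mildly noisy labels, not that it
would match any particular remote-sensing product.

## Accuracy assessment and accounting

Error matrices are oriented rows = reference, columns = predicted (both
statistics are orientation-invariant).  Overall accuracy is the trace over
the total; Cohen's kappa is (p_o − p_e)/(1 − p_e) with margin-product
expected agreement.  p_e = 1 is only reachable when every count lies in one
diagonal cell, where kappa is defined as 1.  Verbal kappa bands
(Landis–Koch, Monserud) are metadata strings only.

Area accounting cross-tabulates two aligned categorical rasters into
hectares (nodata excluded, so totals are exactly valid-cell-count × cell
area) and computes percentage shares with **half-up** integer rounding —
the rounding under which every checkable published percentage reproduces
(64, 66, 59, 70, 54, 48, 49).  The published summary tables ship as
checksummed CSV transcriptions; known internal discrepancies of the source
tables are preserved as printed and noted in annotations rather than
repaired: the unprotected-forest column sums to 30,171 ha against a printed
total of 30,173; the title-type areas sum to 30,175; one column total is
off by one hectare in the oil-palm class table; and the forest-extent
table's printed sum row is column-misaligned.  Every affected headline
percentage is insensitive to the choice of denominator at integer
precision, which the tests check.  The combined-redundancy figure is the
plain sum of mapped grossly-underproductive oil palm (15,810 ha) and
flood-prone unprotected forest (16,207 ha): 32,017 ha.

## Numerical and design choices

- Money in double precision throughout; reported rounded to whole USD (CSV
  outputs at 2 decimals).
- Class-endpoint capacities use the nominal percentages (0.76, 0.75, …),
  not rounded stands-per-hectare ratios.
- Bisection tolerance for break-even: |annualized NPV| < 0.01 USD.
- Raster I/O is the plain-text ESRI ASCII grid (integers exact, floats at
  `repr` precision, hence lossless round-trips); parcels are GeoJSON.
  Categorical layers use small integer codes shipped in
  `palmland/data/codes.csv`.
- Scenario configs are validated by a strict schema (unknown keys rejected
  with their key path); runs log config hash, seed and package version, and
  reruns under the same config and seed are byte-identical.
- Problem sizes in the drivers and tests — 100 × 100 landscapes, 2,000 to
  5,000 training points, 10-fold CV over 10 seeds — are deliberate: they
  are the smallest sizes at which every structural claim (boundary
  recovery, noise tolerance, conservation) is comfortably testable, and
  they keep the whole suite quick to re-run.

## Known limitations

- The suitability model is static: no hydrological simulation, no climate
  or price dynamics; inundation risk enters only through the
  elevation/distance/soil structure the rules encode.
- The published map-level areas (250,617 ha of oil palm; 30,173 ha of
  unprotected forest) and the three published accuracy figures rest on
  imagery and validation points that were never deposited; they enter this
  package only as fixture constants and cannot be recomputed here.
- Calibrated cost components are identified only jointly (F, h given the
  anchors); they should be read as effective values reproducing the anchor
  economics, not as audited estate costs.
- Equivalence with the tree behind the reference rules is at the level of
  recovered thresholds and accuracy, not tree topology.
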