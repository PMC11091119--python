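# Methods

## The cloud model of a vegetation belt's distribution height

A vertical vegetation belt has no sharp boundaries: its patches thin out
gradually into the neighbouring belts, so "the elevation of the deciduous
belt" is a qualitative concept realised by a population of concrete
elevations.  The normal cloud model represents such a concept by three
numerical features — expectation `Ex`, entropy `En`, hyper-entropy `He`,
all in metres here — and by a population of *droplets* `(x, C(x))` with a
stochastic membership degree.

**Backward (reverse) generator.**  Given stratum elevations
`x_1 … x_n`:

```
Ex = mean(x)
S  = sum((x - Ex)^2) / (n - 1)          # sample variance, n-1 divisor
En = sqrt(pi/2) * mean(|x - Ex|)        # entropy from mean absolute deviation
He = sqrt(S - En^2)
```

The `n−1` divisor in `S` is used exactly as the estimator is conventionally
stated, even though the same symbol is often described loosely as "the
variance".  The identity `sqrt(pi/2)·E|X−μ| = σ` for Gaussian X makes `En`
a consistent spread estimator in the `He = 0` limit (verified as a test at
n = 10^5 within 2%).

**Degenerate radicand.**  For platykurtic samples (e.g. near-uniform core
strata) `S < En²` and the `He` radicand is negative.  We clamp `He` to 0
and set a `degenerate` flag rather than raising: this is the standard
failure mode of the moment-based estimator, and aborting would kill
otherwise healthy pipeline runs.  The flag is carried into every output
table.  Note that belt *core* strata are close to uniform in elevation, so
degenerate rows are expected there; `He` is informative mainly in the
extension zones, which is where the scientific interest lies.

**Forward generator.**  For each of `m` droplets: draw `En' ~ N(En, He)`,
redrawing while `En' ≤ 0` (the reference algorithm is silent on
non-positive draws; rejection keeps the `En'` distribution conditional-
positive and is seed-stable), then `x ~ N(Ex, En')` and membership
`C(x) = exp(−(x−Ex)² / 2En'²)`.  With `He = 0` every `En' = En` and the
droplets trace the exact Gaussian kernel; with `En = 0` the concept has
zero spread and all droplets sit at `Ex` with membership 1 (`membership()`
itself still rejects `En' ≤ 0`).  Default `m` = 2 000 per cloud map,
configurable; parameter-recovery tests use 10^5.

**Minimum support.**  A cloud model is only fitted to strata with at least
3 points (`min_points`, configurable upward); smaller strata are listed in
a skip report, never silently dropped.

## Belt delineation

Per-type area proportions are computed over left-closed right-open
elevation bins of width 50 m whose origin defaults to
`floor(z_min / width) · width`, so bin edges sit at multiples of 50 m.
Area is cell count × cell area (the stand map is a per-cell raster).

* **Main range** — the longest contiguous run of bins with proportion at or
  above a floor (default 10%); ties break to the run with the higher peak,
  then to the lower-elevation run.  An explicit per-type override exists
  because published analyses typically choose this range by inspection;
  the override is the faithful mode for reproducing such choices.
* **Threshold** — the unweighted arithmetic mean of the type's per-bin
  percentages across the main range (a fixed value can be substituted,
  e.g. for a belt too small to average meaningfully).
* **Core zone** — the contiguous run of bins *strictly above* the threshold
  containing the maximum-percentage bin ("greater than" is read strictly;
  bins exactly at the threshold fall to the extensions).  Isolated
  super-threshold bins outside that run are reported as outliers and
  logged, not merged, because a belt's zones are single intervals by
  definition.
* **Extensions** — everything below the core is the lower extension,
  everything above the upper extension, open-ended and clipped to the DEM
  range only at reporting time.  When a sample count above the core is
  supplied and falls below `min_points` the upper extension is flagged
  empty (no cloud model will exist there).

These rules make the zone partition total: every elevation belongs to
exactly one of core/lower/upper for each type (a property test).

## Sampling and terrain units

* Point grid: spacing 200 m, origin inset half a spacing from the
  lower-left extent corner (the convention is arbitrary but must be fixed;
  the inset keeps all points strictly interior).
* Elevation extraction: containing-cell lookup; points outside the
  footprint or on nodata are dropped with a logged count.
* Aspect: Horn's 8-neighbour finite differences, border cells via
  edge-replication; cells with gradient magnitude < 1e-8 are flat.  Aspect
  is degrees clockwise from north of the downslope direction.
* Aspect classes: sunny = [112.5°, 292.5°), shady = the rest **including
  flat** (flat ground gets no direct-sun advantage).  All intervals in the
  package, including elevation classes (`<550`, `550-900`, `900-1100`,
  `1100-1350`, `>1350` by default), are left-closed right-open.
* Points keep their containing stand's forest type; non-forest points are
  excluded from cloud modelling.  Zone labels and terrain units are
  independent attributes of a point: the `>1350` elevation class and a
  conifer "upper extension" label need not coincide.

## Synthetic landscape generator

The generator emulates the two inputs of a real study — a fine DEM and a
stand-level inventory with dominant species and composition tenths — with
known ground truth.

* **Terrain**: a radially symmetric cone (base 150 m, summit 1530 m,
  500×500 cells of 25 m by default) keeps sunny and shady aspects balanced
  by construction.  Smoothed white noise (Gaussian filter, σ = 3 cells),
  rescaled to a target std (`roughness`, default 15 m) and clipped at ±3σ,
  adds local relief while keeping every elevation provably inside
  `[base − 3·roughness, peak + 3·roughness]`.
* **Belt occupancy**: type `t` has weight 1 on a plateau
  `[center ± halfwidth]` and decays exponentially outside with separate
  lower/upper e-folding scales.  A constant background weight
  `w0 = f/(1−f)` (non-forest fraction `f`, default 0.30) joins the softmax
  normalisation, so far from every belt the landscape tends to non-forest
  rather than to the nearest belt — without it the bottom belt would
  dominate the whole foothill and its lower core edge would be
  unrecoverable.  Probabilities over {3 types, nonforest} sum to 1 by
  construction.
* **Defaults**: cores `[550, 850]`, `[950, 1250]`, `[1300, 1450]` m with
  decay scales 60 m (lower) / 40 m (upper), mirroring the classical
  internal-structure picture of a wide lower and narrow upper transition.
  The decay scales and the ~100 m gaps between cores were fixed at design
  time by evaluating the closed-form curves against the delineation rule:
  the generator's truth is only well defined if the rule's noise-free
  crossing points land within one bin of the plateau edges, and a 500-run
  Monte-Carlo of per-bin multinomial draws at the default grid confirmed
  recovery within ±1 bin throughout.  Sunny cells shift every belt centre
  up by `aspect_shift` (default +30 m, the warm-aspect effect).
* **Stand patches**: labels are drawn per `patch_scale`×`patch_scale`
  block (default 4, i.e. 100 m patches) at the block's mean elevation and
  majority aspect, mimicking the polygonal, spatially correlated nature of
  inventory data.  Compositions are then drawn conditional on the label
  (pure types get 7–10 tenths of their group; mixed stands 4–6 broadleaf
  tenths), so downstream classification is consistent with the drawn label
  by construction.
* **Not emulated**: hydrology-correct terrain, multi-peak mountains,
  spatially varying non-forest cover (valley farmland), succession
  dynamics, real taxonomies.  Passing tests therefore demonstrate the
  pipeline's correctness and the estimators' statistical behaviour, not
  ecological realism of any particular mountain.

## Problem sizes and reproducibility

The analysis drivers and the acceptance script use the default 500×500-cell
landscape (≈ 1 300 forest points on the 200 m grid); estimator identities
use 10^5 draws; the generator-agreement test uses a 200×200 grid with
per-cell patches so plain binomial tolerances apply.  Every stochastic
step takes one named `numpy` generator; derived seeds come from
`SeedSequence` spawning, so identical configurations reproduce outputs
byte-for-byte (asserted in tests).

## Known limitations

* The mean-proportion threshold rule assumes a unimodal proportion
  profile; multi-modal belts produce outlier-bin warnings, not multi-
  interval zones.
* `He` estimates are noisy (±50% at 10^5 droplets for `He/En` ≈ 0.2) and
  clamp to zero on near-uniform strata; comparisons of `He` across small
  strata should be treated qualitatively.
* Near a cone summit elevation bins contain few cells, so the top belt's
  upper core edge is the least stable delineation — visible as a one-bin
  overshoot in the default noisy run.
* Vector (polygon) stand maps are not read directly; rasterise to the
  cell grid first.
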