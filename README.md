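# vertibelt

Cloud-model analysis of mountain vegetation **vertical belts**.

On a forested mountain the boundaries between altitudinal vegetation belts
are not lines but transition zones: patches of the neighbouring belts
interleave, and any drawn boundary is both fuzzy and random.  `vertibelt`
quantifies this uncertainty.  From a DEM and a forest-stand inventory map it

1. classifies stands into **deciduous broad-leaved**, **temperate
   coniferous** and **mixed coniferous-broadleaved** forest from
   species-composition tenths (a group reaching ≥ 7 of 10 tenths makes the
   stand "pure");
2. profiles each type's **area proportion per 50 m elevation bin** and
   splits its range into a **core zone** (contiguous bins above the mean
   proportion of its main range) and **lower / upper extension zones**;
3. drops a regular **200 m point grid**, extracts elevation and Horn
   aspect, and stratifies points by belt zone, elevation class and
   aspect class (*sunny* = 112.5°–292.5°, everything else *shady*);
4. summarises each stratum's distribution height with the **normal cloud
   model**'s three numerical features, estimated by the backward cloud
   generator from the stratum's elevations $x_1,\dots,x_n$:

   $$Ex = \bar X, \qquad
     En = \sqrt{\tfrac{\pi}{2}}\,\frac{1}{n}\sum_{i=1}^n |x_i - Ex|, \qquad
     He = \sqrt{S - En^2},\; S = \tfrac{1}{n-1}\sum (x_i-\bar X)^2 .$$

   $Ex$ is the central distribution height of the belt (m), $En$ its
   fuzziness (spread, m), and $He$ the randomness of that spread (m).  The
   forward cloud generator draws droplets $En' \sim N(En, He)$,
   $x \sim N(Ex, En')$ with membership
   $C(x) = \exp\!\big(-(x-Ex)^2 / 2En'^2\big)$ for cloud maps;
5. compares belt types through per-unit $|\Delta Ex|$ — a small
   expectation gap between the mixed forest and one pure type in a
   transition unit indicates which habitat the mixed patches are invading.

Because forest-inventory rasters of this kind are rarely shareable, the
package ships a **synthetic mountain generator** with analytic ground truth
(cone DEM, stacked plateau-and-decay occupancy belts, aspect-shifted on
sunny slopes, patch-wise stand draws) so the whole pipeline is testable
end-to-end, plus the published Mount Taishan unit table as a worked-example
input.

## Worked example

The analysis is a chain of thin drivers (each step also available through
the library or the `vertibelt` CLI):

```sh
python analysis/01_simulate_landscape.py   # DEM + stand map + ground truth
python analysis/02_delineate_belts.py      # bin proportions -> zone scheme
python analysis/03_sample_points.py        # 200 m grid, terrain units
python analysis/04_fit_cloud_models.py     # Ex/En/He per stratum + cloud maps
python analysis/05_invasion_differences.py # per-unit |Ex_a - Ex_b|
```

Step 02 prints, for the default 500×500-cell landscape (seed 20240513):

```
belt delineation (mean-proportion threshold rule, 50 m bins):
  deciduous_broadleaf    threshold 54.14%  core [550, 850) m  truth [550, 850] m  edge errors (+0, +0) m
  temperate_conifer      threshold 52.50%  core [950, 1250) m  truth [950, 1250] m  edge errors (+0, +0) m
  mixed                  threshold 52.47%  core [1300, 1550) m  truth [1300, 1450] m  edge errors (+0, +100) m
```

i.e. the threshold rule recovers the generator's true core intervals
exactly for the two large belts; the small summit belt overshoots by two
bins because its uppermost bins contain very few cells.  Step 04 then
reports, per belt zone, the fitted cloud features, e.g.

```
        forest_type  zone   n    Ex_m  En_m  He_m
deciduous_broadleaf  core 562  687.64 91.15  0.00
deciduous_broadleaf lower 198  469.38 66.50 24.91
deciduous_broadleaf upper  77  890.88 35.04 15.65
```

— the core's distribution height centres at 688 m with spread 91 m, and the
extension zones are narrower but (lower zone) noticeably more random.  Step
05 reproduces the published Mount Taishan invasion analysis from the
printed per-unit Ex values: below 550 m the deciduous-vs-mixed expectation
gap is 36.94–39.15 m while the conifer-vs-mixed gap is only 4.79–7.94 m
(pooling the 900–1100 m class), the signature of broadleaf species
encroaching on conifer habitat at low elevations.

A config-driven one-shot run of the same pipeline:

```sh
vertibelt run --config analysis/pipeline_config.yaml --out results/run --seed 1
```

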