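# hipposurvey

Tools for estimating hippopotamus school sizes from drone (UAS) imagery and
for designing the counting protocol around the two things that make hippo
counts hard: most of a school is submerged at any instant (hippos dive for
3–5 minutes), and human observers miss animals at rates that depend on
flight height, weather and their own experience.

The package implements, as a tested pipeline with a fully synthetic data
mode:

* **Footprint geometry** — ground strip width, frame area and ground
  sample distance as linear/quadratic functions of flight height,
  calibrated from a measured reference pair (47.6 m strip at 40 m AGL for
  a 6000×4000 frame).
* **Frame-overlay abundance estimation** — register ≥15 successive
  geo-referenced photos spanning ~25 min (longer than the longest dive),
  track surfaced animals across frames with a gated nearest-neighbour
  matcher, add points for new emergences and never delete them; the
  accumulated point count is the school total for that flight.
* **Detection statistics** — for each *experimental unit* (one photo
  reviewed by one observer), the detection rate `DR = tot.num / est.pop`
  and level of certainty `LC = def.obs / tot.num`, summarized per observer
  and per experience group with 95% CIs.
* **Mixed logistic models** — binomial GLMMs on the logit scale,

  ```
  logit(R) = a + b·Height + c·Windspeed + d·Cloudcover + e·Sunreflection
             + f·Experience + α_flight + β_photo + γ_observer
  ```

  with *crossed* Gaussian random intercepts for flight, photo and
  observer, fitted by Laplace-approximated maximum likelihood (an
  adaptive Gauss–Hermite mode for small instances), plus AIC backward
  selection of fixed and random terms.
* **Correction factors** — factor 1 (inverse detection rate against the
  per-flight total) and factor 2 (against the whole-population total),
  compared by Welch t-test.
* **Survey-effort optimization** — resampling of 1–3 observers × 1–10
  photos, scoring each cell by the error of the best-of-combination
  count, to find the cheapest design with error below a target (≤5%).

The synthetic generator reproduces the reference survey design: 8 flights
over one school of 55–61 animals, 252 photos stratified 42 per height
class (40–140 m), Table-calibrated sun/cloud/wind marginals, 8 observers
(3 experienced), 2016 experimental units, and per-unit counts drawn from
the fitted detection-rate and certainty models.

## Worked example

Generate a survey, estimate one flight's school size from its frame
stack, and compute correction factors and the effort recommendation:

```bash
$ hipposurvey simulate --seed 7 --out demo
wrote 2016 units to demo/units.csv

$ hipposurvey track --frames demo/frames.geojson --flight 4
61

$ hipposurvey correct --units demo/units.csv --out demo/cf.csv
 factor         group     mean    ci_lo    ci_hi  n_units  n_excluded
      1           all 1.195127 1.187516 1.202738     2016           0
      2           all 1.255205 1.246676 1.263734     2016           0
      1   experienced 1.110031 1.103681 1.116380      756           0
      2   experienced 1.165379 1.157738 1.173020      756           0
      1 inexperienced 1.246185 1.235573 1.256797     1260           0
      2 inexperienced 1.309100 1.297199 1.321001     1260           0
factor1 vs factor2 Welch t = -10.301, p = 1.42e-24

$ hipposurvey combos --units demo/units.csv --seed 7 --out demo/em.csv
recommended: 2 observers x 4 photos (error <= 0.05)
```

Reading the output: flight 4 of this synthetic survey truly held 61
hippos and the tracker recovers exactly that from the 15-frame stack.
Observers detect ~84% of animals on average (factor 1 for all observers
is 1.195, i.e. multiply a raw count by ≈1.2), experienced observers do
better (1.110) than novices (1.246), and factor 2 is strictly larger than
factor 1 for every group because its denominator is the whole population
(61) rather than the per-flight total (55–61) — the two factors differ
highly significantly. Resampling the observer×photo grid, two observers
reviewing a handful of photos already brings the expected error of the
best-of-combination count under 5%.

Fitting the detection-rate GLMM on the same units
(`hipposurvey fit --units demo/units.csv --response dr`) returns the
coefficient set — e.g. intercept 2.69, sun −0.52, experience −0.79 on
this replicate, wind not significant (p = 0.51) — together with the three
random-intercept SDs, log-likelihood and AIC. `hipposurvey run --out dir
--seed N` executes the whole chain and writes a checksummed manifest;
rerunning with the same config and seed reproduces every file byte for
byte.

The library mirrors the CLI: see `hipposurvey.simulate`,
`hipposurvey.tracking`, `hipposurvey.glmm`, `hipposurvey.correction`.

## Layout

```
src/hipposurvey/     geometry, simulate, tracking, rates, glmm,
                     correction, io, pipeline, cli
tests/               pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
docs/methods.md      models, assumptions, numerical choices, limitations
```
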