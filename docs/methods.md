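# Methods

This note documents the models, assumptions and numerical choices behind
`hipposurvey`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Footprint geometry

The across-track ground width of a nadir photo is modelled as strictly
linear in flight height AGL and calibrated from a single measured pair
(47.6 m at 40 m for a 6000×4000-pixel frame), rather than derived from
nominal sensor and focal-length physics. The measured pair is
inconsistent with the nominal sensor datasheet (in-camera cropping and
effective focal length are not knowable from the datasheet alone), and
calibrating on the measurement reproduces all observed footprints
exactly. Frame length along track is the strip width scaled by the pixel
aspect ratio (4000/6000), so frame area is quadratic in height. GSD is
strip width over across-track pixels. Lens distortion, terrain relief and
attitude are out of scope; heights are treated as exact.

## 2. Synthetic surveys

The generator's defaults are the reference survey's conditions, and they
are not tuning knobs:

* 8 flights over one school; per-flight true totals
  (57, 60, 58, 61, 59, 55, 57, 57); population total 61 (their maximum),
  emulating mild in/out movement of a school that is otherwise stable
  over a few days.
* 252 photos, exactly 42 per height class in {40, 60, 80, 100, 120,
  140} m.
* Covariate marginals fixed to the survey's photo counts: sun reflection
  {187, 54, 11} for classes 0/1/2; cloud {18, 169, 65}; wind
  {32, 101, 36, 18, 65} for 1–5 m s⁻¹.
* 8 observers, 3 experienced (dummy coding 0 = experienced, 1 = novice).

Wind and cloud are flight-level. Under uniform photo→flight assignment
their photo-level marginals could not be controlled, so the default
flight plan fixes (wind, cloud, photos-per-flight) triples whose totals
reproduce the marginals exactly, and photos are dealt to flights by
shuffling the flight-label multiset within the height stratification.
Sun classes are the exact multiset assigned by noisy acquisition-time
rank (noise SD 60 min), which yields the qualitative sun/time correlation
of real morning flights (later = more reflection) without making the
correlation coefficient itself a target.

Counts: for each photo×observer unit, detected ~ Binomial(true_total,
p_DR) and definite ~ Binomial(detected, p_LC), with p through the
logistic link from the generating coefficients plus flight/photo/observer
random intercepts drawn once per entity and per response. The generating
coefficients default to the fitted detection-rate and certainty models of
the reference survey (DR intercept 2.36659, height −0.07145, cloud
−0.74768, sun −0.61517, experience −0.51469; random SDs 0.4414 flight,
0.3142 photo, 0.2101 observer; analogous LC row). The wind coefficient
defaults to 0: it was eliminated in the source models. By construction
`definite + possible = detected ≤ true_total`; real observers can
over-count (detection rates above 1), which the generator reproduces only
through an optional Poisson false-positive rate, off by default, because
no mechanism for over-counting is available to calibrate.

Covariate encoding is shared between the generator and the fitter so that
recovery experiments are encoding-invariant: height and wind standardized
(sample mean/SD, n−1) over the units, cloud and sun regrouped to binary
indicators (cloud {0,1}→0, {2}→1 in both models; sun {0,1}→0/{2}→1 for
DR, {0}→0/{1,2}→1 for LC), experience entered raw 0/1. Whether the
source analysis additionally standardized its dummies is unknowable from
the printed tables; sharing one encoding makes the recovery targets
well-defined either way.

### School dynamics for the frame stage

Individuals are placed with ≥12 m pairwise separation in a 250×80 m pool
(dart throwing) and alternate surfaced (120–240 s) and dived (180–300 s)
intervals with random phase; they drift with piecewise-constant velocity
at ≤0.002 m s⁻¹, i.e. an essentially resting daytime school. Frames are
sampled every 107.5 s, 15 per flight (~25 min span). These defaults
jointly guarantee the tracker's exactness conditions: every animal's
surfaced interval (≥120 s) contains a frame instant (spacing 107.5 s),
every animal surfaces within the span (max dive 300 s ≪ 25 min), drift
between sightings stays below the 5 m gate, and no two animals ever
approach within the gate. Real schools are denser and more mobile than
this; passing tests therefore validate the accumulation logic under the
protocol's own assumptions, not tracker robustness to crowded or fast
scenes (the original procedure resolved such cases manually).

## 3. Frame-overlay tracker

Registration: 2-D similarity (Umeyama least squares) from ≥3
non-collinear tie-point pairs, reporting the residual RMS; callers should
reject registrations with RMS above their accuracy budget (drone
tie-point stacks achieve ~0.3 m). Collinear configurations raise an
error.

Accumulation: per frame, candidate (track, point) pairs within a hard
gate (default 5 m ≈ one hippo body length + registration error) are
processed in increasing distance with deterministic tie-breaks (lower
track index, then point index), each track/point used once — greedy
mutual nearest neighbour. Unmatched points open tracks; tracks are never
deleted (a missing animal is presumed dived). The manual matching it
replaces had no published tie-break rule; determinism was chosen over
fidelity to an unknown manual process. Consequences: the estimate is
monotone in appended frames, never exceeds the true count when there are
no false positives, and equals the number of distinct surfaced animals
whenever the separation/displacement conditions above hold (verified
against a brute-force identity count).

## 4. Detection rates and summaries

DR may exceed 1 (over-counting); LC is undefined for zero-count units.
Zero-count units contribute DR = 0 to DR summaries but are excluded from
LC aggregation (an observed LC minimum of exactly 0 in the source data
implies zero-definite units with nonzero totals were kept). CIs are
normal-approximation mean ± 1.96·SE on unit-level values — the
presentation used by observer tables in this literature, which do not
name their CI method; a percentile bootstrap is available as an option
and agrees closely at these sample sizes. Group means are emitted both
unit-weighted and observer-weighted because published group figures
rarely specify the weighting.

## 5. Crossed-random-intercepts binomial GLMM

The DR response is binomial with the per-flight school estimate as
denominator; LC uses the observer's own total, excluding zero-count
units. Real over-counts (successes > denominator) are capped at the
denominator for fitting only — a binomial response cannot exceed its
trials — while raw values are retained for the correction factors.

Likelihood: with three crossed Gaussian intercept factors the marginal
likelihood is an integral over all q latent effects (q = 268 at full
design) that does not factorize. The fitter maximizes the Laplace
approximation: the joint mode û is found by penalized IRLS (Newton with
step halving; the inner problem is strictly concave), and

    log L ≈ ℓ(û) − ½ û'Σ⁻¹û − ½ log|Σ| − ½ log|Z'WZ + Σ⁻¹|.

The inner gradient tolerance scales with the total Bernoulli trial count
(1e−10 × Σn), i.e. convergence to the objective's floating-point noise
floor. The outer problem optimizes (β, log σ) by L-BFGS-B with
finite-difference gradients (step 3e−6, projected-gradient tolerance
1e−5 — the realistic noise floor for a finite-differenced objective;
log σ bounded in [−6, 3], estimates near the lower bound reported as 0
with a boundary flag). Starting values: ordinary binomial GLM for β
(statsmodels), σ = 0.3. Standard errors come from a central-difference
Hessian of the negative marginal log-likelihood at the optimum; p-values
are Wald. AIC = 2k − 2 log L with k counting fixed coefficients plus
variance parameters.

For small latent dimension (q ≤ 6) an adaptive Gauss–Hermite mode is
available (`method="agq"`): a product GH rule centered at û and scaled by
the Cholesky factor of the joint curvature, analogous to lme4's nAGQ.
Laplace's error is O(1/m) in the per-level trial count m, so at
denominators ≤5 it is of order 1e−2 and only the quadrature mode reaches
quadrature-oracle agreement below 1e−3; at the full design (denominators
55–61) the Laplace fit matches lme4's glmer to four decimals in every
coefficient, random-effect SD and the log-likelihood.

Backward selection: random intercepts are tested first by
likelihood-ratio comparison of nested fits and kept when they improve
AIC; fixed effects are then removed greedily (largest AIC drop first)
until no removal lowers AIC. A structural caveat documented rather than
"fixed": wind and cloud vary over only 8 flights and are near-confounded
with the flight intercept, so tests of flight-level effects have ~8
effective observations. In replicate simulations with a truly-zero wind
coefficient, the full procedure removes wind in a (reproducible) majority
of seeds, but the single-dataset outcome is genuinely uncertain at this
design size. Flight time is excluded as a covariate (it is arbitrary,
non-uniform, and proxies the weather covariates).

## 6. Correction factors and effort optimization

Factor 1 is the per-unit inverse detection rate (flight denominator);
factor 2 replaces the denominator with the population total, by default
the maximum flight total (61), configurable to a census value. Zero-count
units are excluded and counted. Identities that hold exactly per unit:
factor1 × DR = 1 and factor2/factor1 = population/flight total. The two
factors are compared by Welch's two-sided t-test on the per-unit values.

Effort resampling: for each cell (o observers, p photos), o observers and
p photos are drawn without replacement (with replacement across the 100
replicates), and the maximum DR among the o×p units is the combination's
operational count. The cell error metric defaults to mean |1 − best DR|,
which penalizes over-counting as well (DR can exceed 1); `1 − mean(best
DR)` is available as an alternative because the plotted error definition
in the source material is not stated precisely — for the same reason the
published single-observer single-photo error value is not treated as a
reproduction target. `recommend_design` returns the cheapest cell (cost
w_o·o + w_p·p, ties to fewer observers) under an error threshold
(default 5%).

Because each synthetic survey redraws its flight/photo/observer random
intercepts, a single survey's error matrix carries between-survey
variance that a fixed real dataset does not; expected cell errors are
therefore estimated by averaging the resampling over 8 independently
simulated surveys (acceptance script and tests). The expected
(2 observers, 7 photos) error under the default generating model is
≈4%, below the 5% design threshold.

## 7. Reproducibility and problem sizes

All randomness flows from integer seeds through
`numpy.random.SeedSequence`; the pipeline derives one child stream per
stage from a counter scheme, so adding a stage does not perturb earlier
stages, and identical config + seed reproduces byte-identical outputs
(checksummed in the run manifest).

Problem sizes used by the shipped experiments, chosen as the smallest
that estimate each quantity with comfortable precision: parameter
recovery refits the full 2016-unit design over 48 replicates
(Monte-Carlo SE of the recovered-coefficient means ≈0.015–0.03 logits);
selection-consistency and sign properties run on a reduced survey (42
photos × 4 observers, 168 units) over 20 fixed seeds; the effort matrix
uses 100 resampling replicates per cell over 8 survey replicates; the
tiny quadrature-oracle instances use 4 units so that a dense 6-D
product-quadrature reference is tractable.

## 8. Known limitations

* The tracker is exact only under the resting-school assumptions above;
  it has no multi-hypothesis reasoning and does not maintain identity
  across flights.
* Laplace ML variance components with 8 flight levels are noticeably
  shrunk (a generic small-level-count property); no REML-like correction
  is applied.
* Flight-level covariates have ~8 effective observations (see §5).
* The generator does not synthesize imagery; observer behaviour enters
  only through the logistic models, so pixel-level effects (zoom
  behaviour, mark placement error, double-marking) are represented
  solely by the random intercepts and the optional false-positive rate.
* Real-data mode expects pre-extracted point layers and unit tables; no
  image registration from pixels is provided.
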