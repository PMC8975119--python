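# Methods

This note documents the models, numerical choices and defaults of the
package, what the synthetic-data generator does and does not emulate, and
the problem sizes used by the test suite and `scripts/acceptance.py`.

## Image statistics

All statistics operate on 8-bit luminance grids; float input in [0, 1] is
quantized to 256 levels on construction so histogram measures are always
discrete and comparable.

**Radial power spectrum.** The image is mean-subtracted and windowed with
a separable 2-D Hann window before the FFT (anti-leakage; without a window
the spectral slope of natural-looking textures is biased toward 0 by edge
discontinuities). Squared magnitudes are averaged over linear annuli of
radial frequency expressed in cycles/image of the *shorter* axis, the DC
bin is excluded and empty annuli dropped.

**Spectral slope (α).** OLS of log₁₀ power on log₁₀ frequency over
[4 cycles/image, 0.45 x Nyquist] by default, both ends configurable. The
fit refuses to run on fewer than 8 usable bins. We fit the *power* (not
amplitude) spectrum, so α is the exponent of the energy power law; natural
scenes cluster near α ≈ 2 on this convention. Validation: on
phase-randomized 1/f^α fields (256 x 256, α ∈ {0.5, 1, 1.5, 2}, 20 seeds
each) the mean absolute estimation error is ≤ 0.1 (measured ≈ 0.05, a
small negative bias from windowing and annulus averaging).

**Deviation.** The trapezoidal integral of the *absolute* log₁₀-power
residual against log₁₀ frequency over the fit range. The area-under-curve
definition is sign-ambiguous; integrating |residual| makes deviation a
non-negative distance that is zero exactly on power laws and provably
monotone in the amplitude of an injected spectral bump, which is the
behavior the measure is meant to capture (dominance of particular scales).
A signed variant would cancel bumps against dips.

**Entropy and skew.** Shannon entropy over exactly 256 histogram bins
aligned to the 8-bit levels (0·log 0 = 0; bounds [0, 8] bits with equality
at constant and exactly-uniform histograms). Skew is the population
(moment) estimator g₁, defined as 0 for zero-variance images — a constant
image has no asymmetry, and NaN would poison tile variances downstream.
Constant images make α and deviation *undefined* (NaN plus a reason
string), never silently 0.

**Difference variables.** Properties are computed on disjoint 256-px
tiles anchored at the top-left (partial tiles dropped; exact for the
1280 x 1024 study geometry, 5 x 4 = 20 tiles), the sample variance (n−1)
is taken across tiles for the background-as-presented (decoy contours
already blurred in) and for the composed stimulus, and the background
variance is subtracted. Tiles with undefined α/deviation are excluded
pairwise from both variances. The implementation is checked to 1e−9
against an explicit tile-loop oracle.

## Salience and screening

The salience map follows the graph-based construction: feature maps
(center–surround luminance differences at 3 scale pairs; 4 oriented
gradient-energy maps) each define a fully connected Markov chain over grid
cells with edge weight |M(a)−M(b)| · exp(−d²/2σ²); the stationary
distribution (power iteration, tolerance 1e−9, max 10⁴ iterations,
uniform start) is the activation, a second chain weighted by destination
activation concentrates mass, maps are summed and rescaled to max 1.
Exact parity with the original release is a non-goal.

*Grid resolution:* the chain runs on a grid whose longer axis is **32
cells** (σ = 0.15 x grid width). A fully connected chain over a 128-cell
grid would need a ~1.4 GB dense transition matrix per feature map; 32
cells matches the working scale of the original algorithm and keeps a
map under half a second.

*Screening rule:* a candidate stimulus is accepted iff the mean map value
in the target disk ≥ θ_target **and** the best non-target location disk
≥ θ_rival ("moderately salient, but not the only salient region").
Defaults θ_target = 0.25, θ_rival = 0.10. No quantitative criterion
exists for "moderately salient"; on the synthetic textures the inserted
patch is almost always the dominant region, and rival-disk values for
smooth backgrounds sit near 0.1–0.2, so a rival threshold of 0.25 would
empty whole category-pair strata and make the balanced design infeasible.
Both thresholds are config and are recorded in the pool manifest.

## Stimulus composition

Ring geometry: the quoted ~710-px center distance of the ten locations is
geometrically impossible as a radius on a 1024-px-tall image, so the ring
is implemented with **diameter ≈ 710 px (radius 355 px)**, configurable;
at 40 px/degree this is 18° of visual angle across. Decoy contours: one
combined annulus mask (width 24 px) over all ten location contours,
blended with a Gaussian-blurred (σ = 8 px) copy of the background. Target
border: the patch is composited through a soft disk mask obtained by
Gaussian-smoothing the hard disk indicator with σ = 8 px and finite 3σ
support, so pixels beyond 3σ outside the disk equal the decoy background
bit-exactly. Monochromatization maps gray to HSL lightness at the given
hue (90/210/330°) with saturation 1.0 (unstated in the source studies;
configurable), verified against the stdlib HSL conversion.

Patch sampling is uniform with full-disk containment and pairwise center
distance ≥ diameter/2 by rejection (≤ 10⁴ attempts), seeded.

## Balanced design

Per 36-trial version: target and background categories balanced (counts
differ by ≤ 1; with 3 categories and 36 trials this forces 12/12/12), the
category x depth congruency 2x2 balanced to ±1 per cell (9 ± 1), no image
more than twice per role, and a repeated image's two occurrences must
differ in partner image, location and hue. "Balanced" is read as
near-equality with an explicit tolerance since exact frequencies are not
available. The solver is greedy and seeded: each slot fills the currently
scarcest congruency cell, preferring candidates whose categories are
least represented, with up to 200 restarts per version; the candidate
pool is sampled stratified over congruency x category pairs so every
balance cell has supply. On the synthetic pool the solver terminates in
well under a second per design and the audit (a pure function checking
every invariant) is clean across seeds.

## Gaze analysis

Fixations: I-DT with a 40-px (1°) dispersion window on valid samples;
gaps of invalid samples ≤ 75 ms are bridged, longer gaps split the
window; fixations must exceed 50 ms. Hits: computed on raw samples, not
parsed fixations — the first maximal run of valid in-target samples
spanning ≥ 100 ms and starting before 4500 ms is a hit, and latency is the
run's *onset* (comparable to saccade-latency conventions; the
end-of-dwell alternative would add the dwell duration to every latency).
Runs may bridge a single missing sample. Inclusion: hits kept iff ≥ 80 %
of samples were recorded; misses kept iff summed valid-sample time reaches
the median hit latency of the whole dataset (1240 ms is used as the
fallback when a dataset has no hits). "Rate 1st hit-fixation" is
implemented as the proportion of trials whose first parsed fixation lands
in the target disk; AOI disks use the target diameter at all ten ring
positions, and the first-fixation chance level is 1/10.

Movement covariate: the maximum over a trial's fixations of the
within-fixation range (max − min) of head–camera distance, in mm.

## Mixed models

Success is modelled with a **binomial-logit GLMM with crossed random
intercepts** (participant, background image, target location). The
estimator is written in-house because the environment has no ML binomial
GLMM in Python: the Laplace approximation with penalized IRLS for the
joint (β, u) mode, profiled fixed effects, and Nelder–Mead over the log
random-intercept SDs. It collapses onto the ordinary logistic GLM (to
1e−10) when variance components vanish, matches lme4's glmer on simulated
data within 0.1 on coefficients (cross-checked in the test suite via
Rscript), recovers a 0.55 log-odds coefficient at the study's size
(39 x 36) with mean error well inside ±0.15 and ≥ 19/20 sign agreement,
and its 95 % Wald CIs cover the truth at nominal rates in null
simulations. Complete separation (constant response or diverging
coefficients) raises or flags rather than returning silently.

Latency (hits only) uses a Gaussian LMM (participant and background
intercepts) through statsmodels MixedLM with ML (not REML) so nested
log-likelihoods are comparable; a helper tests the location intercept by
LRT. Significance of predictors is assessed by χ² LRTs on nested ML fits
(df = parameter difference, χ² clipped at 0); Wald 95 % CIs are estimate
± 1.96 SE. Continuous predictors are z-scored over included trials
(coefficient magnitudes presume standardized inputs) and congruency
factors coded 0/1 with incongruent = 0. VIFs (1/(1−R²), threshold 2.5)
screen each model group; diff_luminance interactions are kept only when
the joint LRT improves the model at p < .05. Marginal R² follows the
fixed-over-total variance decomposition with binomial residual variance
π²/3. The AOI coincidence model is a Poisson GLMM (participant intercept)
of fixation counts with the target as reference level; an overdispersion
ratio is reported. No multiple-testing correction is applied, mirroring
the original analysis strategy.

Null calibration: across seed blocks the LRT type-I error at α = .05 sits
near 0.055 at the study-scale latency table (39 participants x ~14 hits),
the mild liberality expected from using the χ² reference in finite
samples.

## Synthetic data

**Textures.** A phase-randomized Gaussian field with amplitude ∝ f^(−α/2)
is rank-remapped onto a discrete target histogram from the beta family;
(a, b) are solved by least squares so the 256-level quantized beta hits
the target entropy and skew (infeasible pairs — e.g. near-8-bit entropy
with strong skew — raise). The remap reproduces entropy and skew
essentially exactly and preserves the spectral slope within ±0.15
(monotone transforms of Gaussian fields keep correlation structure to
first order).

**Catalog.** 27 images, 9 per category, with distinct property regimes —
vegetation (α 1.0, entropy 7.1, skew 0.2), non-living natural elements
(α 1.9, entropy 6.3, skew 0.7), artifacts (α 1.45, entropy 7.5, skew
−0.35), each jittered per image — so category structure is real in
property space (within-category distances are smaller than
between-category). Depth classes are balanced 5/4 within category and
drive the rated-depth score; other ratings carry mild category structure
plus noise. Dissimilarity matrices are scaled property-space distances with symmetric
noise: the child variant uses only the lower-level statistical dimensions
with large noise, the adult variant also weights the depth dimension and
is cleaner — mirroring the age difference in the rating studies these
scores stand in for, and keeping the two predictors clear of the VIF
screen.

**Gaze simulator.** Per trial, the hit is Bernoulli with a logistic model
over standardized design predictors plus crossed random intercepts; hit
latency is log-normal around a linear mean structure (right-skewed and
positive by construction; the original analysis is not generative, so the
family is our choice), truncated at the timeout, with truncation feeding
back into the miss count as real censoring would. The emitted 500 Hz
stream realizes the outcome: a center start, gamma-distributed fixation
durations, AOI-to-AOI jumps with samples lost during saccades, a final
≥ 100 ms target dwell placed exactly at the drawn latency for hits,
dropout (never inside the qualifying dwell, so the scripted outcome
survives re-analysis), and a random-walk head distance. Tracking quality
is bimodal, as in real infant recordings: most trials lose only 1–8 % of
samples while a minority (probability = `dropout_prob`, default 0.10)
are poor-tracking trials losing 35–65 % — the structure the recorded-gaze
inclusion rules are designed to catch. Defaults are calibrated to the
infant group's observed marginals: hit rate ≈ .39 over *included* trials,
median hit latency ≈ 1.47 s (1520 ms intercept with the log-normal median
correction), mean fixation duration 467 ms, median recorded-gaze
proportion ≈ .88. The adult preset uses hit rate ≈ .98, median latency
≈ .63 s, 230 ms fixations, 1 % dropout. What the simulator does **not** emulate: calibration drift,
eye-tracker noise spectra, pupil signals, smooth pursuit, or any
salience-driven scanpath structure — passing recovery tests therefore
shows the analysis chain is correct and calibrated, not that it would be
robust to every artifact of real recordings.

## Pipeline and problem sizes

Stage seeds are derived from the master seed by SHA-256 of
`"{seed}:{stage}"` (kept below 2³¹), so stages can be rerun
independently; every stage directory gets a checksum in `manifest.json`
and a completed stage with matching config fingerprint is loaded rather
than recomputed. Default scale: 27 full-size (1280 x 1024) images, 320
screened pool candidates, 8 x 36 design, 39 simulated participants; this
runs end-to-end in about six minutes on one CPU. The test suite and the
acceptance script exercise structure-level checks on a geometrically
faithful scaled-down setup (640 x 512 images, 117-px targets, 177-px ring
— chosen so disk containment and the 256-px tiling relations survive) and
the image-statistics and inference checks at their stated sizes
(256 x 256 fields, 20 seeds per α; 200–400 inference replicates at the
study's n).

## Known limitations

* The salience screen is a faithful *structure* of the cited algorithm,
  not a bit-exact port; screening decisions on real photographs would
  differ from the original study's.
* The Laplace/profiled-β GLMM carries the usual small attenuation of
  binomial mixed-effect estimates (visible as a ~2 % downward bias at the
  study size), well inside the documented recovery bounds.
* Rated properties and dissimilarities are synthetic stand-ins with
  assumed structure; nothing in the package validates them against human
  judgments.
* The balanced-design solver is greedy with restarts, adequate for the
  loose constraint system here; it is not a general CSP solver and offers
  no completeness guarantee.
* On synthetic textures the five computational difference variables are
  more collinear than photographic stimuli would make them (a discrepant
  patch perturbs several properties at once); the VIF screen flags this
  and the model-suite decision ledger records it.
* In the simulator the movement covariate correlates with trial duration
  (longer search means more head drift), so null simulations show a
  strong movement "effect" on success that is a trial-length artifact,
  not a bug in the covariate.
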