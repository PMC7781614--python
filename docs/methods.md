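# Methods

This note documents the models, parameter choices and numerical
decisions behind `capdyn`, and what the synthetic benchmark does and
does not establish.

## Synthetic cohort model

CAP analysis presumes that resting-state activity visits a small set of
recurring coactivation states. The generator makes that assumption
literal: a first-order Markov chain over K discrete states emits, at
frame t, the state's component pattern plus stationary AR(1) Gaussian
noise, independently per component. The chain's transition matrix is
`P = d·I + (1−d)·1πᵀ`, so the dwell-time parameter d ("persistence")
can be varied without moving the stationary distribution π — group
effects are planted purely as occupancy differences, which is exactly
the quantity the downstream statistics estimate. A first-order chain is
the simplest process with well-defined frequency-of-occurrence
semantics; it makes no claim about the neural dynamics beyond
recurrence.

Benchmark defaults (all configurable in `CohortConfig`):

| parameter | default | rationale |
|---|---|---|
| subjects | 20 per group (40) | enough for stable pooled clustering while keeping Monte-Carlo suites fast |
| frames / TR | 160 pre-trim / 2 s | matches the 155-frame, TR = 2 s analysis geometry after trimming |
| components | 69 non-noise over 12 networks | the component count entering clustering in the motivating design |
| states | 5 | the benchmark's planted truth |
| occupancy | TD (.175, .300, .175, .175, .175) vs ASD uniform .2 | a +0.10 group difference concentrated in one state |
| persistence d | 0.8 | mean dwell ≈ 10 s, inside the 0.01–0.1 Hz band |
| amplitude / noise_sd | 1.0 / 0.9 | pattern RMS across components ≈ 0.44, i.e. a pattern-to-noise RMS ratio ≈ 0.5 — individual frames are noisy, as real frames are |
| AR(1) coefficient | 0.3 | mild temporal smoothness typical of filtered component series |
| site offset / drift / spikes | 0.2 sd, 0.01/frame sd, p = 0.01 at ±4 | nuisance structure for the preprocessing stages to remove |
| motion | gamma FD, mean 0.16 mm | the mean FD of a usable (post-QC) pediatric sample |

State patterns are block-structured over the 12-network vocabulary (two
networks activated at +amplitude, one mildly deactivated, small jitter),
and the seed component is active in every state so supra-threshold
selection samples all states. Realignment files are constructed so
their Power-formula FD reproduces the drawn FD trace exactly, which
exercises both motion-input formats.

What the generator does **not** emulate: hemodynamic convolution,
voxel-space structure and ICA estimation error, spatially correlated
noise across components, scanner-specific spectra, or group differences
in pattern shape (available only via an explicit pattern-perturbation
when constructing a second pattern set). Passing benchmarks therefore
demonstrates that the pipeline recovers planted occupancy structure
under realistic noise — not that any particular empirical dataset
contains such structure.

## Preprocessing decisions

Stage order is fixed: trim → detrend → despike → bandpass (→ z-score).

* **Trim**: drop the first 5 volumes, then cut the tail to 155 frames.
* **Despike**: the classic despiking transform is specified by its clip
  constants, not its baseline. We use a centered running-median baseline
  (window 9 frames, shrinking at the edges) rather than a Fourier-plus-
  polynomial fit; residuals are standardized by 1.4826 × median
  absolute residual, values beyond c1 = 2.5 are compressed by
  `c1 + (c2−c1)·tanh((|s|−c1)/(c2−c1))` with c2 = 4.0, so output
  residuals are strictly below c2. Constant series (σ = 0) pass through.
* **Bandpass**: 5th-order Butterworth applied forward–backward
  (zero phase) as second-order sections; an ideal FFT mask is selectable
  (`filter_design="fft"`). Band edges are validated against the Nyquist
  frequency implied by the TR.
* **Z-scoring** each component per subject (default on) prevents
  high-variance subjects or components from dominating pooled
  clustering; it is recorded in the run manifest and can be disabled.

## Clustering decisions

* **Distance**: Pearson correlation distance (1 − r) by default, the
  convention of the CAP literature; Euclidean selectable. Under the
  correlation metric frames are row-standardized and centroids are means
  of standardized frames, making assignments invariant to per-frame
  affine rescaling.
* **k-means**: implemented in-package (Lloyd iterations, k-means++
  seeding, empty clusters reseeded to the worst-fit frame) because
  correlation distance is not available in standard Euclidean-only
  implementations; on Euclidean instances it is cross-checked against
  scikit-learn and against exhaustive partition enumeration on tiny
  instances. Defaults: n_init = 100 restarts, max_iter = 500, one master
  seed.
* **Frame selection**: the selected count is
  `round_half_away_from_zero(fraction · T)` — the only rounding rule
  consistent with both printed counts (0.20 × 155 = 31;
  0.30 × 155 = 46.5 → 47). "Activation strength" is read as the largest
  signed seed values; ties break toward the earlier frame.
* **Elbow**: the validity curve is normalized to the unit square and the
  elbow is the k farthest below the chord joining the endpoints
  (`method="chord"`); the alternative (`"line"`) takes the most negative
  residual under a single least-squares line. A curve with no downward
  curvature triggers a warning and falls back to the smallest k. The k
  scan uses 20 restarts per k (19 k-values per scan makes the full 100
  restarts disproportionate; 20 is already conservative for these
  problem sizes), while the final solution at the chosen k uses the full
  default.
* **Centroid matching** (for separate-group clustering) maximizes summed
  |r| under a one-to-one assignment — centroid sign is arbitrary in CAP
  decompositions — and reports signed correlations.

## Statistics decisions

* Frequencies are compositional (rows sum to 1); they are analyzed per
  state, as in the motivating design.
* t test: Welch by default (robust to unequal group sizes/variances),
  pooled selectable. Zero-variance-in-both-groups inputs are flagged
  `degenerate` rather than passed to the t distribution.
* Regression: OLS of frequency on intercept, group indicator, site
  dummies (reference = first site alphabetically), mean FD, age, and
  handedness dummies (reference = right). A second preset adds sex. The
  design matrix is rank-checked and collinear columns are named in the
  error. p values are unadjusted by default; Benjamini–Hochberg q values
  across states are opt-in.
* The benchmark suites verify: mean recovered group coefficient within
  0.02 of the planted Δ = 0.1 over 50 replicates with ≥ 95 % sign
  agreement, and per-state type-I error within 5 % ± 2 % over 500 null
  replicates. These run on the generator's latent-label layer (the
  planted state sequences themselves), since they test the statistics,
  not the clustering.

## Surrogate decisions

Phases are randomized independently per component — cross-component
covariance, which is what CAPs measure, is destroyed while each
component's amplitude spectrum (hence mean, variance, autocovariance) is
preserved exactly (DC and Nyquist bins untouched). A multivariate
variant sharing one phase draw across components (preserving
cross-spectra) is available as a contrast condition. Surrogates are
generated from the analysis-ready (post-filter) series. "No noticeable
CAP structure" is operationalized by this package as the mean RMS
centroid value across states, compared against the surrogate score
distribution at the original k; the score definition is ours and is
labeled as such in reports.

## Problem sizes and determinism

The test and acceptance suites use the 40-subject benchmark: a full
elbow scan over k = 2…20 on ~1,240 pooled frames takes a few seconds;
20-replicate recovery suites run in ~2 minutes and the 500-replicate
null calibration under 30 seconds. Recovery-oriented suites run frame
selection and clustering on trimmed, z-scored series (without the
temporal filters) to isolate the clustering machinery; the full
filter path is exercised end-to-end separately. All randomness flows
from explicit integer seeds through `numpy.random.Generator` spawning;
identical seeds reproduce cohorts and pipeline outputs byte-for-byte.

## Known limitations

* The despike baseline is a running median, not a harmonic fit; for
  series with strong slow oscillations the two differ at the margins of
  the clip region.
* The elbow of a nearly flat validity curve is intrinsically unstable;
  on benchmark cohorts the planted k = 5 is recovered in ~85 % of
  replicates, with failures selecting k = 2 when the curve's dip is
  shallow. The full curve is always persisted for audit.
* Frequencies are analyzed per state by OLS; no compositional transform
  or mixed-effects site modeling is attempted.
* The generator's FD traces are i.i.d. gamma draws per frame; real
  motion is temporally clustered.
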