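# capdyn — seed-based dynamic coactivation-pattern (CAP) analysis

`capdyn` implements a component-space pipeline for studying time-varying
brain-network coactivation in resting-state fMRI. It targets the setting
where group ICA has already reduced each subject's scan to a frames ×
components matrix of component time courses, and the question is how often
different whole-brain coactivation states recur — and whether their
frequency of occurrence differs between groups (e.g., autistic vs.
typically developing children scanned at several sites).

It is a library first: the importable API plus the short scripts in
`examples/` are the intended interface, with a thin `capdyn` CLI
(`simulate`, `run`) for end-to-end runs on a cohort directory.

## Method

1. **Post-ICA processing** — each scan is standardized to 155 frames
   (drop 5 leading volumes, cut the tail; 5 min 10 s at TR = 2 s), then
   per component: linear detrend, despike (tanh soft clip of residuals
   beyond 2.5 robust SDs around a running median, saturating at 4),
   zero-phase Butterworth bandpass 0.01–0.1 Hz, z-score.
2. **Motion QC** — Power framewise displacement
   FD_t = Σ|Δd_i| + 50·Σ|Δθ_j| from realignment parameters; subjects with
   mean FD > 0.5 mm and/or more than 35 frames with FD > 0.5 mm are
   excluded before analysis.
3. **CAP discovery** — for each subject the top 20 % (and 30 %) of frames
   by seed-component activation are selected (31 and 47 of 155 frames),
   pooled across subjects over non-noise components, and clustered with
   k-means under Pearson correlation distance (1 − r). k is chosen by
   scanning k = 2…20 and locating the elbow of the cluster validity
   index, CVI(k) = mean within-cluster distance / mean between-centroid
   distance.
4. **Group statistics** — per subject and state, the frequency of
   occurrence (proportion of that subject's selected frames assigned to
   the state); groups compared per state by Welch t test and by OLS
   controlling for site, mean FD, age and handedness.
5. **Surrogate validation** — phase-randomized surrogates (amplitude
   spectra, hence mean/variance/autocorrelation, preserved per component;
   phases independent across components) are re-clustered at the chosen
   k; an RMS-centroid structure score shows coherent CAP structure in the
   data but not in the null.

A synthetic-cohort generator (`capdyn.synthetic`) plants recurring states
via a first-order Markov chain with group-specific stationary occupancy,
so every stage can be validated against known truth.

## Worked example

`python examples/04_cap_discovery.py` simulates the benchmark cohort
(40 subjects in 2 groups across 3 sites, 5 planted states, 69 components,
planted TD−ASD occupancy difference +0.10 in one state), selects each
subject's top-20 % seed frames, scans k, and compares group frequencies:

```
selected 31 of 155 frames per subject (top 20%)
elbow-selected k = 5 (planted: 5)

per-state group comparison (TD relative to ASD):
         mean_ASD  mean_TD       t     t_p  group_coef  group_se  group_p
state_1    0.1661   0.1887 -0.6012  0.5513      0.0295    0.0406   0.4731
state_2    0.2161   0.2903 -1.8943  0.0664      0.0790    0.0377   0.0441
...
```

The elbow recovers the planted k = 5; `group_coef` is the
covariate-adjusted TD−ASD difference in state occupancy, and the planted
+0.10 effect shows up in state 2 (0.079 estimated, p = 0.044 in this
realization). `examples/05_surrogate_null.py` then shows the original
structure score exceeding every one of 20 phase-randomized surrogate
scores (score ratio ≈ 1.4).

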