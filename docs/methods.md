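# Methods

This note documents the models, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not establish.

## Generative model

Each subject's data is `X = S M + E` on a regular voxel grid (default
24 × 24 × 12 at 3 mm; tests and examples often use smaller grids).

* **Network time courses** `S_net` follow a first-order vector
  autoregression `x_t = A_eff x_{t−1} + ε_t` with i.i.d. Gaussian noise
  (`noise_sd = 1`).  `A_eff[i, j]` is the lag-1 influence of network `j` on
  network `i`.  Defaults: diagonal 0.3; static edges AfN→VAN and DAN→VN at
  0.35; modulated edges AfN→VN and DAN→VAN at 0.7 at the reference score
  (20) with slope −0.013 per loneliness point, so the coupling falls to
  ≈ 0.12 at the maximum score of 65 and never changes sign.  The coupling
  matrix is triangular under the ordering (DAN, AfN, VAN, VN), so its
  spectral radius is 0.3 for every score and stationarity never binds.
  The baseline/slope pair was calibrated, before being frozen, so that at
  the study conditions (15 subjects per group, 250 retained volumes) the
  modulated edges stay significant in group tests *and* their negative
  correlation with the loneliness score survives FDR in ≳ 85 % of cohorts;
  a much shallower slope leaves the correlation undetectable at n = 15,
  a much steeper one drives the high-score couplings toward zero and
  destroys the group-level edge significance.
* **Spatial loadings** are uniform(0.5, 1) inside each network's template
  mask and zero outside.  Templates are unions of spherical blobs
  (default 2 blobs of radius 2 voxels per network), rejection-sampled to be
  disjoint across networks — stand-ins for published functional network
  templates, adequate because the pipeline only uses mask membership.
* **Nuisance sources** (default 2) have AR(1) time courses (ρ = 0.3) and
  dense Gaussian loadings — spatially unstructured background processes.
* **Noise** is i.i.d. Gaussian per voxel, scaled so that in-mask signal
  variance over noise variance equals `snr` (default 2; no empirical SNR
  is available for the motivating data, so this is a conventional
  moderate-quality choice).
* **Behavioral scores** are uniform integers per group (loneliness 46–65
  high, 20–27 low; the five other scales share plausible published ranges
  across groups and are sampled independently of loneliness, consistent
  with the reported absence of cross-scale correlation).

Deliberately not modeled: hemodynamic convolution, head motion,
physiological noise, slice timing, anatomical images.  Consequently a
passing benchmark shows the *estimators* are correct under their stated
assumptions, not that real fMRI preprocessing artifacts are handled.

## Dimensionality estimation

`estimate_ndim_mdl` implements the Wax–Kailath criterion

`MDL(k) = −N (p−k) ln(gm_k / am_k) + k (2p−k) ln(N) / 2`

over the sorted covariance eigenvalues, treating the smaller matrix
dimension as the p variables and the larger as the N samples; candidates
are restricted to the numerical rank.  Two practical points:

* The criterion assumes spatially white noise.  Gaussian smoothing
  correlates voxel samples and inflates the estimate badly (6 → ~190 on a
  default-scale subject), so the pipeline runs MDL per subject on
  *pre-smoothing* data and takes the median across subjects.
* On temporally concatenated group data the samples-per-variable ratio
  collapses and the noise eigenvalue spread dominates; per-subject
  estimation avoids this regime.

## Group ICA

Single-stage spatial PCA after temporal concatenation (voxel columns
centered; variance normalization available but off by default), then
symmetric fixed-point FastICA with the tanh contrast on the whitened
spatial basis: `W ← E[g(WZ)Zᵀ] − diag(E[g′(WZ)]) W` followed by symmetric
decorrelation, converged when every component's successive directions
agree to `tol = 1e-6` (max 500 iterations; non-convergence is flagged, not
raised).  The initial unmixing matrix is a seeded random orthogonal matrix.
Each estimated map is oriented so its spatial skewness is positive —
network maps are sparse with heavy positive tails, and the template match
score is sign-sensitive, so the arbitrary ICA sign must be fixed before
matching.  Maps are z-scored across voxels (the conventional reading of
"Fisher-Z" intensity maps in group-ICA toolboxes; atanh is undefined for
|intensity| ≥ 1).

Back-reconstruction is dual regression: subject time courses are the
subject's block of the reduced data through the group unmixing; subject
maps are OLS regressions of the subject's centered data on those time
courses, then z-scored.

The pipeline decomposes the high, low, and pooled cohorts separately.
Per-group decompositions provide the one-sample spatial maps; the
*two-sample* group comparison uses the pooled decomposition's subject maps
(split by group, inside the combined mask) because per-group decompositions
live in different component spaces and cannot be compared voxelwise.

## Conditional Granger causality

For source X, target Y, conditioning set Z (the two remaining networks),
`F_{X→Y|Z} = ln(σ²_restricted / σ²_full)`, the target-equation residual
variances of VARs over {Y} ∪ Z and {Y} ∪ Z ∪ X.  Both models are fit by
OLS of the same order on the identical effective sample (the first `order`
points are reserved as presample), which makes the models nested and
guarantees F ≥ 0 up to round-off (clamped at −1e−12).  Model order is the
Schwarz-criterion argmin over 1..5 with a shared presample so the criterion
values are comparable; ties break to the smaller order.  On the default
generator the selected order is 1, matching the generative lag.

F has no natural scale, so each edge is standardized against a surrogate
null: the source series is circularly shifted by ≥ order+1 samples
(99 surrogates by default, seeded), preserving its autocorrelation while
destroying cross-coupling; `z = (F − mean F_null)/sd F_null`.  Group-level
inference runs one-sample t-tests on z across subjects with BH-FDR over
the 12 directed edges — testing raw F against zero would be ill-posed
since F ≥ 0 by construction.  The t-test is two-sided; an edge can
therefore survive with a significantly *negative* mean z (observed F
systematically below its surrogate null), and the report prints signed
mean z so such edges are visible.

Numerical guards: lag designs with condition number above 1e10 are
rejected with advice to shorten the order; degenerate surrogate nulls
(zero variance) raise.

## Behavioral screen and prediction

Pearson correlations (two-sided t transform, n−2 df) relate each tested
edge's z to the six scales, per group.  FDR is controlled within each
(group, scale) family across the tested edges: the loneliness screen and
each specificity scale are separate hypothesis families, mirroring a
primary analysis followed by per-scale specificity checks.

Prediction is a linear-kernel epsilon-SVR (C = 1, ε = 0.1 — unreported in
the motivating study, so sklearn-conventional defaults, configurable) with
leave-one-out cross validation; features are standardized with
training-fold statistics only, so the held-out subject cannot leak into
the scaler or the model.  Reported: per-fold held-out predictions, RMSEP,
and the predicted-vs-actual Pearson correlation.  At n = 15 a single
LOOCV correlation is itself noisy; across default cohorts roughly half of
edge models that pass the correlation screen reach individual
significance, while pooled held-out predictions are decisively positive.

## Pipeline and reproducibility

Stages (simulate → ica → identify → cgca → stats → predict → report) read
and write on-disk artifacts (NIfTI volumes, TSV tables, JSON sidecars) and
append to a manifest recording config hash, output checksums, wall time,
and every consumed seed.  Sub-seeds are SHA-256 hashes of
(master_seed, stage, item), so they do not depend on execution order; all
stages are bit-reproducible for a fixed master seed, and a stage whose
config hash and outputs are current is skipped unless forced.

## Benchmark problem sizes

Chosen so the full suite runs on a single CPU in well under the time a
coffee takes: unit fixtures use 12 × 12 × 8 grids and 60–80 volumes; the
end-to-end benchmark runs one full voxel-level cohort at 16 × 16 × 10
(2,560 voxels) with 15 subjects per group; the 20-cohort correlation-
recovery and prediction benchmarks run at the network-timecourse level,
where the voxel stages contribute nothing but runtime; the dimensionality
benchmark mixes 40 sources into the default 6,912-voxel grid across two
concatenated subjects.

## Known limitations

* The surrogate normalization destroys source-to-conditioning correlation
  as well as source-to-target coupling; for strongly interdependent
  networks the null can be slightly off-center (visible as small negative
  mean z on null edges).
* MDL requires spatially white noise; it is not robust to smoothed data,
  and the pipeline's pre-smoothing convention must be kept in mind when
  substituting real data.
* Greedy component assignment is not globally optimal when many components
  tie; with four well-separated networks this has not been observed to
  matter.
* The generator's linear score-coupling link and uniform score
  distributions are conveniences; effect sizes in real cohorts are
  unknown, and the calibrated slope should be read as "detectable at this
  design", not as an empirical claim.
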