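# Methods

This note documents the models, conventions and design decisions behind
`spaclust`, in the order the pipeline applies them.

## Synthetic cohort model

**What it emulates.** A two-condition within-subject study: 30 subjects,
blue and red colored-light exposure, 14 physiological channels sampled
at 1 Hz through 8 min baseline / 9 min task / 15 min recovery, plus a
task-performance word count drawn as a rounded Gaussian (58 ± 12,
clipped at 0). Subjects belong to latent reactivity groups — 3 under
blue light, 5 under red — assigned per condition by a seeded
categorical draw with configurable proportions (uniform by default).

**Signal model.** Each channel is

    x(t) = baseline + a · r(t) + m·t + ε(t),

where `a` is the subject's response amplitude, `r(t)` a saturating
exponential onset (1 − e^(−t/τ), τ = 30 s) held through the task phase
and decaying back in recovery, `m` a random linear drift (SD given per
channel in unit/min) and `ε` i.i.d. Gaussian sample noise. A canonical
hemodynamic response shape is deliberately not used: the analysis
consumes only the task-phase integral, so the generator needs a
controllable task-phase area, not a realistic impulse response. The
amplitude is drawn per subject around the group mean
(`a ~ N(A_g, σ_amp)`), which is what gives groups a finite, tunable
overlap; sample noise alone would be averaged down ~23× by the 540-s
integration and would make groups trivially separable.

**Group templates.** Group-mean amplitudes `A_g` are stated in native
units per channel. The extreme groups are anchored to the magnitudes
reported for the observed cohort (skin-conductance responses of ~1 µS
in the least-reactive group versus > 11 µS in the most reactive;
visual-cortex [O₂Hb] changing sign between those groups). The five
red-light groups are parameterized by two latent axes — a
sympathetic-arousal axis `u` (driving SC, HR, MAP and the
hypocapnia-linked channels) and a cerebral-hemodynamic axis `v` — with
the groups placed at pentagon-like vertices in (u, v). This encodes a
structural assumption: the phenotypes differ along a low-dimensional
reactivity plane, so they remain mutually separated in the leading two
principal components of any informative feature subset, which is the
regime the original analysis reports (two components ≈ 80 % variance,
five separable groups).

**Within-group spread.** `σ_amp` defaults are set to roughly a quarter
of the per-channel within-group ranges quoted for the observed cohort.
The reason is a modelling artifact: the generator draws the jitter
independently per channel, whereas real within-group variation is
strongly correlated across channels, so matching per-channel ranges
verbatim would overstate the *joint* 5-feature overlap and produce a
much worse-clustered cohort (mean silhouette ≈ 0.5) than the one the
method was demonstrated on (≈ 0.8–0.9). The defaults land the default
cohort in that reported regime; all SDs are configurable per template.

**Effect size.** `separation` rescales every group's amplitude around
the across-group mean (0 = no structure, 1 = defaults).
`component_separation_sd` reports the realized effect size — the
minimum pairwise distance between component mean vectors after dividing
each feature axis by its within-group SD. At the defaults this is ≈ 23
SD (blue) / 22 SD (red) on the best 5-feature subset; note that min–max
scaling and PCA re-weight axes, so the operative separation during
clustering is substantially smaller than this standardized figure.

**Fast mode.** `generate_feature_table` skips the time series and draws
AUC features directly from the implied Gaussian mixture (component
means = amplitude × task duration; SDs fold the amplitude jitter with
the residual integration noise). Noise-free time-series generation and
fast mode agree up to the onset-transient correction τ·a.

**Determinism.** Every subject/condition has its own keyed substream
(`default_rng([seed, condition, subject, stream])`), so enlarging the
cohort or reordering conditions never reshuffles earlier subjects.

**What passing tests do not show.** The generator contains no
autocorrelated (1/f) physiological noise (an AR(1) switch would be the
natural extension), no motion artifacts, no extracerebral
contamination, no correlated within-group variation, and no
circadian/melanopsin mechanism of colored light. Recovery results on
synthetic cohorts certify the pipeline's correctness, not field
performance on real recordings.

## Feature extraction

The baseline reference is the mean of the final 120 s of the baseline
phase (steady state; window configurable). The task-phase AUC is the
trapezoidal integral of the baseline-subtracted signal over the closed
interval [task start, task end] — sign-preserving, exact for
piecewise-linear signals, and invariant to sampling-rate refinement on
them. Baseline subtraction itself is configurable
(`subtract_baseline=False` yields absolute areas). Missing or
non-finite samples in the task phase are hard errors naming the subject
and channel; no imputation is attempted. Task performance enters the
table unscaled and is normalized like every other feature; it is
excluded from the default search pools (see below).

## Normalization and PCA

Min–max normalization maps each feature onto [0, 1]; a constant column
is mapped to zeros with a logged warning rather than an error so that
exhaustive subset sweeps stay total. PCA mean-centers but does not
re-standardize (min–max is the designated scaling step) and retains the
smallest number of components whose cumulative explained-variance ratio
reaches the threshold (default 0.8, i.e. "≥ 80 %"). Loading signs are
fixed so each component's largest-magnitude loading is positive, making
score plots reproducible across linear-algebra backends. With all
components retained the projection is exactly invertible (tested to
1e−9).

## Validity criteria and consensus

All three indices use the Euclidean metric in PCA score space:

- **Silhouette** s(i) = (b−a)/max(a,b), with a(i) the mean distance to
  the rest of i's cluster and b(i) the smallest mean distance to
  another cluster. Members of singleton clusters score 0 (Rousseeuw's
  convention). Both conventions are recorded in every report.
- **Calinski–Harabasz** (B/(k−1))/(W/(n−k)); W = 0 returns +inf
  ("perfect separation") instead of erroring so sweeps survive
  degenerate fixtures.
- **Davies–Bouldin** (1/k) Σ max_{j≠i} (S_i+S_j)/M_ij; coincident
  centroids are an error.

Optimal k per criterion is the argmax (silhouette, CH) or argmin (DB)
over k = 2…9, ties broken toward smaller k (parsimony). The consensus
is the 2-of-3 majority; without a majority the silhouette vote wins,
because the upstream feature search is itself silhouette-driven. For
DBSCAN, which has no k, the epsilon grid is swept instead and each run
enters the table under the cluster count it found; noise points are
excluded from all index computations and cluster counts.

## Clustering methods

- **k-means**: k-means++ seeding, 50 seeded restarts (10 inside the
  combination search, where the 320-subset × 2-condition × 8-k sweep
  makes the cheaper schedule worthwhile), batched Lloyd iterations; the
  within-cluster sum of squares is non-increasing across iterations and
  is asserted on traces in the tests.
- **k-medoids**: PAM (greedy BUILD + full SWAP) on Euclidean distances;
  the most centrally located data point is the cluster reference.
- **Hierarchical**: Ward linkage (complete/average configurable), cut
  at k.
- **GMM**: full covariances, ridge 1e−6, 10 seeded restarts; hard
  labels by maximum responsibility — a soft method hardened so the
  validity indices apply.
- **SOM**: 1×k output grid with Gaussian neighborhood and
  exponentially decaying learning rate/width; each unit is one cluster
  and points are assigned to their best-matching unit, which makes the
  map a clustering rather than an embedding.
- **DBSCAN**: min_pts = 3 (appropriate for a 30-subject cohort); the
  epsilon grid defaults to 20 quantiles of the pairwise-distance
  distribution; the sweep keeps the run with the best non-noise
  silhouette among runs with ≥ 2 clusters.

The original analysis reports no hyperparameters for any method; all of
the above are this package's own defaults, surfaced in configuration.

## Combination search

Subsets are constrained to 1 PFC + 1 VC + 3 systemic features (320 with
the default pools). Each subset is scored per condition by the best
k-means mean silhouette over k = 2…9 on its PCA scores — max-over-k, so
each subset also reports its optimal k. The filter keeps subsets with
silhouette strictly > 0.6 in every condition; survivors are ranked by
the mean of per-condition best silhouettes (a min-across-conditions
rule is available). Task performance is excluded from the default pools
— in a cohort of students with near-equal verbal fluency it carries
little clustering signal, and it is not a systemic-physiology channel —
but can be added via configuration. Degenerate subsets (constant after
normalization) are marked failed and drop out of the ranking instead of
aborting the sweep.

## Pipeline and reproducibility

One top-level seed fans out to named per-stage substreams (simulate,
search, clustering) via a fixed hash, so stages are independently
reproducible. All report artifacts are delimited text or JSON with
fixed float formatting; two runs with the same configuration are
byte-identical, and each table cross-references a hash of the full
configuration. Figures (PCA score scatter and per-subject silhouette
bars) are emitted together with the tables that underlie them; tests
assert only on tables. An optional exclusion list drops named subjects
before analysis (mirroring cohort exclusions done upstream of this
pipeline); no age or demographic logic is implied.

## Problem sizes

Default problem sizes used throughout the tests and the acceptance
script: 30-subject cohorts at 1 Hz (1 921 samples × 14 channels × 2
conditions), the full 320-subset search, and 20 replicate cohorts for
recovery rates. Recovery criteria are evaluated at `separation = 2`
(twice the default between-group contrast), a regime whose realized
standardized component separation (≈ 44 SD) is comfortably above the
6-SD construction the recovery benchmarks specify.

## Known limitations

- The AUC is the only feature family; slope, latency or recovery-phase
  descriptors are out of scope.
- PCA is computed per evaluated feature subset (a global-PCA variant is
  a config switch); nonlinear embeddings and factor rotation are
  non-goals.
- The consensus rule needs exactly the three shipped criteria; adding a
  fourth would require a different tie policy.
- DBSCAN results depend on the epsilon grid resolution; on 30 points
  the quantile grid is adequate but not adaptive.
- Synthetic-data caveats listed above: independent within-group
  jitter, white noise only, no artifacts.
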