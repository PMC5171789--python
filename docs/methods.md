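# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pbm`, and what the synthetic-data tests do and do not establish
about real recordings.

## The point-based model

The data are per-subject ROI signal matrices `X_s ∈ R^{T×N}` sampled at
interval TR (default 0.72 s).  The pipeline is, in order:

1. **Scrubbing.**  Volumes with framewise displacement FD > 0.5 mm are
   replaced by cubic-spline estimates fitted per ROI on the retained
   volumes.  Series length never changes; the fraction replaced is
   reported.  Flagged volumes at the series boundary hold the nearest
   retained value instead — cubic extrapolation outside the support is
   numerically unstable and can produce excursions far outside the signal
   range.  FD itself is consumed as a precomputed vector; computing it from
   realignment parameters is out of scope.
2. **Band-pass.**  A zero-phase (forward–backward) Butterworth band-pass,
   order 2 per pass, at 0.01–0.1 Hz.  Zero-phase filtering is the standard
   resting-state choice; any phase distortion would systematically shift
   state boundaries in time, which is exactly what this method is built to
   resolve.  Filtering is optional (`band=None`): synthetic data from the
   generator contain neither scanner drift nor physiological noise, and a
   planted state process with mean dwell 6.3 scans (≈4.5 s) concentrates
   much of its power above 0.1 Hz, so filtering such data removes structure
   rather than noise.  Recovery tests therefore cluster unfiltered
   (scrubbed, z-scored) synthetic data; the filter is validated separately
   with DFT amplitude oracles on in-band and out-of-band tones.
3. **Z-scoring** per ROI column (population SD), then **concatenation** of
   subjects along time.  Subject boundaries are carried everywhere
   downstream: dwell runs and inter-contact times never bridge subjects.
   The processing order (scrub → filter → z-score → concatenate) is fixed.
4. **Dimension reduction.**  PCA keeps the smallest `d` whose cumulative
   explained variance reaches `retain_fraction` (default 0.85).  The
   choice of 0.85 trades retained structure against k-means cost; nothing
   downstream is sensitive to a few components either way.
5. **State clustering.**  Euclidean k-means on the reduced time points,
   k-means++ initialisation, best inertia of 20 restarts, up to 1000
   iterations, fixed seed for bit-reproducibility.  Default `k = 8`, with
   the usual sensitivity checks at `k = 5` and `12` available by
   refitting; the clustering family is k-means only, but the function
   surface is small enough to swap another clusterer in front of the
   graphlet stage.  States are relabelled by descending occupancy — the
   clustering itself carries no meaningful state order, and a fixed
   convention keeps cross-run and cross-seed comparisons stable.  When two
   centroids are equidistant the lower state index wins (scikit-learn's
   argmin convention), again for determinism.

## Graphlets

An **s-graphlet** is the Pearson correlation matrix over one state's time
points, computed in the original ROI space (never the PCA space), diagonal
zeroed.  Pearson correlation, not covariance, is used throughout: the data
are z-scored per subject but a cluster's within-state variances still
differ, and correlation makes graphlets comparable across states.  With an
atlas, ROI pairs with centres closer than 15 mm are set to exactly 0 — a
conventional step with spherical ROI templates that suppresses trivially
local connectivity.  A state needs at least 3 time points; fewer is an
error naming the state.

A **t-graphlet** is a pure lookup: time point `t` carries the s-graphlet
of its state.  No per-time-point matrices are materialised; an edge's
trajectory takes at most `k` distinct values and is fully described by the
label sequence.

**Proportional binarization** keeps the top fraction (5% and 10% by
default) of eligible upper-triangle edges of each graphlet by *signed*
weight — the threshold selects the strongest positive connectivity, and
negative edges never outrank positive ones.  Distance-masked pairs are
excluded from both the eligible count and the ranking, so the mask can
neither inflate the denominator nor leak into the top set.  Exactly
`round(fraction × E_eligible)` edges are kept per state; ties break on the
fixed row-major edge order.  Because every t-graphlet is a copy of its
s-graphlet, thresholding happens once per state and is broadcast over
time — identical result, `T`-fold cheaper.

## Statistical tests

**Edge differences between states.**  For a state pair, the two clusters'
time points are pooled and re-split at the original sizes; each of the
(default) 10,000 permutations yields an edge-wise difference of re-derived
correlation matrices.  Two-tailed p-values use the add-one rule
`(1 + #{|null| ≥ |obs|}) / (1 + n_perm)`, so p is never exactly 0.
Benjamini–Hochberg FDR is applied over the pooled family of all edges ×
all tested state pairs (one joint family, not per pair).  Network-level
summaries report, per RSN-pair block, the percentage of edges
significantly larger in one state; blocks without edges are undefined
(NaN), never 0.

**Transitions and dwell.**  Transition probabilities count only change
points (self-transitions are dwell, not transitions); each defined row of
the matrix sums to 100%, rows without outgoing transitions are undefined.
Dwell times are run lengths of the label sequence, truncated at subject
boundaries and counted as complete runs — a simple average that ignores
censoring at the series edges, which shortens the mean slightly for dwell
times comparable to the session length (a documented limitation, irrelevant
at dwell ≈ 6 scans over 1200-scan sessions).

**Graphlet distance and its correlation with transitions.**  The
normalized taxicab distance is the mean absolute upper-triangle weight
difference.  Its association with transition probability uses Spearman's
rank correlation over ordered state pairs (probabilities and distances are
bounded, tied, and far from bivariate normal), with a permutation p-value
on the pairing.

**Transition-boundary profile.**  The mean Euclidean distance between
consecutive time points, aligned to transitions at offsets
`−w … +w`, distinguishes abrupt from gradual state changes: on gradually
drifting data the profile rises toward the transition and peaks at the
crossing step.

## Burstiness

ICTs are gaps between consecutive presences of a binarized edge, pooled
over subjects; gaps spanning a subject boundary are discarded because the
concatenation order is arbitrary.  The coefficient
`B = (σ_τ − μ_τ)/(σ_τ + μ_τ)` uses the **population** standard deviation
(divisor `n`): the coefficient is defined on the gap distribution's σ/μ,
and the sample estimator is simply plugged in; this is configurable in the
sense that `burstiness_coefficient` accepts any ICT vector.  Edges with
fewer than two ICTs are `undefined`, never assigned a value — an edge that
never re-occurs has no gap distribution.  Edges that are always present
have constant ICTs and get exactly −1.

**Classification** uses a max/min-statistic permutation null: each of the
(default) 200 permutations applies one random reordering of the time axis
per subject, simultaneously to all edges — preserving each edge's contact
count and the cross-edge dependence of the null — and records the maximum
and minimum `B` over edges.  An edge is *bursty* iff `B > 0` and `B` is at
or above the `ceil((1 − α/2)·n_perm)`-th ascending order statistic of the
max distribution (the 195th of 200 at α = 0.05), *tonic/periodic* iff
`B < 0` and at or below the `floor(α/2·n_perm)`-th of the min distribution
(the 5th of 200); otherwise *random*.  Non-integral cutoff products round
toward the conservative side.  The comparisons are inclusive: for an
always-present edge every permuted value is also −1, and only the ≤-rule
can classify it tonic.

Implementation shortcut: a pipeline-derived edge's presence series is a
function of its *state signature* — the subset of states in which it
survives the threshold.  Edges sharing a signature have identical presence
series, so `B` and its null are computed once per unique signature
(≤ 2^k) and broadcast; a test verifies exact agreement with the direct
per-edge computation.

**Between- vs within-network contrast.**  Over edges present in at least
one state and with defined `B`, the observed `mean(B_between) −
mean(B_within)` is compared to 1,000 shuffles of the within/between
designation (group sizes preserved), two-tailed via the 975th-order-
statistic rule at α = 0.05.

## The sliding-window baseline

The comparison baseline computes per-window Pearson connectivity (window
120 time points = 86.4 s at TR 0.72 s, stride 1), vectorizes the upper
triangle, reduces to 30 principal components, and k-means clusters the
windows per subject.  Correlation rather than covariance is used per
window for comparability with the s-graphlets (covariance is a one-line
change).  The baseline exists for the temporal-sensitivity contrast only:
on a two-regime fixture the window states blur the change point over a
window length while the point-based labels switch within a couple of
samples.  No quantitative state matching between the two methods is
attempted.

## The synthetic-data generator

`simulate` draws, per subject, a latent Markov state path (self-transition
mass `1 − 1/mean_dwell`, default dwell 6.3 scans; off-diagonal mass
uniform, so the stationary law is uniform) and observations
`x_t ~ N(μ_{s_t}, Σ_{s_t})`, with:

* **Per-state mean offsets** (`mean_scale`, default 1.0 z-units, drawn
  i.i.d. per ROI).  The time-point clustering keys on the global spatial
  configuration, and states in real recordings differ in their per-ROI
  amplitude patterns; zero-mean states distinguishable only by covariance
  are not separable by Euclidean k-means on single time points.  Offsets
  of 1 z-unit give clearly identifiable states against unit-variance
  state noise at realistic ROI counts.  `mean_scale=0` switches the
  offsets off.
* **Per-state covariances** — random low-rank correlation structure mixed
  with the identity (`cov_mix`, default 0.5), guaranteeing PSD and
  near-unit variances.
* **Gradual transitions** (optional): the mean path blends across each
  boundary with a smoothstep whose inflection sits exactly on the step
  crossing the boundary, so the successive-point distance profile peaks at
  the transition; ramp windows are clipped at neighbouring transitions so
  short dwells never overwrite each other.
* **Motion**: FD baseline uniform on [0, 0.3] mm with spikes above the
  0.5 mm threshold at rate 0.012 (the ~1.2% rejection regime of typical
  low-TR sessions); flagged volumes optionally receive a large additive
  signal artifact so scrubbing has something to repair.
* **Atlas**: ROI centres on a 3-D lattice with 12 mm spacing — below the
  15 mm cutoff, so the distance mask is always exercised — and contiguous
  network blocks named after conventional RSN abbreviations.

`simulate_edge_schedule` generates binary presence series directly:
`tonic` (always present), `periodic` (fixed period), `random`
(Bernoulli), and `bursty` with gaps from the discrete power law
`P(G ≥ g) = g^{1−α}` (density exponent α, default 1.8) — the heavy-tail
regime in which `B` is strongly positive.

**What passing tests show, and what they do not.**  The generator
reproduces the *structure* the method assumes — recurring global spatial
states, geometric dwell, gradual or abrupt boundaries, motion spikes,
heavy-tailed edge schedules — under Gaussian noise with known ground
truth.  It does not model hemodynamics, spatially correlated scanner
noise, physiological confounds, or realistic fMRI spectra; recovery
results (ARI, dwell, burstiness classes) certify the estimators, not the
neuroscience.  Conclusions about real data still require real data.

## Numerical conventions

* State labels are 1-based everywhere; state 1 is the most occupied.
* Permutation p-values use the add-one rule and can never be 0.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  fitted or simulated object is bit-reproducible given its seed.
* Degenerate inputs fail loudly: all-flagged motion, zero-variance ROIs
  (named), states below 3 points (named), empty permutation groups, bands
  outside Nyquist.
* Test problem sizes: the reference recovery study uses 20 subjects ×
  1,200 time points × 60 ROIs with 8 planted states — large enough for
  state and dwell recovery to be sharp (ARI ≳ 0.99, dwell within ~2%),
  small enough to fit comfortably in an ordinary test run.  Calibration
  tests use 1,000 permutations × 50 replicates; burstiness classification
  tests use 200 permutations, mirroring the defaults.
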