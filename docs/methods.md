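# Methods

## Overview

`hubshift` implements a longitudinal resting-state functional-connectivity
analysis for small-animal cohorts, of the kind used to track how brain
network hubs reorganize after spinal cord injury. The chain is:

1. region-wise BOLD time series (one matrix per subject × timepoint),
2. temporal bandpass 0.009–0.1 Hz,
3. pairwise Pearson connectivity (raw r, in [−1, 1]),
4. whole-network strength and density,
5. binarization at a fixed threshold (default θ = 0.10),
6. degree centrality per node → node × subject × timepoint panel,
7. longitudinal statistics (change matrices, paired t-tests, mixed ANOVA),
8. hub identification (mean + k·SD rule) and the hub-shift report.

Because no raw animal data are distributed, a synthetic-cohort generator
with a planted, time-shifting hub structure is a first-class module: every
stage of the pipeline is exercised end-to-end on cohorts whose ground
truth is known exactly.

## Connectivity model

An edge weight between regions *i* and *j* is the Pearson correlation of
their filtered series. Correlations are **not** Fisher-z transformed, so
edge weights are bounded in [−1, 1] and the whole-network *strength* is
the sum over the n(n−1)/2 unique pairs (29,646 pairs at n = 244; the
diagonal is never counted). *Weighted density* is strength divided by the
pair count, i.e. the mean connectivity; *binary density* is the fraction
of pairs surviving the threshold.

The bandpass default is a zero-phase order-2 Butterworth (applied
forward–backward with `sosfiltfilt`), chosen because zero-phase filtering
introduces no lag-induced correlation bias; an ideal FFT brick-wall filter
is available as `design="fft_hard"` where an exact passband is preferable.
The filter family and order of the upstream toolboxes in this literature
are generally unreported, so both designs are documented interpretations;
their passband behaviour is pinned by tests against the analytic |H(f)|²
response. Filtering to a 0.091 Hz-wide band reduces the effective number
of independent samples to roughly N·2·BW/f_s (≈ 55 for 300 volumes at
TR = 1 s), which sets the sampling noise of every correlation estimate and
is the dominant noise scale of the downstream statistics.

Binarization keeps **signed** correlations with r ≥ θ (inclusive at
equality): negative correlations never become edges at θ = 0.10. Degree
centrality is undirected (correlation matrices are symmetric, so in- and
out-degree coincide); its ceiling is n − 1 (243 for the 244-area atlas).
The threshold sweep utility reports binary density across θ as a
diagnostic only — there is no reference curve to match.

## Longitudinal statistics

- **Change matrices** are entrywise differences of cross-subject *mean*
  connectivity matrices, either versus baseline or versus the previous
  timepoint. Aggregation by the mean is a documented choice; the
  alternative (a representative subject) is not supported.
- **Strength deltas** are computed per subject first, then summarized as
  cross-subject mean ± SEM (SEM is the error-bar convention throughout).
- **Node-wise tests** are two-sided paired t-tests across subjects on
  degree centrality, timepoint vs baseline, at α = 0.05 by default and
  *uncorrected* by default — hub screens in this literature report raw
  per-node significance counts. A Benjamini–Hochberg flag (`fdr=True`) is
  provided. Nodes whose paired differences have zero variance are flagged
  `none` with an undefined statistic rather than silently dropped.
- **Mean-centrality comparison** averages over nodes within subject first,
  then pairs subjects across time.
- **Between-cohort comparison** (e.g. incomplete contusion vs complete
  transection) is a two-way mixed ANOVA — between factor: group; within
  factor: time — on per-subject node-set mean centrality, without
  sphericity correction by default. It is computed by
  `pingouin.mixed_anova` and cross-checked in the test suite against a
  hand-written sums-of-squares decomposition on a balanced toy design.

## Hub analysis

Motor-related nodes are those whose pre-injury connectivity to *either*
M1 seed (max over the left/right seeds) withstands θ in a given subject;
the group set is the union over subjects, so a node is excluded only when
it is sub-threshold to both seeds in every subject. Per-subject centrality
uses that subject's own mask (subgraph degrees; masked-out nodes are
reported missing).

Hubs at a timepoint are nodes whose cross-subject mean degree exceeds the
cross-node mean by more than k·SD (SD over node means, ddof = 1). k
defaults to exactly 2 but is configurable, since the "approximately 2 SD"
convention is inherently approximate. Centrality ratios divide each
node × subject degree by its baseline value; zero-baseline cells are
flagged undefined and excluded from summaries (never imputed). Ratio
summaries are cross-subject means of per-subject ratios, not ratios of
means. The hub-shift report contrasts the baseline hub set (tested for a
significant decline of its set-mean centrality at the final timepoint)
with the final-timepoint hub set (tested for the absence of such a
decline) and records their overlap.

## Synthetic cohorts

Sessions are drawn from a stationary multivariate Gaussian process:
innovations shaped by the Cholesky factor of a per-timepoint target
correlation matrix pass through an AR(1) recursion (ar_coeff = 0.3,
a modest temporal autocorrelation), then white noise of sd 0.3 (relative
to the unit-variance signal) is added. Hemodynamic response, motion, and
physiological noise are deliberately out of scope, so passing tests show
the statistical machinery recovers planted covariance structure — not that
it is robust to acquisition artifacts.

The target matrix at each timepoint is assembled from interpretable
levels: entry (i, j) = max(background, level_i, level_j), with hub blocks
additionally coupled at `within_hub_corr`. Defaults (study scale: 244
nodes × 600 volumes at TR 1 s, 10 subjects, timepoints pre/1/3/7/14 wpi):

| parameter | default | meaning |
|---|---|---|
| background_schedule | 0.12, 0.12, 0.13, 0.11, 0.095 | bulk connectivity per timepoint |
| global_burst | +0.08 at 1wpi | transient post-injury hyperconnectivity |
| motor_hub_corr | 0.28 → 0.25 → 0.22 → 0.13 → 0.07 | motor hub-to-network coupling (declining) |
| subcortical_hub_corr | 0.14 → 0.16 → 0.19 → 0.22 → 0.25 | subcortical coupling (rising) |
| within_hub_corr | 0.6 | coupling inside each hub block |
| ar_coeff / noise_sd | 0.3 / 0.3 | temporal autocorrelation, measurement noise |

Two constraints shaped these numbers. First, PSD geometry: with bulk
equicorrelation b and m hub nodes mutually correlated at w among k bulk
nodes, the block-mean eigenmode caps the hub-to-network correlation near
√((1 + (m−1)w)(1 + (k−1)b)/(mk)) — about 0.30 at the scaled profile. A
hub-to-network level of 0.45 over a 0.12 background (an intuitively
appealing choice) is simply infeasible as a correlation matrix; the strong
within-block coupling (0.6, realistic for homotopic cortical pairs) is
what makes levels up to ≈ 0.3 attainable. Targets are still projected to
the nearest PSD correlation matrix (eigenvalue clipping + rescaling to
unit diagonal); with the defaults the projection moves no entry by more
than 4 × 10⁻⁴, and a projection exceeding `psd_tolerance` (0.05) raises
an error rather than silently distorting the design. Second, the planted
trajectories must actually emerge through the pipeline: the late
whole-brain strength decline is carried both by the motor rows and by the
modest background decline (0.12 → 0.095), mirroring the matrix-wide
late de-correlation seen in vivo; with hub rows alone the effect sits
near the cohort-level sampling noise (SD of a cohort-mean strength delta
is ≈ 28 strength units at the scaled profile) and the qualitative shape
would be unreliable.

Determinism: the scenario seed fixes every emitted value. Per-session
streams use `SeedSequence(seed, spawn_key=(subject_index,
timepoint_index))`, a stable, documented derivation. The AR recursion
discards a 100-sample burn-in, after which the process is stationary to
within φ¹⁰⁰ ≈ 10⁻⁵².

### Problem sizes

The full study scale (244 × 600, 10 subjects, 5 timepoints) runs in a few
seconds per cohort; the scaled profile used by the analysis drivers and
replicate studies is 60 nodes × 300 volumes (6 motor + 6 subcortical hub
nodes), which preserves every qualitative behaviour at a fraction of the
cost. Replicate studies use 20 cohorts for hub-shift recovery and 10 null
cohorts (600 node-tests) for type-I calibration.

## Numerical and degenerate-input choices

- Non-finite inputs are rejected at load time, never imputed — imputation
  would corrupt correlations invisibly.
- Connectivity CSVs are full square matrices with a NaN diagonal, so files
  are self-describing and symmetry is checked on load; floats are written
  as `%.17g`, making write→read round-trips bit-exact.
- A zero-variance region series raises an error naming the node.
- Equality at the binarization threshold counts as an edge (documented
  arbitrary choice, applied consistently in the seed-connectivity rule).
- NIfTI label images use label = node_id + 1, reserving 0 for background.
- The HSV node coloring runs hue 240° (blue) → 0° (red) linearly across
  the declared domain (absolute: 0..n−1; ratio: 0.6–1.5), clamping
  out-of-range values; every figure has a CSV/JSON twin that is the
  authoritative artifact.

## Known limitations

- The generator's Gaussian copula has frequency-flat cross-coherence;
  real BOLD coherence is band-limited and hemodynamically smoothed.
- Effect sizes are synthetic conventions chosen for feasibility and clear
  planted structure, not estimates from animal data.
- No nuisance regression (global signal, motion) is modeled or applied.
- The mixed ANOVA assumes balanced, complete panels and applies no
  sphericity correction by default.
- Upstream preprocessing (slice timing, motion correction, registration,
  smoothing) is out of scope; inputs are assumed to be registered region
  time series or labeled volumes.
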