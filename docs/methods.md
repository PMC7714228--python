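# Methods

This note documents the models, numerical choices and open design
decisions behind `emgsynergy`, and what the synthetic benchmarks do and
do not demonstrate.

## Signal model and preprocessing

Surface EMG is treated as broadband carrier activity amplitude-modulated
by a slowly varying envelope. The envelope is estimated per channel by
rectification followed by a zero-lag lowpass: a Butterworth filter of
nominal order 4 and 3 Hz cutoff applied forward and backward
(`filtfilt`), so the effective magnitude response has order 8 and no
phase lag. Forward-backward filtering can undershoot below zero near
sharp transients; those samples are clipped to 0 because the
factorization requires nonnegative input. The alternative (adding a
small epsilon) was rejected as it biases quiet channels.

Downsampling to the 100 Hz envelope rate is plain decimation (keep every
20th sample at 2 kHz). No anti-alias stage is needed: the envelope is
band-limited to ~3 Hz, far below the 50 Hz target Nyquist frequency.

Rest-labelled samples are removed and movement samples concatenated
across trials *before* normalization. Each kept channel is divided by
its uncentered standard deviation (root mean square) over the pooled
samples. Normalizing without centering keeps the matrix nonnegative;
the per-channel scale is retained so envelopes can be mapped back to
recorded units. A channel that is constant over the pooled samples is an
error, not a silent pass: it carries no movement information and would
make the local-VAF criterion meaningless. Upper-arm channels (biceps,
triceps) are never pooled — they do not participate in hand/wrist
movements. Stage order is fixed: rectify+filter → decimate → pool →
normalize.

## Factorization

Multiplicative updates for the Frobenius objective ‖E − WH‖²: the VAF
criterion is built on squared error, which pins down the Euclidean
(not KL) update rule. Factors are initialized uniformly in (0, 1] —
avoiding exact zeros, which are absorbing under multiplicative
updates — from an explicit seed. Defaults: `max_iter = 500`,
`tol = 1e-6` on the relative per-iteration decrease of the squared
error, denominator guard `eps = 1e-12`. Doubling `max_iter` moves
recovered VAF by well under 0.1 point on the synthetic benchmarks, so
the cap is not binding in practice. The objective is evaluated every
iteration through the Gram expansion
`SST − 2⟨WᵀE, H⟩ + ⟨WᵀW, HHᵀ⟩`, which avoids forming the n×T
reconstruction; the trace is kept on the model for the monotonicity
contract. W columns are not normalized during iteration — the scale
ambiguity of the factorization is resolved only at the feature-vector
stage, by z-scoring.

VAF is `100·(1 − SSE/SST)` with SST the sum of squared *raw* data (no
mean removal); it equals 100 only for a perfect reconstruction, can be
negative, and the global value is the SST-weighted mean of the
per-channel (local) values.

## Rank selection

For each candidate rank k the pooled samples are split at random into
75% extraction / 25% validation; W is fitted on the extraction part and
frozen; H is refitted on the validation part (H-only multiplicative
updates, same stopping rule); global and local VAF of the validation
reconstruction are recorded. Of the repeated trials (default 50) the one
with maximal validation global VAF is kept, and both criteria — global
VAF strictly > 95 and *every* channel's local VAF strictly > 85 — are
evaluated on that same trial. The chosen rank is the smallest qualifying
k. Choices worth noting:

- Strict inequalities, per the criterion's definition.
- Fresh independent splits per rank (repeats are nested inside the rank
  loop), rather than one split shared across ranks.
- If no rank qualifies the largest scanned rank is returned with
  `saturated=True` rather than inventing a count.
- Seeding: every (rank, repeat) trial derives an independent child seed
  from the master seed (`SeedSequence` spawn keys), so results are
  independent of execution order and amenable to parallelism.
- `stop_when_met=True` stops scanning after the first qualifying rank.
  Because the chosen rank is the *minimum* qualifying one and each rank
  has independent trials, this cannot change the answer — it only
  truncates the reported per-rank curve. Benchmarks use it for runtime.

## Synergy typing

Each synergy's 17-element movement-activation profile (mean of its H row
over all samples of each movement, z-scored across movements with the
population 1/N standard deviation) is the clustering object; electrode
weight vectors are not compared across subjects because electrode
placement is not anatomically precise. K-means under correlation
distance uses: assignment to the nearest centroid by 1 − r; centroid =
arithmetic mean of member profiles re-z-scored. On z-scored vectors
1 − r is a monotone function of squared Euclidean distance, so this
Lloyd iteration converges. An emptied cluster is reseeded from the
sample farthest from its centroid. 50 restarts per k (best by total
within-cluster distance), k scanned 2–15, winner by mean silhouette
(singletons contribute 0; ties prefer the smaller k). Clusters are
relabelled by decreasing size, ids are 1-based, and 0 is reserved for
"untyped".

Representative movements operate on the centroid's 17 entries: with m, s
the mean and population SD across movements, the strongest movement is
primary if its value ≥ m + 2s, the second strongest is secondary if ≥
m + 1s; ties break toward the lower movement id; a constant centroid has
no representatives. The rule is invariant to shifting and positive
rescaling of the centroid.

Patient synergies are never pooled into the control clustering (their
heterogeneity would degrade it); each is assigned to the nearest
centroid iff that distance does not exceed the cluster's maximum
within-cluster sample-to-centroid distance (non-strict, so every
training member re-assigns to its own cluster), else typed 0.

The per-synergy explained-variance share is the global VAF of the rank-1
reconstruction `W[:, i] H[i, :]` against the full envelope. An
incremental (leave-one-out) definition is a plausible alternative; the
rank-1 definition was chosen for being self-contained per synergy.
Because synergies are not orthogonal, shares need not sum to the
full-model VAF.

## Group statistics

Spearman (mid-rank ties, two-sided), Wilcoxon signed-rank (zeros
excluded; exact sign-permutation p via a generating-polynomial
convolution over doubled mid-ranks for up to 25 nonzero differences,
tie-corrected normal approximation beyond), Mann-Whitney U (exact for
small untied samples, asymptotic tie-corrected otherwise), and Welch's
t-test (no equal-variance assumption). All two-sided; no
multiple-testing correction by default (a Holm helper is provided).

## Synthetic generator

The generator instantiates the synergy model itself: an envelope
`W_true · H_true` with a NinaPro-like protocol (17 movements × 6
repetitions, 5 s movement / 3 s rest, 2 kHz; all configurable). Design
choices:

- **W columns are localized**: disjoint dominant electrode subsets
  (round-robin over a random electrode permutation), strong weights
  U(0.7, 1.0) there and weak U(0, 0.15) elsewhere, with rejection
  sampling enforcing pairwise cosine ≤ 0.7. Localization ensures each
  planted synergy holds a variance share that no smaller rank can
  absorb — i.e. that the planted count is actually present in the data.
  Unstructured random nonnegative columns fail this: their overlap lets
  a rank k−1 fit clear the VAF criteria.
- **Activation archetypes ("types")**: per-movement activation rows with
  disjoint dominant movement subsets (round-robin), dominant U(0.7, 1.0)
  vs background U(0, 0.15). Cohorts share one library of 6 types; each
  subject's synergies are jittered copies of a type subset, which is
  what makes cross-subject typing recoverable and provides the oracle
  for the typing benchmark.
- **Temporal structure**: each movement block is a Tukey (α = 0.4) pulse
  with per-repetition amplitude jitter U(0.8, 1.2) and smooth
  nonnegative process noise scaled by `noise_sd`. Both act on H, so the
  noiseless envelope is exactly rank k.
- **Carrier synthesis**: the emitted signal is zero-mean white noise
  amplitude-modulated by the envelope, plus additive sensor noise of SD
  `noise_sd` × mean movement envelope. This forces the preprocessing
  stages to do real work; the recovered envelope correlates > 0.95 per
  channel with the planted one at default settings. `carrier=False`
  emits the envelope directly for fast tests of post-envelope stages.
- **`noise_sd` default 0.1**: k-recovery passes comfortably at this
  level and fails under 10× noise, giving the benchmark a meaningful
  dynamic range.
- **Clinical covariates** are drawn through a Gaussian copula with
  configurable rank correlation to the planted synergy count; marginals
  are uniform over clinically plausible ranges (residual forearm 0–90%,
  age 30–67 y, 1–14 y since amputation, ordinal phantom sensation 0–5).
  The latent Gaussian correlation is calibrated (1-D quadrature +
  root-finding) so that the *population mid-rank Spearman* between the
  covariate and the discretized count equals the configured value —
  naively using the configured value as the latent correlation would
  under-deliver it, since both the discretization of the count and the
  Gaussian-to-grade mapping attenuate rank correlation.
  Defaults embed positive associations for residual forearm length and
  age and none for the other covariates.

What the generator does *not* emulate: volume conduction and electrode
crosstalk, motor-unit statistics, electrode shift, fatigue, power-line
interference (assumed removed upstream), and inter-subject variability
in W beyond random placement. Passing benchmarks therefore show the
*pipeline* recovers planted structure under the stated signal model —
not that real recordings satisfy that model.

## Problem sizes

Benchmarks shorten the protocol blocks, which scales T without touching
the planted structure: rank-recovery uses 1.0 s movement / 0.5 s rest
(≈10 200 pooled envelope samples), typing and cohort benchmarks use
0.5 s / 0.25 s, and unit tests 0.4 s / 0.2 s. The rank-recovery
benchmark runs 20 draws per planted rank 2–6 with 10 scan repeats per
rank (the full protocol default is 50); the typing benchmark uses 40
subjects (~200 synergies), matching the cohort scale the clustering is
meant for. The acceptance script reports 10 draws per rank.

## Known limitations

- The rank-scan criteria evaluate local VAF on the same max-global-VAF
  trial; requiring any trial to pass both jointly is a plausible
  alternative reading and can differ near the threshold.
- NinaPro containers are read for the EMG/label arrays only; glove,
  force and inclinometer channels are ignored, and Exercise A/D layouts
  are out of scope.
- Raw vs refined movement labels: refined (`restimulus`/`rerepetition`)
  win when both are present; the raw vectors remain accessible by
  reading the container directly.
- K-means under 1 − r with silhouette selection can be unstable when the
  feature set has no real group structure; the null-structure test
  asserts the silhouette curve is flat and low in that case, and users
  should treat a shallow silhouette peak as "no reliable typing".
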