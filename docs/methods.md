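# Methods

`statefuse` implements a workflow for studying how discrete latent *states*
of several simultaneously recorded systems — a high-dimensional brain
signal, a multivariate stimulus feature stream, and a low-dimensional
continuous behavioural rating — relate to each other over time. This note
describes the models, the estimation choices, what the synthetic generator
does and does not emulate, and the numerical conventions.

## State model for high-dimensional time series

Brain blocks (one `timepoints × channels` matrix per task block per
participant) are modelled with a K-state Gaussian hidden Markov model in a
PCA-reduced space.

**Reduction.** All blocks are concatenated, channel means removed, and an
orthonormal PCA basis retained holding a requested variance fraction
(default **0.9**). The retained component count is minimal: removing the
last component would drop below the fraction. With fraction 1.0 the basis
has full rank and reconstruction is exact, which is the contract the tests
exercise. Blocks can be polyphase-resampled (with anti-aliasing) to a
common working rate (default **256 Hz**) before reduction.

**HMM.** Emissions are full-covariance Gaussians, one per state; the
latent chain has a row-stochastic K×K transition matrix and an initial
distribution. Parameters are estimated by maximum-likelihood EM
(Baum–Welch) with k-means-seeded restarts (default 5 in the library API, 2
in the pipeline). Blocks are treated as *independent sequences sharing one
model*: the forward recursion restarts from the initial distribution at
each block boundary, so no cross-task transitions are counted. Per-state
covariances carry a ridge of `1e-6 · trace/d` to prevent collapse.
Convergence is a relative log-likelihood change below `1e-6` (max 500
iterations); the EM log-likelihood trace is non-decreasing and the test
suite asserts it.

`fit_score` is the per-sample negative log-likelihood of the best restart.
It plays the role a variational model-evidence score plays in other HMM
toolboxes — a relative index for comparing runs at fixed K — and its
absolute scale is not comparable to such scores.

**Numerics.** Emission densities and Viterbi run in the log domain.
The forward–backward pass uses the classic scaled recursions: emission
weights are max-shifted per timestep, each forward step is normalised to
sum one, and the shifts and scale factors are accumulated into the exact
log-likelihood. This is algebraically equivalent to a log-domain
implementation and allows all equal-length blocks to be processed as one
batched matrix recursion, which is what keeps repeated end-to-end fits
cheap. Viterbi ties break to the lowest state index, deterministically.

**K selection.** `scan_k` fits a model per candidate K and inspects the
transition structure: a state is flagged *under-represented* when its
Viterbi fractional occupancy falls below `0.5/K`, and *over-represented*
when its mean in-flow from other states, `w_k = mean_{j≠k} P[j,k]`,
exceeds `2/K`. Both thresholds are configurable; estimations with flagged
states fit the data poorly. `best_k` prefers the smallest flag-free K.

**State maps.** For interpretation, state means are projected back through
the PCA loadings (`loadings @ means.T`), giving signed per-channel
loadings (channel means are not added back). Maps are thresholded at the
absolute 70th percentile per state (linear-interpolation percentile of
absolute values; ties at the threshold are kept).

## Temporal state metrics

For any 1-based state path:

- **fractional occupancy** — fraction of samples in each state;
- **visits** — number of maximal runs of each state (runs truncated by the
  block edges count as visits; a flag-free alternative was considered and
  rejected because block onsets are meaningful task onsets here);
- **mean lifetime** — mean run length per state, in samples (seconds via
  the rate); *undefined* (NaN) when a state is never visited, never
  silently zero;
- **transition matrix** — empirical next-state probabilities including
  self-transitions; rows of states never occupied before the final sample
  are undefined.

The conservation identity `Σ_k visits_k · lifetimes_k = T` holds exactly
for every path (with `0 · undefined = 0`), and defined transition rows sum
to one; both are asserted property-wise in the tests.

Condition aggregation averages each participant's block metrics per
condition: plain means for occupancy and visits, visit-count-weighted
means for lifetimes (undefined entries drop out), and count-weighted means
for transition rows — identical to pooling the step counts across blocks
before normalising. Vectorized transition matrices flatten row-major; the
order is recorded in the report metadata so latent-variable loadings stay
interpretable.

## Behavioural states

A 2-D rating trajectory maps to five states: quadrants 1–4 by sign —
Q1 (x>0, y>0), Q2 (x<0, y>0), Q3 (x<0, y<0), Q4 (x>0, y<0), with zero
coordinates treated as positive — and a neutral state 5 at the exact
origin, where the cursor rests at each excerpt onset. An optional
ε-radius widens the neutral region for noisy hardware (default 0).
Which on-screen quadrant corresponds to which rating pole is a
configuration table, not code. The same metric family as above is
computed with K = 5, so behavioural and brain dynamics share one
representation.

## Partial least squares

**Mean-centred PLS** decomposes `D = condition means − grand mean` (the
grand mean is the unweighted mean of condition means, balancing unequal
block counts) by SVD. Each latent variable (LV) pairs a condition contrast
with a variable salience pattern and a singular value; `Σ s_i²` equals the
total sum of squares of `D`. With two conditions the decomposition is
rank-1 with contrast `±1/√2` along the mean difference — a closed form the
tests pin down.

**Behavioural PLS** computes, per condition, the `q × p` Pearson
correlation matrix between behaviour columns and variable columns across
rows, stacks the condition blocks vertically, and decomposes the stack.
Because it is correlation-based, results are invariant to column scaling.

**Inference.** LV significance uses permutations (default **500**):
condition labels are permuted across rows (mean-centred) or Y rows are
permuted within condition (behavioural), the i-th permuted singular value
is compared to the i-th observed one (no Procrustes in the permutation
step — a documented simplification), and
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`. Reliability uses bootstrap
resampling of participants (default **100**) — a participant's rows move
together across conditions, and degenerate draws with fewer than two
unique participants are redrawn. Each replicate is aligned to the original
solution before averaging: LV axes are matched by absolute inner product
of the variable saliences and sign-corrected — Procrustes matching
restricted to the signed-permutation subgroup. An unrestricted orthogonal
rotation would absorb genuine sampling variability (and, whenever the
salience matrix is square, map every replicate exactly onto the original,
zeroing the SE), so only order and sign are corrected. Bootstrap ratios
are `salience / bootstrap SE`, capped at `1e6`
when the SE vanishes, and design-salience 95% intervals are percentile
intervals clipped to bracket the point estimate. No family-wise correction
is applied across analyses; bootstrap reliability is the second line of
evidence.

Null calibration was checked by simulation: with independent X and Y at
n = 17, the LV1 rejection rate at the 5% level is binomially compatible
with 0.05 (0.06 over 400 replicates).

## Stability of repeated fits

EM restarts can land in different local optima. `stability_suite` fits
`n_runs` models from distinct seeds, matches states across runs by greedy
maximum-RV assignment of their covariance matrices (Hungarian optional),
stacks each run's matched covariances block-diagonally, and compares runs
with the **RV coefficient** `tr(S₁S₂)/√(tr(S₁²)tr(S₂²))` — a matrix
correlation in [0, 1] for PSD inputs, invariant to simultaneous orthogonal
transforms. **STATIS** summarises the run collection: per-run weights are
the leading eigenvector of the pairwise RV matrix (non-negative by
Perron–Frobenius, rescaled to sum one) and the *compromise* is the
weighted average matrix; an outlying run receives the strictly smallest
weight. Fit-score mean, SD and relative dispersion quantify optimisation
stability. "State matrices" here are the reduced-space state covariances;
channel-space projections would be an alternative the interface leaves
open.

## Synthetic data generator

The generator produces ground-truthed stand-ins for the three modalities,
at the study's geometry by default (17 participants; 10 resting blocks,
10 control and 30 experiment excerpts each; 68 channels at 256 Hz in 40-s
blocks). Tests and the demo pipeline run reduced configurations of the
same process.

- **Brain**: a sticky Markov chain (diagonal 0.9, perturbed off-diagonal
  rows) over `K_true` states (default 4) with full-covariance Gaussian
  emissions; state means are rescaled so the minimum pairwise Mahalanobis
  distance under the pooled covariance equals a separation parameter
  (default 5). The initial distribution is the chain's stationary
  distribution. Between-condition effects are planted on the transition
  matrix: a self-transition boost, solved by bisection on the stationary
  equation so the target state's long-run occupancy rises by exactly the
  requested amount, with the row renormalised. The planted effect is
  visible in the ground-truth paths before any fitting — the sanity
  channel the power tests rely on.
- **Stimulus**: 18 named feature columns at 10 Hz from a 5-regime
  switching model; regimes 1–3 place their means on the fast acoustic
  (context-free) columns, regimes 4–5 on the structural
  (context-dependent) columns.
- **Behaviour**: per-excerpt cursor tracks that start at exactly (0, 0),
  hold there for a uniform random reaction time (≤ 1 s), then follow an
  Ornstein–Uhlenbeck walk — drifting toward a target quadrant for coupled
  participants, weakly reverting to the centre otherwise — with rare
  snap-to-centre events (0.1/s) so neutral-state visits vary across
  excerpts. Effect magnitudes and these behavioural details are
  testability choices: no generative truth exists for the real behaviour,
  so passing tests demonstrate that the machinery detects effects of the
  planted kind at the planted size, not that real effects have that size.

What the generator does **not** emulate: sensor physics, volume
conduction, artifacts, 1/f spectra or oscillatory structure in the brain
signal; audio itself (features are emitted directly); motor noise,
momentum or strategy in the cursor. Conclusions about real recordings
therefore rest on the correctness of the estimators, which is what the
oracle and property tests establish, not on realism of the waveforms.

## Problem sizes used in tests

Decoding optimality is checked exactly against exhaustive enumeration
(K ≤ 3, T ≤ 8, 100 instances). Parameter recovery uses K = 4, d = 10,
T = 20,000 (fitted as four 5,000-sample segments, which batches the
forward–backward without changing the data). Permutation calibration uses
200 replicate datasets at n = 17 with 500 permutations. End-to-end power
uses 17 participants, 8 blocks each of 8 s at 32 Hz, a 3-state truth and a
planted +0.15 occupancy shift, over 20 seeds against 20 null seeds. The
demo pipeline (`demo_study_config`) uses 6 participants, 7 blocks each,
10 channels, 8-s blocks at 32 Hz.

## Known limitations

- Maximum-likelihood EM, not variational Bayes: no model-evidence score,
  so K selection rests on the representation diagnostics above.
- The permutation test compares singular values index-wise; for LVs beyond
  the first this is a simplification (conservative in practice here).
- Transition rows for rarely visited states are noisy at short block
  lengths and are dropped (as undefined columns) from the latent-variable
  analyses with a warning.
- Behavioural PLS assumes enough rows per condition (≥ 3) to estimate
  correlations; small cohorts make bootstrap intervals wide.
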