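# statefuse

Multi-modal dynamic state analysis for simultaneously recorded brain,
behaviour, and stimulus time series.

Continuous recordings — source-space EEG, a music feature stream, a 2-D
continuous rating track — live on different timescales and dimensionalities,
which makes it hard to ask how their dynamics relate. `statefuse` moves all
three into one conceptual space: discrete *state* time series. It decodes
states from high-dimensional signals with a Gaussian hidden Markov model,
assigns states manually where the state space is known (rating-plane
quadrants plus a neutral centre), summarises every modality with the same
temporal metrics, and links modalities with partial least squares (PLS)
under permutation and bootstrap inference. A ground-truthed synthetic-data
generator makes the whole workflow testable end to end.

It is intended for researchers analysing naturalistic-task recordings
(music listening, movie watching, continuous ratings) who want state-level
descriptions and cross-modal latent-variable statistics with explicit
calibration guarantees.

## The model in brief

For blocks of observations `x_t ∈ R^d` (PCA-reduced channels), a K-state
hidden Markov model with Gaussian emissions:

    z_t ∈ {1..K},   P(z_t = k | z_{t-1} = j) = A_jk,   x_t | z_t = k ~ N(μ_k, Σ_k)

is fitted by maximum-likelihood EM across all blocks jointly (blocks are
independent sequences sharing one model), and the most probable state path
is decoded per block with the Viterbi algorithm. From any state path the
package computes **fractional occupancy** (time share per state),
**visits** (maximal runs), **mean lifetimes** (run durations), and the
**transition-probability matrix** — with the exact invariants
`Σ_k FO_k = 1` and `Σ_k visits_k · lifetimes_k = T`.

Condition-aggregated metric matrices feed two PLS variants, both SVD-based:

* **mean-centred PLS** — SVD of `[condition means − grand mean]`, whose
  latent variables (LVs) express condition contrasts;
* **behavioural PLS** — SVD of stacked per-condition correlation matrices
  `corr(Y, X)`, expressing multivariate cross-modal correlation patterns.

LV significance comes from permutation tests
(`p = (1 + #{perm ≥ obs})/(n_perm + 1)`), reliability from participant-level
bootstrap with sign/order alignment; solution stability across EM restarts
is quantified with RV-coefficient similarity of state covariances and a
STATIS consensus. See `docs/methods.md` for the full account.

## Worked example

Plant a known between-condition effect (+0.15 long-run occupancy of one
state during the experiment condition), recover it blind, and test it:

```python
import numpy as np, pandas as pd
from statefuse import (SynthStudyConfig, ConditionEffect, generate_brain_study,
                       fit_gaussian_hmm, viterbi_decode, compute_metrics,
                       aggregate_by_condition, mean_centered_pls)
from statefuse.hmm import pca_reduce_blocks

cfg = SynthStudyConfig(
    n_participants=17, n_excerpts_control=3, n_excerpts_experiment=3,
    n_rest_blocks=2, n_channels=8, sample_rate=32.0, block_duration=8.0,
    K_true=3, separation=6.0, seed=42)
effect = ConditionEffect(state=2, delta_fo=0.15, condition="experiment")
study, truth = generate_brain_study(cfg, effect)
print(f"study: {len(study)} blocks, {cfg.n_channels} channels at {cfg.sample_rate:g} Hz")

reduced, reduction = pca_reduce_blocks(study.matrices(), 0.9)
print(f"PCA: {reduction.n_components} components retain "
      f"{reduction.explained_fraction.sum():.3f} of the variance")
model = fit_gaussian_hmm(reduced, K=3, n_restarts=2, seed=0)
print(f"HMM: fit score {model.fit_score:.4f} after {model.n_iterations} iterations")

sets = []
for block, X in zip(study, reduced):
    path = viterbi_decode(model, X, block_id=block.block_id)
    sets.append(compute_metrics(path, K=3, participant=block.participant,
                                condition=block.condition, block_id=block.block_id))
agg = aggregate_by_condition(sets)
for cond in ("control", "experiment"):
    fo = agg["fo"][cond].values.mean(axis=0).to_numpy()
    print(f"mean occupancy ({cond}): {np.round(fo, 3)}")

frames, labels, parts = [], [], []
for cond, cm in agg["fo"].items():
    frames.append(cm.values); labels += [cond] * len(cm.values)
    parts += list(cm.values.index)
res = mean_centered_pls(pd.concat(frames), labels, n_perm=500, n_boot=100,
                        seed=0, participants=parts)
print(f"LV1: singular value {res.singular_values[0]:.3f}, p = {res.perm_p[0]:.4f}")
print("design contrast (rest, control, experiment):",
      np.round(res.design_saliences[:, 0], 3))
print("bootstrap ratios per state:", np.round(res.bootstrap_ratios[:, 0], 1))
```

Output:

```
study: 136 blocks, 8 channels at 32 Hz
PCA: 5 components retain 0.921 of the variance
HMM: fit score 9.0663 after 5 iterations
mean occupancy (control): [0.308 0.386 0.306]
mean occupancy (experiment): [0.476 0.282 0.242]
LV1: singular value 0.166, p = 0.0020
design contrast (rest, control, experiment): [-0.381 -0.434  0.816]
bootstrap ratios per state: [168.1 -10.5  -7.5]
```

Reading this: decoded state labels are arbitrary, and here fitted state 1
corresponds to the boosted generative state — its occupancy rises from
0.31 (control) to 0.48 (experiment), the planted +0.15. The first latent
variable separates the experiment condition from rest and control
(contrast `[-0.38, -0.43, 0.82]`) and is significant at `p = 0.002`
(500 permutations); the bootstrap ratios mark which states carry the
contrast reliably (|ratio| > 2.58 ≈ 99% confidence).

The same suite runs end to end from the command line:

```bash
statefuse run-all --seed 3 --out-dir report/     # synthetic demo study
statefuse simulate --out study.h5 --seed 2
statefuse fit-hmm --input study.h5 --k 3 --variance 0.9 --seed 0 --out model.h5
statefuse metrics --input study.h5 --model model.h5 --out-dir metrics/
```

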