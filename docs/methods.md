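# Methods

This note documents the models implemented in `cyanoclock`, the default
parameters and why they hold their values, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## 1. Study design

The package analyses genes × time-points expression matrices with
per-sample metadata (time in hours, light condition, experiment id,
train/test split). The reference design, reproduced by the synthetic
generator, is: three 12 h light/dark (L/D) entrainment cycles followed by
24 h of continuous light (LL), sampled every 4 h — 18 training samples and
6 held-out test samples. L/D and LL samples belong to separate experiments
(they model separately grown cultures), so no computation ever pairs
consecutive samples across that boundary.

## 2. Preprocessing

**Two-channel normalization.** Raw Cy3/Cy5 intensities are mapped to
MA coordinates per array (M = log2 ratio, A = mean log2 intensity); the
intensity-dependent dye bias is estimated by lowess regression of M on A
(smoothing fraction 0.2, the conventional value for this array type) and
subtracted. Dye-swap arrays are sign-flipped, probe replicates averaged
within array, and replicate arrays averaged per sample. An operonic-pair
check (median within-pair Pearson correlation of co-transcribed pairs must
strictly exceed that of non-operonic pairs) serves as a normalization
sanity verdict; pairs with constant genes are skipped with a warning.

**Upsampling.** For network learning, each gene is interpolated per
experiment with a natural cubic spline and two extra points are inserted
between consecutive observations (4 h → 1 h 20 min spacing). Natural
boundary conditions were chosen because they are the conventional default
and reproduce linear data exactly, which makes the interpolant testable in
closed form. Observed samples are passed through unchanged; inserted
samples inherit the condition/split labels of their left neighbour.
Interpolation always precedes discretization — states are never
interpolated.

**Discretization.** Per gene, samples are ranked (ties broken by original
sample order, for determinism across platforms) and split into three
equal-frequency states; when the sample count is not divisible by the state
count the remainder goes to the lowest states. Constant genes collapse to a
single state (r = 1) with a warning and are forced to an empty parent set
downstream.

## 3. Network reconstruction (order-1 DBN, MIT score)

A dynamic Bayesian network of order 1 explains each gene's state at t+1
from a set of parent genes at t; cycles and self-loops in the unrolled
graph are legal (self-loop candidates can be disabled with a flag). The
node score is the Mutual Information Test:

S(X_i | Pa_i) = 2N·I(X_i^{t+1}, Pa_i^t) − Σ_{j=1..s_i} χ²_{α, l_iσ(j)},
with the empty parent set scoring 0.

- Mutual information is the plug-in estimate in **natural log** so that
  2N·I is the G-statistic, asymptotically χ²-distributed under
  independence — the penalty is then exactly the null quantile at
  significance α. Default α = 0.999.
- Degrees of freedom: l_iσ(j) = (r_i − 1)(r_iσ(j) − 1)·∏_{k<j} r_iσ(k)
  with parents sorted by decreasing state count; ties in state count leave
  the total penalty unchanged, so any such permutation is equivalent.
  A zero-dof term (single-state variable) contributes no penalty.
- χ² quantiles are computed by `scipy.stats.chi2.ppf` and cached per
  (α, dof), since the same quantiles recur throughout the search.

**Global optimality.** The score decomposes over nodes, so each node's
parent set is optimized independently by exhaustive enumeration. Sizes are
pruned by a provable bound: the cheapest possible penalty of an s-parent
set (attained by the s candidates with the fewest states — the penalty is
monotone in every state count) is compared with the largest possible gain
2N·ln r_i; once it exceeds the gain, size s and everything larger scores
below the empty set. The returned bound is therefore conservative — it can
never exclude the optimum — and never decreases with N. A configurable
cap (`max_parents_cap`, default 3) bounds the combinatorics on top.
Enumeration is size-ascending and lexicographic with strict-improvement
updates, which implements the tie-break "smaller set, then lexicographic
gene ids" without a separate pass.

**MDL.** The alternative metric is the description length
N·Ĥ(X_i^{t+1}|Pa_i^t) + (ln N / 2)(r_i − 1)·∏_j r_ij, negated internally so
both metrics are maximized by the same search.

## 4. Predictive model of transcription factors

Each target y follows τ·dy/dt = −y + g(β·Z): relaxation with time constant
τ (default 15 min, the literature value for transcriptional response
scales) toward a truncated-linear function of the design Z. Z contains
every regulator profile and, by default, the elementwise minimum of every
regulator pair (78 candidates for 12 regulators); min-pairs model AND-like
joint requirements. Design values are standardized with statistics computed
from the training samples of each individual fit and stored on the fitted
model, so raw-unit rescaling of the regulators provably cancels and no
held-out information leaks into the scaling.

**Training response.** The ODE is discretized over consecutive
within-experiment sample pairs. Two pairings are implemented:

- left (classical explicit form): r_t = τ·(y_{t+1} − y_t)/Δt + y_t with Z
  at time t;
- right (implicit form, the fitting default):
  r_{t+1} = τ·(y_{t+1} − y_t)/Δt + y_{t+1} with Z at t + 1.

When τ ≪ Δt the target lags its drive by ≈ τ·(d drive/dt). The left form
over-corrects this lag by a term of order τ·Δt·(drive)″ — a smooth,
systematic residual that collinear candidate predictors will happily
absorb, inflating false selections — while the right form cancels it to
O(τ²/Δt). τ = 0 reduces both to the pure equilibrium regression of y on Z.

**Selection and fitting.** The lasso path is computed by least-angle
regression; the L1 constraint is chosen by leave-one-out cross-validation
(fold paths are evaluated on the full-path breakpoint grid — lasso
coefficients are piecewise linear in the constraint, so this is exact) with
the one-standard-error rule. The active set is truncated to at most 5
single and 2 min-pair predictors in path-entry order, then refined by
greedy drop/swap moves under the extended BIC
(n·ln(RSS/n) + k·ln n + 2γ·k·ln P, γ = 1), and finally refit by ordinary
least squares (the "relaxed" fit; `relax=False` keeps the shrunk path
coefficients). The EBIC stage matters because the candidate dictionary is
strongly collinear: plain CV retains near-duplicates of a true predictor
(or a near-duplicate instead of it), and the ln P charge per selected
feature is the standard consistency correction when selecting among P ≫ n
candidates. Link truncation bounds (lo, hi) are the min/max of the training
responses — the conventional clamp when the data give no other anchor.

**Prediction** assumes equilibrium: ŷ = clamp(β·Z + intercept, lo, hi).

## 5. Evaluation protocol

- **LOOCV (training):** each of the 18 training points is predicted at
  equilibrium by a model fit from scratch (including standardization,
  selection and refinement) on the other 17; ρ_train is the Pearson
  correlation between stitched predictions and observations. Note the range
  clamp slightly shrinks the two extreme folds, so even a perfect predictor
  tops out just below ρ = 1 (≈ 0.998 on this design).
- **Circadian filter:** targets with ρ_train ≥ ρ_min = 0.5, inclusive (the
  boundary convention is a choice; nothing in the method fixes it).
  Undefined correlations (constant series) are flagged, excluded from
  aggregate means, and never pass the filter.
- **Holdout:** a single model refit on all training points predicts the 6
  LL samples; ρ_test per target. (Refit-on-all, rather than an ensemble of
  LOOCV models, is the conventional and simpler choice.)
- The pipeline is deterministic given its config: rerunning produces
  byte-identical reports.

## 6. Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study — schedule, sample
sizes, regulator/target roles, two-channel raw intensities with an
intensity-dependent dye bias and dye-swap/replicate layout, discrete DBN
trajectories with explicit CPTs — with known ground truth throughout:

- **Clock regulators** are sinusoids (amplitude 1, period 24 h, phases
  evenly spread) plus i.i.d. Gaussian measurement noise, sd 0.35. The
  waveform is a stand-in: nothing is claimed about real clock-gene shapes.
  The noise level is deliberately in the range two-channel arrays show on
  unit-amplitude log-ratio oscillations, and it carries a structural role:
  noise-free sinusoids of a common period span only a two-dimensional
  space, so each gene's private noise is the *only* signature that
  distinguishes co-periodic regulators from one another. Support-recovery
  results should be read with that in mind — they show the estimator
  exploits gene-specific variation correctly, not that 18 smooth samples
  could ever identify individual regulators among exact collinears.
- **Driven targets** integrate the kinetic model (explicit Euler, step
  ≤ τ/10, drive linearly interpolated between samples, equilibrium start)
  from the *observed* (noisy) regulator profiles, then add observation
  noise of sd 0.1 (10% of the signal amplitude). Ground-truth draws whose
  combined drive has standard deviation below 0.5 are rejected and redrawn:
  two randomly signed, similar-shaped terms can otherwise cancel, yielding
  a "driven" label with no detectable rhythm — a mislabelled fixture, not a
  hard case. **Noise targets** are unit-variance Gaussian series.
- **Discrete DBN fixtures** use copy CPTs (one parent) or minimum CPTs
  (two parents) with fidelity 0.85, i.i.d. uniform root genes. Roots being
  i.i.d. removes lag-1 autocorrelation from the whole system, so only true
  edges carry signal and false-edge rates reflect the penalty calibration.

Passing tests on these fixtures demonstrate correctness of the algorithms
and calibration of the scores under known generative models. They do not
establish performance on real microarray data, whose noise is neither
Gaussian nor independent, whose rhythms are not sinusoidal, and whose
regulation is not a truncated-linear function of 78 candidate terms.

## 7. Problem sizes of the validation experiments

Chosen as the smallest sizes at which each property is informative:
oracle-agreement on 50 random instances of ≤ 5 genes / 3 states / ≤ 300
transitions (brute force is exact there); penalty calibration over 1000
independent binary pairs at N = 500; edge recovery on 10-gene networks
(≤ 2 parents, N = 500) over 20 seeds; predictor recovery over 50 seeds on
the dense-sampling variant of the design (1 h spacing, 72 training samples
— at 18 samples the coherent 78-atom dictionary is not statistically
resolvable); end-to-end discrimination (10 driven + 10 noise targets) over
20 seeds in the test suite.

## 8. Known limitations

- Only order-1 DBNs; no static-network mode; no higher-order lags.
- The search is exhaustive per node; with the provable bound it is
  polynomial for fixed state counts, but very large gene sets would need
  the `max_parents_cap` (default 3) to stay tractable.
- The kinetic model is single-equation per target with a fixed global τ;
  no temporal clustering of targets, no bicluster inputs.
- Probe-to-gene mapping, background correction and operon prediction are
  out of scope: operonic pairs are inputs.
- LOOCV inner model selection at 17 samples is noisy by nature; the EBIC
  refinement trades a little recall for a large precision gain, which is
  the right trade for calling circadian targets but means weakly driven
  targets (drive sd near the noise floor) can be missed.
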