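# cyanoclock

Reconstruction and predictive modelling of a cyanobacterial circadian clock
network from time-series gene expression.

Unicellular diazotrophic cyanobacteria separate photosynthesis (day) and
nitrogen fixation (night) in time, coordinated by a KaiABC-type circadian
clock. Two questions arise from expression time courses of such an
organism: *which regulatory interactions connect the core clock genes*, and
*which transcription factors are under clock control, tightly enough that
their expression can be predicted from the clock genes alone — even under a
changed light regime*. This package implements both analyses for
genes × time-points expression matrices sampled over light/dark (L/D)
entrainment cycles followed by a continuous-light (LL) free run, together
with a fully specified synthetic-data generator so every stage can be
validated against known ground truth.

## Methods at a glance

**Network reconstruction.** Expression is spline-upsampled (two inserted
points per 4 h gap → 1 h 20 min spacing), discretized per gene into three
equal-frequency states, and modelled as an order-1 dynamic Bayesian network:
parents at time *t* explain a child at *t + 1*. Parent sets are scored by
the Mutual Information Test (MIT),

    S(X_i | Pa_i) = 2N·I(X_i^{t+1}, Pa_i^t) − Σ_{j=1..s_i} χ²_{α, l_iσ(j)}

where I is plug-in mutual information in nats (so 2N·I is the G-statistic),
and each χ² quantile (α = 0.999) charges the degrees of freedom
l_iσ(j) = (r_i − 1)(r_iσ(j) − 1)·∏_{k<j} r_iσ(k) added by the j-th parent,
parents ordered by decreasing state count. Because the score decomposes
over nodes and the cumulative penalty of large parent sets provably exceeds
the bounded gain 2N·ln r_i, an exhaustive per-node search returns the
globally optimal network in polynomial time. Minimum Description Length
(MDL) is available as an alternative metric.

**Predictive modelling.** Each target TF *y* follows the kinetic model

    τ·dy/dt = −y + g(β·Z),   g = truncated linear,   τ = 15 min

with design Z containing every clock gene and every pairwise minimum of two
clock genes (AND-like joint regulation). Coefficients are selected on the
least-angle-regression lasso path with leave-one-out cross-validation,
truncated to at most 5 single and 2 min-pair predictors, refined under the
extended BIC, and refit by ordinary least squares. Training is scored by
leave-one-out cross-validation over the 18 L/D samples (each point
predicted at equilibrium, ŷ = g(β·Z), from a model fit on the other 17);
targets with LOOCV correlation ρ ≥ 0.5 are called circadian-controlled, and
a final model refit on all training points is evaluated on the 6 held-out
LL samples.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1). Output below is what they print:

```
$ python analysis/01_simulate.py
simulated 12 clock regulators and 20 targets over 24 samples (18 L/D train, 6 LL test); artifacts in results/data

$ python analysis/02_preprocess.py
upsampled 24 -> 68 samples; 3-state discretization; 66 order-1 transition pairs (experiment boundaries respected); artifacts in results/preprocessed

$ python analysis/03_infer_network.py
MIT network: 15 edges (total score 631.65); MDL network: 12 edges; 11 edges shared between the two metrics; artifacts in results/network

$ python analysis/04_fit_models.py
selected 10/20 targets at rho_min=0.5 (10 of 10 driven, 0 of 10 noise); mean rho_train(all)=0.144, mean rho_train(selected)=0.939, mean rho_test(selected)=0.986; artifacts in results/models

$ python analysis/05_validate.py
validation summary: oracle agreement 1.00; null positive rate 0.0000 (α=0.999); edge F1 0.991; predictor F1 0.933 (coef rel err 0.023); discrimination acc driven/noise 0.97/1.00; details in results/validation.json
```

Reading the modelling step: of the 20 simulated TFs, exactly the 10 that
were generated as kinetic functions of the clock pass the ρ ≥ 0.5 filter
(none of the 10 unregulated ones do); over the selected set the mean LOOCV
correlation is 0.94 on the L/D training samples, and 0.99 on the
continuous-light holdout — the fitted clock models keep predicting under a
light regime they never saw. The validation step confirms the learner
itself: the bounded search is exactly the brute-force optimum, an
independent parent is accepted at about the nominal 1 − α rate, and known
network edges / predictor sets / coefficients are recovered from synthetic
ground truth.

The same stages are exposed as a CLI (`cyanoclock simulate | preprocess |
infer-network | fit-models | evaluate | run`); `cyanoclock run config.yaml`
executes the full pipeline from a YAML config, reproducibly for a fixed
seed.

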