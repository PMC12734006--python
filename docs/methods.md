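# Methods

## Problem and model

`mmrisk` predicts a rare binary clinical outcome (motivating case:
short-term mortality after a transcatheter valve procedure) from four
input channels per patient: a static laboratory panel, irregularly
sampled ICU monitoring series, and two precomputed embedding sequences
standing in for frozen waveform (ECG) and clinical-text foundation-model
encoders. Real cohorts of this kind have pervasive, structured
missingness — e.g. patients never admitted to the ICU have no monitoring
series at all — so the architecture treats whole-modality absence as a
first-class input, not an imputation problem.

The classifier is dual-branch:

1. **Unimodal branch.** Each modality is linearly projected into a
   shared working dimension `D` and refined by its own single-layer
   transformer encoder (8 heads, pre-LayerNorm, GELU feed-forward, no
   parameter sharing across modalities). The lab vector enters as a
   single token (optionally split into fixed-size groups), the aligned
   series as one token per grid step with learned positional embeddings,
   the embedding matrices as one token per row. Each branch is reduced
   to a summary vector by mean pooling over non-padding tokens.
2. **Fusion branch.** A learnable latent token matrix
   `H ∈ R^{L×D}` is expanded over the batch and updated once per
   modality in the fixed order (lab, time, ecg, note) by masked
   multi-head cross-attention with a gated residual,
   `H ← MHCA(H, K_m, V_m, M) ⊙ M_u + H`. The additive mask `M` blocks
   attention to padding and to the keys of absent samples; the binary
   per-sample gate `M_u` zeroes the entire update for samples missing
   the modality, so their latent state passes through bit-for-bit
   unchanged. A softmax row whose keys are all blocked is defined as the
   zero vector (including the output-projection bias), not NaN.

The four modality summaries plus the pooled latent summary are fused by
**attention pooling**: a learnable linear scorer produces one score per
source, a masked softmax normalizes over present sources only (absent
sources are excluded before normalization and reported with weight
exactly 0), dropout regularizes the normalized weights during training,
and the fused vector is the weighted sum. A two-layer feed-forward head
(LayerNorm → linear → GELU → dropout → linear → sigmoid) emits the event
probability. Missing-modality robustness is therefore structural: every
computational path out of an absent modality is multiplied by an exact
zero, which the tests assert as bit-level invariance under arbitrary
perturbations of absent-modality features.

Open design points resolved here: the latent loop makes a single pass
per modality per forward (the update index ranges over modalities, not
epochs); dropout on pooling weights is applied after softmax
normalization; the classifier head has two layers; per-head key
dimension is `D / 8` and is the `d` in the attention scaling.

## Loss

Training uses a class-balanced dual focal loss. With a single sigmoid
output, the non-target probability is `p_other = 1 − p_true`, giving

    L = − α_t · (1 − p_true + p_other)^γ · log(p_true)
      = − α_t · (2(1 − p_true))^γ · log(p_true)

with `α_t = α` for positives and `1 − α` for negatives (the focal-loss
α_t convention), defaults `α = 0.25`, `γ = 3`. The modulator uses both
the target and non-target probabilities, so confident correct
predictions are suppressed more aggressively than in plain focal loss
while hard examples keep their gradient. `p_true` is clamped at 1e−7
inside the log. No learning-rate schedule or early stopping is used.

## Numerical substrate

The network, its gradients, and the optimizer are implemented on a small
reverse-mode automatic-differentiation engine over float64 numpy arrays
(`mmrisk.autodiff`): broadcast-aware arithmetic, batched matmul,
reductions, GELU/sigmoid/ReLU, a clamped log, concatenation, and a
masked softmax whose fully-blocked rows are exactly zero. Every backward
rule is verified against central finite differences in the test suite,
and the full model's parameter gradients are spot-checked the same way.
GELU (smooth) rather than ReLU is used in feed-forwards so that the
midpoint-rule integrated-gradients approximation converges cleanly.

## Preprocessing

Monitoring series are aligned to a uniform per-variable grid. The
variable's mean sampling interval pools every consecutive-pair gap over
all patients (series with fewer than two points contribute nothing).
The grid starts at each patient's first observation, is spaced by that
mean interval, and has a fixed configurable length (default 12 steps),
truncating or padding stays; the aggregation window half-width is half
the interval, so windows partition the timeline without overlap.
Within-window aggregation is the mean for continuous variables and the
mode for discrete ones (ties to the earliest observed value). Gaps are
closed by carrying boundary values (first observed value backward over a
leading gap, last forward over a trailing gap), linear interpolation for
interior numeric gaps, and a dedicated null category for discrete gaps;
observed grid points are never altered, and provenance tags record the
fill rule per point. A patient series whose every measurement is a
missing marker falls back to the variable's cohort mean (the strict
`fill_aligned` contract still errors on fully-missing input when called
directly).

Lab panels are completed by chained-equation multiple imputation:
independent chains of iterative conditional linear regressions with
posterior draws (backed by scikit-learn's `IterativeImputer`), pooled by
averaging the chains' imputed values into a single table (point-estimate
pooling only; between-chain variance is not propagated because only the
completed table feeds the model). Defaults: 20 chains, 10 iterations.
Labs and aligned series are z-scored on the processed cohort.

## Synthetic cohorts

The generator emulates the study conditions the model targets: 800
patients per cohort at 4.2% outcome prevalence, four modalities with
structured missingness (defaults: monitoring series absent for 30% of
patients — the "never in the ICU" pattern — waveform and text embeddings
absent for 10%, labs always present, at least one modality guaranteed),
10% scattered missingness inside lab panels and series, and
asynchronous multi-rate sampling (patient-specific Poisson rates of
0.25–2 observations/hour over 48 h, floored at two points per series).

Each patient draws one standard-normal factor per modality; the latent
risk is their linear combination with the configured effect sizes, and
the label is Bernoulli with `sigmoid(b0 + risk)`, the intercept solved
by Gauss–Hermite quadrature so the population prevalence is exact.
Observables are noisy linear functions of their own modality's factor
only, so no single channel suffices to recover the risk: lab loadings
(1.0, 0.4, 0.2, 0, …) make lab feature 0 the strongest single input
(the planted signal for attribution tests — the loading gap is wide
enough that no sibling readout of the same factor rivals it); series
levels follow the
same loading pattern plus a circadian drift; embeddings are a fixed
random direction matrix (unit-norm rows, so the signal is diffuse across
coordinates as in real foundation-model embeddings and no single
coordinate rivals the planted lab signal) scaled by the factor plus
token-level noise
(surrogates for frozen foundation encoders — the direction matrices are
drawn from a separate structure seed shared by all cohorts, so models
transfer across patient seeds). Missingness is independent of outcome
(MCAR) by default; an `mnar` switch links missingness odds to the risk.

Default effect sizes are {lab: 3.0, time: 2.5, ecg: 2.5, note: 2.0}.
They were calibrated, as part of the study-conditions design, so that
the population AUC of the true latent risk is ≈0.98 and the ceiling
attainable from the observable features (a regularized logistic
regression on oracle per-modality summaries) is ≈0.92 — the same
discrimination regime the method is intended for. What passing tests
show is that the pipeline recovers most of the recoverable signal and
that its masking, loss, and attribution semantics are exact; they do not
show performance on real clinical data, whose nonlinearities,
confounding, and non-random missingness the generator deliberately does
not model.

## Training protocol and desk scale

Full-scale defaults mirror the intended deployment scale: working
dimension 768, 256 latent tokens, 8 heads, dropout 0.1, Adam
(β1 = 0.9, β2 = 0.999) at learning rate 1e−4 with L2 weight decay, 20
epochs, stratified 5-fold cross-validation (seed 2025) with metrics on
out-of-fold predictions, and percentile-bootstrap 95% CIs from 1000
patient-level resamples.

All verification runs at a reduced desk scale chosen for single-CPU
runtimes: D = 32, L = 8, 12 grid steps, 800 patients. At this scale the
full-scale step size is too small to traverse the loss landscape in the
available ~500 Adam steps, so the desk protocol uses lr 1e−3 with
weight decay 1e−2 (strong decay substitutes for the regularization
head-room of a larger cohort), batch 32, 30 epochs. One desk-scale
5-fold run takes a few minutes on one CPU; out-of-fold AUC lands around
0.87 (±0.03 across cohort seeds) with Brier ≈ 0.04, against the ≈0.92
oracle ceiling. These are scaled-down verification numbers, not
reproductions of full-scale results.

## Evaluation

AUC is the Mann–Whitney pairwise statistic (ties 1/2); AUPR is the
step-interpolated area (average precision — no optimistic linear
interpolation); both delegate to scikit-learn and are verified against
brute-force enumeration oracles in the tests. The operating threshold
maximizes the Youden index over observed scores with ties broken toward
the higher threshold. Calibration uses 10 equal-width bins (empty bins
omitted). Decision curves implement net benefit
`TP/N − FP/N · p_t/(1 − p_t)` on a 0.01–0.50 grid (step 0.01) against
treat-all and treat-none. Bootstrap CIs are percentile (not BCa);
single-class resamples are redrawn with a warning; the recall CI keeps
the Youden threshold fixed at its full-table value across resamples.

## Attribution

Integrated gradients with the midpoint rule,
`α_k = (k − 0.5)/m`, default m = 128, baseline = the all-zero input in
standardized space (the cohort feature-wise mean). The attribution
target is the pre-threshold predicted probability. All m interpolants
are evaluated as one batch. Absent-modality coordinates receive exactly
zero attribution (their path gradients vanish structurally). Group-level
importance averages |IG| per feature across records — absolute values so
patients with opposing signs do not cancel — with series attributions
averaged over grid steps per variable and embedding attributions
averaged over tokens per coordinate, scoring each feature by its average
per-occurrence contribution so repeated occurrences do not inflate a
feature relative to the scalar labs. The completeness identity
`Σ IG ≈ F(x) − F(x′)` is asserted at m = 256 on trained models.

## Known limitations

* The generator's linear factor structure cannot probe nonlinear
  cross-modal interactions; the fusion module's benefit over a summary
  concatenation is not measurable on it.
* Rubin-style between-imputation variance is not propagated into model
  uncertainty; only point-estimate pooling is used.
* Attribution stops at the embedding inputs; it cannot name features
  inside the (out-of-scope) waveform/text encoders.
* Discrete monitoring variables are aligned and filled but not yet
  consumed by the model, which takes numeric grids only.
* With ~34 positives per desk-scale cohort, out-of-fold AUC/AUPR have
  wide sampling variability across cohort seeds; single-seed numbers
  should be read with that in mind.
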