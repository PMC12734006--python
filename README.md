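# mmrisk

Multimodal clinical risk prediction that stays exact under missing
modalities.

`mmrisk` is for modelers working with heterogeneous clinical cohorts —
a static laboratory panel, irregularly sampled ICU monitoring series,
and precomputed waveform (ECG) and clinical-text embedding sequences per
patient — where whole channels are frequently absent (a patient never
admitted to the ICU simply has no monitoring series) and the outcome is
rare (~4–5% prevalence). It provides the full pipeline: a synthetic
cohort generator with a known outcome mechanism, temporal alignment and
chained-equation imputation, a masked-attention latent fusion
classifier, class-balanced dual-focal-loss training with cross-validated
evaluation, and integrated-gradients attribution.

## The model

Each modality `m` is projected into a shared dimension `D`, refined by
its own single-layer transformer encoder, and mean-pooled into a summary
vector. In parallel, a learnable latent token matrix `H ∈ R^{L×D}` is
updated once per modality by masked multi-head cross-attention with a
gated residual:

    H ← M-MHCA(H, K_m, V_m, M) ⊙ M_u + H,
    M-MHCA(Q, K, V, M) = Softmax(QW_Q (KW_K)^T / √d + M) V W_V

where the additive mask `M` blocks padding/absent keys and the binary
gate `M_u` zeroes the whole update for samples missing the modality.
The four modality summaries plus the latent summary are fused by a
masked attention-pooling layer (softmax over present sources only;
absent sources get weight exactly 0) and a small feed-forward head emits
the event probability. Absence is handled structurally: perturbing the
features of an absent modality changes the output by exactly zero.

Training minimizes the class-balanced dual focal loss

    L = −α_t (1 − p_true + p_other)^γ log(p_true),   α = 0.25, γ = 3,

with Adam under stratified 5-fold cross-validation; metrics (AUC, AUPR,
recall at the Youden threshold, Brier score, calibration bins, and
decision-curve net benefit) are computed on out-of-fold predictions with
percentile-bootstrap CIs. Integrated gradients (midpoint rule) attribute
predictions to lab features, series values, and embedding coordinates.

The network runs on a small numpy reverse-mode autodiff engine included
in the package (`mmrisk.autodiff`); no deep-learning framework is
required. See `docs/methods.md` for assumptions, defaults, and
limitations.

## Worked example

```python
import mmrisk

# an 800-patient cohort at 4.2% prevalence with structured missingness
spec = mmrisk.CohortSpec(n_patients=800, seed=2025)
records = mmrisk.generate_cohort(spec)
mmrisk.preprocess_cohort(records)  # align series, impute labs, z-score

table, models = mmrisk.cross_validate(
    records,
    mmrisk.ModelConfig.small(),           # D=32, L=8 desk-scale model
    mmrisk.TrainConfig(lr=1e-3, l2=1e-2, epochs=30, batch_size=32, seed=2025),
)
thr = mmrisk.youden_threshold(table)
print(f"AUC   {mmrisk.auc(table):.4f}")
print(f"AUPR  {mmrisk.aupr(table):.4f}")
print(f"Recall@Youden {mmrisk.recall_at(table, thr):.4f}")
print(f"Brier {mmrisk.brier(table):.4f}")
```

On this seed the run prints:

```
AUC   0.8710
AUPR  0.2772
Recall@Youden 0.8214
Brier 0.0370
```

i.e. the out-of-fold ranking separates eventual events from survivors
with AUC ≈ 0.87 (against an information ceiling of ≈ 0.92 for this
generator setting), catches ~82% of events at the Youden operating
point, and keeps mean squared probability error under 0.04 at 3.5%
observed prevalence. Attribution then names what drives high-risk calls:

```python
positives = [r for r in records if r.label == 1]
print(mmrisk.group_importance(models[0], positives, m=128).head())
```

which ranks the generator's planted strongest signal (`lab_0`) first.

A thin CLI wraps the same steps:

```bash
mmrisk generate --out cohort/
mmrisk preprocess --in cohort/ --out prepped/
mmrisk train --data prepped/ --out runs/
mmrisk evaluate --pred runs/oof_predictions.csv --out report.json
mmrisk explain --model runs/fold0.npz --data prepped/ --out importances.csv
```

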