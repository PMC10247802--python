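# dti — similarity-accumulation drug–target interaction prediction

`dti` predicts drug–target interactions (DTIs) from heterogeneous
association data, for computational drug-repurposing work: given a binary
interaction matrix **X** (m drugs × n targets) plus per-side similarity
and association matrices (drug–drug structure/interactions, drug–disease,
drug–side-effect, target–target sequence/interactions, target–disease),
it learns to score unseen (drug, target) pairs.

## The method

1. **Feature accumulation.** Every association matrix is converted to an
   entity×entity cosine-similarity matrix, R_kl = ⟨o_k, o_l⟩/(‖o_k‖‖o_l‖);
   each side's similarity matrices are then summed element-wise into one
   feature matrix per side, D = Σᵢ D⁽ⁱ⁾ (m×m) and T = Σⱼ T⁽ʲ⁾ (n×n).
   Row d_i of D is drug i's feature vector; t_j likewise for targets.
2. **Direct pipeline ("dedti").** A 1-D convolutional classifier
   (4 × [Conv1D–ReLU–batchnorm–dropout] → dense → sigmoid) scores each
   concatenation [d_i ‖ t_j] (length m+n), trained with Adam on binary
   cross-entropy. The output bias is preset to ln(P/N) so the untrained
   model predicts the class prior.
3. **Embedding pipeline ("iedti").** k-means pseudo-labels over the
   feature rows supervise per-side triplet-loss embedders
   (L = mean max(0, γ + d(a,p) − d(a,n)), semi-hard mining, 256-d
   L2-normalized output); the same classifier then scores concatenated
   embeddings (length 512).
4. **Evaluation.** Negatives sampled at 1:r from the zeros of X
   (r ∈ {1,3,5,10}), stratified ten-fold cross-validation, metrics
   suited to imbalance (AUPR, MCC, F1) alongside AUC-ROC,
   sensitivity/specificity/precision, and a paired t-test between
   fold-wise metric vectors. High-scoring unknown pairs (score ≥ 0.9)
   are ranked as novel-interaction candidates.

Bundles in the dense plain-text dialect (whitespace-separated rows, as
distributed with the DTINet and Yamanishi gold-standard sets) are read
via a small YAML manifest; a seeded synthetic generator produces
structurally faithful bundles with planted ground truth for testing.
See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
import dti

bundle, truth = dti.generate_bundle(dti.SyntheticSpec(seed=7))
D, T = dti.build_feature_matrices(bundle)
print(f"bundle: {bundle.m} drugs x {bundle.n} targets, "
      f"{int(bundle.X.sum())} known interactions")
print(f"feature matrices: D {D.shape}, T {T.shape}")

config = dti.PredictorConfig(input_length=bundle.m + bundle.n,
                             conv_filters=(8, 16, 16, 16), dense_width=64,
                             batch_size=256, epochs=5, seed=0)
report = dti.run_cross_validation(bundle, "dedti",
                                  dti.SamplingSpec(ratio=3, seed=7),
                                  predictor_config=config)
for name in ("auc_roc", "aupr", "f1", "mcc"):
    print(f"{name:8s} {report.mean[name]:.3f} +/- {report.std[name]:.3f}")
```

prints (a few minutes on one CPU):

```
bundle: 150 drugs x 300 targets, 3520 known interactions
feature matrices: D (150, 150), T (300, 300)
auc_roc  0.874 +/- 0.015
aupr     0.645 +/- 0.033
f1       0.751 +/- 0.069
mcc      0.670 +/- 0.080
```

The synthetic bundle plants interactions inside favored
(drug-cluster, target-cluster) blocks at rate 0.35 over a 0.01 noise
floor; given those rates the best achievable AUC-ROC is ≈ 0.88, so the
cross-validated 0.874 ± 0.015 means the pipeline recovers essentially
all of the planted signal, and the AUPR of 0.645 is far above the 0.25
prevalence of the 1:3-sampled evaluation set.

The same experiment from a shell:

```sh
dti simulate --seed 7 --out-dir bundle/
dti train --mode dedti --manifest bundle/manifest.yaml --ratio 3 --seed 7 --out run/
dti predict-novel --run-dir run/ --threshold 0.9 --out novel.tsv
```

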