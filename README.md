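# leafgate

Gated multi-branch CNN/transformer fusion for leaf-disease image
classification.

Automated diagnosis of crop diseases from leaf photographs has to cope
with symptoms that live at very different spatial scales: rust shows as
tiny high-frequency pustules, blights as large smooth discolorations,
and some viral diseases as lesions aligned with the vein architecture.
`leafgate` implements a hybrid classifier that addresses this directly
with three complementary feature extractors — a high-resolution
**detail CNN**, a strongly-downsampling **global-context CNN**, and a
**vision-transformer** branch for long-range structure — whose
embeddings are combined by **Gated Scale-Attention Fusion (GSAF)**.

GSAF projects each branch embedding φ_i to a common width C, pools it
to a global descriptor z_i = GAP(φ_i), and predicts an image-adaptive
gate from the concatenated descriptors:

    u = [z_d; z_g; z_t],   s = W₂ σ(W₁u + b),   g = softmax(s/τ),

with σ the GELU and τ > 0 a temperature. The fused representation is
the convex combination Φ = g_d φ_d + g_g φ_g + g_t φ_t, classified by a
single linear head. Training minimises

    L = L_C(y, ŷ) + λ·E[H(g)],    H(g) = −Σ_i g_i log g_i,

cross-entropy (or focal loss) plus an entropy-sparsity term that
rewards decisive, interpretable gating; λ is held at zero during a
warm-up phase. The gate adds only 3Ch + h + 3h + 3 parameters (9 267 at
the default C = 256, h = 12 — under 10 k). Evaluation machinery covers
per-class precision/recall/F1 from the confusion matrix, macro-F1,
stratified 5-fold cross-validation with identical folds across model
variants, McNemar's paired test for model comparisons, and per-image
gate-weight exports.

Everything runs on plain numpy: the package contains a small
reverse-mode autodiff engine (`leafgate.nn`), a seeded synthetic
leaf-image generator that gives every component a download-free test
surface, a scikit-learn-style estimator, and a CLI. See
`docs/methods.md` for the model, the generator, and the design choices.

## Worked example

```python
import numpy as np
from leafgate import GatedFusionImageClassifier, SyntheticDatasetSpec, synth_generate

# 3-class synthetic set: each class's cue targets one branch
spec = SyntheticDatasetSpec(classes=("blotch", "speckle", "vein_aligned"),
                            n_per_class=200, seed=1)
images, classes = synth_generate(spec)

clf = GatedFusionImageClassifier(epochs=12, learning_rate=0.03,
                                 lambda_sparsity=0.1, warmup_epochs=3, seed=0)
clf.fit(images.pixels[::2], images.labels[::2])        # train on half
print("accuracy:", clf.score(images.pixels[1::2], images.labels[1::2]))
gates = clf.gate_weights(images.pixels[1::2])
for k, name in enumerate(classes):
    mean = gates[images.labels[1::2] == k].mean(axis=0).round(3)
    print(f"{name:>13}: detail={mean[0]} global={mean[1]} transformer={mean[2]}")
```

prints (one CPU, a couple of minutes):

```
accuracy: 1.0
       blotch: detail=0.0 global=1.0 transformer=0.0
      speckle: detail=1.0 global=0.0 transformer=0.0
 vein_aligned: detail=0.0 global=1.0 transformer=0.0
```

The gate routes each image by the scale of its symptom: speckled leaves
lean on the detail branch, large discolorations on the global-context
branch — the model explains *which* kind of evidence drove each
prediction.

The CLI exposes the same machinery:

```bash
leafgate synth --spec spec.yaml --out data/synth
leafgate train --config experiment.yaml --out runs/base
leafgate ablate --config experiment.yaml --strategy gsaf --strategy static_average
leafgate eval --checkpoint runs/base/fold0_model.npz --data data/synth --out eval/
```

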