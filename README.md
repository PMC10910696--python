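# fundusseg

Joint optic disc (OD) and optic cup (OC) segmentation for retinal fundus
images, with an attention-aware encoder-decoder, a rim-constrained
multi-label loss, and optional contrastive self-supervised pretraining of
the encoder. From the two segmented structures the package derives the
vertical cup-to-disc ratio (CDR), the screening quantity for glaucoma
(normal ≈ 0.3–0.4; larger values indicate risk).

The package is aimed at medical-image-analysis practitioners who want a
fully reproducible, CPU-only reference implementation of this family of
models: every component — including the neural-network layer, which runs on
a small NumPy reverse-mode autodiff engine — is self-contained, seeded, and
tested against brute-force oracles, and a synthetic fundus generator makes
the whole pipeline runnable without any dataset download.

## Model

A residual CNN pyramid encodes the image into feature maps F1..F4
(strides 4–32). Each stage is followed by a **multi-scale KNN-attention
block** operating on flattened tokens X ∈ R^(B×C×P):

    X' = MHSA(LN(X)) + X
    Y  = MSMLP(LN(X')) + X'

where MSMLP gathers, for each token, its k nearest tokens under cosine
similarity S = FᵀF of L2-normalized features (k ∈ {4, 6, 8}), applies two
1×1 convolutions with a ReLU, max-reduces over neighbors and sums the
scales. After F4, an **aggregation-attention block** clusters the tokens
into C = 3 groups with seeded mini-batch k-means and runs residual scaled
dot-product attention Softmax(QKᵀ/√D)V inside each group and across the
three group centroids, broadcasting the updated centroids back to their
members. A skip-connected decoder restores full resolution and an
independent sigmoid per structure yields p_D, p_C.

Training minimizes the rim-constrained multi-label loss

    L = (BCE(p_D, g_D) + BCE(p_C, g_C) + BCE(clamp(p_D − p_C), g_D − g_C)) / 3,

whose third term scores the predicted disc-minus-cup difference against the
optic rim, injecting the anatomical prior OC ⊆ OD. The encoder can be
initialized by two-view InfoNCE pretraining (rotation / sharpen / gamma /
blur augmentations, RoiAlign-pooled 24×24 global feature, single FC
projection, in-batch negatives):

    L_q = −log exp(q·k₊/τ) / Σ_{i=0..K} exp(q·k_i/τ).

Evaluation reports per-structure precision, recall, F1, Dice, the boundary
localization error BLE (mean |d_g − d_0| over 24 rays from the disc
centroid, in pixels), and CDR. See `docs/methods.md` for assumptions,
parameter defaults and numerical choices.

## Worked example

```python
from fundusseg.synthetic import make_dataset
from fundusseg.pipeline import TrainConfig, train, evaluate
from fundusseg.model import ModelConfig

make_dataset(40, "train", seed=100, out_dir="data/train")
make_dataset(10, "val", seed=200, out_dir="data/val")
train("data/train/manifest.yaml", "model.npz",
      TrainConfig(epochs=10, lr=3e-3, max_steps=200, seed=1),
      model_config=ModelConfig(seed=1))
df = evaluate("model.npz", "data/val/manifest.yaml")
print(df[df["id"] == "mean"][["disc_f1", "cup_f1", "disc_ble", "cup_ble",
                              "cdr_pred", "cdr_gt"]])
```

200 optimizer steps on 40 synthetic scenes are enough for the desk-scale
recipe (lr 3e-3, rare-class head initialization) to segment held-out
synthetic scenes well; a run of the acceptance pipeline printed

```
disc_f1 0.9748   cup_f1 0.7221   disc_ble_px 0.649   cup_ble_px 3.153
cdr_mae 0.0656
```

i.e. the disc boundary is recovered to sub-pixel radial error, the
(much smaller) cup to about 3 px, and the derived cup-to-disc ratio is off
by ≈ 0.07 on average — at a training budget several orders of magnitude
below the full-scale recipe (100 epochs at batch 1, which the defaults in
`TrainConfig` encode).

The same CLI is available as `fundusseg synth | pretrain | train | eval |
predict`.

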