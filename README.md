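# echomasa

Left-ventricle segmentation in echocardiography video with a
temporal-feature-fused Vision Retentive Network.

Echocardiography quantifies cardiac function from the left ventricle's
area at end-diastole (ED) and end-systole (ES) — the only frames
clinicians annotate. Segmenting those key frames is hard: speckle noise
blurs the endocardial border, contrast is low, and heart or probe motion
can push part of the ventricle out of the scan sector. This package
implements a video model that attacks both problems at once:

* a **Temporal Feature Fusion Module (TFFM)** applies self-attention over
  the fused temporal–channel axis of an 8-frame clip (4 frames before the
  key frame, 3 after), so boundary evidence visible in neighbouring frames
  sharpens the key frame, followed by a channel-aggregation stage that
  injects complementary inter-frame features;
* a **Vision RetNet encoder** whose Manhattan self-attention (MaSA)
  multiplies attention weights with an explicit spatial prior
  `D[n,m] = γ^(|xₙ−xₘ| + |yₙ−yₘ|)` — softmax attention with exponential
  decay in the Manhattan distance between token coordinates. Stages 1–3
  use a decomposed form (two 1D attentions, one per image axis) that never
  builds the N×N decay matrix; stage 4 uses the full 2D form:

  ```
  full:        MaSA(X) = (softmax(QKᵀ) ⊙ D_2d) V
  decomposed:  Attn_H = softmax(Q K ᵀ)|rows ⊙ γ^|Δy| ,  Attn_W analogous with γ^|Δx|
  ```

* an **FPN decoder** that projects the four encoder scales to a common
  width, upsamples to the finest level, sums, and predicts the key-frame
  mask through a small head.

Everything runs on a compact numpy autodiff core inside the package
(`echomasa.nn`: conv/attention/bilinear primitives with reverse-mode
gradients, AdamW) — no GPU or deep-learning framework required. Evaluation
uses the field's standard Dice similarity coefficient (DSC) and
95th-percentile Hausdorff distance (HD95, in pixels). A synthetic
echo-phantom generator (pulsating ellipse, multiplicative speckle, scan
sector, out-of-view truncation) makes the whole pipeline trainable and
testable without downloading data; readers for EchoNet-Dynamic-style
(videos + tracing tables) and CAMUS-style (MetaImage volumes) layouts are
included.

## Worked example

Train the reduced configuration on a 64-clip synthetic corpus and evaluate
on the held-out split (about a minute on one CPU):

```python
from echomasa import (PhantomConfig, generate_corpus, assemble_model,
                      ModelConfig, TrainConfig, fit)
from echomasa.data import clip_items
from echomasa.metrics import evaluate_model

recs, splits = generate_corpus(64, PhantomConfig(image_size=64), seed=11)
train_recs = [r for r, s in zip(recs, splits) if s == "TRAIN"]
test_recs  = [r for r, s in zip(recs, splits) if s == "TEST"]

model = assemble_model(ModelConfig.reduced(image_size=64, channels=1), seed=1)
fit(model, clip_items(train_recs, channels=1),
    TrainConfig(lr=1e-3, epochs=10, batch_size=1, augment=False, milestones=(8,)))

report = evaluate_model(model, clip_items(test_recs, channels=1))
print(f"held-out key frames: {len(report.dsc)}")
print(f"held-out mean DSC  {report.mean_dsc:.3f}")
print(f"held-out mean HD95 {report.mean_hd95:.2f} px")
```

prints

```
held-out key frames: 22
held-out mean DSC  0.918
held-out mean HD95 1.84 px
```

i.e. on 22 held-out annotated key frames (ED and ES of 11 test clips) the
predicted masks overlap the ground truth at Dice 0.92, with a robust
boundary error under 2 pixels. The same workflow is available from the
shell via `echomasa generate / train / evaluate / predict /
inspect-config`; model and phantom hyperparameters live in YAML configs
(`echomasa inspect-config --reduced`).

See `docs/methods.md` for the model conventions (token ordering, decay
factorization, head parameterizations), the training protocol, what the
phantom does and does not emulate, and known limitations.

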