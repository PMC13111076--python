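# rtsnet

Thyroid-ultrasound nodule segmentation with a hierarchical transformer
encoder, a cascaded KNN-graph-convolution decoder, and serial dual-path
(spatial + channel) attention — plus a synthetic ultrasound phantom
generator so the entire pipeline trains, evaluates and tests without any
external data.

## The problem

B-mode thyroid ultrasound is the first-line exam for nodule detection,
but the images are hard: multiplicative speckle, low lesion/parenchyma
contrast, and acoustic artifacts such as posterior shadowing. The
network implemented here (RTS-Net) addresses this with three ideas:

1. **Hierarchical transformer encoder** (PVT-v2-b2 design) producing a
   four-level feature pyramid at strides 4/8/16/32 with channels
   64/128/320/512 — global context at every scale.
2. **Dynamic KNN-graph convolution in the decoder.** Feature pixels are
   treated as graph nodes; a k-nearest-neighbour graph is rebuilt from
   feature distances at every forward pass and aggregated with
   max-relative convolution,
   `GCB(x) = R(BN(C(GConv(R(BN(C(x)))))))`, `GConv = GELU(BN(DynConv))`,
   imposing a soft spatial-coherence prior on the prediction.
3. **Serial dual-path attention.** Softmax-factorised spatial attention
   `E(Q,K,V) = ρ_q(Q)(ρ_k(K)ᵀV)` — linear in the number of positions —
   suppresses background first; channel-transpose attention
   `C(Q,K,V) = V·softmax(KᵀQ/r)` with a learnable temperature `r` then
   recalibrates channel responses.

Four deep-supervision heads (one per decoder stage) are upsampled to
input resolution and merged; training minimises the mean of their Dice
losses `L = 1 − 2Σp·g / (Σp + Σg)` under SGD (momentum 0.9, weight
decay 5e-4, lr 0.01 with polynomial decay of power 0.9). Evaluation
reports IoU, Dice, accuracy, precision, recall, F1, the 95th-percentile
Hausdorff boundary distance, and pixel AUC.

The compute core is a compact reverse-mode autodiff engine over NumPy
(`rtsnet.nn`), gradient-checked against finite differences, so the
package has no deep-learning-framework dependency.

## Worked example

Generate phantoms, train the quarter-width model on the CPU, and
evaluate — either through the library:

```python
from rtsnet import PhantomConfig, TrainConfig
from rtsnet.train import phantom_dataset, fit, evaluate

train = phantom_dataset(PhantomConfig(seed=0), 200)    # 96x96 phantoms
val   = phantom_dataset(PhantomConfig(seed=10_000), 50)
cfg = TrainConfig(variant="tiny", image_size=96, batch_size=8,
                  max_iterations=375, seed=0)          # 15 epochs
model, log = fit(cfg, train, val)
report = evaluate(model, val, cfg)
print(report.aggregates["mean_per_image"])
```

which printed, on the run recorded in this repository's documentation:

```
{'iou': 0.8383, 'dice': 0.9067, 'accuracy': 0.9813, 'precision': 0.9291,
 'recall': 0.9010, 'f1': 0.9067, 'hd95': 4.8366, 'auc': 0.9972}
```

Read: the tiny model reaches a mean per-image IoU of 0.84 on held-out
phantoms (an all-foreground baseline scores 0.11), with a mean HD95
boundary error under 5 pixels. Or through the CLI:

```bash
rtsnet phantom --n 200 --out data/train --seed 0 --image-size 96
rtsnet phantom --n 50  --out data/val   --seed 10000 --image-size 96
rtsnet train --data data --out run --variant tiny --image-size 96 \
             --batch-size 8 --max-iterations 375 --seed 0
rtsnet eval --checkpoint run/checkpoint.npz --data data/val --out report
rtsnet predict --checkpoint run/checkpoint.npz --data data/val --out masks
```

`report/metrics.json` holds both aggregation modes (mean per image and
dataset-pooled counts); `report/metrics.csv` the per-image rows.

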