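# mscnet

Multi-task retinal image analysis: vessel segmentation plus per-pixel
artery/vein (A/V) classification for fundus photographs, implemented as a
tested library and CLI with a synthetic data generator so the whole pipeline
runs end-to-end on a laptop CPU.

The network has three chained stages:

1. **MVE** — a U-shaped encoder/decoder for vessel segmentation whose encoder
   stages are split-concat residual blocks: channels are split into subsets
   processed by a cascade of small 3×3 convolutions with cross-subset
   concatenation, enlarging the receptive field at low parameter cost.
2. **MAE** — a U-shaped hybrid for A/V classification consuming the raw RGB
   image concatenated with the MVE vessel probability. Its encoder stages add
   a contextual-attention block that replaces the quadratic query–key product
   with concatenation: a grouped convolution of the keys produces a *static*
   context; 1×1 convolutions over concat(static, query) yield per-pixel,
   per-group softmax weights over a small local neighborhood; the *dynamic*
   context aggregates the values under those weights. Cost is linear in
   pixel count.
3. **MFI** — fuses the two streams. The vessel probability map is passed
   through the activation `F(x) = exp(-|x - 0.5|) - exp(-0.5)` (peaks at
   vessel boundaries / micro-vessels, vanishes for confident background and
   thick-vessel interiors) and combined with the MAE logits and features by a
   residual refinement head that is an exact identity at initialization.

Training minimizes `L = L_v + L_a` with `L_v = BCE + 0.1 · Dice` on the
vessel probability and `L_a` a masked cross-entropy over
{background, artery, vein} that ignores pixels annotated as *uncertain*.

All tensor operations run on a small numpy-based reverse-mode autodiff engine
(`mscnet._nn`) — no deep-learning framework is required. This keeps the
package self-contained at the reduced scales it targets; it is not intended
for full-resolution, GPU-scale training.

## Tests

```bash
python -m pytest tests/
```

The suite includes brute-force loop oracles for the residual and attention
blocks, property tests (hypothesis) for the geometry and metric code, and two
training-based acceptance tests that each train a reduced-width network on
synthetic data (several minutes of CPU each).

## CLI

```bash
# generate a synthetic dataset (images + masks + A/V labels + manifest.json)
msc synth --out data/ --n 16 --size 256 --seed 7

# train (config is optional YAML; defaults follow the published recipe:
# Adam, lr 0.001, 256x256 patches, rotation + Gaussian-noise augmentation;
# see configs/reduced.yaml for a CPU-scale example with all keys)
msc train --manifest data/manifest.json --out runs/exp1 --config configs/reduced.yaml

# tiled inference: ordered patches, predictions stitched back losslessly
msc predict --ckpt runs/exp1/best.npz --images data/sample_000.png --out preds/

# pooled Sen/Spe/Acc/F1 for vessel (vessel = positive) and A/V
# (artery = positive, vein = negative, evaluated on labelled A/V pixels)
msc evaluate --pred preds/ --gt data/manifest.json --out report.json
```

Label images use red = artery, blue = vein, green = uncertain, black =
background; vessel masks are white-on-black.

## Layout

```
src/mscnet/
  _nn/                 numpy autodiff engine, layers, Adam
  io_datasets.py       image/mask/label I/O, canonical color coding
  synthetic_fundus.py  seeded synthetic sample/dataset generator
  preprocessing.py     CLAHE green channel, patching, tiling, augmentation
  mve.py               vessel-extraction network (split-concat blocks)
  mae.py               A/V-extraction network (contextual attention)
  mfi.py               enhancement activation + fusion head
  objectives_metrics.py losses, confusion counts, Sen/Spe/Acc/F1
  model.py             chained three-stage network, checkpoints
  pipeline_cli.py      training loop, tiled inference, evaluation, CLI
  experiments.py       desk-scale synthetic train/eval experiments
```
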