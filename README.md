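# nucleiseg

Segmentation of cell nuclei in bright/dark-field microscopy images with a
light-weight, encoder-enhanced U-Net ("U-Net+"), built for settings where
compute is scarce: the model family is small (0.4–2.3 M weights), runs on
CPU, and the whole pipeline — synthetic data, preprocessing, patching,
training, tiled inference, per-cell evaluation — works end to end without
any external dataset or deep-learning framework.

It is aimed at researchers and engineers who need accurate nucleus masks
from grayscale microscopy (cell counting, phenotyping, downstream
morphometry) on modest hardware, and at anyone studying how encoder skip
topology affects small segmentation networks.

## The model

All networks map a 256×256 grayscale patch to a per-pixel nucleus
probability via sigmoid, with 2^(n−1)·B filters at level n = 1..N
(N = 5).  The core architecture, `unet_plus`, replaces the plain encoder
of U-Net with a dense triangular grid: each level carries a chain of
convolution blocks (conv 3×3 – batch norm – ReLU), and every chain block
concatenates its predecessor with a stride-2 down-sampled feature from
the level above, so fine, high-resolution detail is repeatedly fused into
deeper representations before decoding — the boundary of a nucleus is
where such networks typically fail.  The decoder is U-Net-like, with
either transposed-convolution (halves channels) or repetition up-sampling
(preserves them).  Reference `unet` and `unet_pp` (nested-skip U-Net++)
builders are included for controlled comparison.

Training minimizes, over a batch of M patches,

    L = λ_BCE · BCE(y, p) + (1/M) Σᵢ −log D(yᵢ, pᵢ),
    D(y, p) = (2|y ∩ p| + s) / (|y| + |p| + s)      (soft Dice),

with Adam (lr 5e−4), best-validation-loss checkpointing and optional
fine-tuning.  Whole images are predicted by 256×256 tiling with
overlap-max fusion, thresholded at 0.5, cleaned morphologically, and
evaluated per cell: IOU-based one-to-one matching at thresholds
0.50–0.95 and AP₅₀:₉₅-style precision TP/(TP+FN+FP) averaged over
thresholds.

## Worked example

Count weights and inspect the architecture:

```sh
$ nucleiseg summarize --arch unet_plus -B 16 --mode transposed_conv | tail -1
Total weights: 1,926,129 (1.926 M)
```

The four builders at B = 16 / B = 8 give 1.941/0.486 M (`unet`),
2.262/0.566 M (`unet_pp`), 1.926/0.484 M (`unet_plus`, transposed conv)
and 1.730/0.435 M (`unet_plus`, up-sampling) — U-Net+ is the smallest of
the three at equal width.

Close the full loop on synthetic data (about five minutes on one CPU
core):

```python
import numpy as np
import nucleiseg as ns
from nucleiseg.training import TrainConfig, train, dice_coefficient

cfg = ns.SynthConfig(seed=7)                     # elliptical nuclei, uneven
pairs = [ns.generate_sample(cfg, i) for i in range(8)]   # illumination, noise
x = np.stack([im for im, _ in pairs]).astype(np.float32)
t = np.stack([(mk > 0) for _, mk in pairs]).astype(np.float32)

model = ns.build_model(ns.ModelConfig(arch="unet_plus", base_filters=8))
model, hist = train(model, (x, t), None,
                    TrainConfig(lr=5e-3, epochs=30, batch_size=1, seed=0))

dice = np.mean([dice_coefficient(t[i], model.predict(x[i:i+1][..., None])[0, :, :, 0])
                for i in range(8)])
post = ns.PostprocConfig(min_object_area=100, max_hole_area=100)
preds = [(mk, ns.label_instances(ns.binarize_and_clean(
              ns.predict_image(model, im.astype(np.float32), preproc=None), post)))
         for im, mk in pairs]
rep = ns.evaluate_dataset(preds)
print(f"soft Dice {dice:.3f}  per-cell IOU {rep['mean_iou']:.3f}  "
      f"precision {rep['mean_precision_pct']:.1f}%")
```

prints

```
soft Dice 0.977  per-cell IOU 0.999  precision 100.0%
```

i.e. after 30 epochs the network reproduces its training masks almost
pixel-perfectly (soft Dice 0.98), and after thresholding and cleanup
every synthetic nucleus is recovered with essentially full overlap —
the capacity and plumbing check for the whole pipeline.

The same stages are available as a CLI for real datasets in the
per-sample `images/`+`masks/` directory layout (run-length CSV masks are
also supported):

```sh
nucleiseg synth --out data/ --n 16
nucleiseg prepare --data data/ --out patches/
nucleiseg train --patches patches/ --out run/
nucleiseg predict --model run/model.npz --data data/ --out preds/ --rle-csv preds.csv
nucleiseg evaluate --pred preds/ --gt data/ --out report.json
```

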