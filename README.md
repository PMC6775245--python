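# earcount

Counting wheat ears (spikes) in overhead canopy RGB photographs, and
converting the count to ear density (ears/m²) — a yield component that field
phenotyping campaigns otherwise measure by hand.

The package implements a two-branch counting tool:

* **Learned pipeline** — the image is partitioned into ~equally sized,
  color-homogeneous superpixels by SLIC (localized k-means over
  `(l, a, b, x, y)` with spectral–spatial distance
  `D = sqrt(d_lab² + (m/S)²·d_xy²)`); each superpixel crop is resized to the
  network input and classified pixel-wise (ear vs background) by a U-Net
  whose encoder is a VGG-style stack of 3×3 convolutions with four 2×2
  max-pools, a single-convolution bottleneck, and a decoder of 2× up-sampling
  + skip concatenations; the stitched probability map is thresholded,
  denoised with a 7×7 sliding median, and touching ears are separated by
  marker-based watershed on the Euclidean distance transform. Each surviving
  contour is one ear.
* **Edge baseline** — the classical handcrafted alternative: grayscale →
  Sobel gradient magnitude → threshold → elliptical dilation → hole filling
  → small-object removal → erosion → contour counting.

If the scene contains a ground standard (an A4 sheet of known physical area,
auto-detected or supplied as four corners), the count is scaled to ears/m²
via `ears / (H·W · physical_area / pixel_area)`.

Counts are evaluated with the usual paired statistics over reference `r_i`
and estimate `e_i`:

    RMSE  = sqrt(mean((r_i − e_i)²))
    rRMSE = sqrt(mean(((r_i − e_i)/r_i)²))
    bias  = mean(r_i − e_i)          (negative ⇒ over-counting)

plus R² and the regression line of reference on estimate.

Everything is exercised end-to-end on a bundled synthetic-canopy generator
(`earcount.synthetic`) that renders textured spike ellipses with optional awn
strokes over green/brown canopy texture, with illumination gradients,
shadows, blur, and an exact per-instance ground truth. The network is
implemented in numpy (im2col convolutions, manual backpropagation, Adam), so
training at desk scale runs on one CPU with no accelerator.

## Worked example

Train a desk-scale model on synthetic patches, then count a directory of
synthetic scenes:

```bash
earcount make-fixtures --out scenes --n-scenes 3 --seed 100
earcount train --synthetic 200 --epochs 10 --out run --seed 7
earcount count --method unet --checkpoint run/checkpoint.npz \
    --images scenes --superpixels 900 --out counts
earcount evaluate --pred counts/counts.csv --ref scenes/truth.csv
```

The training step prints its final validation quality:

```
final val accuracy 0.9878, val loss 0.0316
```

meaning 98.8% of validation pixels are labeled correctly. `counts/counts.csv`
holds one row per image (`id,count,ears_per_m2`; the density column is empty
unless a ground standard is given), with numbered overlay PNGs next to it:

```
id,count,ears_per_m2
scene_000,24,
scene_001,24,
scene_002,25,
```

All three scenes truly contain 24 ears, so the pipeline recovered two counts
exactly and over-counted one scene by a single ear. `evaluate` prints the
paired statistics:

```
n      = 3
RMSE   = 0.5774
rRMSE  = 2.4%
bias   = -0.3333
slope  = -1.468e-16
offset = 24
```

(2.4% relative RMSE; the slight negative bias is the one extra ear; R² is
omitted because the reference counts are all equal here, so it is
undefined). A scene with a reference sheet can be scaled to ears/m² with
`--standard auto` (or `--standard x0,y0,...,x3,y3`).

The same `count` command with `--method edge` runs the handcrafted baseline
for comparison.

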