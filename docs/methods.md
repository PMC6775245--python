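# Methods

## Overview

`earcount` estimates the number of wheat ears (spikes) visible in a
nadir-view canopy photograph, and, when a ground standard of known physical
size is visible, the ear density in ears/m². Two independent branches are
provided: a learned pipeline (superpixel partitioning, pixel-wise neural
classification, watershed instance separation) and a handcrafted
edge/morphology baseline. Both end in the same contour-counting and
reporting stages, so they are directly comparable with the bundled
count-regression statistics.

## Superpixel partitioning (SLIC)

The image is converted to CIELAB and clustered by localized k-means in the
5-D space `(l, a, b, x, y)`. Cluster seeds sit on an aspect-balanced grid
with spacing `S = sqrt(H·W/N)`, nudged to the lowest-gradient pixel in their
3×3 neighborhood so no seed starts on an edge. Each center competes only for
pixels within `±S` of itself using the squared spectral–spatial distance
`d_lab² + (m/S)²·d_xy²`; assignments and center means alternate for a fixed
10 iterations. Afterwards every 4-connected component becomes its own
region and components smaller than `min_region_fraction` (default 0.25) of
the mean superpixel area are merged into the neighbor with the longest
shared boundary, so the output is a partition into connected regions.

Parameters:

* `n_superpixels` (default 3000) — sized for multi-megapixel field images;
  desk-scale runs on 320 px synthetic scenes use N = 900, which preserves
  the superpixel-to-ear size ratio (superpixels a bit smaller than an ear).
* `compactness m` (default 10) — trade-off between boundary adherence
  (small m) and compact, square regions (large m). 10 is the conventional
  default for CIELAB inputs and is not critical here because ears and
  background differ strongly in color.
* On images small enough that `2S` reaches across the whole frame the
  windowed search degenerates to a global one; this makes the algorithm
  exactly equivalent to unwindowed 5-D k-means there, which is how the
  implementation is validated (the test oracle is an independent k-means).

Determinism: ties in the assignment go to the lowest center index;
relabeling after connectivity is by row-major first occurrence. Identical
inputs always produce identical maps.

## Pixel classification (U-Net with a VGG-style encoder)

Each superpixel's bounding-box crop is resized bilinearly to the network
input (224×224 at full scale) and classified per pixel. The encoder stacks
3×3 convolutions in four stages of 2, 2, 3, 3 layers (64/128/256/512
channels), each stage followed by 2×2 max pooling; a single 3×3 convolution
of 512 channels forms the bottleneck, so the deepest feature map is 1/16 of
the input on each side. The decoder mirrors the encoder with four stages of
nearest-neighbor 2× up-sampling, concatenation with the matching encoder
output, and two 3×3 convolutions; nearest-neighbor up-sampling plus
convolution is used instead of transposed convolution to avoid checkerboard
artifacts. A 1×1 convolution and sigmoid produce the per-pixel ear
probability.

Training minimizes mean binary cross-entropy (probabilities clipped at
1e-7) with Adam. The network, its gradients, and the optimizer are
implemented directly in numpy (im2col convolutions lowered to BLAS matrix
multiplies, manual backpropagation); gradients are verified against finite
differences in the test suite's development history and the loss against a
scalar-loop oracle. A `width_multiplier` scales every channel count for
desk-scale work: at 0.125 and 64×64 inputs the model has ~3.2×10⁵
parameters and trains in minutes on one CPU. Pretrained encoder weights are
not bundled; the `pretrained_encoder` flag exists for interface
compatibility and is refused.

Desk-scale training conditions (used by the tests and the acceptance
script): 200 generator patches (100 ear / 100 background) plus one randomly
augmented copy of each, an 80/20 split, 10 epochs, learning rate 1e-3,
batch size 8. This reaches ≈98% validation pixel accuracy. The full-scale
defaults (15 epochs, learning rate 1e-4) reflect the regime appropriate to
a corpus of hundreds of thousands of patches.

Predicted region maps are resized back to their boxes and stitched: only
pixels owned by a region's mask are written, and the stitcher asserts every
image pixel is written exactly once.

## From probability map to count

1. Threshold at 0.5 (the sigmoid midpoint; `binarize` exposes the value).
2. 7×7 sliding median filter (reflection at borders) to remove speckle
   misclassification. The window size is fixed by the method; consequently
   the synthetic scenes render ears several times wider than 7 px — at
   smaller ear scales the filter itself bridges between-ear gaps, which is
   a scale artifact, not a property of the method.
3. Euclidean distance transform of the foreground; markers are its regional
   maxima. For marker detection only, the transform is smoothed with a
   1 px Gaussian (pixelation bumps along an elongated ear's ridge would
   otherwise spawn spurious markers), and maxima closer than
   `min_peak_separation` are merged. The default separation is 0.8× the
   median inscribed radius of the foreground components (the per-component
   EDT maximum). An area-based equivalent diameter was rejected because it
   is inflated exactly when two ears merge into one component — the case
   the markers exist to fix. Components that end up without a marker get
   one at their EDT maximum.
4. Marker-based watershed on the negated distance transform, restricted to
   the foreground.
5. Components smaller than `min_area` (default 0.02% of the image pixels)
   are discarded; each survivor is traced as a closed contour and counted.

Known limitation: when two ears cross at a shallow angle their union has a
single thick core and the distance transform is unimodal — no marker policy
can split such a blob. Counts therefore under-estimate in heavily
overlapped canopies; the synthetic default keeps pairwise instance overlap
below 7% of the smaller instance's area (an overlap depth of roughly 30% of
the ear half-width), the regime in which watershed separation is reliable.

## Ear density and the ground standard

`ears_per_m2 = count / (H·W · physical_area / P)` where `P` is the pixel
area of the standard's quadrilateral (shoelace formula) and
`physical_area` defaults to an A4 sheet (0.210 m × 0.297 m = 0.06237 m²).
The formula is scale-invariant: doubling the image resolution quadruples
both `P` and `H·W` and leaves the density unchanged. Perspective is
ignored (nadir-view assumption); an obliquely placed sheet biases the
scale, which is a known error source of the protocol itself.

Auto-detection looks for the largest connected region with value ≥ 0.5 and
saturation ≤ 0.15 in HSV (a white sheet keeps near-zero saturation even in
shade, while vegetation is strongly saturated; the tight saturation gate
also excludes the blurred half-sheet halo at the edge), fits the
minimum-area rotated rectangle of its boundary pixel centers, and accepts
it if the region fills ≥ 80% of that rectangle. Anything else raises an
error that tells the user to supply the four corners manually.

## Edge-detection baseline

Grayscale (BT.601 weights) → 3×3 Sobel gradient magnitude → threshold
(Otsu by default; fixed values supported because a wrong threshold
distorts the result) → dilation with an elliptical structuring element
(default diameter 5, 2 iterations) to close broken edge rings → flood-fill
hole filling → removal of components below `min_object_area` (default
64 px) → one erosion → contour tracing and counting. Every intermediate is
exposed (`edge_stages`) and obeys set-inclusion contracts (dilation and
filling are extensive, erosion anti-extensive). The baseline is texture-
blind and, as expected, more sensitive to background clutter than the
learned pipeline.

## Synthetic canopy generator

The generator is the package's test bed and defines its study conditions.
A scene is: low-frequency green/brown mottle (coarse noise upsampled with
cubic interpolation) plus fine grain; rotated ellipses with golden base
color, sinusoidal intensity banding along the major axis (spikelet
texture), and optionally 5 thin pale awn strokes fanning from one tip
(blended at half strength — awns are sub-pixel thin in practice); an
illumination ramp (±20%), up to 3 soft Gaussian shadows (20% deep), and a
1 px Gaussian blur. An optional white, slightly rotated A4-proportioned
quadrilateral is rendered before ears are placed, and ears never overlap
it. Instance masks and labels are captured before blur and shading, so
ground truth is exact; the blur-after-capture is an idealization that
keeps mask edges crisp.

Defaults: 320×320 px, 24 ears with semi-axes 16–26 × 6–10 px, pairwise
area overlap ≤ 7%, awn probability 0.5. Rejection sampling enforces the
overlap limit (and, optionally, a minimum clearance used by the
well-separated fixture families); placement failure raises an error rather
than silently under-filling. Everything derives from one seed;
identical parameters reproduce byte-identical scenes.

What the generator does not emulate: perspective and lens distortion,
specular highlights, wind motion blur, leaves and stems as structured
distractors (the background is textured noise, not geometry), cultivar
differences, and the scale of real field images (tens of megapixels,
hundreds of ears). Passing tests on these scenes therefore demonstrate the
pipeline's mechanics — partitioning, learning, stitching, separation,
scaling — under controlled conditions, not field-level accuracy.

## Evaluation statistics

For paired reference/estimate counts: `RMSE = sqrt(mean((r−e)²))`,
`rRMSE = sqrt(mean(((r−e)/r)²))` (reference counts must be positive),
`bias = mean(r−e)` so over-counting yields a negative bias. R² is the
squared Pearson correlation; the regression line is fit with the reference
as ordinate (the orientation of plotting automatic against manual counts)
and is configurable, since R² itself is orientation-free.

## Numerical and degenerate-input choices

* Median filter: scipy's reflect mode, equal to symmetric padding; window
  must be odd.
* Probabilities are float32 in the network, float64 afterwards; the loss
  clips at 1e-7, so a perfect prediction scores ≤ 2·1e-7·|log 1e-7|.
* Empty masks count zero (not an error); empty superpixels keep their
  previous center; an all-equal gradient image leaves seeds on the grid.
* Max-pool gradient ties route to the first maximum, making training
  deterministic for fixed seeds on one CPU.
* 16-bit PNG is used for label maps (≤ 65535 regions).

## Desk-scale problem sizes

The bundled tests and the acceptance script run the whole study at sizes
chosen for a single CPU: 320 px scenes, 24 ears, N = 900 superpixels,
64×64 network inputs at width multiplier 0.125, 400 training patches, 10
epochs. These sizes are stated here as the package's reference desk
configuration; all of them scale up by changing the respective parameters.
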