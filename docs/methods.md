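# Methods

## Problem and model

`csfrtd` detects red tides (harmful algal blooms) in time series of
multispectral remote-sensing reflectance (Rrs, sr⁻¹) imagery with the eight
GOCI band centers 412/443/490/555/660/680/745/865 nm. Detection is pixelwise
binary segmentation of 32×32 patches, informed by two spectral indices:

* **Red-tide index** RI = (Rrs₅₅₅ − Rrs₄₄₃)/(Rrs₄₉₀ − Rrs₄₄₃), a blue-green
  band-ratio statistic (the same principle as blue-green chlorophyll
  ratios) that is elevated over bloom water. The printed form of this ratio
  is ambiguous about grouping; the band-ratio reading used here is the one
  consistent with its blue-green ratio rationale.
* **NDVI** = (Rrs₈₆₅ − Rrs₆₆₀)/(Rrs₈₆₅ + Rrs₆₆₀). Over open water both
  classes are negative, clear seawater more negative than bloom water; NDVI
  is appended to the six visible bands to form the 7-channel network input
  (bands 745/865 nm enter only through NDVI).

The detector (**CSF-RTDNet**) is a U-Net with three modifications:

1. a single-layer **ConvLSTM** stem (3×3 convolutional gates, hidden width =
   configurable, last-hidden-state readout) consuming the T-frame sequence;
2. **ECA** channel attention after each encoder stage: global average
   pooling → shared 1-D convolution across neighbouring channels → sigmoid →
   per-channel rescale. The 1-D kernel size is adaptive in the channel
   count: the largest odd integer ≤ |log₂C/γ + b/γ| (γ=2, b=1), minimum 1;
3. **ASPC-DSC** blocks replacing the plain double convolutions of encoder
   stages 1–3: parallel depthwise-separable 3×3 convolutions at dilations
   1/2/3 with 50/25/25 % of the output channels (stages 1–2) or dilations
   1/2 at 50/50 % (stage 3), concatenated and fused by a 1×1 convolution
   with batch normalisation and ReLU (no residual). Stacked dilated kernels
   grow the receptive field linearly in the summed rate,
   rf = 1 + (k−1)·Σdᵢ, so 3×3 kernels stacked at rates (1,2) see 7×7 and at
   (2,3) see 11×11; this composition rule is cross-checked in the tests by a
   gradient-footprint measurement on instantiated networks.

The encoder has four stages plus a bottleneck at twice the last stage width
(stage 4 and the bottleneck are plain double convolutions — only stages 1–3
are modified). Dropout (default rate 0.3) is applied at the bottleneck,
before upsampling. The decoder uses nearest-neighbour 2× upsampling, a 3×3
channel-reducing convolution, skip concatenation and a double convolution
per level; a 1×1 head emits 2-class logits at the input's spatial size.
ECA placement is encoder-only by default (a flag enables it in the decoder).
Ablation flags (`use_convlstm`, `use_eca`, `use_aspc`) recover the
intermediate architectures; disabling all three leaves the basic
single-frame U-Net baseline. A generic width-matched FCN-8s and a per-pixel
RBF-kernel SVM (scikit-learn) complete the baseline set.

All networks run on the package's own numpy autodiff core (`csfrtd.nn`):
float32, stride-1 same-padding convolutions, deterministic 2×2 max pooling
(row-major tie-break), and bit-reproducible results for a fixed seed.

## Datasets and labels

Scenes are tiled into 32×32 patches on a deterministic stride-4 grid
(count per axis = ⌊(dim−32)/4⌋+1), then shuffled under a seed — the reading
of "randomly divided with a stride" as deterministic tiling plus random
presentation order. For each patch position a sequence sample stacks the
patch's 7-channel features over the frame set of a dataset variant, in
chronological order; the **label is the final frame's mask** (training
labels end before the final acquisition day; the test sample ends at the
final frame, mirroring the held-out final-day convention). Variants over a
(days × frames-per-day) acquisition grid: DS1 = same hour on four
consecutive days (T=4); DS5 = four consecutive hours within the anchor day
(T=4); DS2/DS3 = DS1 plus the four morning hours of the window's first/third
day (T=8); DS4 = the same hour on four prior days plus four hours of the
anchor day (T=8).

Operational labels threshold the RI map (`LabelRule.ri_threshold`); pixels
invalid in the input or in an index denominator are labeled 0 and excluded
from the loss and all metrics. When simulator ground truth exists it is
preferred over thresholded labels. Features are z-scored per channel with
statistics from the training split only (Rrs is ~10⁻³–10⁻² sr⁻¹ while NDVI
is order 1, so unnormalised channels would be badly mixed in scale).

## Synthetic scenes

The simulator emulates what the method needs from real bloom imagery, not
radiative transfer. Two endmember spectra — blue-dominant clear water and
bloom water with a depressed blue, a green peak and a raised red edge, both
order 10⁻³–10⁻² sr⁻¹ — satisfy RI(bloom) > RI(water) and
NDVI(water) < NDVI(bloom) < 0. Bloom geometry covers the three qualitative
morphologies: compact (filled ellipses), strip (ellipses with axis ratio
≥ 4) and dispersed (clouds of 1–3-pixel speckles). Dynamics are linear:
area grows by (1+growth_rate) per frame (default 0.1/frame) and centers
drift by an integer pixel offset per frame — the simplest dynamics that make
frame order informative for the ConvLSTM. Pixel spectra are endmember +
i.i.d. per-band Gaussian noise truncated at zero (default σ = 10⁻⁴ sr⁻¹).
Clouds are invalid-pixel ellipses, never spectra. At the default noise
level, thresholding RI at the midpoint of the two endmember RI values
recovers ≥ 99 % of ground-truth pixels on clean frames; this bound is the
documented `NOISE_SD_SEPARABLE_BOUND`.

What the simulator does **not** reproduce: atmospheric and adjacency
effects, spatially correlated noise, spectral variability within a bloom,
mixed pixels at bloom edges beyond rasterisation, sensor georeferencing.
Passing benchmarks therefore demonstrate that the pipeline and architecture
work as specified under the assumed separability structure — not field
performance on real GOCI scenes.

## Training and evaluation

Adam with batch size 50 and dropout 0.3. The long-schedule default learning
rate is 1e-3; the scaled-down benchmark (see below) runs only ~80 optimiser
steps and uses 5e-3, since 1e-3 demonstrably underfits schedules this short.
The loss is masked pixelwise cross-entropy with inverse-frequency class
weights (w_k = N/(2N_k)) by default — bloom pixels are a small minority
(~8 % in the synthetic banks) and unweighted CE biases short schedules
toward the majority class. An optional validation tail of the training list
(val_fraction, default 0) drives best-checkpoint selection; with folds this
small the selection is noisy, so the default keeps the final state. A
non-finite loss aborts with a diagnostic. Training is deterministic given the seed (single-threaded
numpy; seeded shuffling, initialisation and dropout streams).

Metrics come exactly from pooled TP/FP/TN/FN counts over valid pixels:
accuracy, precision and recall in percent, plus Cohen's kappa
κ = (p_o − p_e)/(1 − p_e). A kappa shorthand sometimes printed in the
applied literature — counts divided by products of counts, without the N²
normalisation or the 1−p_e denominator — is dimensionally inconsistent with
Cohen's kappa; the standard form is used everywhere, and the shorthand is
retained as `verbatim_kappa` for audit only. Undefined
precision/recall (zero denominators) are reported as absent, never as 0 or
100. Full scenes are predicted by tiled inference with overlap resolved by
logit averaging, which is independent of tile visit order.

## Benchmark problem sizes

The synthetic benchmark trains on 200 independent single-patch sequences
(T=4, 32×32, mixed morphologies, seeded) for 20 epochs at reduced widths
(stages 8/16/32/64, ConvLSTM hidden 8) and evaluates on 50 held-out
sequences. The directional ablation (full model vs single-frame basic
U-Net, median recall over 5 seeds) repeats the same 200-sequence/20-epoch
recipe per seed and arm. These sizes are the package's CPU-scale study
conditions;
headline accuracies from the original GOCI experiments are not reproducible
without the proprietary scenes and bulletin-derived labels and are not
targeted.

## Numerical choices and edge cases

- Index denominators below ε = 10⁻⁹ sr⁻¹ (configurable) mark the pixel
  invalid rather than producing infinities; invalidity propagates to every
  derived product.
- Max-pool ties break to the first element in row-major order.
- Batch norm uses ε = 10⁻⁵ and momentum 0.1; evaluation uses running stats.
- ECA attention weights are strictly inside (0,1) (sigmoid), so attention
  never zeroes or amplifies a channel.
- A sequence of length 1 is accepted everywhere (the ConvLSTM degenerates
  to a single gated step).
- Seeds: one global seed fans out to named substreams (simulation,
  shuffling, initialisation) via SHA-256, all below 2³¹.

## Known limitations

- Because synthetic pixels are pure endmember spectra and the label is the
  final frame's mask, the final frame alone determines every label with
  strong spectral margin; single-frame baselines can therefore match the
  temporal model on this benchmark. Ordering comparisons between the full
  model and single-frame baselines on the synthetic bank operate at
  saturation and mostly measure seed noise — the regime where temporal
  fusion pays off (partially informative current-day imagery) requires real
  multi-day scenes outside this simulator's scope.
- The numpy training loop is CPU-bound and suited to the reduced-width
  benchmark scale, not to full-width 120-epoch runs.
- Nearest-neighbour upsampling plus convolution (instead of transposed
  convolution) slightly smooths mask boundaries.
- The FCN-8s baseline uses a generic width-matched backbone (the original
  VGG backbone is neither specified for this task nor appropriate at 32×32).
- GeoTIFF output is plain multiband TIFF with band metadata; georeferencing
  is out of scope.
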