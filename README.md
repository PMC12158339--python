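# csfrtd — spatiotemporal red-tide detection on ocean-color time series

Red tides (harmful algal blooms) discolor coastal water and damage
fisheries; geostationary ocean-color sensors such as GOCI image the same
sea area every hour in eight spectral bands (412–865 nm), which makes the
*temporal evolution* of a bloom observable, not just its spectral
signature. `csfrtd` implements a detection pipeline for such data:

* **Spectral indices.** The red-tide index
  RI = (Rrs₅₅₅ − Rrs₄₄₃)/(Rrs₄₉₀ − Rrs₄₄₃) is elevated over bloom water;
  NDVI = (Rrs₈₆₅ − Rrs₆₆₀)/(Rrs₈₆₅ + Rrs₆₆₀) is negative over open water
  with clear seawater more negative than blooms. The model input per frame
  is a 7-channel stack: the six visible bands plus NDVI.
* **Sequence datasets.** Scenes are tiled into 32×32 patches with stride 4;
  each sample stacks a patch over T frames (same hour across days, several
  hours within a day, or unions of both — variants DS1–DS5) and is labeled
  by the final frame, with the final acquisition held out for testing.
* **CSF-RTDNet.** A U-Net whose input first passes a ConvLSTM stem
  (convolutional-gate recurrence over the T frames), with efficient channel
  attention (ECA) after each encoder stage and dilated depthwise-separable
  pyramid blocks (ASPC-DSC, rates 1/2/3 at 50/25/25 % channels in stages
  1–2, rates 1/2 at 50/50 % in stage 3) in place of plain convolutions.
  Stacked dilations grow the receptive field as rf = 1 + (k−1)·Σdᵢ. Output
  is a per-pixel 2-class map at input size.
* **Baselines and metrics.** Single-frame basic U-Net, width-matched
  FCN-8s, and a per-pixel kernel SVM; evaluation by accuracy, precision,
  recall (percent) and Cohen's kappa from pooled confusion counts over
  valid pixels.
* **Synthetic scenes.** A seeded simulator produces 8-band reflectance
  series with ground-truth masks whose bloom/water spectra satisfy the
  index orderings above — compact, strip-shaped and dispersed blooms that
  grow and drift across frames, with optional cloud masks.

Networks run on a small numpy autodiff core inside the package
(`csfrtd.nn`); runs are deterministic given a seed.

## Worked example

```python
from csfrtd import BloomSimConfig, compute_ri, default_endmembers, simulate_series
from csfrtd.train_eval import run_benchmark

# a 64x64, 4-frame scene with one compact bloom
em = default_endmembers()
series = simulate_series(em, BloomSimConfig(height=64, width=64, n_frames=4,
                                            morphology="compact", seed=7))
ri = compute_ri(series.frames[0])
bloom = series.masks[0].astype(bool)
print(f"mean RI over bloom pixels  {ri.values[bloom].mean():.2f}")
print(f"mean RI over water pixels  {ri.values[~bloom].mean():.2f}")

# train the full model on 200 synthetic sequences and score 50 held-out ones
report, history = run_benchmark(seed=0, n_train=200, n_test=50, epochs=20)
print(f"held-out recall    {report.recall:.1f}%")
print(f"held-out precision {report.precision:.1f}%")
print(f"held-out kappa     {report.kappa:.3f}")
```

prints

```
mean RI over bloom pixels  3.27
mean RI over water pixels  1.50
held-out recall    99.8%
held-out precision 98.6%
held-out kappa     0.992
```

The RI gap (3.27 vs 1.50) is the separability the simulator guarantees by
construction: thresholding RI midway between the endmember values recovers
≥ 99 % of ground-truth pixels on clean frames. The benchmark numbers say
that, trained on 200 sequences for 20 epochs (a few minutes on one CPU at
reduced widths), the network recovers nearly all bloom pixels of unseen
scenes with chance-corrected agreement close to 1. The run takes a couple
of minutes; `run_benchmark(..., model="unet")` scores the single-frame
U-Net baseline on the identical data.

There is also a CLI: `csfrtd simulate | index | prepare | train | evaluate
| compare | run`, driven by a YAML config (see `csfrtd run --help`).

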