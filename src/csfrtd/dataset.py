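"""From labeled scene series to model-ready sequence samples.

Three stages:

1. **Labeling** — threshold the red-tide index map (or take simulator ground
   truth when available) to get a per-frame binary mask; invalid pixels are
   labeled 0 and excluded from the loss.
2. **Patching** — deterministic 32x32 sliding-window tiling with stride 4,
   then a seeded shuffle.
3. **Sequence assembly** — for each spatial patch, stack its 7-channel
   feature stacks over the temporal frame set of a dataset variant (DS1–DS5)
   in chronological order; the label comes from the final frame.  The test
   split is anchored at the series' final acquisition time, mirroring the
   held-out final-day evaluation convention; training anchors end on earlier
   days, so train and test labels never share an acquisition time.

Variant frame selections (over a days x frames-per-day acquisition grid):

======  =====================================================  ==
DS1     same hour on four consecutive days                     T=4
DS2     DS1 plus four morning hours of the window's 1st day    T=8
DS3     DS1 plus four morning hours of the window's 3rd day    T=8
DS4     same hour on four prior days plus four hours of the
        anchor day                                             T=8
DS5     four consecutive hours within the anchor day           T=4
======  =====================================================  ==
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .radiometry import FeatureStack, IndexMap, build_feature_stack
from .synthetic_scene import BloomSimConfig, SceneSeries, SpectralEndmembers, \
    default_endmembers, simulate_series

PATCH_SIZE = 32
PATCH_STRIDE = 4

VARIANTS = ("DS1", "DS2", "DS3", "DS4", "DS5")


@dataclass
class LabelRule:
    """RI-threshold labeling: bloom where RI >= ri_threshold on valid pixels."""

    ri_threshold: float
    require_valid: bool = True


@dataclass
class SequenceSample:
    """One training/evaluation unit: a T x 32 x 32 x 7 input sequence with the
    binary label of its final frame (and that frame's validity mask)."""

    x: np.ndarray                 # (T, size, size, 7)
    y: np.ndarray                 # (size, size) in {0,1}
    valid: np.ndarray             # (size, size) bool, final frame
    frame_times: list[str] = field(default_factory=list)
    footprint: tuple = ()         # (top, left, anchor) identifier

    def __post_init__(self):
        if self.x.ndim != 4 or self.x.shape[3] != 7:
            raise ValueError(f"x must be T x H x W x 7, got {self.x.shape}")
        if self.y.shape != self.x.shape[1:3]:
            raise ValueError("label must match patch spatial dims")


@dataclass
class DatasetSplit:
    train: list[SequenceSample]
    test: list[SequenceSample]
    variant: str
    normalization_stats: dict | None = None   # {"mean": (7,), "sd": (7,)}


# ---------------------------------------------------------------------------
# Labeling
# ---------------------------------------------------------------------------

def generate_labels(ri: IndexMap, rule: LabelRule) -> tuple[np.ndarray, np.ndarray]:
    """Binary mask from an RI map plus the per-pixel inclusion mask.

    Returns (labels, included): labels is 1 where RI >= threshold on valid
    pixels; invalid pixels get label 0 and included=False so they are
    excluded from the loss and from metrics.
    """
    if ri.kind != "RI":
        raise ValueError(f"labeling expects an RI map, got {ri.kind}")
    included = ri.valid if rule.require_valid else np.ones_like(ri.valid)
    labels = ((ri.values >= rule.ri_threshold) & included).astype(np.uint8)
    return labels, included


# ---------------------------------------------------------------------------
# Patching
# ---------------------------------------------------------------------------

def patch_grid(height: int, width: int, size: int = PATCH_SIZE,
               stride: int = PATCH_STRIDE) -> list[tuple[int, int]]:
    """Top-left anchors of the sliding-window grid.

    Count per axis is floor((dim - size)/stride) + 1; raises if the scene is
    smaller than one window.
    """
    if height < size or width < size:
        raise ValueError(f"scene {height}x{width} smaller than patch size {size}")
    tops = range(0, height - size + 1, stride)
    lefts = range(0, width - size + 1, stride)
    return [(t, l) for t in tops for l in lefts]


def extract_patches(stack: FeatureStack, mask: np.ndarray,
                    size: int = PATCH_SIZE, stride: int = PATCH_STRIDE,
                    seed: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Tile one frame's feature stack and label mask into (patch, label) pairs.

    Deterministic stride tiling, then a seeded shuffle when `seed` is given
    ("randomly divided" = random presentation order of a fixed tiling).
    """
    H, W = stack.features.shape[:2]
    pairs = [(stack.features[t:t + size, l:l + size],
              np.asarray(mask)[t:t + size, l:l + size])
             for t, l in patch_grid(H, W, size, stride)]
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(pairs))
        pairs = [pairs[i] for i in order]
    return pairs


# ---------------------------------------------------------------------------
# Variant frame selection
# ---------------------------------------------------------------------------

def variant_frame_indices(variant: str, anchor: int, frames_per_day: int) -> list[int]:
    """Chronological frame indices for one sample ending at frame `anchor`.

    Raises ValueError when the series grid cannot support the variant at this
    anchor (too few prior days/hours).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    fpd = frames_per_day
    day, hour = divmod(anchor, fpd)

    def daily(n_days: int, end_day: int) -> list[int]:
        if end_day - (n_days - 1) < 0:
            raise ValueError(
                f"{variant} needs {n_days} days ending day {end_day}; series too short")
        return [(end_day - k) * fpd + hour for k in range(n_days - 1, -1, -1)]

    def hours(day_i: int, end_hour: int, n: int = 4) -> list[int]:
        if end_hour - (n - 1) < 0 or fpd < n:
            raise ValueError(f"{variant} needs {n} hours within a day "
                             f"(frames_per_day={fpd}, hour={end_hour})")
        return [day_i * fpd + h for h in range(end_hour - n + 1, end_hour + 1)]

    if variant == "DS1":
        idx = daily(4, day)
    elif variant == "DS5":
        idx = hours(day, hour)
    elif variant == "DS2":
        idx = sorted(set(daily(4, day)) | set(hours(day - 3, fpd - 1)))
    elif variant == "DS3":
        idx = sorted(set(daily(4, day)) | set(hours(day - 1, fpd - 1)))
    else:  # DS4: four prior days at this hour, plus four hours of the anchor day
        if day < 4:
            raise ValueError("DS4 needs four days before the anchor day")
        prior = [(day - k) * fpd + hour for k in range(4, 0, -1)]
        idx = sorted(set(prior) | set(hours(day, hour)))
    if idx[-1] != anchor:
        raise AssertionError("variant selection must end at the anchor frame")
    return idx


def variant_seq_len(variant: str) -> int:
    return {"DS1": 4, "DS2": 8, "DS3": 8, "DS4": 8, "DS5": 4}[variant]


# ---------------------------------------------------------------------------
# Sequence assembly
# ---------------------------------------------------------------------------

def _series_stacks(series: SceneSeries) -> list[FeatureStack]:
    return [build_feature_stack(f) for f in series.frames]


def compute_normalization(samples: list[SequenceSample]) -> dict:
    """Per-channel mean/sd over all training pixels (sd floored at 1e-12)."""
    data = np.concatenate([s.x.reshape(-1, 7) for s in samples], axis=0)
    sd = data.std(axis=0)
    return {"mean": data.mean(axis=0), "sd": np.maximum(sd, 1e-12)}


def normalize_x(x: np.ndarray, stats: dict) -> np.ndarray:
    return (x - stats["mean"]) / stats["sd"]


def assemble_sequences(series: SceneSeries, variant: str,
                       labels: list[np.ndarray] | None = None,
                       size: int = PATCH_SIZE, stride: int = PATCH_STRIDE,
                       seed: int = 0) -> DatasetSplit:
    """Build a DS-variant train/test split from one labeled scene series.

    `labels` defaults to the series' ground-truth masks.  Training samples
    anchor at every feasible frame whose day precedes the final day; the test
    sample set anchors at the final frame only.
    """
    if labels is None:
        labels = series.masks
    F = len(series)
    fpd = series.frames_per_day
    stacks = _series_stacks(series)
    H, W = series.frames[0].rrs.shape[:2]
    grid = patch_grid(H, W, size, stride)
    last_day = (F - 1) // fpd

    def feasible(anchor: int) -> bool:
        try:
            variant_frame_indices(variant, anchor, fpd)
            return True
        except ValueError:
            return False

    train_anchors = [a for a in range(F) if a // fpd < last_day and feasible(a)]
    test_anchors = [F - 1] if feasible(F - 1) else []
    if not train_anchors or not test_anchors:
        need = variant_seq_len(variant)
        raise ValueError(
            f"series too short for variant {variant}: needs T={need} frames "
            f"with feasible train/test anchors (got {F} frames, "
            f"{fpd} frames/day)")

    def build(anchors: list[int]) -> list[SequenceSample]:
        out = []
        for a in anchors:
            idx = variant_frame_indices(variant, a, fpd)
            for top, left in grid:
                x = np.stack([stacks[i].features[top:top + size, left:left + size]
                              for i in idx])
                y = np.asarray(labels[a])[top:top + size, left:left + size]
                v = series.valid[a][top:top + size, left:left + size] \
                    & stacks[a].valid[top:top + size, left:left + size]
                out.append(SequenceSample(
                    x=x, y=y.astype(np.uint8), valid=v,
                    frame_times=[series.frames[i].timestamp for i in idx],
                    footprint=(top, left, a)))
        return out

    train = build(train_anchors)
    test = build(test_anchors)
    rng = np.random.default_rng(seed)
    train = [train[i] for i in rng.permutation(len(train))]
    split = DatasetSplit(train=train, test=test, variant=variant)
    split.normalization_stats = compute_normalization(train)
    return split


# ---------------------------------------------------------------------------
# Synthetic sequence bank (independent 32x32 series)
# ---------------------------------------------------------------------------

def make_sequence_bank(n_train: int, n_test: int, seed: int,
                       seq_len: int = 4, size: int = PATCH_SIZE,
                       endmembers: SpectralEndmembers | None = None,
                       variant: str = "DS4") -> DatasetSplit:
    """A bank of independent single-patch bloom sequences for benchmarking.

    Each sample is its own simulated 32x32 scene series of `seq_len` frames
    with mixed morphologies (compact / strip / dispersed cycling, with
    occasional bloom-free scenes), labeled by the simulator's ground truth on
    the final frame.  Normalization statistics come from the training portion
    only.
    """
    endmembers = endmembers or default_endmembers()
    root = np.random.default_rng(seed)
    morphs = ("compact", "strip", "dispersed", "mixed")

    def draw(n: int, tag: int) -> list[SequenceSample]:
        samples = []
        for i in range(n):
            sub_seed = int(root.integers(0, 2 ** 31 - 1))
            r = np.random.default_rng(sub_seed)
            n_blooms = 0 if r.random() < 0.1 else int(r.integers(1, 3))
            cfg = BloomSimConfig(
                height=size, width=size, n_frames=seq_len,
                morphology=morphs[i % len(morphs)], n_blooms=n_blooms,
                growth_rate=float(r.uniform(0.05, 0.2)),
                drift=(int(r.integers(-1, 2)), int(r.integers(-1, 2))),
                cloud_fraction=0.0, seed=sub_seed)
            series = simulate_series(endmembers, cfg)
            stacks = _series_stacks(series)
            samples.append(SequenceSample(
                x=np.stack([s.features for s in stacks]),
                y=series.masks[-1].astype(np.uint8),
                valid=series.valid[-1] & stacks[-1].valid,
                frame_times=[f.timestamp for f in series.frames],
                footprint=(0, 0, tag * 10 ** 6 + i)))
        return samples

    train = draw(n_train, 0)
    test = draw(n_test, 1)
    split = DatasetSplit(train=train, test=test, variant=variant)
    split.normalization_stats = compute_normalization(train)
    return split


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_split(split: DatasetSplit, nc_path, manifest_path=None) -> None:
    """Persist a split as NetCDF (sample, time, y, x, channel) + JSON manifest."""
    import xarray as xr

    def pack(samples, name):
        if not samples:
            return {}
        return {
            f"{name}_x": (("s_" + name, "time", "y", "x", "channel"),
                          np.stack([s.x for s in samples]).astype(np.float32)),
            f"{name}_y": (("s_" + name, "y", "x"),
                          np.stack([s.y for s in samples]).astype(np.int8)),
            f"{name}_valid": (("s_" + name, "y", "x"),
                              np.stack([s.valid for s in samples]).astype(np.int8)),
        }

    ds = xr.Dataset({**pack(split.train, "train"), **pack(split.test, "test")})
    ds.attrs["variant"] = split.variant
    ds.to_netcdf(str(nc_path), engine="scipy")
    if manifest_path is not None:
        stats = split.normalization_stats
        manifest = {
            "variant": split.variant,
            "n_train": len(split.train),
            "n_test": len(split.test),
            "normalization": None if stats is None else
                {"mean": list(map(float, stats["mean"])),
                 "sd": list(map(float, stats["sd"]))},
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)


def load_split(nc_path, manifest_path=None) -> DatasetSplit:
    """Reload a persisted split (inverse of save_split; footprints and frame
    times are not round-tripped)."""
    import xarray as xr

    with xr.open_dataset(str(nc_path), engine="scipy") as ds:
        parts = {}
        for name in ("train", "test"):
            if f"{name}_x" not in ds:
                parts[name] = []
                continue
            xs = ds[f"{name}_x"].values
            ys = ds[f"{name}_y"].values.astype(np.uint8)
            vs = ds[f"{name}_valid"].values.astype(bool)
            parts[name] = [SequenceSample(x=xs[i], y=ys[i], valid=vs[i])
                           for i in range(xs.shape[0])]
        variant = str(ds.attrs.get("variant", "DS1"))
    split = DatasetSplit(train=parts["train"], test=parts["test"],
                         variant=variant)
    if manifest_path is not None:
        with open(manifest_path) as fh:
            norm = json.load(fh).get("normalization")
        if norm:
            split.normalization_stats = {
                "mean": np.asarray(norm["mean"]), "sd": np.asarray(norm["sd"])}
    elif split.train:
        split.normalization_stats = compute_normalization(split.train)
    return split
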