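"""Training, inference and evaluation for the detection networks.

Optimisation follows the experimental recipe of the method: Adam, batch size
50, dropout 0.3, with masked pixelwise cross-entropy (invalid pixels carry no
loss or gradient).  Evaluation reports accuracy, precision and recall as
percentages plus Cohen's kappa, all recomputed exactly from a TP/FP/TN/FN
confusion accumulator over valid pixels.

Full-scene prediction tiles the scene into 32x32 patches and resolves
overlapping tiles by averaging logits, which makes the mosaic independent of
tile visit order.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import (DatasetSplit, SequenceSample, make_sequence_bank,
                      normalize_x)
from .network import (CSFRTDNet, NetworkConfig, SVMBaseline,
                      build_csf_rtdnet, build_unet_baseline)

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "MetricsReport",
    "train",
    "predict",
    "predict_scene",
    "confusion_counts",
    "compute_metrics",
    "verbatim_kappa",
    "compare_methods",
    "render_detection_map",
    "evaluate_model",
    "benchmark_network_config",
    "run_benchmark",
]


@dataclass
class TrainConfig:
    """Optimisation settings (Adam; defaults follow the reference recipe
    except epochs, which callers scale to their problem size)."""

    batch_size: int = 50
    epochs: int = 120
    dropout: float = 0.3
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.0
    class_weight: str | None = "balanced"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    """Percent-scale accuracy/precision/recall plus Cohen's kappa.

    precision is None when no pixel was predicted positive and recall is None
    when no pixel is truly positive (undefined, never reported as 0 or 100).
    """

    accuracy: float
    precision: float | None
    recall: float | None
    kappa: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "kappa": self.kappa,
                "tp": self.counts.tp, "fp": self.counts.fp,
                "tn": self.counts.tn, "fn": self.counts.fn}


def confusion_counts(pred: np.ndarray, truth: np.ndarray,
                     valid: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts over valid pixels; TP+FP+TN+FN = #valid."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if valid is None:
        valid = np.ones(pred.shape, dtype=bool)
    valid = np.asarray(valid).astype(bool)
    if valid.shape != pred.shape:
        raise ValueError("valid mask shape mismatch")
    return ConfusionCounts(
        tp=int((pred & truth & valid).sum()),
        fp=int((pred & ~truth & valid).sum()),
        tn=int((~pred & ~truth & valid).sum()),
        fn=int((~pred & truth & valid).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy/precision/recall (percent) and Cohen's kappa from counts.

    kappa = (p_o - p_e) / (1 - p_e), p_o the observed agreement and p_e the
    chance agreement from the marginals; kappa = 1 when agreement is perfect
    (p_e = 1 degenerates to perfect agreement too and is reported as 1).
    """
    n = c.n
    if n == 0:
        raise ValueError("metrics undefined for empty confusion counts")
    accuracy = 100.0 * (c.tp + c.tn) / n
    precision = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tn + c.fp) * (c.tn + c.fn) + (c.fn + c.tp) * (c.fp + c.tp)) / (n * n)
    kappa = 1.0 if p_e == 1.0 else (p_o - p_e) / (1.0 - p_e)
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall,
                         kappa=kappa, counts=c)


def verbatim_kappa(c: ConfusionCounts) -> float:
    """A kappa shorthand sometimes printed in the applied literature:
    (TP+TN) / ((TN+FP)(TN+FN) + (FN+TP)(FP+TP)) x 100%.

    Kept only for audit: it is dimensionally inconsistent with Cohen's kappa
    (counts divided by products of counts, no N^2 normalisation, no 1-p_e
    denominator) and is NOT used in reports.
    """
    den = (c.tn + c.fp) * (c.tn + c.fn) + (c.fn + c.tp) * (c.fp + c.tp)
    if den == 0:
        raise ValueError("verbatim kappa undefined: zero denominator")
    return 100.0 * (c.tp + c.tn) / den


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _batch_arrays(samples: list[SequenceSample], stats: dict | None):
    x = np.stack([s.x for s in samples]).astype(np.float32)
    if stats is not None:
        x = normalize_x(x, stats).astype(np.float32)
    y = np.stack([s.y for s in samples]).astype(np.int64)
    v = np.stack([s.valid for s in samples]).astype(bool)
    return x, y, v


def _loss_on(model, samples, stats, batch_size, class_weights=None) -> float:
    model.eval()
    total, n = 0.0, 0
    for i in range(0, len(samples), batch_size):
        x, y, v = _batch_arrays(samples[i:i + batch_size], stats)
        loss = nn.softmax_cross_entropy_masked(model(x), y, v, class_weights)
        total += float(loss.data) * len(y)
        n += len(y)
    return total / n


def _balanced_class_weights(samples: list[SequenceSample]) -> np.ndarray:
    """Inverse-frequency class weights w_k = N / (K * N_k) over valid pixels."""
    counts = np.zeros(2, dtype=np.float64)
    for s in samples:
        for k in (0, 1):
            counts[k] += int(((s.y == k) & s.valid).sum())
    counts = np.maximum(counts, 1.0)
    return (counts.sum() / (2.0 * counts)).astype(np.float32)


def train(model: nn.Module, split: DatasetSplit, cfg: TrainConfig
          ) -> tuple[nn.Module, dict]:
    """Seeded Adam optimisation of masked cross-entropy.

    When val_fraction > 0, a tail of the (already shuffled) training list
    serves as the validation fold and the parameter state with the best
    validation loss is restored at the end; with the default val_fraction of
    0 the final state is kept (small validation folds select unreliably).
    Raises on an empty split or non-finite loss.
    """
    if not split.train:
        raise ValueError("cannot train on an empty split")
    stats = split.normalization_stats
    n_val = int(len(split.train) * cfg.val_fraction)
    fit_samples = split.train[:-n_val] if n_val > 0 else split.train
    val_samples = split.train[-n_val:] if n_val > 0 else split.train
    restore_best = n_val > 0

    weights = _balanced_class_weights(fit_samples) \
        if cfg.class_weight == "balanced" else None
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_loss": []}
    best_val, best_state = math.inf, None

    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(fit_samples))
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = [fit_samples[j] for j in order[i:i + cfg.batch_size]]
            x, y, v = _batch_arrays(batch, stats)
            loss = nn.softmax_cross_entropy_masked(model(x), y, v, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // cfg.batch_size}: "
                    f"{float(loss.data)}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
            n_seen += len(batch)
        history["train_loss"].append(epoch_loss / n_seen)
        if restore_best:
            val_loss = _loss_on(model, val_samples, stats, cfg.batch_size,
                                weights)
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(model, samples: list[SequenceSample], stats: dict | None = None,
            batch_size: int = 50) -> np.ndarray:
    """Per-pixel argmax class masks, shape (N, H, W), dtype uint8."""
    if isinstance(model, SVMBaseline):
        return np.stack([model.predict(s.x[-1]) for s in samples])
    model.eval()
    out = []
    for i in range(0, len(samples), batch_size):
        x, _, _ = _batch_arrays(samples[i:i + batch_size], stats)
        logits = model(x).data
        out.append(np.argmax(logits, axis=1).astype(np.uint8))
    return np.concatenate(out, axis=0)


def predict_scene(model, sequence: np.ndarray, stats: dict | None = None,
                  size: int = 32, stride: int = 16,
                  batch_size: int = 50) -> np.ndarray:
    """Full-scene mask by tiled inference with overlap logit averaging.

    sequence: (T, H, W, 7).  Tiles cover the scene on a stride grid (edges
    snapped so the last row/column is always covered); overlapping logits are
    averaged before the argmax, so the result does not depend on tile order.
    """
    T, H, W, C = sequence.shape
    tops = sorted({min(t, H - size) for t in range(0, H, stride)})
    lefts = sorted({min(l, W - size) for l in range(0, W, stride)})
    coords = [(t, l) for t in tops for l in lefts]
    logit_sum = np.zeros((2, H, W), dtype=np.float64)
    weight = np.zeros((H, W), dtype=np.float64)
    model.eval()
    for i in range(0, len(coords), batch_size):
        chunk = coords[i:i + batch_size]
        x = np.stack([sequence[:, t:t + size, l:l + size] for t, l in chunk])
        x = x.astype(np.float32)
        if stats is not None:
            x = normalize_x(x, stats).astype(np.float32)
        logits = model(x).data
        for (t, l), lg in zip(chunk, logits):
            logit_sum[:, t:t + size, l:l + size] += lg
            weight[t:t + size, l:l + size] += 1.0
    return np.argmax(logit_sum / weight, axis=0).astype(np.uint8)


def evaluate_model(model, samples: list[SequenceSample],
                   stats: dict | None = None) -> MetricsReport:
    """Pool confusion counts over a sample list and compute metrics."""
    preds = predict(model, samples, stats)
    total = ConfusionCounts()
    for p, s in zip(preds, samples):
        total = total + confusion_counts(p, s.y, s.valid)
    return compute_metrics(total)


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

def compare_methods(methods: dict[str, object], split: DatasetSplit,
                    cfg: TrainConfig) -> list[dict]:
    """Train and evaluate each method on the identical split and seeds.

    `methods` maps a display name to an untrained model (an nn.Module or an
    SVMBaseline).  Returns one row per method with accuracy / precision /
    recall / kappa, in input order.
    """
    if len(methods) < 2:
        raise ValueError("compare_methods needs at least 2 methods")
    stats = split.normalization_stats
    rows = []
    for name, model in methods.items():
        if isinstance(model, SVMBaseline):
            feats = np.concatenate([s.x[-1].reshape(-1, 7) for s in split.train])
            labels = np.concatenate([s.y.reshape(-1) for s in split.train])
            valid = np.concatenate([s.valid.reshape(-1) for s in split.train])
            model.fit(feats, labels, valid)
        else:
            train(model, split, cfg)
        report = evaluate_model(model, split.test, stats)
        rows.append({"method": name, **report.as_dict()})
    return rows


def write_comparison(rows: list[dict], csv_path=None, json_path=None) -> None:
    cols = ["method", "accuracy", "precision", "recall", "kappa",
            "tp", "fp", "tn", "fn"]
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            writer.writerows(rows)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=2)


# ---------------------------------------------------------------------------
# Visualisation
# ---------------------------------------------------------------------------

def render_detection_map(pred: np.ndarray, truth: np.ndarray, path) -> None:
    """Three-colour PNG: dark blue water (agreement on 0), red detected tide
    (agreement on 1), yellow disagreement."""
    from PIL import Image

    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes must match")
    img = np.zeros((*pred.shape, 3), dtype=np.uint8)
    img[~pred & ~truth] = (12, 44, 132)      # water
    img[pred & truth] = (200, 30, 30)        # detected red tide
    img[pred != truth] = (250, 220, 40)      # disagreement
    Image.fromarray(img).save(str(path))


# ---------------------------------------------------------------------------
# Scaled-down synthetic benchmark
# ---------------------------------------------------------------------------

def benchmark_network_config(seed: int = 0, seq_len: int = 4,
                             **overrides) -> NetworkConfig:
    """Reduced-width configuration used for the CPU-scale benchmark."""
    base = dict(seq_len=seq_len, stage_widths=(8, 16, 32, 64),
                convlstm_hidden=8, seed=seed)
    base.update(overrides)
    return NetworkConfig(**base)


def run_benchmark(seed: int = 0, n_train: int = 200, n_test: int = 50,
                  epochs: int = 20, seq_len: int = 4,
                  model: str = "csf") -> tuple[MetricsReport, dict]:
    """Train a detector on the synthetic sequence bank and score it.

    `model` is "csf" (full network) or "unet" (single-frame basic U-Net).
    Returns the held-out MetricsReport and the training history.
    """
    split = make_sequence_bank(n_train, n_test, seed=seed, seq_len=seq_len)
    cfg = benchmark_network_config(seed=seed, seq_len=seq_len)
    if model == "csf":
        net = build_csf_rtdnet(cfg)
    elif model == "unet":
        net = build_unet_baseline(cfg)
    else:
        raise ValueError(f"unknown benchmark model {model!r}")
    # short schedule (tens of optimiser steps): larger Adam step size than
    # the 1e-3 long-schedule default
    tcfg = TrainConfig(epochs=epochs, seed=seed, learning_rate=5e-3)
    net, history = train(net, split, tcfg)
    report = evaluate_model(net, split.test, split.normalization_stats)
    return report, history
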