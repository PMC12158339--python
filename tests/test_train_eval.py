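"""Metrics identities, the training loop's contracts, and inference mosaics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csfrtd.dataset import make_sequence_bank
from csfrtd.network import build_csf_rtdnet, build_unet_baseline
from csfrtd.train_eval import (ConfusionCounts, TrainConfig, compare_methods,
                               compute_metrics, confusion_counts,
                               evaluate_model, predict, predict_scene,
                               render_detection_map, train, verbatim_kappa)

counts_strategy = st.tuples(st.integers(0, 500), st.integers(0, 500),
                            st.integers(0, 500), st.integers(0, 500)) \
    .filter(lambda t: sum(t) > 0)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        truth = np.array([[1, 0], [0, 1]])
        c = confusion_counts(truth, truth)
        assert c.fp == 0 and c.fn == 0 and c.tp == 2 and c.tn == 2

    def test_inverted_prediction(self):
        truth = np.array([[1, 0], [0, 1]])
        c = confusion_counts(1 - truth, truth)
        assert c.tp == 0 and c.tn == 0

    def test_direct_enumeration_with_valid_mask(self):
        truth = np.zeros(110, dtype=int)
        truth[:7] = 1
        valid = np.ones(110, bool)
        valid[100:] = False
        c = confusion_counts(np.zeros(110, int), truth, valid)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 0, 93, 7)
        assert c.n == 100

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMetrics:
    def test_hand_computed_example(self):
        rep = compute_metrics(ConfusionCounts(tp=50, tn=40, fp=5, fn=5))
        assert rep.accuracy == pytest.approx(90.0)
        assert rep.precision == pytest.approx(100 * 50 / 55)
        assert rep.recall == pytest.approx(100 * 50 / 55)
        assert rep.kappa == pytest.approx(0.79798, abs=1e-5)

    def test_perfect_kappa(self):
        assert compute_metrics(ConfusionCounts(tp=10, tn=20)).kappa == 1.0

    def test_chance_agreement_kappa_zero(self):
        # prediction independent of truth at matched marginals:
        # P(pred=1)=0.5, P(true=1)=0.5, counts proportional to products
        rep = compute_metrics(ConfusionCounts(tp=25, fp=25, fn=25, tn=25))
        assert rep.kappa == pytest.approx(0.0)

    def test_undefined_precision_recall_reported_absent(self):
        rep = compute_metrics(ConfusionCounts(tn=10, fn=5))
        assert rep.precision is None
        rep = compute_metrics(ConfusionCounts(tn=10, fp=5))
        assert rep.recall is None

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts())

    @given(counts_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_kappa_symmetry(self, counts):
        """Swapping prediction and truth transposes the table (FP <-> FN)
        and leaves Cohen's kappa unchanged."""
        tp, fp, tn, fn = counts
        a = compute_metrics(ConfusionCounts(tp, fp, tn, fn)).kappa
        b = compute_metrics(ConfusionCounts(tp, fn, tn, fp)).kappa
        assert a == pytest.approx(b, abs=1e-12)

    @given(counts_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_accuracy_identity(self, counts):
        """accuracy = (recall*P + specificity*N_neg)/N on random tables."""
        tp, fp, tn, fn = counts
        rep = compute_metrics(ConfusionCounts(tp, fp, tn, fn))
        pos, neg = tp + fn, tn + fp
        expected = 0.0
        if pos:
            expected += (tp / pos) * pos
        if neg:
            expected += (tn / neg) * neg
        assert rep.accuracy == pytest.approx(100 * expected / rep.counts.n)

    def test_metrics_recompute_exactly_from_counts(self):
        c = ConfusionCounts(tp=123, fp=7, tn=456, fn=14)
        rep = compute_metrics(c)
        assert rep.accuracy == 100 * (c.tp + c.tn) / c.n

    def test_verbatim_kappa_differs_from_cohen(self):
        c = ConfusionCounts(tp=50, tn=40, fp=5, fn=5)
        assert verbatim_kappa(c) != pytest.approx(compute_metrics(c).kappa)
        assert verbatim_kappa(c) == pytest.approx(100 * 90 / (45 * 45 + 55 * 55))


class TestTraining:
    def test_single_batch_overfit_loss_decreases(self, tiny_net_config):
        split = make_sequence_bank(8, 1, seed=3, seq_len=2)
        model = build_csf_rtdnet(tiny_net_config)
        cfg = TrainConfig(batch_size=8, epochs=10, seed=0, val_fraction=0.0)
        _, history = train(model, split, cfg)
        losses = history["train_loss"]
        assert len(losses) == 10
        assert losses[-1] < losses[0]
        # largely monotone descent on a single easy batch
        assert sum(b < a for a, b in zip(losses, losses[1:])) >= 8

    def test_same_seed_reproduces_final_loss(self, tiny_net_config, tiny_split):
        cfg = TrainConfig(batch_size=5, epochs=2, seed=7)
        _, h1 = train(build_csf_rtdnet(tiny_net_config), tiny_split, cfg)
        _, h2 = train(build_csf_rtdnet(tiny_net_config), tiny_split, cfg)
        assert h1["train_loss"] == h2["train_loss"]

    def test_empty_split_rejected(self, tiny_net_config, tiny_split):
        empty = type(tiny_split)(train=[], test=tiny_split.test, variant="DS1")
        with pytest.raises(ValueError, match="empty"):
            train(build_csf_rtdnet(tiny_net_config), empty, TrainConfig(epochs=1))


class TestPrediction:
    def test_patch_mask_shapes(self, tiny_net_config, tiny_split):
        model = build_csf_rtdnet(tiny_net_config)
        masks = predict(model, tiny_split.test, tiny_split.normalization_stats)
        assert masks.shape == (len(tiny_split.test), 32, 32)
        assert set(np.unique(masks)) <= {0, 1}

    def test_mosaic_equals_disjoint_patch_metrics(self, tiny_net_config,
                                                  endmembers):
        """With disjoint 32-stride tiling, metrics pooled over patches equal
        metrics on the stitched scene."""
        from csfrtd.dataset import SequenceSample
        from csfrtd.synthetic_scene import BloomSimConfig, simulate_series

        series = simulate_series(endmembers, BloomSimConfig(
            height=64, width=64, n_frames=2, morphology="compact", seed=9))
        from csfrtd.radiometry import build_feature_stack
        seq = np.stack([build_feature_stack(f).features for f in series.frames])
        model = build_csf_rtdnet(tiny_net_config).eval()
        scene_pred = predict_scene(model, seq, stride=32)
        pooled = None
        samples = []
        for top in (0, 32):
            for left in (0, 32):
                s = SequenceSample(
                    x=seq[:, top:top + 32, left:left + 32],
                    y=series.masks[-1][top:top + 32, left:left + 32],
                    valid=np.ones((32, 32), bool))
                samples.append((top, left, s))
        for top, left, s in samples:
            c = confusion_counts(scene_pred[top:top + 32, left:left + 32],
                                 s.y, s.valid)
            pooled = c if pooled is None else pooled + c
        whole = confusion_counts(scene_pred, series.masks[-1],
                                 np.ones((64, 64), bool))
        assert pooled.__dict__ == whole.__dict__
        # and the tiles themselves reproduce the mosaic prediction
        patch_preds = predict(model, [s for _, _, s in samples])
        for (top, left, _), p in zip(samples, patch_preds):
            np.testing.assert_array_equal(
                p, scene_pred[top:top + 32, left:left + 32])


class TestComparison:
    def test_table_columns_and_duplicate_rows(self, tiny_net_config, tiny_split):
        cfg = TrainConfig(batch_size=5, epochs=2, seed=4)
        rows = compare_methods(
            {"unet_a": build_unet_baseline(tiny_net_config),
             "unet_b": build_unet_baseline(tiny_net_config)},
            tiny_split, cfg)
        assert {"accuracy", "precision", "recall", "kappa"} <= set(rows[0])
        a, b = rows
        assert {k: v for k, v in a.items() if k != "method"} == \
            {k: v for k, v in b.items() if k != "method"}

    def test_needs_two_methods(self, tiny_split):
        with pytest.raises(ValueError, match="2"):
            compare_methods({}, tiny_split, TrainConfig(epochs=1))


class TestRendering:
    def test_detection_map_colors(self, tmp_path):
        from PIL import Image

        truth = np.zeros((8, 8), int)
        truth[:2] = 1
        path = tmp_path / "map.png"
        render_detection_map(np.zeros((8, 8), int), truth, path)
        img = np.asarray(Image.open(path))
        assert img.shape == (8, 8, 3)
        disagreement = (img == (250, 220, 40)).all(axis=2).sum()
        assert disagreement == truth.sum()

    def test_perfect_prediction_has_no_disagreement(self, tmp_path):
        from PIL import Image

        truth = np.eye(6, dtype=int)
        path = tmp_path / "map.png"
        render_detection_map(truth, truth, path)
        img = np.asarray(Image.open(path))
        assert not (img == (250, 220, 40)).all(axis=2).any()
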