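"""Architecture contracts: attention, dilated pyramid blocks, receptive
fields, parameter counts, and the full model's shape/time-order behaviour."""

import itertools

import numpy as np
import pytest

from csfrtd import nn
from csfrtd.network import (ASPCDSCBlock, CSFRTDNet, ConvLSTMCell,
                            DepthwiseSeparableConv, DoubleConv, ECA,
                            NetworkConfig, build_csf_rtdnet,
                            build_fcn8s_baseline, build_svm_baseline,
                            build_unet_baseline, count_parameters,
                            cumulative_receptive_field, eca, eca_kernel_size)


class TestECA:
    def test_kernel_rule_c64(self):
        # |log2(64)/2 + 1/2| = 3.5 -> floor-to-odd -> 3
        assert eca_kernel_size(64, gamma=2, b=1) == 3

    @pytest.mark.parametrize("c,k", [(2, 1), (8, 1), (32, 3), (128, 3), (512, 5)])
    def test_kernel_rule_is_odd_and_monotone(self, c, k):
        assert eca_kernel_size(c) == k

    def test_output_shape_and_weight_range(self, rng):
        fm = rng.normal(size=(16, 16, 8)).astype(np.float32)
        out = eca(fm, rng=rng)
        assert out.shape == fm.shape
        ratio = out[fm != 0] / fm[fm != 0]
        assert np.all(ratio > 0) and np.all(ratio < 1)

    def test_per_channel_spatially_constant_rescaling(self, rng):
        x = nn.Tensor(rng.normal(size=(2, 8, 6, 6)).astype(np.float32))
        module = ECA(8, rng=rng)
        out = module(x)
        ratio = out.data / x.data
        for b in range(2):
            for c in range(8):
                rc = ratio[b, c]
                assert np.allclose(rc, rc.flat[0], rtol=1e-5)
                assert 0.0 < rc.flat[0] < 1.0


class TestASPCDSC:
    def test_variant3_branch_widths(self, rng):
        block = ASPCDSCBlock(8, 64, (1, 2, 3), (0.5, 0.25, 0.25), rng=rng)
        assert block.branch_widths == (32, 16, 16)

    def test_variant2_branch_widths(self, rng):
        block = ASPCDSCBlock(8, 64, (1, 2), (0.5, 0.5), rng=rng)
        assert block.branch_widths == (32, 32)

    def test_non_integral_split_rejected(self, rng):
        with pytest.raises(ValueError, match="0.25"):
            ASPCDSCBlock(8, 10, (1, 2, 3), (0.5, 0.25, 0.25), rng=rng)

    def test_spatial_dims_preserved(self, rng):
        block = ASPCDSCBlock(4, 8, (1, 2, 3), (0.5, 0.25, 0.25), rng=rng)
        x = nn.Tensor(rng.normal(size=(2, 4, 20, 24)).astype(np.float32))
        assert block(x).data.shape == (2, 8, 20, 24)


def gradient_footprint(dilations, kernel: int = 3) -> int:
    """Independent receptive-field oracle: instantiate the stacked dilated
    convolutions with all-positive weights and measure the input-gradient
    support of one output pixel."""
    rf_bound = 1 + (kernel - 1) * sum(dilations)
    n = 2 * rf_bound + 3
    x = nn.Tensor(np.zeros((1, 1, n, n), dtype=np.float32), requires_grad=True)
    out = x
    for d in dilations:
        w = nn.Tensor(np.ones((1, 1, kernel, kernel), dtype=np.float32),
                      requires_grad=True)
        out = nn.conv2d(out, w, dilation=d)
    seed = np.zeros_like(out.data)
    seed[0, 0, n // 2, n // 2] = 1.0
    out.backward(seed)
    rows = np.nonzero(x.grad[0, 0].sum(axis=1))[0]
    cols = np.nonzero(x.grad[0, 0].sum(axis=0))[0]
    side_r = rows.max() - rows.min() + 1
    side_c = cols.max() - cols.min() + 1
    assert side_r == side_c
    return int(side_r)


class TestReceptiveField:
    @pytest.mark.parametrize("dils,expected", [([1], 3), ([1, 2], 7), ([2, 3], 11)])
    def test_formula_reference_values(self, dils, expected):
        assert cumulative_receptive_field(dils) == expected

    def test_formula_matches_gradient_oracle_for_all_small_lists(self):
        """Every dilation list with summed rate <= 8 agrees with the
        gradient-footprint measurement on an instantiated network."""
        lists = []
        for length in range(1, 4):
            for dils in itertools.product(range(1, 9), repeat=length):
                if sum(dils) <= 8:
                    lists.append(list(dils))
        assert lists
        for dils in lists:
            assert cumulative_receptive_field(dils) == gradient_footprint(dils)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            cumulative_receptive_field([])
        with pytest.raises(ValueError):
            cumulative_receptive_field([0, 2])


class TestParameterCounts:
    def test_standard_conv_closed_form(self):
        conv = nn.Conv2d(16, 16, k=3, bias=False)
        assert conv.weight.data.size == 9 * 16 * 16 == 2304

    def test_dsc_closed_form(self, rng):
        dsc = DepthwiseSeparableConv(16, 16, bias=False, rng=rng)
        assert count_parameters(dsc) == 9 * 16 + 16 * 16 == 400

    @pytest.mark.parametrize("c", [2, 4, 16, 64])
    def test_dsc_cheaper_than_standard(self, c, rng):
        dsc = DepthwiseSeparableConv(c, c, bias=False, rng=rng)
        assert count_parameters(dsc) < 9 * c * c

    def test_unet_stage1_heavier_than_aspc_stage1(self, tiny_net_config):
        full = build_csf_rtdnet(tiny_net_config)
        base = build_unet_baseline(tiny_net_config)
        # at equal stage width the plain double-conv stage outweighs the
        # depthwise-separable pyramid stage
        assert count_parameters(base.enc_blocks[0]) > \
            count_parameters(full.enc_blocks[0])


class TestCSFRTDNet:
    def test_sequence_in_classmap_out(self, tiny_net_config, rng):
        model = build_csf_rtdnet(tiny_net_config)
        x = rng.normal(size=(2, 2, 32, 32, 7)).astype(np.float32)
        out = model(x)
        assert out.data.shape == (2, 2, 32, 32)

    def test_single_frame_sequence_accepted(self, tiny_net_config, rng):
        model = build_csf_rtdnet(tiny_net_config)
        x = rng.normal(size=(1, 1, 32, 32, 7)).astype(np.float32)
        assert model(x).data.shape == (1, 2, 32, 32)

    def test_frame_order_sensitivity(self, tiny_net_config, rng):
        """The ConvLSTM recurrence is not permutation invariant: reversing
        the frame order of a varying sequence changes the logits."""
        model = build_csf_rtdnet(tiny_net_config).eval()
        x = rng.normal(size=(1, 2, 32, 32, 7)).astype(np.float32)
        fwd = model(x).data
        rev = model(x[:, ::-1].copy()).data
        assert not np.allclose(fwd, rev)

    def test_builder_is_pure(self, tiny_net_config, rng):
        a = build_csf_rtdnet(tiny_net_config)
        b = build_csf_rtdnet(tiny_net_config)
        x = rng.normal(size=(1, 2, 32, 32, 7)).astype(np.float32)
        np.testing.assert_array_equal(a.eval()(x).data, b.eval()(x).data)

    def test_stage_blocks_follow_layout(self, tiny_net_config):
        model = build_csf_rtdnet(tiny_net_config)
        assert isinstance(model.enc_blocks[0], ASPCDSCBlock)
        assert isinstance(model.enc_blocks[1], ASPCDSCBlock)
        assert model.enc_blocks[0].branch_widths[0] * 2 == tiny_net_config.stage_widths[0]
        assert isinstance(model.enc_blocks[2], ASPCDSCBlock)
        assert len(model.enc_blocks[2].branch_widths) == 2
        assert isinstance(model.enc_blocks[3], DoubleConv)

    def test_shape_trace_through_encoder(self, tiny_net_config, rng):
        """Every stage preserves spatial dims; only pooling halves them."""
        model = build_csf_rtdnet(tiny_net_config)
        frames = model._prepare(rng.normal(size=(1, 2, 32, 32, 7)).astype("f4"))
        cur = model.stem(frames)
        size = 32
        for i, block in enumerate(model.enc_blocks):
            f = block(cur)
            assert f.data.shape[2:] == (size, size)
            cur = nn.max_pool2d(model.enc_eca[i](f))
            size //= 2

    def test_invalid_input_shape_raises(self, tiny_net_config, rng):
        model = build_csf_rtdnet(tiny_net_config)
        with pytest.raises(ValueError, match="7"):
            model(rng.normal(size=(1, 2, 32, 32, 5)).astype(np.float32))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="integer"):
            NetworkConfig(stage_widths=(6, 12, 24, 48))
        with pytest.raises(ValueError, match="dropout"):
            NetworkConfig(dropout_rate=1.5)


class TestAblationsAndBaselines:
    def test_removing_convlstm_gives_single_frame_eca_aspc_net(self, tiny_net_config):
        cfg = NetworkConfig(**{**tiny_net_config.__dict__, "use_convlstm": False})
        model = CSFRTDNet(cfg)
        assert model.stem is None
        assert isinstance(model.enc_blocks[0], ASPCDSCBlock)
        assert model.enc_eca

    def test_unet_baseline_is_plain(self, tiny_net_config):
        model = build_unet_baseline(tiny_net_config)
        assert model.stem is None and not model.enc_eca
        assert all(isinstance(b, DoubleConv) for b in model.enc_blocks)

    def test_baselines_emit_per_pixel_maps(self, tiny_net_config, rng):
        x = rng.normal(size=(2, 2, 32, 32, 7)).astype(np.float32)
        for model in (build_unet_baseline(tiny_net_config),
                      build_fcn8s_baseline(tiny_net_config)):
            assert model(x).data.shape == (2, 2, 32, 32)

    def test_svm_separable_training_accuracy(self, endmembers, rng):
        """On noiseless endmember pixels the kernel SVM fits the training
        set perfectly."""
        n = 200
        X = np.vstack([np.tile(endmembers.water_rrs[:7], (n, 1)),
                       np.tile(endmembers.bloom_rrs[:7], (n, 1))])
        X += rng.normal(0, 1e-6, X.shape)
        y = np.repeat([0, 1], n)
        clf = build_svm_baseline(seed=0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0


class TestConvLSTM:
    def test_last_hidden_state_shape(self, rng):
        cell = ConvLSTMCell(3, 5, rng=rng)
        frames = [nn.Tensor(rng.normal(size=(2, 3, 8, 8)).astype("f4"))
                  for _ in range(3)]
        h = cell(frames)
        assert h.data.shape == (2, 5, 8, 8)

    def test_gradients_flow_to_first_frame(self, rng):
        cell = ConvLSTMCell(2, 3, rng=rng)
        frames = [nn.Tensor(rng.normal(size=(1, 2, 6, 6)).astype("f4"),
                            requires_grad=True) for _ in range(3)]
        out = nn.mean(cell(frames))
        out.backward()
        assert frames[0].grad is not None and np.abs(frames[0].grad).sum() > 0
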