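"""The CSF-RTDNet detection architecture and its baselines/ablations.

The full model is a U-Net segmentation network over 32x32 7-channel inputs
with three additions:

* a **ConvLSTM stem** that consumes the T-frame input sequence and hands its
  last hidden state to the encoder, so temporal bloom evolution informs the
  spatial segmentation;
* **ECA** (efficient channel attention) after each encoder stage — global
  average pooling to a channel descriptor, a shared 1-D convolution of
  adaptively chosen odd kernel size across neighbouring channels, a sigmoid,
  and a per-channel rescale of the feature map;
* **ASPC-DSC blocks** replacing the plain double convolutions of encoder
  stages 1–3: parallel depthwise-separable 3x3 convolutions at several
  dilation rates (stages 1–2 use rates 1/2/3 with 50/25/25% of the output
  channels; stage 3 uses rates 1/2 at 50/50%), concatenated and fused by a
  1x1 convolution.  Stacking dilated kernels grows the receptive field
  linearly in the summed dilation rate: rf = 1 + (k-1) * sum(d_i), so 3x3
  kernels at rates (1,2) see 7x7 and at (2,3) see 11x11.

Dropout sits at the bottleneck, before upsampling.  Builders are pure
(config in, model out); every model maps an input sequence to a per-pixel
2-class logit map of the input's spatial size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor

__all__ = [
    "NetworkConfig",
    "eca_kernel_size",
    "ECA",
    "cumulative_receptive_field",
    "ASPCDSCBlock",
    "ConvLSTMCell",
    "CSFRTDNet",
    "build_csf_rtdnet",
    "build_unet_baseline",
    "build_fcn8s_baseline",
    "build_svm_baseline",
    "count_parameters",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    stage_widths are the four encoder stage output widths (the bottleneck is
    twice the last); each width must let every ASPC branch proportion yield
    an integer channel count.  The use_* flags are the ablation switches:
    disabling all three leaves a basic single-frame U-Net.
    """

    in_channels: int = 7
    seq_len: int = 4
    stage_widths: tuple[int, ...] = (16, 32, 64, 128)
    aspc3_dilations: tuple[int, ...] = (1, 2, 3)
    aspc3_proportions: tuple[float, ...] = (0.5, 0.25, 0.25)
    aspc2_dilations: tuple[int, ...] = (1, 2)
    aspc2_proportions: tuple[float, ...] = (0.5, 0.5)
    eca_gamma: int = 2
    eca_b: int = 1
    dropout_rate: float = 0.3
    convlstm_hidden: int = 16
    n_classes: int = 2
    use_convlstm: bool = True
    use_eca: bool = True
    use_aspc: bool = True
    eca_in_decoder: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        for dils, props in ((self.aspc3_dilations, self.aspc3_proportions),
                            (self.aspc2_dilations, self.aspc2_proportions)):
            if len(dils) != len(props):
                raise ValueError("dilations and proportions must align")
            if abs(sum(props) - 1.0) > 1e-9:
                raise ValueError(f"branch proportions must sum to 1, got {props}")
        for w in self.stage_widths:
            for props in (self.aspc3_proportions, self.aspc2_proportions):
                for p in props:
                    if abs(w * p - round(w * p)) > 1e-9:
                        raise ValueError(
                            f"stage width {w} x proportion {p} is not an "
                            f"integer channel count")


# ---------------------------------------------------------------------------
# ECA
# ---------------------------------------------------------------------------

def eca_kernel_size(channels: int, gamma: int = 2, b: int = 1) -> int:
    """Adaptive odd 1-D kernel size: largest odd integer <= |log2(C)/gamma +
    b/gamma|, at least 1."""
    if channels < 2:
        raise ValueError("ECA needs at least 2 channels")
    t = abs(math.log2(channels) / gamma + b / gamma)
    k = int(math.floor(t))
    if k % 2 == 0:
        k -= 1
    return max(k, 1)


class ECA(Module):
    """Efficient channel attention: GAP -> shared 1-D conv -> sigmoid -> scale.

    The attention weights lie strictly in (0, 1) and rescale each channel by
    a spatially constant factor.
    """

    def __init__(self, channels: int, gamma: int = 2, b: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.k = eca_kernel_size(channels, gamma, b)
        self.kernel = Parameter(rng.normal(0.0, 0.3, size=self.k))

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.data.shape[:2]
        pooled = nn.mean(x, axis=(2, 3))                    # (B, C)
        w = nn.sigmoid(nn.conv1d_channels(pooled, self.kernel))
        return nn.mul(x, w.reshape(B, C, 1, 1))


def eca(feature_map: np.ndarray, gamma: int = 2, b: int = 1,
        rng: np.random.Generator | None = None) -> np.ndarray:
    """Functional channel attention over one H x W x C feature map.

    Convenience wrapper around :class:`ECA` (a fresh kernel drawn from `rng`):
    returns the attention-rescaled map with the same shape.
    """
    fm = np.asarray(feature_map, dtype=np.float32)
    if fm.ndim != 3:
        raise ValueError("feature map must be H x W x C")
    module = ECA(fm.shape[2], gamma, b, rng=rng)
    x = Tensor(fm.transpose(2, 0, 1)[None])
    out = module(x)
    return out.data[0].transpose(1, 2, 0)


# ---------------------------------------------------------------------------
# ASPC-DSC
# ---------------------------------------------------------------------------

def cumulative_receptive_field(dilations, kernel: int = 3) -> int:
    """Side length of the receptive field of stacked dilated convolutions.

    Each k x k convolution at dilation d has effective kernel d*(k-1)+1;
    composing them adds the reaches: rf = 1 + (k-1) * sum(d_i).
    """
    dilations = list(dilations)
    if not dilations or any(d < 1 for d in dilations):
        raise ValueError("dilations must be a nonempty list of rates >= 1")
    return 1 + (kernel - 1) * sum(dilations)


class DepthwiseSeparableConv(Module):
    """3x3 depthwise (grouped per channel, optionally dilated) convolution
    followed by a 1x1 pointwise mix; 9*C_in + C_in*C_out weights vs
    9*C_in*C_out for a standard 3x3 convolution."""

    def __init__(self, c_in: int, c_out: int, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.depthwise = nn.Conv2d(c_in, c_in, k=3, dilation=dilation,
                                   groups=c_in, bias=False, rng=rng)
        self.pointwise = nn.Conv2d(c_in, c_out, k=1, bias=bias, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class ASPCDSCBlock(Module):
    """Parallel depthwise-separable dilated branches, concatenated and fused.

    Branch i runs a 3x3 DSC at dilation rates[i] producing proportions[i] of
    out_channels; outputs concatenate along channels and a 1x1 convolution
    (+ batch-norm + ReLU) fuses them.  Spatial dims are preserved.
    """

    def __init__(self, c_in: int, c_out: int, dilations, proportions,
                 rng: np.random.Generator | None = None):
        super().__init__()
        widths = []
        for d, p in zip(dilations, proportions):
            w = c_out * p
            if abs(w - round(w)) > 1e-9:
                raise ValueError(
                    f"proportion {p} of {c_out} channels is not an integer")
            widths.append(int(round(w)))
        self.branch_widths = tuple(widths)
        self.branches = [DepthwiseSeparableConv(c_in, w, dilation=d, rng=rng)
                         for d, w in zip(dilations, widths)]
        self.fuse = nn.Conv2d(sum(widths), c_out, k=1, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        parts = [br(x) for br in self.branches]
        return nn.relu(self.bn(self.fuse(nn.concat(parts, axis=1))))


class DoubleConv(Module):
    """Two 3x3 conv + BN + ReLU layers — the classic U-Net stage block."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        super().__init__()
        self.c1 = nn.Conv2d(c_in, c_out, k=3, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.c2 = nn.Conv2d(c_out, c_out, k=3, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)

    def forward(self, x: Tensor) -> Tensor:
        return nn.relu(self.bn2(self.c2(nn.relu(self.bn1(self.c1(x))))))


# ---------------------------------------------------------------------------
# ConvLSTM
# ---------------------------------------------------------------------------

class ConvLSTMCell(Module):
    """LSTM cell whose gates are 3x3 convolutions over (input, hidden)."""

    def __init__(self, c_in: int, hidden: int, rng=None):
        super().__init__()
        self.hidden = hidden
        self.gates = nn.Conv2d(c_in + hidden, 4 * hidden, k=3, bias=True, rng=rng)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = self.gates(nn.concat([x, h], axis=1))
        hs = self.hidden
        i = nn.sigmoid(nn.slice_channels(z, 0, hs))
        f = nn.sigmoid(nn.slice_channels(z, hs, 2 * hs))
        o = nn.sigmoid(nn.slice_channels(z, 2 * hs, 3 * hs))
        g = nn.tanh(nn.slice_channels(z, 3 * hs, 4 * hs))
        c_new = nn.add(nn.mul(f, c), nn.mul(i, g))
        h_new = nn.mul(o, nn.tanh(c_new))
        return h_new, c_new

    def forward(self, frames: list[Tensor]) -> Tensor:
        """Run over a chronological frame list; return the last hidden state."""
        B, _, H, W = frames[0].data.shape
        h = Tensor(np.zeros((B, self.hidden, H, W), dtype=np.float32))
        c = Tensor(np.zeros((B, self.hidden, H, W), dtype=np.float32))
        for x in frames:
            h, c = self.step(x, h, c)
        return h


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

class CSFRTDNet(Module):
    """ConvLSTM stem -> 4-stage U-Net encoder (stages 1-2 ASPC-DSC-3,
    stage 3 ASPC-DSC-2, stage 4 double conv; ECA after each stage) ->
    bottleneck with dropout -> skip-connected decoder -> 1x1 2-class head."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        widths = list(cfg.stage_widths)

        if cfg.use_convlstm:
            self.stem = ConvLSTMCell(cfg.in_channels, cfg.convlstm_hidden, rng=rng)
            enc_in = cfg.convlstm_hidden
        else:
            self.stem = None
            enc_in = cfg.in_channels

        def stage_block(i: int, c_in: int, c_out: int) -> Module:
            if cfg.use_aspc and i < 2:
                return ASPCDSCBlock(c_in, c_out, cfg.aspc3_dilations,
                                    cfg.aspc3_proportions, rng=rng)
            if cfg.use_aspc and i == 2:
                return ASPCDSCBlock(c_in, c_out, cfg.aspc2_dilations,
                                    cfg.aspc2_proportions, rng=rng)
            return DoubleConv(c_in, c_out, rng=rng)

        self.enc_blocks = []
        c_prev = enc_in
        for i, w in enumerate(widths):
            self.enc_blocks.append(stage_block(i, c_prev, w))
            c_prev = w
        self.enc_eca = [ECA(w, cfg.eca_gamma, cfg.eca_b, rng=rng)
                        for w in widths] if cfg.use_eca else []

        bott = widths[-1] * 2
        self.bottleneck = DoubleConv(widths[-1], bott, rng=rng)
        self.dropout = nn.Dropout(cfg.dropout_rate,
                                  seed=int(rng.integers(0, 2 ** 31 - 1)))

        self.up_convs = []     # channel reducers after nearest-neighbour upsample
        self.dec_blocks = []
        self.dec_eca = []
        c_prev = bott
        for w in reversed(widths):
            self.up_convs.append(nn.Conv2d(c_prev, w, k=3, bias=False, rng=rng))
            self.dec_blocks.append(DoubleConv(2 * w, w, rng=rng))
            if cfg.use_eca and cfg.eca_in_decoder:
                self.dec_eca.append(ECA(w, cfg.eca_gamma, cfg.eca_b, rng=rng))
            c_prev = w
        self.head = nn.Conv2d(widths[0], cfg.n_classes, k=1, bias=True, rng=rng)

    # -- forward ------------------------------------------------------------

    def _prepare(self, x) -> list[Tensor]:
        """(B, T, H, W, C) array -> list of T (B, C, H, W) frame tensors."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 4:       # single sample
            x = x[None]
        if x.ndim != 5 or x.shape[4] != self.cfg.in_channels:
            raise ValueError(
                f"expected (B, T, H, W, {self.cfg.in_channels}) input, "
                f"got shape {x.shape}")
        return [Tensor(np.ascontiguousarray(x[:, t].transpose(0, 3, 1, 2)))
                for t in range(x.shape[1])]

    def forward(self, x) -> Tensor:
        frames = x if isinstance(x, list) else self._prepare(x)
        if self.stem is not None:
            cur = self.stem(frames)
        else:
            cur = frames[-1]
        skips = []
        for i, block in enumerate(self.enc_blocks):
            f = block(cur)
            if self.enc_eca:
                f = self.enc_eca[i](f)
            skips.append(f)
            cur = nn.max_pool2d(f)
        cur = self.dropout(self.bottleneck(cur))
        for j, (up, dec) in enumerate(zip(self.up_convs, self.dec_blocks)):
            cur = up(nn.upsample2(cur))
            cur = dec(nn.concat([skips[-1 - j], cur], axis=1))
            if self.dec_eca:
                cur = self.dec_eca[j](cur)
        return self.head(cur)


def build_csf_rtdnet(cfg: NetworkConfig) -> CSFRTDNet:
    """Pure builder: identical configs give identical initial weights."""
    return CSFRTDNet(cfg)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def build_unet_baseline(cfg: NetworkConfig) -> CSFRTDNet:
    """Basic single-frame U-Net: no ConvLSTM, no ECA, no ASPC-DSC.  Consumes
    the last frame of each input sequence."""
    base = NetworkConfig(**{**cfg.__dict__, "use_convlstm": False,
                            "use_eca": False, "use_aspc": False})
    return CSFRTDNet(base)


class FCN8s(Module):
    """Generic width-matched FCN-8s: five conv/pool stages scoring at 1/8,
    1/16 and 1/32 resolution, fused by stepwise 2x upsampling then restored
    to input size by 8x upsampling.  Single-frame input."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = list(cfg.stage_widths)
        widths = w + [w[-1] * 2]                     # five stages
        self.blocks = []
        c_prev = cfg.in_channels
        for width in widths:
            self.blocks.append(DoubleConv(c_prev, width, rng=rng))
            c_prev = width
        k = cfg.n_classes
        self.score3 = nn.Conv2d(widths[2], k, k=1, rng=rng)
        self.score4 = nn.Conv2d(widths[3], k, k=1, rng=rng)
        self.score5 = nn.Conv2d(widths[4], k, k=1, rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            arr = np.asarray(x, dtype=np.float32)
            if arr.ndim == 4:
                arr = arr[None]
            if arr.ndim == 5:                        # sequence: take last frame
                arr = arr[:, -1]
            x = Tensor(np.ascontiguousarray(arr.transpose(0, 3, 1, 2)))
        pools = []
        cur = x
        for block in self.blocks:
            cur = nn.max_pool2d(block(cur))
            pools.append(cur)
        s5 = self.score5(pools[4])                   # 1/32
        s4 = self.score4(pools[3])                   # 1/16
        s3 = self.score3(pools[2])                   # 1/8
        fused = nn.add(nn.upsample2(s5), s4)
        fused = nn.add(nn.upsample2(fused), s3)
        for _ in range(3):                           # 8x back to input size
            fused = nn.upsample2(fused)
        return fused


def build_fcn8s_baseline(cfg: NetworkConfig) -> FCN8s:
    return FCN8s(cfg)


class SVMBaseline:
    """Per-pixel kernel SVM over 7-channel feature vectors.

    Training subsamples pixels (class-balanced where possible) to keep the
    kernel solve tractable; prediction is vectorised over whole patches.
    """

    def __init__(self, kernel: str = "rbf", C: float = 1.0, seed: int = 0,
                 max_train_pixels: int = 20000):
        from sklearn.svm import SVC

        self.clf = SVC(kernel=kernel, C=C, random_state=seed)
        self.seed = seed
        self.max_train_pixels = max_train_pixels

    def fit(self, features: np.ndarray, labels: np.ndarray,
            valid: np.ndarray | None = None) -> "SVMBaseline":
        X = features.reshape(-1, features.shape[-1])
        y = np.asarray(labels).reshape(-1)
        if valid is not None:
            keep = np.asarray(valid).reshape(-1)
            X, y = X[keep], y[keep]
        if len(y) > self.max_train_pixels:
            rng = np.random.default_rng(self.seed)
            idx = rng.choice(len(y), size=self.max_train_pixels, replace=False)
            X, y = X[idx], y[idx]
        self.clf.fit(X, y)
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        shape = features.shape[:-1]
        return self.clf.predict(features.reshape(-1, features.shape[-1])) \
            .reshape(shape).astype(np.uint8)


def build_svm_baseline(kernel: str = "rbf", C: float = 1.0,
                       seed: int = 0) -> SVMBaseline:
    return SVMBaseline(kernel=kernel, C=C, seed=seed)


def count_parameters(model: Module) -> int:
    """Exact trainable-scalar count of a built model."""
    return model.num_parameters()
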