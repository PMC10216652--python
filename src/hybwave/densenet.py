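"""Densely connected classification head.

A DenseNet stacks "dense blocks" in which every layer receives the
concatenation of all preceding feature maps in the block,

    x_l = H_l([x_0, x_1, ..., x_{l-1}]),

so a block entered with ``c0`` channels and ``L`` layers of growth rate
``k`` leaves with ``c0 + L * k`` channels.  Blocks are joined by
transition layers (batch-norm + 1x1 conv + pooling) and the head is a
global average pool followed by three dense layers and a soft-max.

Two presets are provided.  ``"text"`` is the internally consistent
canonical layout: 7x7 stride-2 stem, 3x3 stride-2 max pool (224 -> 112 ->
56), bottleneck dense layers (1x1 then 3x3 conv).  ``"table1"`` instead
reproduces a published specification table verbatim (8x8 stem, 4x4 pool,
per-block 5x5 / 1x1 / 5x5 / 7x7 convolutions, transition convs of
growing kernel size); its arithmetic differs and it exists for fidelity,
not performance.  ``n_channels=4`` builds four parallel stems whose
pooled features are fused by two combination blocks before the dense
head (the four-perspective fusion variant).

The classifier can also consume plain feature vectors (after feature
selection) instead of images, in which case only the dense head is built.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "DenseNetConfig",
    "Prediction",
    "dense_block_channels",
    "DenseBlock",
    "DenseNet",
    "build_densenet",
    "train_classifier",
    "predict",
]


@dataclass(frozen=True)
class DenseNetConfig:
    """Architecture configuration.

    ``growth_rate`` is the per-layer channel increment k; ``block_sizes``
    the number of dense layers in each of the four blocks; ``preset``
    selects the stem/kernel layout (see module docstring).  ``n_channels``
    = 4 enables the four-stem fusion variant; ``input_kind`` switches
    between the convolutional stem ("image") and a dense-only head
    ("features").
    """

    growth_rate: int = 12
    block_sizes: tuple = (2, 2, 2, 2)
    input_size: int = 224
    n_classes: int = 3
    n_channels: int = 1
    preset: str = "text"
    input_kind: str = "image"
    feature_dim: int = 0  # required when input_kind == "features"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.block_sizes) != 4 or any(b < 1 for b in self.block_sizes):
            raise ValueError("block_sizes must be four integers >= 1")
        if self.preset not in ("text", "table1"):
            raise ValueError("preset must be 'text' or 'table1'")
        if self.input_kind not in ("image", "features"):
            raise ValueError("input_kind must be 'image' or 'features'")
        if self.n_channels not in (1, 4):
            raise ValueError("n_channels must be 1 or 4")


@dataclass(frozen=True)
class Prediction:
    """Class probabilities and the argmax label (ties -> lowest index)."""

    probabilities: np.ndarray
    label: int


def dense_block_channels(c0: int, n_layers: int, k: int) -> int:
    """Channels leaving a dense block: c0 + n_layers * k."""
    if min(c0, n_layers, k) < 0:
        raise ValueError("arguments must be non-negative")
    return c0 + n_layers * k


class _DenseLayer(nn.Layer):
    """BN -> ReLU -> 1x1 conv (4k) -> BN -> ReLU -> KxK conv (k)."""

    def __init__(self, c_in, k, conv_kernel, rng):
        self.block = nn.Sequential(
            nn.BatchNorm2D(c_in), nn.ReLU(),
            nn.Conv2D(c_in, 4 * k, 1, pad=0, rng=rng),
            nn.BatchNorm2D(4 * k), nn.ReLU(),
            nn.Conv2D(4 * k, k, conv_kernel, pad="same", rng=rng))

    def params(self):
        return self.block.params()

    def forward(self, x, train=True):
        return self.block.forward(x, train=train)

    def backward(self, grad):
        return self.block.backward(grad)


class DenseBlock(nn.Layer):
    """Concatenative dense connectivity: layer l sees [x0, ..., x_{l-1}]."""

    def __init__(self, c_in, n_layers, k, conv_kernel, rng):
        self.k = k
        self.c_in = c_in
        self.layers = [_DenseLayer(c_in + i * k, k, conv_kernel, rng)
                       for i in range(n_layers)]
        self.c_out = dense_block_channels(c_in, n_layers, k)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=True, zero_layer_index=None):
        """``zero_layer_index`` zeroes one stored intermediate map (used to
        demonstrate that the dense connections are live, not nominal)."""
        maps = [x]
        for i, layer in enumerate(self.layers):
            inp = np.concatenate(maps, axis=1)
            out = layer.forward(inp, train=train)
            if zero_layer_index is not None and i == zero_layer_index:
                out = np.zeros_like(out)
            maps.append(out)
        self._n_maps = len(maps)
        return np.concatenate(maps, axis=1)

    def backward(self, grad):
        k, c_in = self.k, self.c_in
        # split the concatenated gradient back into per-map slices
        g_maps = []
        start = 0
        for width in [c_in] + [k] * len(self.layers):
            g_maps.append(grad[:, start:start + width].copy())
            start += width
        for i in reversed(range(len(self.layers))):
            g_in = self.layers[i].backward(g_maps[i + 1])
            # g_in distributes over the concatenated inputs [x0..x_i]
            start = 0
            for j, width in enumerate([c_in] + [k] * i):
                g_maps[j] += g_in[:, start:start + width]
                start += width
        return g_maps[0]


class _Transition(nn.Layer):
    """BN -> 1x1 (or preset) conv halving channels -> 2x2 average pool."""

    def __init__(self, c_in, c_out, kernel, rng):
        self.bn = nn.BatchNorm2D(c_in)
        self.relu = nn.ReLU()
        self.conv = nn.Conv2D(c_in, c_out, kernel, stride=2, pad="same",
                              rng=rng)

    def params(self):
        return self.bn.params() + self.conv.params()

    def forward(self, x, train=True):
        return self.conv.forward(
            self.relu.forward(self.bn.forward(x, train), train), train)

    def backward(self, grad):
        return self.bn.backward(self.relu.backward(self.conv.backward(grad)))


def _spatial_after(n, kernel, stride, pad):
    out = (n + 2 * pad - kernel) // stride + 1
    if out < 1:
        raise ValueError(
            f"layer with kernel {kernel}, stride {stride} collapses a "
            f"{n}-pixel input")
    return out


class DenseNet:
    """The full network; built by :func:`build_densenet`."""

    def __init__(self, cfg: DenseNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        k = cfg.growth_rate
        self.stems = []
        self.blocks = []
        self.transitions = []
        self.size_trace = []  # (name, spatial size) pairs, asserted on build

        if cfg.input_kind == "image":
            if cfg.preset == "text":
                stem_k, stem_pad = 7, 3
                pool_k, pool_pad = 3, 1
                block_kernels = (3, 3, 3, 3)
                trans_kernels = (1, 1, 1)
            else:  # table1 preset: published table rows verbatim
                stem_k, stem_pad = 8, 3
                pool_k, pool_pad = 4, 1
                block_kernels = (5, 1, 5, 7)
                trans_kernels = (2, 4, 6)
            n_stems = cfg.n_channels if cfg.n_channels == 4 else 1
            c_stem = 2 * k
            size = cfg.input_size
            size = _spatial_after(size, stem_k, 2, stem_pad)
            self.size_trace.append(("stem", size))
            size = _spatial_after(size, pool_k, 2, pool_pad)
            self.size_trace.append(("pool", size))
            for _ in range(n_stems):
                self.stems.append(nn.Sequential(
                    nn.Conv2D(1, c_stem, stem_k, stride=2, pad=stem_pad,
                              rng=rng),
                    nn.BatchNorm2D(c_stem), nn.ReLU(),
                    nn.MaxPool2D(pool_k, stride=2, pad=pool_pad)))
            c = c_stem
            for i, n_layers in enumerate(cfg.block_sizes):
                self.blocks.append(DenseBlock(c, n_layers, k,
                                              block_kernels[i], rng))
                c = self.blocks[-1].c_out
                self.size_trace.append((f"dense_block_{i + 1}", size))
                if i < 3:
                    c_half = max(c // 2, k)
                    tk = trans_kernels[i]
                    self.transitions.append(
                        _Transition(c, c_half, tk, rng))
                    size = _spatial_after(size, tk, 2, (tk - 1) // 2)
                    self.size_trace.append((f"transition_{i + 1}", size))
                    c = c_half
            self.gap = nn.GlobalAvgPool()
            feat = c * n_stems
            if n_stems == 4:
                # two combination blocks fuse the four pooled stems
                self.fusion = nn.Sequential(
                    nn.Dense(feat, 2 * c, rng=rng), nn.ReLU(),
                    nn.Dense(2 * c, c, rng=rng), nn.ReLU())
                feat = c
            else:
                self.fusion = None
        else:
            if cfg.feature_dim < 1:
                raise ValueError("feature_dim required for feature input")
            feat = cfg.feature_dim
            self.fusion = None

        self.head = nn.Sequential(
            nn.Dense(feat, 64, rng=rng), nn.ReLU(),
            nn.Dense(64, 32, rng=rng), nn.ReLU(),
            nn.Dense(32, cfg.n_classes, rng=rng))

    def params(self):
        out = []
        for stem in self.stems:
            out.extend(stem.params())
        for b in self.blocks:
            out.extend(b.params())
        for t in self.transitions:
            out.extend(t.params())
        if self.fusion is not None:
            out.extend(self.fusion.params())
        out.extend(self.head.params())
        return out

    def _conv_trunk(self, x, train):
        for i, block in enumerate(self.blocks):
            x = block.forward(x, train=train)
            if i < len(self.transitions):
                x = self.transitions[i].forward(x, train=train)
        return x

    def _conv_trunk_backward(self, grad):
        for i in reversed(range(len(self.blocks))):
            if i < len(self.transitions):
                grad = self.transitions[i].backward(grad)
            grad = self.blocks[i].backward(grad)
        return grad

    def forward(self, x, train=True):
        cfg = self.cfg
        if cfg.input_kind == "features":
            self._flat = np.asarray(x, dtype=float)
            return self.head.forward(self._flat, train=train)
        x = np.asarray(x, dtype=float)
        if x.ndim != 4 or x.shape[1] != cfg.n_channels:
            raise ValueError(
                f"expected (N, {cfg.n_channels}, H, W) input, got {x.shape}")
        if x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ValueError(
                f"expected {cfg.input_size}x{cfg.input_size} images")
        if len(self.stems) == 1:
            z = self.stems[0].forward(x, train=train)
            z = self._conv_trunk(z, train)
            flat = self.gap.forward(z, train=train)
        else:
            pooled = []
            self._gaps = []
            for ch, stem in enumerate(self.stems):
                z = stem.forward(x[:, ch:ch + 1], train=train)
                z = self._conv_trunk(z, train)
                gap = nn.GlobalAvgPool()
                pooled.append(gap.forward(z, train=train))
                self._gaps.append(gap)
            flat = np.concatenate(pooled, axis=1)
        if self.fusion is not None:
            flat = self.fusion.forward(flat, train=train)
        return self.head.forward(flat, train=train)

    def backward(self, grad):
        grad = self.head.backward(grad)
        if self.cfg.input_kind == "features":
            return grad
        if self.fusion is not None:
            grad = self.fusion.backward(grad)
        if len(self.stems) == 1:
            grad = self.gap.backward(grad)
            grad = self._conv_trunk_backward(grad)
            return self.stems[0].backward(grad)
        # fused variant shares the trunk; gradients sum over stems
        width = grad.shape[1] // len(self.stems)
        for ch in reversed(range(len(self.stems))):
            g = self._gaps[ch].backward(grad[:, ch * width:(ch + 1) * width])
            g = self._conv_trunk_backward(g)
            self.stems[ch].backward(g)
        return None


def build_densenet(cfg: DenseNetConfig) -> DenseNet:
    """Construct the network, asserting the layer-size arithmetic on the way."""
    return DenseNet(cfg)


def train_classifier(inputs, labels, cfg: DenseNetConfig, epochs: int = 20,
                     lr: float = 1e-3, batch_size: int = 32,
                     seed: int | None = None):
    """Cross-entropy training with Adam; returns ``(model, log)``.

    ``inputs`` is (N, H, W) or (N, C, H, W) for images, (N, D) for feature
    vectors.  The log records per-epoch mean loss and training accuracy.
    Deterministic given the seed.
    """
    y = np.asarray(labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes present")
    X = np.asarray(inputs, dtype=float)
    if cfg.input_kind == "image" and X.ndim == 3:
        X = X[:, None]
    model = build_densenet(cfg)
    opt = nn.Adam(model.params(), lr=lr)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    log = {"loss": [], "accuracy": []}
    for _epoch in range(epochs):
        order = rng.permutation(len(y))
        losses, correct = [], 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            logits = model.forward(X[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        log["loss"].append(float(np.mean(losses)))
        log["accuracy"].append(correct / len(y))
    return model, log


def predict(model: DenseNet, x) -> Prediction:
    """Probabilities and argmax label for a single input."""
    arr = np.asarray(x, dtype=float)
    if model.cfg.input_kind == "image":
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[None]
    else:
        arr = arr.reshape(1, -1)
    logits = model.forward(arr, train=False)
    probs = nn.softmax(logits)[0]
    return Prediction(probabilities=probs, label=int(np.argmax(probs)))
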