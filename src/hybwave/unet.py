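"""Shallow U-Net autoencoder feature extraction and segmentation-loss operators.

The feature extractor is a small encoder-decoder ("U") network trained as
an MSE autoencoder; the flattened bottleneck activations are the per-image
feature vector handed to feature selection.  The classical segmentation
operators that accompany U-Net training — the pixel-wise soft-max, the
border-emphasizing weight map

    w(x) = w_c(x) + w_0 * exp(-(d1(x) + d2(x))^2 / (2 sigma^2)),

and the weighted cross-entropy penalty E = -sum_x w(x) log p_{l(x)}(x) —
are provided as standalone, tested operators (usable as a segmentation head
when label masks exist).  Elastic-style augmentation (flip / shift / shear
/ zoom) completes the training toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn

__all__ = [
    "UNetConfig",
    "ElasticParams",
    "softmax_map",
    "weight_from_distances",
    "class_weight_map",
    "weighted_cross_entropy",
    "elastic_augment",
    "UNet",
    "train_autoencoder",
    "extract_features",
    "early_stop_epoch",
]


@dataclass(frozen=True)
class UNetConfig:
    """Autoencoder architecture and training configuration.

    ``depth`` counts down/up-sampling stages; the bottleneck carries
    ``base_filters * 2**depth`` channels at ``input / 2**depth`` spatial
    resolution.  Training: MSE loss, Adam, MAE tracked, early stopping
    after ``patience`` epochs without validation improvement.
    """

    depth: int = 2
    base_filters: int = 16
    batch_size: int = 64
    epochs: int = 100
    patience: int = 15
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1 or self.batch_size < 1:
            raise ValueError("depth and batch_size must be >= 1")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


# --- segmentation-loss operators -----------------------------------------

def softmax_map(activations) -> np.ndarray:
    """Pixel-wise soft-max over K channel activation grids.

    ``activations`` has shape (K, H, W) with K >= 2; returns per-channel
    probability grids summing to 1 at every pixel (max-subtraction for
    numerical stability).
    """
    a = np.asarray(activations, dtype=float)
    if a.ndim != 3 or a.shape[0] < 2:
        raise ValueError("expected (K, H, W) activations with K >= 2")
    if not np.all(np.isfinite(a)):
        raise ValueError("activations must be finite")
    z = a - a.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def weight_from_distances(wc, d1, d2, w0: float = 10.0,
                          sigma: float = 5.0) -> np.ndarray:
    """The border-emphasis weight w = wc + w0 * exp(-(d1 + d2)^2 / (2 sigma^2))."""
    return np.asarray(wc, float) + w0 * np.exp(
        -np.square(np.asarray(d1, float) + np.asarray(d2, float))
        / (2.0 * sigma ** 2))


def class_weight_map(label_mask, w0: float = 10.0, sigma: float = 5.0):
    """Class-balancing weight map with border emphasis between components.

    ``wc`` is the inverse pixel frequency of each label, normalized so its
    mean over the image is 1.  d1 and d2 are the Euclidean distances to the
    nearest and second-nearest foreground connected component (labels > 0);
    with a single component d2 = d1, and with none the map is wc alone.

    Returns ``(weights, wc_map, d1, d2)``.
    """
    lab = np.asarray(label_mask)
    if lab.ndim != 2:
        raise ValueError("label_mask must be 2-D")
    classes, counts = np.unique(lab, return_counts=True)
    inv = {c: lab.size / cnt for c, cnt in zip(classes, counts)}
    wc_map = np.vectorize(inv.get)(lab).astype(float)
    wc_map /= wc_map.mean()

    comps, n_comp = ndimage.label(lab > 0)
    if n_comp == 0:
        zeros = np.zeros_like(wc_map)
        return wc_map.copy(), wc_map, zeros, zeros
    dists = np.stack([ndimage.distance_transform_edt(comps != i)
                      for i in range(1, n_comp + 1)])
    dists.sort(axis=0)
    d1 = dists[0]
    d2 = dists[1] if n_comp >= 2 else d1
    return weight_from_distances(wc_map, d1, d2, w0, sigma), wc_map, d1, d2


def weighted_cross_entropy(p, labels, weights) -> float:
    """Weighted negative log-likelihood E = -sum_x w(x) log p_{l(x)}(x).

    ``p`` is a (K, H, W) probability stack (e.g. from :func:`softmax_map`),
    ``labels`` an integer grid in [0, K), ``weights`` a matching float
    grid.  Probabilities are clipped at 1e-12 before the log, so E >= 0.
    """
    p = np.asarray(p, dtype=float)
    lab = np.asarray(labels)
    w = np.asarray(weights, dtype=float)
    if p.ndim != 3 or lab.shape != p.shape[1:] or w.shape != lab.shape:
        raise ValueError("shape mismatch between p, labels and weights")
    if lab.min() < 0 or lab.max() >= p.shape[0]:
        raise ValueError("labels out of range")
    p_true = np.take_along_axis(p, lab[None], axis=0)[0]
    return float(-(w * np.log(np.clip(p_true, 1e-12, None))).sum())


# --- augmentation ---------------------------------------------------------

@dataclass(frozen=True)
class ElasticParams:
    """One draw of the augmentation transform (identity when all zero)."""

    flip: bool = False
    shift_y: float = 0.0  # pixels
    shift_x: float = 0.0
    shear: float = 0.0    # shear factor applied to x as a function of y
    zoom: float = 1.0

    @classmethod
    def draw(cls, rng, size: int) -> "ElasticParams":
        return cls(flip=bool(rng.uniform() < 0.5),
                   shift_y=float(rng.uniform(-0.1, 0.1) * size),
                   shift_x=float(rng.uniform(-0.1, 0.1) * size),
                   shear=float(rng.uniform(-0.1, 0.1)),
                   zoom=float(rng.uniform(0.9, 1.1)))


def _forward_matrix(params: ElasticParams):
    """Forward affine map (about the image centre) as a 2x2 matrix."""
    zoom = np.array([[params.zoom, 0.0], [0.0, params.zoom]])
    shear = np.array([[1.0, 0.0], [params.shear, 1.0]])  # x += shear * y
    return shear @ zoom


def transform_point(point, params: ElasticParams, shape):
    """Where a (row, col) point lands under the forward transform."""
    c = (np.asarray(shape, float) - 1.0) / 2.0
    pt = np.asarray(point, float)
    if params.flip:
        pt = np.array([pt[0], shape[1] - 1.0 - pt[1]])
    t = np.array([params.shift_y, params.shift_x])
    return _forward_matrix(params) @ (pt - c) + c + t


def elastic_augment(image, seed: int = 0, params: ElasticParams | None = None,
                    mask=None, order: int = 1):
    """Randomly composed flip / shift / shear / zoom augmentation.

    A single parameter draw (seeded, or given explicitly via ``params``)
    is applied to the image with bilinear interpolation; when ``mask`` is
    supplied it receives the identical geometric transform with
    nearest-neighbour interpolation and is returned alongside.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    if params is None:
        params = ElasticParams.draw(np.random.default_rng(seed), arr.shape[0])

    def _apply(a, interp_order):
        out = a[:, ::-1] if params.flip else a
        c = (np.asarray(a.shape, float) - 1.0) / 2.0
        fwd = _forward_matrix(params)
        inv = np.linalg.inv(fwd)
        t = np.array([params.shift_y, params.shift_x])
        offset = c - inv @ (c + t)
        return ndimage.affine_transform(out, inv, offset=offset,
                                        order=interp_order, mode="constant")

    out = _apply(arr, order)
    if mask is not None:
        return out, _apply(np.asarray(mask, float), 0)
    return out


# --- the network ----------------------------------------------------------

class _DoubleConv(nn.Layer):
    def __init__(self, c_in, c_out, rng):
        self.block = nn.Sequential(
            nn.Conv2D(c_in, c_out, 3, rng=rng), nn.ReLU(),
            nn.Conv2D(c_out, c_out, 3, rng=rng), nn.ReLU())

    def params(self):
        return self.block.params()

    def forward(self, x, train=True):
        return self.block.forward(x, train=train)

    def backward(self, grad):
        return self.block.backward(grad)


class UNet:
    """Shallow U-Net autoencoder (NCHW, single input channel).

    Encoder: ``depth`` double-conv stages with 2x max-pooling; bottleneck
    double conv; decoder: nearest upsampling + conv, skip concatenation,
    double conv; final 1x1 conv back to one channel.
    """

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        bf, depth = config.base_filters, config.depth
        self.enc = []
        c = 1
        for lvl in range(depth):
            self.enc.append(_DoubleConv(c, bf * 2 ** lvl, rng))
            c = bf * 2 ** lvl
        self.pool = nn.MaxPool2D(2)
        self.bottleneck = _DoubleConv(c, bf * 2 ** depth, rng)
        c = bf * 2 ** depth
        self.up_convs, self.dec = [], []
        for lvl in reversed(range(depth)):
            c_skip = bf * 2 ** lvl
            self.up_convs.append(nn.Conv2D(c, c_skip, 3, rng=rng))
            self.dec.append(_DoubleConv(2 * c_skip, c_skip, rng))
            c = c_skip
        self.up = nn.Upsample2D(2)
        self.head = nn.Conv2D(c, 1, 1, pad=0, rng=rng)

    def params(self):
        out = []
        for block in (*self.enc, self.bottleneck, *self.up_convs, *self.dec,
                      self.head):
            out.extend(block.params())
        return out

    def forward(self, x, train=True):
        self._pools = []
        skips = []
        for block in self.enc:
            x = block.forward(x, train)
            skips.append(x)
            pool = nn.MaxPool2D(2)
            x = pool.forward(x, train)
            self._pools.append(pool)
        x = self.bottleneck.forward(x, train)
        self.bottleneck_out = x
        self._ups = []
        self._skip_channels = []
        for up_conv, dec, skip in zip(self.up_convs, self.dec,
                                      reversed(skips)):
            up = nn.Upsample2D(2)
            x = up.forward(x, train)
            self._ups.append(up)
            x = up_conv.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, grad):
        grad = self.head.backward(grad)
        skip_grads = []
        for i in reversed(range(len(self.dec))):
            grad = self.dec[i].backward(grad)
            c_skip = self._skip_channels[i]
            g_skip, grad = grad[:, :c_skip], grad[:, c_skip:]
            skip_grads.append(g_skip)
            grad = self.up_convs[i].backward(grad)
            grad = self._ups[i].backward(grad)
        grad = self.bottleneck.backward(grad)
        # dec[i] pairs with enc[depth-1-i], so the reversed walk above
        # appended skip gradients already in encoder order
        for i in reversed(range(len(self.enc))):
            grad = self._pools[i].backward(grad)
            grad = grad + skip_grads[i]
            grad = self.enc[i].backward(grad)
        return grad

    def bottleneck_dim(self, input_size: int) -> int:
        """Feature dimension: base_filters * 2**depth * (input / 2**depth)^2."""
        cfg = self.config
        spatial = input_size // 2 ** cfg.depth
        return cfg.base_filters * 2 ** cfg.depth * spatial * spatial


def early_stop_epoch(losses, patience: int) -> int:
    """Number of epochs a patience-based early stopper would train.

    The counter resets on strict improvement of the best loss so far and
    training stops once ``patience`` consecutive non-improving epochs have
    accumulated.
    """
    best = np.inf
    streak = 0
    for e, loss in enumerate(losses):
        if loss < best:
            best, streak = loss, 0
        else:
            streak += 1
            if streak >= patience:
                return e + 1
    return len(losses)


def train_autoencoder(images, config: UNetConfig):
    """Train the U-Net as an MSE autoencoder; returns ``(model, log)``.

    ``images`` is a list/array of same-shape 2-D images (sides divisible by
    2**depth); a seeded ``validation_fraction`` split drives early stopping
    on validation loss; the log records per-epoch training loss,
    validation loss and validation MAE.
    """
    X = np.stack([np.asarray(im, dtype=float) for im in images])[:, None]
    if X.shape[0] < config.batch_size:
        raise ValueError("need at least batch_size images")
    if any(s % 2 ** config.depth for s in X.shape[2:]):
        raise ValueError("image sides must be divisible by 2**depth")
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val, tr = perm[:n_val], perm[n_val:]
    model = UNet(config)
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    log = {"loss": [], "val_loss": [], "val_mae": []}
    best = np.inf
    streak = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(tr)
        losses = []
        for start in range(0, len(order), config.batch_size):
            xb = X[order[start:start + config.batch_size]]
            out = model.forward(xb, train=True)
            loss, dout = nn.mse_loss(out, xb)
            model.backward(dout)
            opt.step()
            losses.append(loss)
        out_val = model.forward(X[val], train=False)
        val_loss = float(np.mean((out_val - X[val]) ** 2))
        log["loss"].append(float(np.mean(losses)))
        log["val_loss"].append(val_loss)
        log["val_mae"].append(float(np.mean(np.abs(out_val - X[val]))))
        if val_loss < best:
            best, streak = val_loss, 0
        else:
            streak += 1
            if streak >= config.patience:
                break
    return model, log


def extract_features(model: UNet, image) -> np.ndarray:
    """Flattened bottleneck activations of one image (a fixed-dim vector)."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D image")
    if any(s % 2 ** model.config.depth for s in arr.shape):
        raise ValueError("image sides must be divisible by 2**depth")
    model.forward(arr[None, None], train=False)
    vec = model.bottleneck_out.reshape(-1)
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite bottleneck activations")
    return vec.copy()
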