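"""The small spectrogram CNN: four Conv-MaxPool-Dropout blocks, GAP, softmax.

Architecture (input 40 x 862 x 1):

    Conv2D(16, kernel 2, ReLU, valid) - MaxPool(2) - Dropout(0.2)  -> 19 x 430 x 16
    Conv2D(32, ...)                   - MaxPool(2) - Dropout(0.2)  ->  9 x 214 x 32
    Conv2D(64, ...)                   - MaxPool(2) - Dropout(0.2)  ->  4 x 106 x 64
    Conv2D(128, ...)                  - MaxPool(2) - Dropout(0.2)  ->  1 x  52 x 128
    GlobalAveragePooling2D                                         -> 128
    Dense(2, softmax)                                              -> 2

Convolutions are unpadded ("valid": each spatial extent shrinks by 1 for a
2 x 2 kernel) and pooling uses floor division; both are forced by the shape
trace above.  The network is implemented directly on numpy (im2col convolution,
explicit backprop) and trained with Adam on categorical cross-entropy.
Dropout is inverted and active only during training, so inference is
deterministic.  All arithmetic is float32.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .features import FeatureMatrix


class LayerShape(NamedTuple):
    height: int
    width: int
    channels: int


@dataclass
class ModelConfig:
    input_bins: int = 40
    input_frames: int = 862
    input_channels: int = 1
    block_filters: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 2
    pool: int = 2
    dropout_rate: float = 0.2
    n_labels: int = 2

    def __post_init__(self) -> None:
        self.block_filters = tuple(self.block_filters)
        if any(b <= a for a, b in zip(self.block_filters, self.block_filters[1:])):
            raise ValueError("block_filters must be strictly increasing")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.kernel < 1 or self.pool < 1:
            raise ValueError("kernel and pool must be >= 1")
        if min(self.input_bins, self.input_frames, self.input_channels) < 1:
            raise ValueError("input extents must be >= 1")
        if self.n_labels < 2:
            raise ValueError("n_labels must be >= 2")


@dataclass
class TrainConfig:
    """Adam + categorical cross-entropy training hyperparameters.

    The optimizer choice is fixed (Adam); step size and moment decays default
    to the standard 1e-3 / 0.9 / 0.999.
    """

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def output_shapes(config: ModelConfig) -> list:
    """Per-block output shapes, then the pooled-vector length and label count.

    A kernel-k unpadded convolution maps (h, w) -> (h-k+1, w-k+1); a p x p max
    pool maps (h, w) -> (h//p, w//p).  Raises if any extent falls below 1.
    """
    h, w = config.input_bins, config.input_frames
    shapes: list = []
    for i, filters in enumerate(config.block_filters):
        h, w = h - config.kernel + 1, w - config.kernel + 1
        if h < 1 or w < 1:
            raise ValueError(f"input too small for block {i + 1} (conv output {h}x{w})")
        h, w = h // config.pool, w // config.pool
        if h < 1 or w < 1:
            raise ValueError(f"input too small for block {i + 1} (pool output {h}x{w})")
        shapes.append(LayerShape(h, w, filters))
    shapes.append(config.block_filters[-1])
    shapes.append(config.n_labels)
    return shapes


def parameter_count(config: ModelConfig) -> int:
    """Trainable parameters: conv (k*k*c_in + 1)*c_out per block, dense (c+1)*n."""
    k = config.kernel
    c_in = config.input_channels
    total = 0
    for c_out in config.block_filters:
        total += (k * k * c_in + 1) * c_out
        c_in = c_out
    total += (config.block_filters[-1] + 1) * config.n_labels
    return total


def _conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 2-D convolution, NHWC layout. w: (k, k, c_in, c_out)."""
    k = w.shape[0]
    n, h, hw, c_in = x.shape
    ho, wo = h - k + 1, hw - k + 1
    cols = np.empty((n, ho, wo, k * k * c_in), dtype=x.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            cols[..., idx : idx + c_in] = x[:, di : di + ho, dj : dj + wo, :]
            idx += c_in
    out = cols.reshape(-1, k * k * c_in) @ w.reshape(-1, w.shape[-1])
    out = out.reshape(n, ho, wo, -1)
    out += b
    return out, cols


def _conv2d_backward(
    grad: np.ndarray, cols: np.ndarray, x_shape: tuple, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = w.shape[0]
    n, h, hw, c_in = x_shape
    ho, wo = grad.shape[1], grad.shape[2]
    g2 = grad.reshape(-1, grad.shape[-1])
    dw = (cols.reshape(-1, k * k * c_in).T @ g2).reshape(w.shape)
    db = g2.sum(axis=0)
    dcols = (g2 @ w.reshape(-1, w.shape[-1]).T).reshape(n, ho, wo, k * k * c_in)
    dx = np.zeros(x_shape, dtype=grad.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            dx[:, di : di + ho, dj : dj + wo, :] += dcols[..., idx : idx + c_in]
            idx += c_in
    return dx, dw, db


def _pool_views(x: np.ndarray, p: int) -> list[np.ndarray]:
    """Strided (n, h//p, w//p, c) views, one per in-window position, row-major order."""
    n, h, w, c = x.shape
    ho, wo = h // p, w // p
    return [
        x[:, di : ho * p : p, dj : wo * p : p, :]
        for di in range(p)
        for dj in range(p)
    ]


def _maxpool_forward(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """p x p max pool with floor division; ties go to the first window element.

    Returns the pooled map and an int8 winner index per output element
    (position within the window in row-major order), used by the backward pass.
    """
    views = _pool_views(x, p)
    out = views[0].copy()
    idx = np.zeros(out.shape, dtype=np.int8)
    for k, v in enumerate(views[1:], start=1):
        better = v > out
        np.maximum(out, v, out=out)
        idx[better] = k
    return out, idx


def _maxpool_backward(grad: np.ndarray, idx: np.ndarray, x_shape: tuple, p: int) -> np.ndarray:
    dx = np.zeros(x_shape, dtype=grad.dtype)
    for k, v in enumerate(_pool_views(dx, p)):
        np.add(v, grad * (idx == k), out=v)
    return dx


class CNNClassifier:
    """Trainable CNN with deterministic initialization and inference.

    ``seed`` controls weight initialization; training randomness (shuffling,
    dropout masks) is controlled by :class:`TrainConfig.rng_seed`.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        c_in = config.input_channels
        k = config.kernel
        for c_out in config.block_filters:
            fan_in = k * k * c_in
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, c_in, c_out))
            self.weights.append(w.astype(np.float32))
            self.biases.append(np.zeros(c_out, dtype=np.float32))
            c_in = c_out
        d = config.block_filters[-1]
        self.dense_w = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, config.n_labels)).astype(
            np.float32
        )
        self.dense_b = np.zeros(config.n_labels, dtype=np.float32)
        self.loss_history: list[float] = []
        self._shapes = output_shapes(config)

    # -- forward ----------------------------------------------------------

    def _forward(
        self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None
    ):
        cfg = self.config
        caches = []
        a = x.astype(np.float32)
        for w, b in zip(self.weights, self.biases):
            z, cols = _conv2d_forward(a, w, b)
            relu_mask = z > 0
            z *= relu_mask
            pooled, pool_mask = _maxpool_forward(z, cfg.pool)
            drop_mask = None
            if train and cfg.dropout_rate > 0:
                keep = 1.0 - cfg.dropout_rate
                u = rng.random(pooled.shape, dtype=np.float32)
                drop_mask = (u < keep).astype(np.float32) / np.float32(keep)
                pooled *= drop_mask
            caches.append((a.shape, cols, relu_mask, z.shape, pool_mask, drop_mask))
            a = pooled
        gap = a.mean(axis=(1, 2))
        logits = gap @ self.dense_w + self.dense_b
        logits = logits - logits.max(axis=1, keepdims=True)
        exp = np.exp(logits)
        probs = exp / exp.sum(axis=1, keepdims=True)
        return probs, gap, a.shape, caches

    def introspect_shapes(self) -> list:
        """Shapes observed by pushing a dummy input through the network."""
        cfg = self.config
        x = np.zeros((1, cfg.input_bins, cfg.input_frames, cfg.input_channels), np.float32)
        shapes: list = []
        a = x
        for w, b in zip(self.weights, self.biases):
            z, _ = _conv2d_forward(a, w, b)
            a, _ = _maxpool_forward(z, cfg.pool)
            shapes.append(LayerShape(a.shape[1], a.shape[2], a.shape[3]))
        gap = a.mean(axis=(1, 2))
        shapes.append(gap.shape[1])
        shapes.append((gap @ self.dense_w + self.dense_b).shape[1])
        return shapes

    def parameter_count(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases)) + (
            self.dense_w.size + self.dense_b.size
        )

    # -- training ---------------------------------------------------------

    def _backward(self, probs, onehot, gap, pooled_shape, caches, batch_n):
        cfg = self.config
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.weights)
        dlogits = (probs - onehot) / batch_n
        d_dense_w = gap.T @ dlogits
        d_dense_b = dlogits.sum(axis=0)
        dgap = dlogits @ self.dense_w.T
        n, h, w_, c = pooled_shape
        da = np.broadcast_to(
            dgap[:, None, None, :] / (h * w_), pooled_shape
        ).astype(np.float32)
        for i in range(len(self.weights) - 1, -1, -1):
            x_shape, cols, relu_mask, z_shape, pool_mask, drop_mask = caches[i]
            if drop_mask is not None:
                da = da * drop_mask
            dz = _maxpool_backward(da, pool_mask, z_shape, cfg.pool)
            dz *= relu_mask
            da, grads_w[i], grads_b[i] = _conv2d_backward(dz, cols, x_shape, self.weights[i])
        return grads_w, grads_b, d_dense_w, d_dense_b

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        tcfg: TrainConfig,
    ) -> list[float]:
        """Train on (N, H, W, C) inputs and integer labels; returns loss history."""
        cfg = self.config
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y)
        if x.ndim != 4 or x.shape[1:] != (cfg.input_bins, cfg.input_frames, cfg.input_channels):
            raise ValueError(
                f"expected input shape (N, {cfg.input_bins}, {cfg.input_frames}, "
                f"{cfg.input_channels}), got {x.shape}"
            )
        if len(np.unique(y)) < 2:
            raise ValueError("training requires at least one sample of each class")
        onehot_full = np.eye(cfg.n_labels, dtype=np.float32)[y]
        rng = np.random.default_rng(tcfg.rng_seed)

        params = self.weights + self.biases + [self.dense_w, self.dense_b]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        nb = len(self.weights)
        for _ in range(tcfg.epochs):
            order = rng.permutation(len(x))
            epoch_losses = []
            for start in range(0, len(x), tcfg.batch_size):
                idx = order[start : start + tcfg.batch_size]
                xb, yb = x[idx], onehot_full[idx]
                probs, gap, pooled_shape, caches = self._forward(xb, train=True, rng=rng)
                loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
                epoch_losses.append(float(loss) * len(idx))
                gw, gb, gdw, gdb = self._backward(
                    probs, yb, gap, pooled_shape, caches, len(idx)
                )
                grads = gw + gb + [gdw, gdb]
                t += 1
                lr_t = (
                    tcfg.learning_rate
                    * np.sqrt(1 - tcfg.beta2**t)
                    / (1 - tcfg.beta1**t)
                )
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = tcfg.beta1 * m[j] + (1 - tcfg.beta1) * g
                    v[j] = tcfg.beta2 * v[j] + (1 - tcfg.beta2) * g * g
                    p -= lr_t * m[j] / (np.sqrt(v[j]) + tcfg.eps)
            self.loss_history.append(sum(epoch_losses) / len(x))
        # params were updated in place; re-bind for clarity
        self.weights, self.biases = params[:nb], params[nb : 2 * nb]
        self.dense_w, self.dense_b = params[-2], params[-1]
        return self.loss_history

    # -- inference --------------------------------------------------------

    def predict_proba(self, features) -> np.ndarray:
        """Class probabilities for one FeatureMatrix/array or a batch.

        Returns shape (n_labels,) for a single input, (N, n_labels) for a batch.
        """
        x, single = self._as_batch(features)
        probs, *_ = self._forward(x, train=False)
        return probs[0] if single else probs

    def predict(self, features) -> np.ndarray | int:
        p = self.predict_proba(features)
        return int(np.argmax(p)) if p.ndim == 1 else np.argmax(p, axis=1)

    def _as_batch(self, features) -> tuple[np.ndarray, bool]:
        cfg = self.config
        if isinstance(features, FeatureMatrix):
            arr = features.values[None, :, :, None]
            single = True
        else:
            arr = np.asarray(features, dtype=np.float32)
            single = arr.ndim in (2, 3)
            if arr.ndim == 2:
                arr = arr[None, :, :, None]
            elif arr.ndim == 3:
                arr = arr[None]
        if arr.shape[1:] != (cfg.input_bins, cfg.input_frames, cfg.input_channels):
            raise ValueError(
                f"expected shape ({cfg.input_bins}, {cfg.input_frames}, "
                f"{cfg.input_channels}), got {arr.shape[1:]}"
            )
        return arr.astype(np.float32), single

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"conv_w{i}": w for i, w in enumerate(self.weights)}
        arrays |= {f"conv_b{i}": b for i, b in enumerate(self.biases)}
        arrays |= {"dense_w": self.dense_w, "dense_b": self.dense_b}
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"config": asdict(self.config), "seed": self.seed})
        )

    @classmethod
    def load(cls, path: str | Path) -> "CNNClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        cfg_d = meta["config"]
        cfg_d["block_filters"] = tuple(cfg_d["block_filters"])
        model = cls(ModelConfig(**cfg_d), seed=meta["seed"])
        npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        with np.load(npz_path) as data:
            model.weights = [data[f"conv_w{i}"] for i in range(len(model.weights))]
            model.biases = [data[f"conv_b{i}"] for i in range(len(model.biases))]
            model.dense_w = data["dense_w"]
            model.dense_b = data["dense_b"]
        return model


def build(config: ModelConfig, seed: int = 0) -> CNNClassifier:
    """Assemble the CNN with deterministic (seeded) initialization."""
    output_shapes(config)  # validates the stack fits the input
    return CNNClassifier(config, seed=seed)


def train(
    classifier: CNNClassifier,
    features: Sequence[FeatureMatrix] | np.ndarray,
    labels: Sequence[int],
    tcfg: TrainConfig,
) -> tuple[CNNClassifier, list[float]]:
    """Train on a list of 40x862 FeatureMatrix (or a prepared array) and labels."""
    if isinstance(features, np.ndarray):
        x = features
    else:
        x = np.stack([f.values for f in features])[..., None]
    history = classifier.fit(x, np.asarray(labels, dtype=int), tcfg)
    return classifier, history
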