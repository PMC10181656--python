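"""Model adapters and a tiny CAM-compatible convolutional classifier.

The saliency methods only need a narrow contract from a model: class scores,
the activations of a designated last convolutional layer, the gradients of a
class score with respect to those activations, and — for CAM — the global-
average-pooled values and the softmax classifier weights.  That contract is
:class:`ModelAdapter`.

:class:`TinyCNN` implements it with a four-stage convolutional stack
(16/32/64/128 filters; the first kernel 2x2, the rest 3x3; ReLU; a 2x2
max-pool after each of the first three stages) followed by global average
pooling and a single dense softmax layer over two classes — the canonical
CAM-compatible shape.  Forward, backward and Adam training are written
directly on numpy (im2col convolutions), which keeps every run bit-for-bit
reproducible from its seed.

GAP is implemented as the spatial *mean*; the sum variant differs only by
the constant number of spatial positions Z, which is absorbed when saliency
maps are min-max normalised before thresholding.
"""

from __future__ import annotations

import abc
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .synthetic import ConfigurationError, ImageSample

logger = logging.getLogger(__name__)

__all__ = [
    "ModelAdapter",
    "TinyCNN",
    "TrainConfig",
    "EvalMetrics",
    "build_tiny_cnn",
    "train",
    "evaluate",
    "save_checkpoint",
    "load_checkpoint",
]


class ModelAdapter(abc.ABC):
    """Contract between a classifier and the saliency computations.

    Images are channels-last float arrays (H, W, C); feature maps are
    channels-last (h, w, K).
    """

    id: str
    cam_compatible: bool

    @abc.abstractmethod
    def score(self, image: np.ndarray, class_c: int) -> float:
        """Pre-softmax score y^c of class ``class_c``."""

    @abc.abstractmethod
    def probabilities(self, image: np.ndarray) -> np.ndarray:
        """Softmax class probabilities; sums to 1."""

    @abc.abstractmethod
    def feature_maps(self, image: np.ndarray) -> np.ndarray:
        """Activations A^k of the last convolutional layer, shape (h, w, K)."""

    @abc.abstractmethod
    def feature_gradients(self, image: np.ndarray, class_c: int) -> np.ndarray:
        """Gradients dy^c / dA^k_ij, same shape as :meth:`feature_maps`."""

    @abc.abstractmethod
    def gap_values(self, image: np.ndarray) -> np.ndarray:
        """Globally average-pooled feature values F_k, shape (K,)."""

    @abc.abstractmethod
    def classifier_weights(self, class_c: int) -> np.ndarray:
        """Dense softmax weights w_kc, shape (K,); CAM-compatible models only."""


# ---------------------------------------------------------------------------
# im2col convolution primitives (stride 1, 'same' padding)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,kh*kw*C) patch matrix with 'same' zero padding."""
    n, h, w, c = x.shape
    pt, pb = (kh - 1) // 2, kh // 2
    pl, pr = (kw - 1) // 2, kw // 2
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    s = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp, shape=(n, h, w, kh, kw, c), strides=(s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return patches.reshape(n, h, w, kh * kw * c)


def _col2im(cols: np.ndarray, x_shape: tuple, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to the input."""
    n, h, w, c = x_shape
    pt, pb = (kh - 1) // 2, kh // 2
    pl, pr = (kw - 1) // 2, kw // 2
    xp = np.zeros((n, h + pt + pb, w + pl + pr, c), dtype=cols.dtype)
    cols = cols.reshape(n, h, w, kh, kw, c)
    for di in range(kh):
        for dj in range(kw):
            xp[:, di : di + h, dj : dj + w, :] += cols[:, :, :, di, dj, :]
    return xp[:, pt : pt + h, pl : pl + w, :]


class _Conv:
    def __init__(self, kh, kw, c_in, c_out, rng):
        fan_in = kh * kw * c_in
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.kh, self.kw = kh, kw

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.kh, self.kw)
        return self._cols @ self.w + self.b

    def backward(self, grad):
        n, h, w, _ = grad.shape
        g2 = grad.reshape(-1, grad.shape[-1])
        self.gw = self._cols.reshape(g2.shape[0], -1).T @ g2
        self.gb = g2.sum(axis=0)
        gcols = g2 @ self.w.T
        return _col2im(gcols.reshape(n, h, w, -1), self._x_shape, self.kh, self.kw)

    @property
    def params(self):
        return [("w", self.w), ("b", self.b)]


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class _MaxPool2:
    def forward(self, x):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        self._argmask = xr == out[:, :, None, :, None, :]
        self._x_shape = x.shape
        return out

    def backward(self, grad):
        n, h2, w2, c = grad.shape
        mask = self._argmask
        # normalise ties: divide gradient equally among tied positions
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (grad[:, :, None, :, None, :] / counts)
        return g.reshape(self._x_shape)


class TinyCNN(ModelAdapter):
    """Four-conv-layer CNN with GAP and a dense softmax head (two classes)."""

    cam_compatible = True
    N_POOL = 3  # 2x2 max-pool after each of the first three conv stages

    def __init__(self, image_size: int, channels: int, seed: int, id: Optional[str] = None):
        if image_size < 16:
            raise ConfigurationError(
                f"image_size {image_size} too small for {self.N_POOL + 1} "
                "convolutional stages with pooling; need at least 16"
            )
        if image_size % (2**self.N_POOL) != 0:
            raise ConfigurationError(
                f"image_size must be divisible by {2 ** self.N_POOL}"
            )
        self.image_size = image_size
        self.channels = channels
        self.seed = seed
        self.id = id if id is not None else f"tinycnn_s{seed}"

        rng = np.random.default_rng(seed)
        self.conv = [
            _Conv(2, 2, channels, 16, rng),
            _Conv(3, 3, 16, 32, rng),
            _Conv(3, 3, 32, 64, rng),
            _Conv(3, 3, 64, 128, rng),
        ]
        self.relu = [_ReLU() for _ in range(4)]
        self.pool = [_MaxPool2() for _ in range(self.N_POOL)]
        k = 128
        self.wd = (rng.normal(0, np.sqrt(1.0 / k), (k, 2))).astype(np.float32)
        self.bd = np.zeros(2, dtype=np.float32)
        # fixed per-channel standardisation of the GAP vector, set once from
        # the training data before optimisation (data-dependent init).  It is
        # a frozen diagonal affine, so it folds into the dense layer: the
        # effective classifier weights are wd / feat_sd and CAM stays exact.
        self.feat_mu = np.zeros(k, dtype=np.float32)
        self.feat_sd = np.ones(k, dtype=np.float32)

    # -- forward ------------------------------------------------------------

    def _forward_conv(self, x: np.ndarray) -> np.ndarray:
        """Convolutional trunk: (N,H,W,C) -> last-conv activations (N,h,w,128)."""
        for i in range(4):
            x = self.relu[i].forward(self.conv[i].forward(x))
            if i < self.N_POOL:
                x = self.pool[i].forward(x)
        return x

    def _forward(
        self, x: np.ndarray, training: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a = self._forward_conv(x)
        gap = a.mean(axis=(1, 2))
        z = (gap - self.feat_mu) / self.feat_sd
        logits = z @ self.wd + self.bd
        return a, gap, logits

    def _batch(self, image: np.ndarray) -> np.ndarray:
        if image.ndim == 3:
            image = image[None]
        # centre [0,1] pixels to [-1,1]; zero-mean inputs condition the
        # early conv layers far better than raw intensities
        return (image.astype(np.float32) - 0.5) * 2.0

    # -- adapter contract ---------------------------------------------------

    def logits(self, images: np.ndarray) -> np.ndarray:
        return self._forward(self._batch(images))[2]

    def score(self, image: np.ndarray, class_c: int) -> float:
        return float(self.logits(image)[0, class_c])

    def probabilities(self, image: np.ndarray) -> np.ndarray:
        z = self.logits(image)[0]
        z = z - z.max()
        p = np.exp(z)
        return p / p.sum()

    def feature_maps(self, image: np.ndarray) -> np.ndarray:
        return self._forward_conv(self._batch(image))[0].astype(np.float64)

    def feature_gradients(self, image: np.ndarray, class_c: int) -> np.ndarray:
        """Backpropagate d y^c through the head (dense then GAP) to A^k.

        The score head is linear in the GAP values, so the gradient at each
        spatial position of map k is w_kc / Z with Z = h*w.
        """
        a = self._forward_conv(self._batch(image))
        _, h, w, k = a.shape
        # head backward, seeded with the one-hot vector of class_c:
        # dense -> d z = wd[:, c]; frozen standardisation -> d gap = d z / sd;
        # mean-GAP spreads each channel gradient uniformly over h*w positions
        dgap = self.classifier_weights(class_c)
        grad = np.broadcast_to(dgap / (h * w), (h, w, k)).copy()
        return grad

    def gap_values(self, image: np.ndarray) -> np.ndarray:
        return self.feature_maps(image).mean(axis=(0, 1))

    def classifier_weights(self, class_c: int) -> np.ndarray:
        """Effective dense weights acting on the raw GAP values.

        The frozen standardisation is a diagonal affine, so it folds into the
        dense layer: w_eff = wd / feat_sd (the mean shift only moves the
        bias, which CAM ignores).
        """
        return (self.wd[:, class_c] / self.feat_sd).astype(np.float64)

    # -- training -----------------------------------------------------------

    def _parameters(self):
        for conv in self.conv:
            yield conv, "w"
            yield conv, "b"
        yield self, "wd"
        yield self, "bd"

    def _backward(self, dlogits: np.ndarray, a: np.ndarray, gap: np.ndarray):
        """Full backward pass from logit gradients; stores parameter grads."""
        n, h, w, k = a.shape
        z = (gap - self.feat_mu) / self.feat_sd
        self.gwd = z.T @ dlogits
        self.gbd = dlogits.sum(axis=0)
        dgap = (dlogits @ self.wd.T) / self.feat_sd
        da = np.broadcast_to(dgap[:, None, None, :] / (h * w), a.shape)
        g = self.relu[3].backward(da)
        g = self.conv[3].backward(g)
        for i in (2, 1, 0):
            g = self.pool[i].backward(g)
            g = self.relu[i].backward(g)
            g = self.conv[i].backward(g)

    def _grads(self):
        for conv in self.conv:
            yield conv.gw
            yield conv.gb
        yield self.gwd
        yield self.gbd


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; optimiser is Adam with cross-entropy loss.

    The default regime is transfer-learning style: the convolutional trunk
    is frozen (``freeze_trunk=True``) and only the GAP+softmax head is
    trained, at ``head_learning_rate``.  Random convolutional projections of
    these images are already linearly separable, and joint full-network
    updates at desk scale destabilise the features faster than they improve
    them, so the frozen-trunk regime is both the fast and the robust one.
    ``freeze_trunk=False`` enables full joint training, with
    ``learning_rate`` on the trunk.
    """

    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    head_learning_rate: float = 1e-2
    freeze_trunk: bool = True
    seed: int = 0
    augment: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be a positive integer")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be a positive integer")
        if self.learning_rate <= 0 or self.head_learning_rate <= 0:
            raise ConfigurationError("learning rates must be positive")


@dataclass
class EvalMetrics:
    """Confusion-matrix counts and derived rates for binary classification."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float  # sensitivity
    specificity: float


def build_tiny_cnn(image_size: int, channels: int, seed: int, id: Optional[str] = None) -> TinyCNN:
    """Construct a seeded, CAM-compatible tiny CNN adapter."""
    return TinyCNN(image_size, channels, seed, id=id)


def _stack(samples: Sequence[ImageSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.pixels for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.int64)
    return x, y


def train(
    adapter: TinyCNN,
    samples: Sequence[ImageSample],
    cfg: TrainConfig,
) -> tuple[TinyCNN, list[dict]]:
    """Train on the train split with Adam; returns the adapter and a history.

    History has one record per epoch with train and test accuracy.  The run
    is deterministic given ``cfg.seed`` (numpy backend, no threading
    nondeterminism).
    """
    from . import synthetic as _syn

    train_samples = [s for s in samples if s.split == "train"]
    test_samples = [s for s in samples if s.split == "test"]
    labels = {s.label for s in train_samples}
    if labels != {0, 1}:
        raise ValueError(
            f"training split must contain both classes; found labels {sorted(labels)}"
        )

    rng = np.random.default_rng(cfg.seed)
    if cfg.augment:
        train_samples = [_syn.augment(s, rng) for s in train_samples]
    x_train, y_train = _stack(train_samples)
    x_test, y_test = _stack(test_samples) if test_samples else (None, None)

    # data-dependent init: freeze the GAP standardisation to the train-set
    # statistics of the initial network (constant offsets in the features
    # would otherwise dominate Adam's second moment and stall the head)
    adapter.feat_mu = np.zeros(128, dtype=np.float32)
    adapter.feat_sd = np.ones(128, dtype=np.float32)
    g = _gap_features(adapter, x_train)
    adapter.feat_mu = g.mean(axis=0).astype(np.float32)
    adapter.feat_sd = np.maximum(g.std(axis=0), 1e-4).astype(np.float32)

    if cfg.freeze_trunk:
        return _train_head(adapter, cfg, x_train, y_train, x_test, y_test, rng)
    return _train_full(adapter, cfg, x_train, y_train, x_test, y_test, rng)


def _gap_features(adapter: TinyCNN, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    gaps = []
    for start in range(0, len(x), chunk):
        a = adapter._forward_conv(adapter._batch(x[start : start + chunk]))
        gaps.append(a.mean(axis=(1, 2)))
    return np.concatenate(gaps)


class _Adam:
    def __init__(self, arrays: list, lrs: list):
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.lrs = lrs
        self.t = 0

    def step(self, arrays: list, grads: list) -> None:
        self.t += 1
        for i, (arr, g) in enumerate(zip(arrays, grads)):
            self.m[i] = 0.9 * self.m[i] + 0.1 * g
            self.v[i] = 0.999 * self.v[i] + 0.001 * g * g
            mh = self.m[i] / (1 - 0.9**self.t)
            vh = self.v[i] / (1 - 0.999**self.t)
            arr -= (self.lrs[i] * mh / (np.sqrt(vh) + 1e-8)).astype(arr.dtype)


def _softmax_grad(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    d = p
    d[np.arange(len(y)), y] -= 1.0
    return d / len(y)


def _train_head(adapter, cfg, x_train, y_train, x_test, y_test, rng):
    """Frozen-trunk training: Adam on the dense head over cached features."""
    z_train = ((_gap_features(adapter, x_train) - adapter.feat_mu) / adapter.feat_sd)
    z_test = (
        ((_gap_features(adapter, x_test) - adapter.feat_mu) / adapter.feat_sd)
        if x_test is not None else None
    )
    opt = _Adam(
        [adapter.wd, adapter.bd],
        [cfg.head_learning_rate, cfg.head_learning_rate],
    )
    n = len(z_train)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            zb, yb = z_train[idx], y_train[idx]
            dlogits = _softmax_grad(zb @ adapter.wd + adapter.bd, yb).astype(np.float32)
            opt.step(
                [adapter.wd, adapter.bd],
                [zb.T @ dlogits, dlogits.sum(axis=0)],
            )
        train_acc = float(((z_train @ adapter.wd + adapter.bd).argmax(1) == y_train).mean())
        test_acc = (
            float(((z_test @ adapter.wd + adapter.bd).argmax(1) == y_test).mean())
            if z_test is not None else float("nan")
        )
        history.append({"epoch": epoch + 1, "train_acc": train_acc, "test_acc": test_acc})
        logger.info(
            "model %s epoch %d/%d train_acc %.3f test_acc %.3f",
            adapter.id, epoch + 1, cfg.epochs, train_acc, test_acc,
        )
    return adapter, history


def _train_full(adapter, cfg, x_train, y_train, x_test, y_test, rng):
    """Joint training of trunk and head."""
    params = [(obj, name) for obj, name in adapter._parameters()]
    opt = _Adam(
        [getattr(o, n) for o, n in params],
        [
            cfg.head_learning_rate if name in ("wd", "bd") else cfg.learning_rate
            for _, name in params
        ],
    )
    n = len(x_train)
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            a, gap, logits = adapter._forward(xb, training=True)
            dlogits = _softmax_grad(logits, yb).astype(np.float32)
            adapter._backward(dlogits, a, gap)
            opt.step([getattr(o, n_) for o, n_ in params], list(adapter._grads()))
        train_acc = _accuracy(adapter, x_train, y_train)
        test_acc = _accuracy(adapter, x_test, y_test) if x_test is not None else float("nan")
        history.append({"epoch": epoch + 1, "train_acc": train_acc, "test_acc": test_acc})
        logger.info(
            "model %s epoch %d/%d train_acc %.3f test_acc %.3f",
            adapter.id, epoch + 1, cfg.epochs, train_acc, test_acc,
        )
    return adapter, history


def _predict(adapter: TinyCNN, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    preds = []
    for start in range(0, len(x), chunk):
        logits = adapter.logits(x[start : start + chunk])
        preds.append(np.argmax(logits, axis=1))  # argmax ties break toward class 0
    return np.concatenate(preds)


def _accuracy(adapter: TinyCNN, x: np.ndarray, y: np.ndarray) -> float:
    return float((_predict(adapter, x) == y).mean())


def evaluate(adapter: ModelAdapter, samples: Sequence[ImageSample]) -> EvalMetrics:
    """Confusion-matrix metrics of the adapter's argmax predictions."""
    if not samples:
        raise ValueError("evaluate requires at least one sample")
    x, y = _stack(samples)
    pred = _predict(adapter, x)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    total = tp + tn + fp + fn
    return EvalMetrics(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / total,
        precision=tp / (tp + fp) if tp + fp > 0 else float("nan"),
        recall=tp / (tp + fn) if tp + fn > 0 else float("nan"),
        specificity=tn / (tn + fp) if tn + fp > 0 else float("nan"),
    )


# ---------------------------------------------------------------------------
# checkpoints (numpy .npz)


def save_checkpoint(adapter: TinyCNN, path: str) -> None:
    arrays = {
        "meta": np.array([adapter.image_size, adapter.channels, adapter.seed]),
        "wd": adapter.wd, "bd": adapter.bd,
        "feat_mu": adapter.feat_mu, "feat_sd": adapter.feat_sd,
    }
    for i, conv in enumerate(adapter.conv):
        arrays[f"conv{i}_w"] = conv.w
        arrays[f"conv{i}_b"] = conv.b
    np.savez(path, id=np.array(adapter.id), **arrays)


def load_checkpoint(path: str) -> TinyCNN:
    data = np.load(path, allow_pickle=False)
    size, channels, seed = (int(v) for v in data["meta"])
    adapter = TinyCNN(size, channels, seed, id=str(data["id"]))
    for i, conv in enumerate(adapter.conv):
        conv.w = data[f"conv{i}_w"]
        conv.b = data[f"conv{i}_b"]
    adapter.wd = data["wd"]
    adapter.bd = data["bd"]
    adapter.feat_mu = data["feat_mu"]
    adapter.feat_sd = data["feat_sd"]
    return adapter
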