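"""Compact CNN backbones for EEG trial classification.

Three architectures are provided as per-band models:

``shallow``
    One temporal convolution, a spatial convolution spanning all
    channels, batch normalization, squaring, average pooling and a log —
    i.e. a trainable log-bandpower feature extractor — followed by a
    dense softmax layer.  This mirrors the classic shallow
    temporal-spatial convnet used throughout MI-EEG decoding.
``eegnet``
    An EEGNet-style compact network: temporal convolution, depthwise
    spatial convolution, then a separable (depthwise temporal +
    pointwise) convolution, each block with batch norm, ELU, average
    pooling and dropout, ending in a dense softmax.
``deep``
    A deeper temporal-spatial convnet with four conv/max-pool blocks.

All backbones accept arbitrary ``(channels, samples)`` input, computing
the dense-layer size from the shape, and satisfy the
:class:`ClassifierModel` contract: ``predict_proba`` returns a valid
probability vector per trial and is deterministic in evaluation mode.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from . import _nn

__all__ = ["BackboneConfig", "ClassifierModel", "build_backbone", "BACKBONE_REGISTRY"]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters.

    Defaults are the cited shallow-convnet settings at 250 Hz: temporal
    kernel 25 samples, 40 temporal and 40 spatial filters, average pool
    75 with stride 15, dropout 0.5.  ``eegnet()`` and ``deep()`` supply
    the conventional defaults of those architectures.
    """

    arch: str = "shallow"
    temporal_kernel_len: int = 25
    n_temporal_filters: int = 40
    n_spatial_filters: int = 40
    pool_len: int = 75
    pool_stride: int = 15
    dropout_rate: float = 0.5
    # eegnet extras
    depth_multiplier: int = 2
    separable_kernel_len: int = 16
    n_pointwise_filters: int = 16

    def __post_init__(self) -> None:
        if self.arch not in ("shallow", "eegnet", "deep"):
            raise ValueError(f"unknown arch {self.arch!r}")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError(f"dropout_rate must lie in [0, 1), got {self.dropout_rate}")
        for name in ("temporal_kernel_len", "n_temporal_filters", "n_spatial_filters",
                     "pool_len", "pool_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def shallow(cls, **kw) -> "BackboneConfig":
        return cls(arch="shallow", **kw)

    @classmethod
    def eegnet(cls, **kw) -> "BackboneConfig":
        defaults = dict(
            arch="eegnet",
            temporal_kernel_len=64,
            n_temporal_filters=8,
            n_spatial_filters=16,  # F1 * depth_multiplier
            pool_len=4,
            pool_stride=4,
            dropout_rate=0.5,
        )
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def deep(cls, **kw) -> "BackboneConfig":
        defaults = dict(
            arch="deep",
            temporal_kernel_len=10,
            n_temporal_filters=25,
            n_spatial_filters=25,
            pool_len=3,
            pool_stride=3,
            dropout_rate=0.5,
        )
        defaults.update(kw)
        return cls(**defaults)


class ClassifierModel:
    """A trainable per-band classifier emitting class probabilities.

    Wraps a :class:`ofbcnn._nn.Sequential` network together with its
    input contract.  Identical seeds yield identical initial parameters;
    ``predict_proba`` runs the network in evaluation mode (dropout off,
    batch-norm running statistics), so it is deterministic.
    """

    #: chunk size for evaluation-mode forward passes; bounds the size of
    #: the convolution workspaces on long trials
    EVAL_CHUNK = 32

    def __init__(self, net: _nn.Sequential, config: BackboneConfig,
                 input_shape: tuple[int, int], class_count: int, rng_seed: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.net = net
        self.config = config
        self.input_shape = tuple(input_shape)
        self.class_count = class_count
        self.rng_seed = rng_seed
        self.rng = rng  # drives dropout masks during training
        self.dtype = np.dtype(dtype)

    def _check_shape(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1:] != self.input_shape:
            raise ValueError(
                f"trial shape mismatch: expected (*, {self.input_shape[0]}, "
                f"{self.input_shape[1]}), got {X.shape}"
            )
        return X

    def logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(self._check_shape(X), training=training)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, shape (n_trials, C); (C,) for a single trial."""
        single = np.asarray(X).ndim == 2
        X = self._check_shape(X)
        chunks = [
            _nn.softmax(self.net.forward(X[i : i + self.EVAL_CHUNK], training=False))
            for i in range(0, X.shape[0], self.EVAL_CHUNK)
        ]
        p = np.concatenate(chunks).astype(np.float64)
        p /= p.sum(axis=1, keepdims=True)
        return p[0] if single else p

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        return int(np.argmax(p)) if p.ndim == 1 else np.argmax(p, axis=1)


def _shallow_net(cfg: BackboneConfig, C: int, T: int, n_classes: int,
                 rng: np.random.Generator) -> _nn.Sequential:
    Tc = T - cfg.temporal_kernel_len + 1
    Tp = (Tc - cfg.pool_len) // cfg.pool_stride + 1
    if Tp < 1:
        raise ValueError(
            f"input of {T} samples too short for kernel {cfg.temporal_kernel_len} "
            f"and pool {cfg.pool_len}"
        )
    return _nn.Sequential([
        _nn.TemporalConv(cfg.n_temporal_filters, cfg.temporal_kernel_len, rng),
        _nn.SpatialConv(cfg.n_spatial_filters, cfg.n_temporal_filters, C, rng),
        _nn.BatchNorm(cfg.n_spatial_filters),
        _nn.Square(),
        _nn.AvgPool1d(cfg.pool_len, cfg.pool_stride),
        _nn.SafeLog(),
        _nn.Dropout(cfg.dropout_rate, rng),
        _nn.Flatten(),
        _nn.Dense(cfg.n_spatial_filters * Tp, n_classes, rng),
    ])


def _eegnet_net(cfg: BackboneConfig, C: int, T: int, n_classes: int,
                rng: np.random.Generator) -> _nn.Sequential:
    F1 = cfg.n_temporal_filters
    D = cfg.depth_multiplier
    F2 = cfg.n_pointwise_filters
    T1 = T - cfg.temporal_kernel_len + 1
    T1p = (T1 - cfg.pool_len) // cfg.pool_stride + 1
    T2 = T1p - cfg.separable_kernel_len + 1
    T2p = (T2 - 8) // 8 + 1
    if T2p < 1:
        raise ValueError(f"input of {T} samples too short for the eegnet block structure")
    return _nn.Sequential([
        _nn.TemporalConv(F1, cfg.temporal_kernel_len, rng),
        _nn.BatchNorm(F1),
        _nn.DepthwiseSpatialConv(F1, D, C, rng),
        _nn.BatchNorm(F1 * D),
        _nn.ELU(),
        _nn.AvgPool1d(cfg.pool_len, cfg.pool_stride),
        _nn.Dropout(cfg.dropout_rate, rng),
        _nn.DepthwiseConv1d(F1 * D, cfg.separable_kernel_len, rng),
        _nn.Conv1d(F2, F1 * D, 1, rng),
        _nn.BatchNorm(F2),
        _nn.ELU(),
        _nn.AvgPool1d(8, 8),
        _nn.Dropout(cfg.dropout_rate, rng),
        _nn.Flatten(),
        _nn.Dense(F2 * T2p, n_classes, rng),
    ])


def _deep_net(cfg: BackboneConfig, C: int, T: int, n_classes: int,
              rng: np.random.Generator) -> _nn.Sequential:
    K, L, s = cfg.temporal_kernel_len, cfg.pool_len, cfg.pool_stride
    widths = [cfg.n_temporal_filters, 2 * cfg.n_temporal_filters,
              4 * cfg.n_temporal_filters, 8 * cfg.n_temporal_filters]
    layers: list[_nn.Layer] = [
        _nn.TemporalConv(widths[0], K, rng),
        _nn.SpatialConv(cfg.n_spatial_filters, widths[0], C, rng),
        _nn.BatchNorm(cfg.n_spatial_filters),
        _nn.ELU(),
        _nn.MaxPool1d(L, s),
    ]
    t = (T - K + 1 - L) // s + 1
    n_in = cfg.n_spatial_filters
    for w in widths[1:]:
        t_next = ((t - K + 1) - L) // s + 1
        if t_next < 1:
            break  # trial too short for another block; stop deepening
        layers += [
            _nn.Dropout(cfg.dropout_rate, rng),
            _nn.Conv1d(w, n_in, K, rng),
            _nn.BatchNorm(w),
            _nn.ELU(),
            _nn.MaxPool1d(L, s),
        ]
        n_in, t = w, t_next
    layers += [_nn.Flatten(), _nn.Dense(n_in * t, n_classes, rng)]
    return _nn.Sequential(layers)


BACKBONE_REGISTRY = {
    "shallow": _shallow_net,
    "eegnet": _eegnet_net,
    "deep": _deep_net,
}


def register_backbone(name: str, builder) -> None:
    """Register a third-party builder ``f(cfg, C, T, n_classes, rng) -> Sequential``."""
    BACKBONE_REGISTRY[name] = builder


def _cast_layer_arrays(net: _nn.Sequential, dtype) -> None:
    names = ("W", "b", "gamma", "beta", "running_mean", "running_var",
             "dW", "db", "dgamma", "dbeta")
    for layer in net.layers:
        for name in names:
            arr = getattr(layer, name, None)
            if isinstance(arr, np.ndarray):
                setattr(layer, name, arr.astype(dtype))


def build_backbone(
    config: BackboneConfig,
    input_shape: tuple[int, int],
    class_count: int,
    rng_seed: int,
    dtype=np.float32,
) -> ClassifierModel:
    """Instantiate a backbone with seeded, reproducible initialization.

    ``dtype`` is the working precision of parameters and activations;
    single precision (the default) is standard for CNN training.
    """
    if class_count < 2:
        raise ValueError(f"class_count must be >= 2, got {class_count}")
    C, T = input_shape
    if config.temporal_kernel_len > T:
        raise ValueError(f"temporal kernel {config.temporal_kernel_len} longer than trial ({T})")
    rng = np.random.default_rng(rng_seed)
    net = BACKBONE_REGISTRY[config.arch](config, C, T, class_count, rng)
    _cast_layer_arrays(net, dtype)
    return ClassifierModel(net, config, input_shape, class_count, rng_seed, rng, dtype=dtype)
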