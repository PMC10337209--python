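"""Training: one backbone per band, cross-entropy loss, Adam.

Each band of the filter bank gets its own independently trained model.
Band n's inputs are the training trials filtered to band n and then
standardized; its model is initialized and batched from a per-band seed
``seed + n``, so training bands in any order (or in parallel) gives
identical per-band results.  No early stopping: the protocol trains for
a fixed number of epochs and summarizes test metrics over the final
epoch window (see :mod:`ofbcnn.evaluate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from . import _nn
from .backbones import BackboneConfig, ClassifierModel, build_backbone
from .ensemble import BandEnsemble
from .evaluate import EvalReport, classification_metrics
from .filterbank import FilterBankSpec
from .preprocess import DEFAULT_ALPHA, DEFAULT_EPS, TrialSet, band_preprocess

__all__ = ["TrainConfig", "train_model", "train_band_ensemble", "EnsembleTrainResult"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: fixed-epoch Adam with minibatches."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    eval_every: int = 1
    deterministic: bool = True  # kept for API clarity; numpy path is always deterministic
    alpha: float = DEFAULT_ALPHA  # standardization smoothing factor
    eps: float = DEFAULT_EPS  # standardization variance floor

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.eval_every < 1:
            raise ValueError(f"eval_every must be >= 1, got {self.eval_every}")


def train_model(
    model: ClassifierModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    seed: Optional[int] = None,
    X_test: Optional[np.ndarray] = None,
    y_test: Optional[np.ndarray] = None,
) -> dict:
    """Fit one model in place; returns the training trace.

    The trace holds per-epoch mean training loss and, when a test set is
    given, per-evaluated-epoch test metrics and the raw test probability
    matrix (used later for ensemble fusion).
    """
    X = np.asarray(X, dtype=model.dtype)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    opt = _nn.Adam(model.net.params(), lr=cfg.learning_rate)
    n = X.shape[0]
    trace: dict = {"loss": [], "test_metrics": {}, "test_proba": {}}
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.logits(X[idx], training=True)
            loss, g = _nn.softmax_cross_entropy(logits, y[idx])
            model.net.backward(g)
            opt.step()
            losses.append(loss)
        trace["loss"].append(float(np.mean(losses)))
        if X_test is not None and epoch % cfg.eval_every == 0:
            proba = model.predict_proba(X_test)
            pred = np.argmax(proba, axis=1)
            trace["test_metrics"][epoch] = classification_metrics(y_test, pred, proba)
            trace["test_proba"][epoch] = proba
    return trace


@dataclass
class EnsembleTrainResult:
    """Everything `train_band_ensemble` produces."""

    ensemble: BandEnsemble
    #: per-band training traces (loss, per-epoch test metrics/probabilities)
    band_traces: list[dict]
    #: per-epoch metrics of the summed-probability ensemble on the test set
    ensemble_per_epoch: dict[int, dict[str, float]]

    def report(self, window_len: int) -> EvalReport:
        """Final-window summary of the fused ensemble's test trace."""
        if not self.ensemble_per_epoch:
            raise ValueError("no test set was provided during training; no trace to report")
        return EvalReport.from_trace(self.ensemble_per_epoch, window_len)

    def band_report(self, band_index: int, window_len: int) -> EvalReport:
        return EvalReport.from_trace(self.band_traces[band_index]["test_metrics"], window_len)


def train_band_ensemble(
    train_set: TrialSet,
    bank: FilterBankSpec,
    backbone_cfg: BackboneConfig,
    train_cfg: TrainConfig,
    test_set: Optional[TrialSet] = None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> EnsembleTrainResult:
    """Train one backbone per band of ``bank`` on ``train_set``.

    Band n's model uses seed ``train_cfg.seed + n`` for initialization
    and batch shuffling.  When ``test_set`` is given, test metrics are
    recorded every ``eval_every`` epochs per band, and the fused
    (probability-sum) ensemble's test metrics are derived from the
    stored per-band probability traces.
    """
    fs = train_set.fs
    bank.validate_against_fs(fs)  # reject any invalid band before training starts
    train_set.require_all_classes()
    if test_set is not None and test_set.fs != fs:
        raise ValueError(f"test fs {test_set.fs} != train fs {fs}")

    X_raw = train_set.X
    y = train_set.labels
    Xt_raw = test_set.X if test_set is not None else None
    yt = test_set.labels if test_set is not None else None
    shape = (train_set.n_channels, train_set.n_samples)

    members = []
    band_traces = []
    for n, band in enumerate(bank):
        Xb = band_preprocess(X_raw, band, fs, alpha=train_cfg.alpha, eps=train_cfg.eps)
        Xtb = (
            band_preprocess(Xt_raw, band, fs, alpha=train_cfg.alpha, eps=train_cfg.eps)
            if Xt_raw is not None
            else None
        )
        seed_n = train_cfg.seed + n
        model = build_backbone(backbone_cfg, shape, train_set.class_count, seed_n)
        trace = train_model(model, Xb, y, train_cfg, seed=seed_n, X_test=Xtb, y_test=yt)
        members.append((band, model))
        band_traces.append(trace)
        if progress is not None:
            progress(n + 1, len(bank))

    ensemble = BandEnsemble(
        members=members,
        class_count=train_set.class_count,
        fs=fs,
        alpha=train_cfg.alpha,
        eps=train_cfg.eps,
    )

    ensemble_per_epoch: dict[int, dict[str, float]] = {}
    if test_set is not None:
        epochs = sorted(band_traces[0]["test_proba"])
        for e in epochs:
            summed = np.sum([tr["test_proba"][e] for tr in band_traces], axis=0)
            pred = np.argmax(summed, axis=1)
            # renormalize rows so the metric helper sees probabilities
            ensemble_per_epoch[e] = classification_metrics(yt, pred, summed / len(bank))
    return EnsembleTrainResult(ensemble, band_traces, ensemble_per_epoch)
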