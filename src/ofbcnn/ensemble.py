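"""Probability-sum fusion of per-band classifiers.

An ensemble pairs each pass band with the classifier trained on trials
filtered to that band.  At prediction time the raw trial is filtered and
standardized per band exactly as during training (the same preprocessing
code path), each member emits a class-probability vector O_n, and the
predicted label is

    L = argmax_c  sum_{n=1..N} O_n[c]

i.e. an unweighted probability sum over the N bands.  Ties are broken by
the lowest class index.  With N = 1 this reduces to the single-model
argmax, the broadband baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .backbones import ClassifierModel
from .filterbank import BandSpec
from .preprocess import DEFAULT_ALPHA, DEFAULT_EPS, band_preprocess

__all__ = ["BandEnsemble", "ensemble_proba", "ensemble_predict"]


@dataclass
class BandEnsemble:
    """Ordered (band, trained model) pairs with the summed-probability
    predictor.  ``fs`` is the sampling rate the members were trained at;
    ``alpha``/``eps`` are the standardization constants used in training."""

    members: list[tuple[BandSpec, ClassifierModel]]
    class_count: int
    fs: float
    alpha: float = DEFAULT_ALPHA
    eps: float = DEFAULT_EPS
    weights: Optional[np.ndarray] = None  # optional non-default weighted fusion

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one (band, model) member")
        c0 = self.members[0][1].class_count
        ch0 = self.members[0][1].input_shape[0]
        for i, (_, m) in enumerate(self.members):
            if m.class_count != c0:
                raise ValueError(f"member {i} class_count {m.class_count} != {c0}")
            if m.input_shape[0] != ch0:
                raise ValueError(f"member {i} channel count {m.input_shape[0]} != {ch0}")
        if c0 != self.class_count:
            raise ValueError(f"class_count {self.class_count} != members' {c0}")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (len(self.members),) or (w < 0).any():
                raise ValueError("weights must be a nonnegative vector, one per member")
            self.weights = w

    def __len__(self) -> int:
        return len(self.members)

    @property
    def bands(self) -> list[BandSpec]:
        return [b for b, _ in self.members]

    def _check_fs(self, fs: float) -> None:
        if fs != self.fs:
            raise ValueError(f"sampling rate mismatch: ensemble trained at {self.fs} Hz, got {fs}")

    def proba_matrix(self, raw_trial: np.ndarray, fs: float) -> np.ndarray:
        """N x C matrix: row n is member n's probabilities for the trial."""
        self._check_fs(fs)
        raw_trial = np.asarray(raw_trial, dtype=np.float64)
        rows = []
        for band, model in self.members:
            x = band_preprocess(raw_trial, band, fs, alpha=self.alpha, eps=self.eps)
            rows.append(model.predict_proba(x))
        return np.stack(rows)

    def batch_proba(self, X: np.ndarray, fs: float) -> np.ndarray:
        """(n_trials, N, C) per-band probabilities for a batch of raw trials."""
        self._check_fs(fs)
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        per_band = []
        for band, model in self.members:
            xb = band_preprocess(X, band, fs, alpha=self.alpha, eps=self.eps)
            per_band.append(model.predict_proba(xb))
        return np.stack(per_band, axis=1)

    def fuse(self, proba: np.ndarray) -> np.ndarray:
        """Sum per-band probabilities (optionally weighted) over axis -2."""
        if self.weights is None:
            return proba.sum(axis=-2)
        return np.tensordot(
            np.moveaxis(proba, -2, -1), self.weights, axes=([-1], [0])
        )

    def batch_predict(self, X: np.ndarray, fs: float) -> np.ndarray:
        return np.argmax(self.fuse(self.batch_proba(X, fs)), axis=-1)


def ensemble_proba(ens: BandEnsemble, raw_trial: np.ndarray, fs: float) -> np.ndarray:
    """Per-band probability matrix (N x C) for one raw, unfiltered trial."""
    return ens.proba_matrix(raw_trial, fs)


def ensemble_predict(ens: BandEnsemble, raw_trial: np.ndarray, fs: float) -> int:
    """Predicted label: argmax of the per-band probability column sums.

    ``np.argmax`` returns the first maximizer, so ties resolve to the
    lowest class index.
    """
    sums = ens.fuse(ensemble_proba(ens, raw_trial, fs))
    return int(np.argmax(sums))
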