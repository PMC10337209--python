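"""Trial containers, cue-locked segmentation and running standardization.

EEG arrives either as continuous recordings from which cue-locked trials
are cut, or as an already-epoched :class:`TrialSet`.  Before entering a
classifier each trial is bandpass filtered (see :mod:`ofbcnn.filterbank`)
and then normalized per channel with *exponential running
standardization*: a causal normalization that tracks the mean and
variance of each channel with exponentially weighted running estimates

    m_t = (1 - alpha) m_{t-1} + alpha x_t        (m_0 = x_0)
    v_t = (1 - alpha) v_{t-1} + alpha (x_t - m_t)^2   (v_0 = 0)
    y_t = (x_t - m_t) / max(sqrt(v_t), eps)

with ``alpha = 1e-3`` and variance floor ``eps = 1e-4`` by default, the
configuration standard in CNN EEG-decoding toolboxes.  State is reset at
each trial boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .filterbank import BandSpec

__all__ = [
    "Trial",
    "TrialSet",
    "extract_segment",
    "exponential_running_standardize",
    "band_preprocess",
    "DEFAULT_ALPHA",
    "DEFAULT_EPS",
]

DEFAULT_ALPHA = 1e-3
DEFAULT_EPS = 1e-4


@dataclass
class Trial:
    """One EEG trial: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    label: int
    subject: int
    band_tag: Optional[BandSpec] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"trial data must be 2-D (channels x samples), got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("trial data contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class TrialSet:
    """An ordered collection of homogeneous trials with labels and subjects."""

    trials: list[Trial]
    class_count: int
    channel_names: Optional[list[str]] = None
    class_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("TrialSet must contain at least one trial")
        t0 = self.trials[0]
        for i, t in enumerate(self.trials):
            if t.data.shape != t0.data.shape:
                raise ValueError(
                    f"trial {i} shape {t.data.shape} differs from trial 0 {t0.data.shape}"
                )
            if t.fs != t0.fs:
                raise ValueError(f"trial {i} fs {t.fs} differs from trial 0 {t0.fs}")
            if not (0 <= t.label < self.class_count):
                raise ValueError(f"trial {i} label {t.label} outside 0..{self.class_count - 1}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def fs(self) -> float:
        return self.trials[0].fs

    @property
    def n_channels(self) -> int:
        return self.trials[0].n_channels

    @property
    def n_samples(self) -> int:
        return self.trials[0].n_samples

    @property
    def X(self) -> np.ndarray:
        """Stacked data, shape (trials, channels, samples)."""
        return np.stack([t.data for t in self.trials])

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=np.int64)

    @property
    def subjects(self) -> np.ndarray:
        return np.array([t.subject for t in self.trials], dtype=np.int64)

    def classes_present(self) -> np.ndarray:
        return np.unique(self.labels)

    def require_all_classes(self) -> None:
        present = set(self.classes_present().tolist())
        missing = sorted(set(range(self.class_count)) - present)
        if missing:
            raise ValueError(f"classes {missing} absent from TrialSet")

    @classmethod
    def from_arrays(
        cls,
        X: np.ndarray,
        labels: Sequence[int],
        subjects: Sequence[int],
        fs: float,
        class_count: int,
        channel_names: Optional[list[str]] = None,
        class_names: Optional[list[str]] = None,
    ) -> "TrialSet":
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError(f"X must be (trials, channels, samples), got {X.shape}")
        trials = [
            Trial(data=X[i], fs=fs, label=int(labels[i]), subject=int(subjects[i]))
            for i in range(X.shape[0])
        ]
        return cls(trials, class_count, channel_names, class_names)

    # -- on-disk container: raw float32 array + JSON sidecar ---------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.bin`` (float32 trials x channels x samples, C
        order) and ``<prefix>.json`` (fs, labels, subjects, names)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        X32 = self.X.astype(np.float32)
        X32.tofile(prefix.with_suffix(".bin"))
        meta = {
            "shape": list(X32.shape),
            "dtype": "float32",
            "fs": self.fs,
            "labels": self.labels.tolist(),
            "subjects": self.subjects.tolist(),
            "class_count": self.class_count,
            "channel_names": self.channel_names,
            "class_names": self.class_names,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "TrialSet":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        shape = tuple(meta["shape"])
        X = np.fromfile(prefix.with_suffix(".bin"), dtype=np.float32).reshape(shape)
        return cls.from_arrays(
            X,
            meta["labels"],
            meta["subjects"],
            meta["fs"],
            meta["class_count"],
            meta.get("channel_names"),
            meta.get("class_names"),
        )


def extract_segment(
    continuous: np.ndarray,
    fs: float,
    cue_onset_s: float,
    pre_s: float,
    post_s: float,
) -> np.ndarray:
    """Cut a cue-locked segment from a continuous channels x samples record.

    Returns exactly ``round((pre_s + post_s) * fs)`` samples per channel,
    starting ``pre_s`` seconds before the cue.
    """
    continuous = np.asarray(continuous)
    if continuous.ndim != 2:
        raise ValueError(f"continuous record must be 2-D, got shape {continuous.shape}")
    start = int(round((cue_onset_s - pre_s) * fs))
    n_out = int(round((pre_s + post_s) * fs))
    stop = start + n_out
    if start < 0 or stop > continuous.shape[1]:
        raise ValueError(
            f"segment [{start}, {stop}) samples exceeds recording of "
            f"{continuous.shape[1]} samples (cue at {cue_onset_s}s, pre {pre_s}s, post {post_s}s)"
        )
    return continuous[:, start:stop].copy()


def exponential_running_standardize(
    data: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Causal per-channel standardization with exponential running moments.

    Operates along the last axis.  Implemented with first-order IIR
    recursions (``scipy.signal.lfilter``), initialized so that the running
    mean starts at the first sample and the running variance at zero.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    x = np.asarray(data, dtype=np.float64)
    if x.shape[-1] == 0:
        return x.copy()
    b = [alpha]
    a = [1.0, -(1.0 - alpha)]
    # m_t = (1-alpha) m_{t-1} + alpha x_t with m_0 = x_0: the filter's
    # internal state must hold (1-alpha) x_0 before the first sample.
    x0 = x[..., :1]
    zi_m = (1.0 - alpha) * x0
    m, _ = _signal.lfilter(b, a, x, axis=-1, zi=zi_m)
    d2 = (x - m) ** 2
    v, _ = _signal.lfilter(b, a, d2, axis=-1, zi=np.zeros_like(x0))
    v = np.maximum(v, 0.0)  # guard tiny negative round-off
    return (x - m) / np.maximum(np.sqrt(v), eps)


def decimate_trials(X: np.ndarray, factor: int) -> np.ndarray:
    """Integer-factor downsampling along time with anti-alias filtering.

    ``X`` is (..., samples); the output has ``ceil(samples / factor)``
    samples and represents a sampling rate of ``fs / factor``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    if factor == 1:
        return np.asarray(X, dtype=np.float64).copy()
    return _signal.decimate(np.asarray(X, dtype=np.float64), int(factor), axis=-1,
                            zero_phase=True)


def decimate_trialset(ts: TrialSet, factor: int) -> TrialSet:
    """Return a new TrialSet resampled at ``fs / factor``."""
    X = decimate_trials(ts.X, factor)
    return TrialSet.from_arrays(
        X, ts.labels, ts.subjects, ts.fs / factor, ts.class_count,
        ts.channel_names, ts.class_names,
    )


def band_preprocess(
    X: np.ndarray,
    band: BandSpec,
    fs: float,
    alpha: float = DEFAULT_ALPHA,
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Bandpass then standardize a batch of raw trials.

    This single entry point is used both when building training inputs and
    at prediction time, so the two paths cannot diverge.  ``X`` is
    (trials, channels, samples) or a single (channels, samples) trial.
    """
    from .filterbank import apply_bandpass

    filtered = apply_bandpass(X, band, fs)
    return exponential_running_standardize(filtered, alpha=alpha, eps=eps)
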