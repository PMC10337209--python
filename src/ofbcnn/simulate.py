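"""Synthetic multisubject motor-imagery-like EEG.

The generator reproduces the statistical structure a filter-bank
ensemble exploits: class information is carried by event-related
desynchronization (ERD) — a task-locked *drop* in band-limited
oscillatory power — and the informative band differs between subjects.

Per subject:

* a smooth random spatial mixing matrix maps source-space 1/f^k
  background noise onto the channels;
* one narrowband rhythm per class (amplitude-modulated bandpass-filtered
  noise centered at the subject's band center) is projected through a
  smooth spatial pattern concentrated on a class-specific channel group;
* in a trial of class c, rhythm c's envelope is attenuated after the cue
  so its power drops by ``erd_depth`` (other rhythms stay at baseline) —
  the classifier must detect *which* rhythm desynchronized.

Defaults emulate a desk-scale version of standard MI benchmark shapes:
2 subjects x 4 classes, 22 channels, 250 Hz, 4.5 s trials with the cue
at 0.5 s, 25 training and 15 test trials per class per subject, subject
band centers at 10 and 24 Hz.  Generation is fully determined by the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter1d

from .filterbank import BandSpec, apply_bandpass
from .preprocess import TrialSet

__all__ = ["SimConfig", "simulate_dataset", "spectral_profile"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the desk-scale study conditions."""

    n_subjects: int = 2
    trials_per_class_per_subject: int = 25
    test_trials_per_class_per_subject: int = 15
    n_channels: int = 22
    fs: float = 250.0
    duration_s: float = 4.5
    cue_onset_s: float = 0.5
    class_count: int = 4
    subject_band_centers: tuple[float, ...] = (10.0, 24.0)
    band_width_hz: float = 4.0
    erd_depth: float = 0.75  # fractional post-cue power decrease of the class rhythm
    snr: float = 1.0  # rhythm RMS / background RMS at the channels
    noise_exponent: float = 1.0  # 1/f^k background slope
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subject_band_centers) != self.n_subjects:
            raise ValueError(
                f"{self.n_subjects} subjects but {len(self.subject_band_centers)} band centers"
            )
        top = max(self.subject_band_centers) + self.band_width_hz
        if self.fs / 2 <= top:
            raise ValueError(
                f"band center + width reaches {top} Hz, at/above Nyquist {self.fs / 2} Hz"
            )
        if not (0 <= self.erd_depth < 1):
            raise ValueError(f"erd_depth must lie in [0, 1), got {self.erd_depth}")
        if self.snr <= 0:
            raise ValueError(f"snr must be positive, got {self.snr}")
        if self.cue_onset_s >= self.duration_s:
            raise ValueError("cue must fall inside the trial")


def _one_over_f_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                      fs: float, exponent: float) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit RMS rows."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    # flat below 1 Hz so the DC region does not blow up
    shape = np.where(freqs < 1.0, 1.0, freqs) ** (-exponent / 2.0)
    shape[0] = 0.0
    spec = (rng.standard_normal((n_series, freqs.size))
            + 1j * rng.standard_normal((n_series, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def _smooth_mixing_matrix(rng: np.random.Generator, n_channels: int) -> np.ndarray:
    """Random mixing smoothed along both channel axes, biased to identity
    so it stays well conditioned."""
    G = rng.standard_normal((n_channels, n_channels))
    G = gaussian_filter1d(gaussian_filter1d(G, sigma=1.5, axis=0), sigma=1.5, axis=1)
    G /= np.abs(G).max()
    return np.eye(n_channels) + 0.8 * G


def _class_patterns(rng: np.random.Generator, n_channels: int, n_classes: int) -> np.ndarray:
    """Smooth nonnegative spatial patterns, one per class, each peaking on
    its own channel group."""
    patterns = np.zeros((n_classes, n_channels))
    centers = (np.arange(n_classes) + 0.5) * n_channels / n_classes
    idx = np.arange(n_channels)
    for c in range(n_classes):
        jitter = rng.uniform(-0.5, 0.5)
        patterns[c] = np.exp(-0.5 * ((idx - centers[c] - jitter) / 1.5) ** 2)
        patterns[c] /= np.linalg.norm(patterns[c])
    return patterns


def _narrowband_rhythm(rng: np.random.Generator, n_samples: int, fs: float,
                       center: float, width: float) -> np.ndarray:
    """Amplitude-modulated bandpass-filtered noise, unit RMS."""
    lo = max(center - width / 2.0, 0.5)
    hi = center + width / 2.0
    white = rng.standard_normal(n_samples)
    x = apply_bandpass(white[None, :], BandSpec(lo, hi), fs)[0]
    # slow positive envelope (~0.5 Hz fluctuation) for a realistic waxing/waning rhythm
    env_noise = gaussian_filter1d(rng.standard_normal(n_samples), sigma=fs / 2.0)
    env = 1.0 + 0.4 * env_noise / max(np.abs(env_noise).max(), 1e-12)
    x = x * env
    return x / np.sqrt(np.mean(x**2))


def _erd_gate(n_samples: int, fs: float, cue_onset_s: float, depth: float) -> np.ndarray:
    """Amplitude gate dropping to sqrt(1-depth) after the cue, with a
    200 ms raised-cosine transition."""
    gate = np.ones(n_samples)
    onset = int(round(cue_onset_s * fs))
    ramp = int(round(0.2 * fs))
    target = np.sqrt(1.0 - depth)
    stop = min(onset + ramp, n_samples)
    t = np.arange(stop - onset)
    gate[onset:stop] = 1.0 + (target - 1.0) * 0.5 * (1 - np.cos(np.pi * t / max(ramp, 1)))
    gate[stop:] = target
    return gate


def simulate_dataset(cfg: SimConfig) -> tuple[TrialSet, TrialSet]:
    """Generate disjoint, label-balanced train and test TrialSets."""
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration_s * cfg.fs))
    C = cfg.n_channels

    def make_trials(n_per_class: int, subject: int, mixing: np.ndarray,
                    patterns: np.ndarray, center: float) -> list:
        trials = []
        labels = np.repeat(np.arange(cfg.class_count), n_per_class)
        for y in labels:
            bg = _one_over_f_noise(rng, C, n_samples, cfg.fs, cfg.noise_exponent)
            X_bg = mixing @ bg
            X_rh = np.zeros_like(X_bg)
            for c in range(cfg.class_count):
                rhythm = _narrowband_rhythm(rng, n_samples, cfg.fs, center, cfg.band_width_hz)
                if c == y and cfg.erd_depth > 0:
                    rhythm = rhythm * _erd_gate(n_samples, cfg.fs, cfg.cue_onset_s,
                                                cfg.erd_depth)
                X_rh += np.outer(patterns[c], rhythm)
            bg_rms = np.sqrt(np.mean(X_bg**2))
            rh_rms = np.sqrt(np.mean(X_rh**2))
            X_rh *= cfg.snr * bg_rms / max(rh_rms, 1e-30)
            trials.append((X_bg + X_rh, int(y), subject))
        return trials

    train_trials, test_trials = [], []
    for s in range(cfg.n_subjects):
        mixing = _smooth_mixing_matrix(rng, C)
        patterns = _class_patterns(rng, C, cfg.class_count)
        center = cfg.subject_band_centers[s]
        train_trials += make_trials(cfg.trials_per_class_per_subject, s, mixing,
                                    patterns, center)
        test_trials += make_trials(cfg.test_trials_per_class_per_subject, s, mixing,
                                   patterns, center)

    def to_set(raw: list) -> TrialSet:
        X = np.stack([t[0] for t in raw])
        labels = [t[1] for t in raw]
        subjects = [t[2] for t in raw]
        return TrialSet.from_arrays(X, labels, subjects, cfg.fs, cfg.class_count)

    return to_set(train_trials), to_set(test_trials)


def spectral_profile(trial_data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel power spectral density (periodogram, density scaling).

    Returns ``(freqs, psd)`` with ``psd`` shaped like ``trial_data`` along
    channels.  With ``detrend=False`` the integral of the density equals
    the time-domain mean square power (Parseval).
    """
    trial_data = np.asarray(trial_data, dtype=np.float64)
    if not np.isfinite(trial_data).all():
        raise ValueError("trial contains non-finite samples")
    freqs, psd = _signal.periodogram(trial_data, fs=fs, axis=-1, detrend=False,
                                     scaling="density")
    return freqs, psd
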