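"""Bandpass filter banks for EEG decomposition.

A filter bank is an ordered list of pass bands applied to the same
multichannel trial.  Four schemes are supported:

``fixed``
    All bands share a common low-cut edge while the high edge widens in
    constant steps (e.g. 0-8, 0-12, ..., 0-36 Hz).  Bands are nested.
``sliding``
    A constant-width band translated upward in constant steps
    (e.g. 0-12, 4-16, ..., 24-36 Hz).  Adjacent bands overlap.
``nonoverlapping``
    Contiguous disjoint bands tiling a range (e.g. nine 4 Hz bands over
    4-40 Hz), the classical FBCSP-style decomposition.
``broadband``
    A single wide band; the no-filter-bank baseline.

Filtering is zero phase: a 4th-order Butterworth is applied forward and
backward (``sosfiltfilt``) after reflect-padding each trial by one second
to absorb IIR transients.  A band with a 0 Hz low edge is realized as a
pure low-pass, since a true 0 Hz bandpass edge is ill-posed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import signal

__all__ = [
    "BandSpec",
    "FilterBankSpec",
    "build_fixed_bank",
    "build_sliding_bank",
    "build_nonoverlapping_bank",
    "build_broadband_bank",
    "apply_bandpass",
]

#: tolerance used when checking that a frequency range divides into steps
_DIV_TOL = 1e-9

#: Butterworth order per pass direction
_BUTTER_ORDER = 4

#: seconds of reflect padding applied before forward-backward filtering
_PAD_SECONDS = 1.0


@dataclass(frozen=True)
class BandSpec:
    """A single pass band ``[low_hz, high_hz]`` in Hz."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(
                f"invalid band: need 0 <= low < high, got "
                f"[{self.low_hz}, {self.high_hz}]"
            )

    @property
    def width_hz(self) -> float:
        return self.high_hz - self.low_hz

    def contains(self, other: "BandSpec") -> bool:
        """True if this band's pass interval contains ``other``'s."""
        return self.low_hz <= other.low_hz and other.high_hz <= self.high_hz

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.low_hz:g}-{self.high_hz:g} Hz"


@dataclass(frozen=True)
class FilterBankSpec:
    """An ordered bank of pass bands produced by one of the four schemes."""

    scheme: str
    bands: tuple[BandSpec, ...]
    low_cut_hz: float
    step_hz: float
    max_high_hz: float

    _SCHEMES = ("fixed", "sliding", "nonoverlapping", "broadband")

    def __post_init__(self) -> None:
        if self.scheme not in self._SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {self._SCHEMES}")
        if not self.bands:
            raise ValueError("filter bank must contain at least one band")
        keys = [(b.low_hz, b.high_hz) for b in self.bands]
        if keys != sorted(keys):
            raise ValueError("bands must be ordered by (low_hz, high_hz) ascending")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self) -> Iterable[BandSpec]:
        return iter(self.bands)

    def validate_against_fs(self, fs: float) -> None:
        """Reject the bank if any band touches the Nyquist frequency."""
        for b in self.bands:
            if b.high_hz >= fs / 2:
                raise ValueError(
                    f"band {b} reaches Nyquist for fs={fs} Hz (limit {fs / 2} Hz)"
                )

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "bands": [[b.low_hz, b.high_hz] for b in self.bands],
            "low_cut_hz": self.low_cut_hz,
            "step_hz": self.step_hz,
            "max_high_hz": self.max_high_hz,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBankSpec":
        return cls(
            scheme=d["scheme"],
            bands=tuple(BandSpec(lo, hi) for lo, hi in d["bands"]),
            low_cut_hz=d["low_cut_hz"],
            step_hz=d["step_hz"],
            max_high_hz=d["max_high_hz"],
        )


def _check_divisible(span: float, step: float, what: tuple) -> int:
    """Return span/step as an int, rejecting non-divisible ranges."""
    if step <= 0:
        raise ValueError(f"step/width must be positive, got {step} in {what}")
    k = span / step
    if abs(k - round(k)) > _DIV_TOL * max(1.0, abs(k)):
        raise ValueError(
            f"range of {span} Hz is not an integer multiple of {step} Hz "
            f"(offending parameters: {what})"
        )
    return int(round(k))


def build_fixed_bank(
    low_cut_hz: float,
    step_hz: float,
    first_high_hz: float,
    max_high_hz: float,
) -> FilterBankSpec:
    """Fixed-low-cut bank: nested bands widening from ``first_high_hz``.

    Example: ``build_fixed_bank(0, 4, 8, 36)`` gives 0-8, 0-12, ..., 0-36 Hz.
    The number of bands is ``(max_high - first_high) / step + 1``.
    """
    if not (low_cut_hz < first_high_hz <= max_high_hz):
        raise ValueError(
            f"need low_cut < first_high <= max_high, got "
            f"({low_cut_hz}, {first_high_hz}, {max_high_hz})"
        )
    k = _check_divisible(
        max_high_hz - first_high_hz, step_hz, (low_cut_hz, step_hz, first_high_hz, max_high_hz)
    )
    bands = tuple(BandSpec(low_cut_hz, first_high_hz + i * step_hz) for i in range(k + 1))
    return FilterBankSpec("fixed", bands, low_cut_hz, step_hz, max_high_hz)


def build_sliding_bank(
    low_cut_hz: float,
    step_hz: float,
    width_hz: float,
    max_high_hz: float,
) -> FilterBankSpec:
    """Sliding bank: a constant-width band translated upward by ``step_hz``.

    Example: ``build_sliding_bank(0, 4, 12, 36)`` gives 0-12, 4-16, ..., 24-36 Hz.
    """
    if width_hz <= 0:
        raise ValueError(f"width must be positive, got {width_hz}")
    if low_cut_hz + width_hz > max_high_hz:
        raise ValueError(
            f"first band [{low_cut_hz}, {low_cut_hz + width_hz}] exceeds max_high {max_high_hz}"
        )
    k = _check_divisible(
        max_high_hz - low_cut_hz - width_hz, step_hz, (low_cut_hz, step_hz, width_hz, max_high_hz)
    )
    bands = tuple(
        BandSpec(low_cut_hz + i * step_hz, low_cut_hz + i * step_hz + width_hz)
        for i in range(k + 1)
    )
    return FilterBankSpec("sliding", bands, low_cut_hz, step_hz, max_high_hz)


def build_nonoverlapping_bank(
    low_cut_hz: float,
    width_hz: float,
    max_high_hz: float,
) -> FilterBankSpec:
    """Contiguous disjoint bands of ``width_hz`` tiling ``[low_cut, max_high]``.

    Example: ``build_nonoverlapping_bank(0, 4, 36)`` gives the nine bands
    0-4, 4-8, ..., 32-36 Hz.
    """
    k = _check_divisible(max_high_hz - low_cut_hz, width_hz, (low_cut_hz, width_hz, max_high_hz))
    if k < 1:
        raise ValueError("range must contain at least one band")
    bands = tuple(
        BandSpec(low_cut_hz + i * width_hz, low_cut_hz + (i + 1) * width_hz) for i in range(k)
    )
    return FilterBankSpec("nonoverlapping", bands, low_cut_hz, width_hz, max_high_hz)


def build_broadband_bank(low_cut_hz: float, max_high_hz: float) -> FilterBankSpec:
    """The single-band baseline ``[low_cut, max_high]`` ("Original")."""
    band = BandSpec(low_cut_hz, max_high_hz)
    return FilterBankSpec("broadband", (band,), low_cut_hz, max_high_hz - low_cut_hz, max_high_hz)


from functools import lru_cache


@lru_cache(maxsize=256)
def _design_sos_cached(low_hz: float, high_hz: float, fs: float) -> np.ndarray:
    return _design_sos(BandSpec(low_hz, high_hz), fs)


def _design_sos(band: BandSpec, fs: float) -> np.ndarray:
    if band.high_hz >= fs / 2:
        raise ValueError(f"band {band} at/above Nyquist for fs={fs} Hz")
    if band.low_hz == 0:
        return signal.butter(_BUTTER_ORDER, band.high_hz, btype="lowpass", fs=fs, output="sos")
    return signal.butter(
        _BUTTER_ORDER, [band.low_hz, band.high_hz], btype="bandpass", fs=fs, output="sos"
    )


def apply_bandpass(trial_data: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase bandpass filter one trial (channels x samples).

    Forward-backward 4th-order Butterworth; the trial is reflect-padded by
    one second on each side beforehand and cropped afterwards, so the
    output has the same shape as the input.
    """
    trial_data = np.asarray(trial_data, dtype=np.float64)
    if not np.isfinite(trial_data).all():
        raise ValueError("trial contains non-finite samples")
    sos = _design_sos_cached(band.low_hz, band.high_hz, fs)
    n = trial_data.shape[-1]
    pad = min(int(round(_PAD_SECONDS * fs)), n - 1)
    padded = np.pad(trial_data, [(0, 0)] * (trial_data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.sosfiltfilt(sos, padded, axis=-1, padtype=None)
    return np.ascontiguousarray(out[..., pad : pad + n])


def apply_bank(trial_data: np.ndarray, bank: FilterBankSpec, fs: float) -> list[np.ndarray]:
    """Apply every band of ``bank``; returns one filtered copy per band."""
    bank.validate_against_fs(fs)
    return [apply_bandpass(trial_data, b, fs) for b in bank]
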