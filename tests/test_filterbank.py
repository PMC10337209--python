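"""Filter-bank construction and zero-phase bandpass filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ofbcnn import (
    BandSpec,
    FilterBankSpec,
    apply_bandpass,
    build_broadband_bank,
    build_fixed_bank,
    build_nonoverlapping_bank,
    build_sliding_bank,
)


def bands_of(bank):
    return [(b.low_hz, b.high_hz) for b in bank]


class TestBankConstruction:
    @pytest.mark.parametrize(
        "args, expected",
        [
            # standard fixed-0 Hz bank: nested bands widening by 4 Hz
            ((0, 4, 8, 36), [(0, 8), (0, 12), (0, 16), (0, 20), (0, 24), (0, 28), (0, 32), (0, 36)]),
            # degenerate single-filter bank
            ((4, 4, 36, 36), [(4, 36)]),
        ],
    )
    def test_fixed_bank_examples(self, args, expected):
        assert bands_of(build_fixed_bank(*args)) == expected

    def test_fixed_bank_1hz_step_has_29_filters(self):
        bank = build_fixed_bank(0, 1, 8, 36)
        assert len(bank) == 29
        assert bands_of(bank)[0] == (0, 8)
        assert bands_of(bank)[-1] == (0, 36)

    @pytest.mark.parametrize(
        "args, expected",
        [
            ((0, 4, 12, 36), [(0, 12), (4, 16), (8, 20), (12, 24), (16, 28), (20, 32), (24, 36)]),
            ((4, 4, 12, 36), [(4, 16), (8, 20), (12, 24), (16, 28), (20, 32), (24, 36)]),
            # step == width degenerates to a partition
            ((0, 12, 12, 36), [(0, 12), (12, 24), (24, 36)]),
        ],
    )
    def test_sliding_bank_examples(self, args, expected):
        assert bands_of(build_sliding_bank(*args)) == expected

    @pytest.mark.parametrize(
        "args, n, first, last",
        [
            ((0, 4, 36), 9, (0, 4), (32, 36)),
            ((4, 4, 40), 9, (4, 8), (36, 40)),
            ((4, 32, 36), 1, (4, 36), (4, 36)),
        ],
    )
    def test_nonoverlapping_bank_examples(self, args, n, first, last):
        bank = build_nonoverlapping_bank(*args)
        assert len(bank) == n
        assert bands_of(bank)[0] == first
        assert bands_of(bank)[-1] == last

    def test_broadband_is_single_band(self):
        bank = build_broadband_bank(0, 36)
        assert bands_of(bank) == [(0, 36)]
        assert bank.scheme == "broadband"

    @pytest.mark.parametrize("step", range(1, 15))
    def test_fixed_bank_count_closed_form(self, step):
        span = 36 - 8
        if span % step == 0:
            bank = build_fixed_bank(0, step, 8, 36)
            assert len(bank) == span // step + 1
        else:
            with pytest.raises(ValueError, match="not an integer multiple"):
                build_fixed_bank(0, step, 8, 36)

    def test_fixed_bank_is_nested(self):
        bank = build_fixed_bank(4, 4, 12, 36)
        for prev, cur in zip(bank.bands, bank.bands[1:]):
            assert cur.contains(prev)

    def test_nonoverlapping_bank_partitions_range(self):
        bank = build_nonoverlapping_bank(4, 4, 40)
        for prev, cur in zip(bank.bands, bank.bands[1:]):
            assert prev.high_hz == cur.low_hz  # contiguous, measure-zero overlap
        assert bank.bands[0].low_hz == 4
        assert bank.bands[-1].high_hz == 40
        assert sum(b.width_hz for b in bank) == 36

    @pytest.mark.parametrize(
        "fn, args",
        [
            (build_fixed_bank, (0, -1, 8, 36)),
            (build_fixed_bank, (8, 4, 8, 36)),  # low_cut not < first_high
            (build_sliding_bank, (0, 4, 0, 36)),
            (build_sliding_bank, (0, 4, 40, 36)),
            (build_nonoverlapping_bank, (0, 5, 36)),
        ],
    )
    def test_invalid_parameters_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)

    def test_band_invariant(self):
        with pytest.raises(ValueError):
            BandSpec(8, 8)
        with pytest.raises(ValueError):
            BandSpec(-1, 8)

    def test_bank_roundtrips_through_dict(self):
        bank = build_fixed_bank(0, 4, 8, 36)
        assert FilterBankSpec.from_dict(bank.to_dict()) == bank

    def test_nyquist_validation(self):
        bank = build_fixed_bank(0, 4, 8, 36)
        bank.validate_against_fs(250.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bank.validate_against_fs(70.0)


FS = 250.0
T = np.arange(int(4 * FS)) / FS


def sine(freq):
    return np.sin(2 * np.pi * freq * T)[None, :]


class TestApplyBandpass:
    def test_stopband_attenuation(self):
        # 20 Hz tone far inside the stop band of a 0-8 Hz low-pass
        out = apply_bandpass(sine(20.0), BandSpec(0, 8), FS)
        assert np.sqrt((out**2).mean()) < 0.1 * np.sqrt((sine(20.0) ** 2).mean())

    def test_passband_preserves_amplitude(self):
        x = sine(10.0)
        out = apply_bandpass(x, BandSpec(4, 16), FS)
        n = x.shape[1]
        mid = slice(n // 4, 3 * n // 4)
        rms_in = np.sqrt((x[:, mid] ** 2).mean())
        rms_out = np.sqrt((out[:, mid] ** 2).mean())
        assert abs(rms_out - rms_in) < 0.1 * rms_in

    def test_zero_input_gives_zero_output(self):
        out = apply_bandpass(np.zeros((3, 500)), BandSpec(4, 16), FS)
        assert np.all(out == 0)

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 1000))
        y = rng.standard_normal((2, 1000))
        band = BandSpec(4, 16)
        lhs = apply_bandpass(2.5 * x - 1.5 * y, band, FS)
        rhs = 2.5 * apply_bandpass(x, band, FS) - 1.5 * apply_bandpass(y, band, FS)
        assert np.allclose(lhs, rhs, rtol=1e-6, atol=1e-9)

    def test_zero_phase(self):
        # in-band sinusoid: cross-correlation with the input peaks at lag 0
        x = sine(10.0)[0]
        out = apply_bandpass(x[None, :], BandSpec(4, 16), FS)[0]
        n = len(x)
        core = slice(n // 4, 3 * n // 4)
        lags = range(-10, 11)
        corr = [np.dot(out[core], np.roll(x, lag)[core]) for lag in lags]
        assert lags[int(np.argmax(corr))] == 0

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            apply_bandpass(sine(10.0), BandSpec(4, 130), FS)

    def test_nonfinite_rejected(self):
        x = sine(10.0).copy()
        x[0, 5] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            apply_bandpass(x, BandSpec(4, 16), FS)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(freq=st.floats(min_value=30.0, max_value=60.0))
    def test_out_of_band_tones_attenuated(self, freq):
        out = apply_bandpass(np.sin(2 * np.pi * freq * T)[None, :], BandSpec(4, 16), FS)
        assert np.sqrt((out**2).mean()) < 0.35  # >= ~9 dB even just past the edge
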