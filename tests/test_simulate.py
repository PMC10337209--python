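"""Synthetic EEG generator: determinism, balance, spectra, discriminability."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ofbcnn import BandSpec, SimConfig, apply_bandpass, simulate_dataset, spectral_profile


def small_cfg(**kw):
    base = dict(
        n_subjects=1,
        trials_per_class_per_subject=8,
        test_trials_per_class_per_subject=4,
        n_channels=8,
        fs=125.0,
        duration_s=2.0,
        cue_onset_s=0.5,
        class_count=2,
        subject_band_centers=(12.0,),
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


def log_bandpower(ts, band):
    Xf = apply_bandpass(ts.X, band, ts.fs)
    return np.log(Xf.var(axis=-1))


class TestGeneration:
    def test_seed_determinism(self):
        a_tr, a_te = simulate_dataset(small_cfg())
        b_tr, b_te = simulate_dataset(small_cfg())
        assert np.array_equal(a_tr.X, b_tr.X)
        assert np.array_equal(a_te.X, b_te.X)
        c_tr, _ = simulate_dataset(small_cfg(seed=1))
        assert not np.array_equal(a_tr.X, c_tr.X)

    def test_label_balance_and_shapes(self):
        cfg = small_cfg(n_subjects=2, subject_band_centers=(10.0, 20.0), class_count=3)
        tr, te = simulate_dataset(cfg)
        assert tr.n_channels == 8 and tr.n_samples == 250
        for ts, per in ((tr, 8), (te, 4)):
            for s in range(2):
                for c in range(3):
                    n = np.sum((ts.subjects == s) & (ts.labels == c))
                    assert n == per

    def test_infeasible_band_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            small_cfg(subject_band_centers=(62.0,))

    def test_erd_depth_bounds(self):
        with pytest.raises(ValueError, match="erd_depth"):
            small_cfg(erd_depth=1.0)

    def test_band_center_count_must_match_subjects(self):
        with pytest.raises(ValueError, match="band centers"):
            small_cfg(n_subjects=3)


class TestSpectralProfile:
    def test_pure_tone_peaks_at_its_frequency(self):
        fs, n = 250.0, 1000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        freqs, psd = spectral_profile(x, fs)
        assert freqs[np.argmax(psd[0])] == pytest.approx(10.0)

    def test_parseval(self, rng):
        x = rng.standard_normal((3, 2048))
        freqs, psd = spectral_profile(x, 250.0)
        df = freqs[1] - freqs[0]
        total = psd.sum(axis=-1) * df
        power = (x**2).mean(axis=-1)
        assert np.allclose(total, power, rtol=0.01)

    def test_white_noise_is_flat(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 50_000))
        freqs, psd = spectral_profile(x, 250.0)
        lo = psd[0, (freqs > 10) & (freqs < 50)].mean()
        hi = psd[0, (freqs > 60) & (freqs < 100)].mean()
        assert 0.9 < lo / hi < 1.1

    def test_background_follows_power_law(self):
        # near-zero rhythm amplitude leaves only the 1/f^k background
        cfg = small_cfg(snr=1e-8, noise_exponent=1.0, duration_s=4.0,
                        trials_per_class_per_subject=10)
        tr, _ = simulate_dataset(cfg)
        freqs, psd = spectral_profile(tr.X, tr.fs)
        mean_psd = psd.mean(axis=(0, 1))
        sel = (freqs >= 2) & (freqs <= 40)
        slope = np.polyfit(np.log(freqs[sel]), np.log(mean_psd[sel]), 1)[0]
        assert abs(slope + cfg.noise_exponent) < 0.3


class TestDiscriminability:
    def test_high_snr_single_subject_bandpower_rule(self):
        """With strong ERD and favorable SNR a log-bandpower LDA in the
        subject's band separates the classes almost perfectly."""
        cfg = small_cfg(
            trials_per_class_per_subject=30,
            test_trials_per_class_per_subject=20,
            snr=4.0,
            erd_depth=0.9,
            duration_s=3.0,
        )
        tr, te = simulate_dataset(cfg)
        band = BandSpec(10.0, 14.0)
        lda = LinearDiscriminantAnalysis().fit(log_bandpower(tr, band), tr.labels)
        acc = lda.score(log_bandpower(te, band), te.labels)
        assert acc >= 0.95

    def test_discriminability_is_band_localized(self):
        """Accuracy of the bandpower oracle across nonoverlapping 4 Hz bands
        peaks at the configured subject band and stays near chance far away."""
        cfg = small_cfg(
            trials_per_class_per_subject=30,
            test_trials_per_class_per_subject=20,
            snr=3.0,
            erd_depth=0.9,
            duration_s=3.0,
            subject_band_centers=(12.0,),
        )
        tr, te = simulate_dataset(cfg)
        accs = {}
        for lo in (4, 8, 12, 32, 40):
            band = BandSpec(float(lo), float(lo + 4))
            lda = LinearDiscriminantAnalysis().fit(log_bandpower(tr, band), tr.labels)
            accs[lo] = lda.score(log_bandpower(te, band), te.labels)
        in_band = max(accs[8], accs[12])  # 12 Hz center straddles 8-12/12-16
        assert in_band >= 0.9
        assert accs[32] <= 0.75 and accs[40] <= 0.75

    def test_subject_specific_bands(self):
        """A 4-16 Hz bandpower oracle works for the 10 Hz subject but not the
        22 Hz subject; a broad 4-36 Hz feature set covers both."""
        cfg = small_cfg(
            n_subjects=2,
            subject_band_centers=(10.0, 22.0),
            trials_per_class_per_subject=30,
            test_trials_per_class_per_subject=20,
            snr=3.0,
            erd_depth=0.9,
            duration_s=3.0,
        )
        tr, te = simulate_dataset(cfg)

        def subject_acc(bands, subject):
            Ftr = np.concatenate([log_bandpower(tr, b) for b in bands], axis=1)
            Fte = np.concatenate([log_bandpower(te, b) for b in bands], axis=1)
            lda = LinearDiscriminantAnalysis().fit(Ftr, tr.labels)
            mask = te.subjects == subject
            return np.mean(lda.predict(Fte[mask]) == te.labels[mask])

        low_band = [BandSpec(4, 16)]
        all_bands = [BandSpec(4 + 4 * k, 8 + 4 * k) for k in range(8)]
        assert subject_acc(low_band, 0) >= 0.8
        assert subject_acc(low_band, 1) <= 0.7  # near chance for the 22 Hz subject
        assert subject_acc(all_bands, 0) >= 0.8
        assert subject_acc(all_bands, 1) >= 0.8


def test_erd_free_simulation_is_exchangeable():
    """erd_depth = 0 removes all class information: bandpower features carry
    no signal, so the oracle stays near chance."""
    cfg = small_cfg(
        erd_depth=0.0,
        trials_per_class_per_subject=25,
        test_trials_per_class_per_subject=25,
        snr=3.0,
        duration_s=2.0,
    )
    tr, te = simulate_dataset(cfg)
    band = BandSpec(10.0, 14.0)
    lda = LinearDiscriminantAnalysis().fit(log_bandpower(tr, band), tr.labels)
    acc = lda.score(log_bandpower(te, band), te.labels)
    assert abs(acc - 0.5) < 0.2
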