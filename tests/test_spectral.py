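import numpy as np
import pytest

from rhythmnet import (EpochedSignal, hanning_fft_power, hfb_envelope, irasa,
                       morlet_transform)
from rhythmnet.spectral import HFB_FREQS, fractal_slope

from conftest import cosine_epochs


def _fractal_epochs(chi, n_trials, n=1500, fs=1000.0, seed=0, extra=None):
    rng = np.random.default_rng(seed)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-chi / 2.0)
    spec = amp * np.exp(1j * rng.uniform(0, 2 * np.pi, (n_trials, f.size)))
    x = np.fft.irfft(spec, n, axis=1) * n
    if extra is not None:
        x = x + extra
    return EpochedSignal("A", "c", "cue", -1000.0, fs, x, np.arange(n_trials))


class TestMorlet:
    def test_phase_ramp_of_pure_cosine(self):
        sig = cosine_epochs(10.0)
        sp = morlet_transform(sig, [10.0], 3.0)
        expected = np.angle(np.exp(2j * np.pi * 10.0 * sp.times_ms / 1000.0))
        dev = np.angle(np.exp(1j * (sp.phase[0, 0] - expected)))
        assert np.abs(dev[sp.valid[0]]).max() < 0.01

    def test_quarter_cycle_phase_convention(self):
        # cosine peak at t=0 -> phase 0; a quarter cycle later -> +pi/2
        sig = cosine_epochs(5.0)
        sp = morlet_transform(sig, [5.0], 3.0, times_ms=[0.0, 50.0])
        assert abs(sp.phase[0, 0, 0]) < 0.05
        assert sp.phase[0, 0, 1] == pytest.approx(np.pi / 2.0, abs=0.05)

    def test_frequency_selectivity(self):
        sig = cosine_epochs(10.0)
        sp = morlet_transform(sig, [10.0, 20.0], 3.0, times_ms=[-250.0])
        ratio = sp.amplitude[0, 0, 0] / sp.amplitude[0, 1, 0]
        # analytic Gaussian response of the 20 Hz / 3-cycle wavelet at
        # 10 Hz is exp(-9/8) ~ 0.32 -> ratio ~3; wider wavelets sharpen it
        assert ratio > 2.5
        sp7 = morlet_transform(sig, [10.0, 20.0], 7.0, times_ms=[-250.0])
        assert sp7.amplitude[0, 0, 0] / sp7.amplitude[0, 1, 0] > 10.0

    def test_zero_signal_gives_zero_coefficients(self):
        sig = cosine_epochs(10.0, amplitude=0.0)
        sp = morlet_transform(sig, [5.0, 12.0], 3.0)
        assert np.allclose(sp.coefficients, 0.0)

    def test_phase_invariant_to_amplitude_scaling(self):
        a = morlet_transform(cosine_epochs(8.0, amplitude=1.0), [8.0], 3.0,
                             times_ms=[-300.0])
        b = morlet_transform(cosine_epochs(8.0, amplitude=7.5), [8.0], 3.0,
                             times_ms=[-300.0])
        assert a.phase[0, 0, 0] == pytest.approx(b.phase[0, 0, 0], abs=1e-9)
        assert b.amplitude[0, 0, 0] == pytest.approx(
            7.5 * a.amplitude[0, 0, 0], rel=1e-6)

    def test_nyquist_and_too_short_epochs_raise(self):
        sig = cosine_epochs(10.0, epoch_ms=(-200.0, 200.0))
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_transform(sig, [600.0])
        with pytest.raises(ValueError, match="short"):
            morlet_transform(sig, [2.0], n_cycles=6.0)

    def test_edge_flags_cover_wavelet_support(self):
        sig = cosine_epochs(5.0, epoch_ms=(-1000.0, 0.0))
        sp = morlet_transform(sig, [5.0], 2.0)
        # 2 cycles at 5 Hz = 400 ms support: first/last 200 ms are flagged
        assert not sp.valid[0, sp.times_ms < -801.0].any()
        assert sp.valid[0, (sp.times_ms > -799.0)
                        & (sp.times_ms < -201.0)].all()

    def test_matches_mne_oracle(self):
        """Independent implementation check against MNE's Morlet TFR."""
        mne = pytest.importorskip("mne")
        rng = np.random.default_rng(3)
        sig = EpochedSignal("A", "c", "cue", -500.0, 1000.0,
                            rng.normal(size=(2, 1000)), np.arange(2))
        freqs = np.array([8.0, 15.0])
        ours = morlet_transform(sig, freqs, 5.0)
        theirs = mne.time_frequency.tfr_array_morlet(
            sig.samples[:, None, :], 1000.0, freqs, n_cycles=5.0,
            output="complex", zero_mean=False)[:, 0]
        mid = ours.valid.all(axis=0)
        for i in range(freqs.size):
            a = ours.coefficients[:, i, mid].ravel()
            b = theirs[:, i, mid].ravel()
            # the two implementations differ only by a per-frequency
            # normalization constant
            scale = np.vdot(a, b) / np.vdot(a, a)
            rel = np.linalg.norm(b - scale * a) / np.linalg.norm(b)
            assert rel < 0.01
            dphi = np.angle(np.exp(1j * (np.angle(b) - np.angle(a))))
            assert np.median(np.abs(dphi)) < 0.01


class TestHanningPower:
    def test_peak_at_exact_bin(self):
        ps = hanning_fft_power(cosine_epochs(10.0), (-500.0, 0.0))
        assert ps.freqs_hz[np.argmax(ps.total_power)] == 10.0

    def test_power_scales_with_amplitude_squared(self):
        p1 = hanning_fft_power(cosine_epochs(10.0, amplitude=1.0),
                               (-500.0, 0.0))
        p2 = hanning_fft_power(cosine_epochs(10.0, amplitude=2.0),
                               (-500.0, 0.0))
        ratio = p2.total_power.max() / p1.total_power.max()
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(0)
        sig = EpochedSignal("A", "c", "cue", -500.0, 1000.0,
                            rng.normal(size=(500, 500)), np.arange(500))
        ps = hanning_fft_power(sig, (-500.0, 0.0))
        assert ps.total_power.max() / ps.total_power.min() < 3.0

    def test_window_too_short_raises(self):
        with pytest.raises(ValueError, match="cycle"):
            hanning_fft_power(cosine_epochs(10.0), (-200.0, 0.0))


class TestIrasa:
    def test_fractal_slope_recovered(self):
        sig = _fractal_epochs(1.5, 500)
        ps = irasa(sig, (-750.0, -250.0))
        assert fractal_slope(ps) == pytest.approx(-1.5, abs=0.15)

    def test_oscillation_lands_in_residual(self):
        t = np.arange(1500) / 1000.0
        extra = 3.0 * np.cos(2 * np.pi * 10.0 * t)
        sig = _fractal_epochs(1.5, 200, extra=extra, seed=1)
        ps = irasa(sig, (-750.0, -250.0))
        peak = ps.freqs_hz[np.argmax(ps.oscillatory_residual)]
        assert peak == pytest.approx(10.0, abs=1.0)

    def test_decomposition_identity_and_nonnegative_fractal(self):
        sig = _fractal_epochs(1.0, 50, seed=2)
        ps = irasa(sig, (-750.0, -250.0))
        assert np.allclose(ps.total_power,
                           ps.fractal_power + ps.oscillatory_residual)
        assert (ps.fractal_power >= 0).all()

    def test_zero_signal_all_zero(self):
        sig = EpochedSignal("A", "c", "cue", -1000.0, 1000.0,
                            np.zeros((3, 1500)), np.arange(3))
        ps = irasa(sig, (-750.0, -250.0))
        assert not ps.total_power.any()
        assert not ps.fractal_power.any()
        assert not ps.oscillatory_residual.any()

    def test_integer_h_rejected(self):
        with pytest.raises(ValueError, match="non-integer"):
            irasa(_fractal_epochs(1.0, 3), (-750.0, -250.0), h_set=[2.0])


class TestHFB:
    def _noise_spect(self, n_trials=200, seed=0, boost_late=1.0,
                     extra_osc=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n_trials, 1200))
        if boost_late != 1.0:
            x[:, 600:] *= boost_late
        if extra_osc:
            t = np.arange(1200) / 1000.0
            x = x + extra_osc * np.cos(2 * np.pi * 30.0 * t)
        sig = EpochedSignal("A", "c", "cue", -600.0, 1000.0, x,
                            np.arange(n_trials))
        return morlet_transform(sig, HFB_FREQS, 7.0)

    def test_self_baseline_mean_near_zero(self):
        sp = self._noise_spect()
        hfb = hfb_envelope(sp, (-400.0, -100.0))
        sel = (hfb.times_ms >= -400) & (hfb.times_ms < -100)
        assert abs(hfb.zscored_hfb[:, sel].mean()) < 0.05

    def test_broadband_increase_raises_z(self):
        sp = self._noise_spect(boost_late=1.5, seed=1)
        hfb = hfb_envelope(sp, (-500.0, -200.0))
        late = (hfb.times_ms >= 100) & (hfb.times_ms < 500)
        assert (hfb.zscored_hfb[:, late].mean(axis=0) > 0.5).all()

    def test_band_limited_oscillation_does_not_leak(self):
        base = hfb_envelope(self._noise_spect(seed=2), (-400.0, -100.0))
        osc = hfb_envelope(self._noise_spect(seed=2, extra_osc=2.0),
                           (-400.0, -100.0))
        sel = (base.times_ms >= 0) & (base.times_ms < 400)
        delta = abs(osc.zscored_hfb[:, sel].mean()
                    - base.zscored_hfb[:, sel].mean())
        assert delta < 0.1
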