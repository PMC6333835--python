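import numpy as np
import pytest

from rhythmnet import (CouplingConfig, SignalConfig, TaskConfig,
                       ThetaBinDefinition, fit_mvar, gc_permutation_test,
                       generate_trials, preprocess_gc,
                       synthesize_coupled_regions, synthesize_lfp,
                       theta_binned_granger)
from rhythmnet.session import EpochedSignal


def _var_epochs(coefs, n_trials=200, seed=0, epoch_ms=(-1000.0, 0.0)):
    trials = generate_trials(TaskConfig(n_trials=n_trials, seed=seed))
    sigs = synthesize_coupled_regions(
        trials, CouplingConfig(var_coefficients=np.asarray(coefs, float),
                               seed=seed + 1, epoch_ms=epoch_ms),
        np.asarray(coefs).shape[1])
    return np.stack([s.samples for s in sigs], axis=1)


class TestPreprocess:
    def test_decimation_arithmetic(self):
        sig = EpochedSignal("A", "c", "target", -1000.0, 1000.0,
                            np.random.default_rng(0).normal(size=(5, 1000)),
                            np.arange(5))
        epochs, rate, _ = preprocess_gc([sig])
        assert rate == 250.0
        assert epochs.shape == (5, 1, 250)

    def test_normalization_contract(self):
        sig = EpochedSignal("A", "c", "target", -1000.0, 250.0,
                            np.random.default_rng(1).normal(size=(4, 250)),
                            np.arange(4))
        epochs, _, _ = preprocess_gc([sig])
        assert np.abs(epochs.mean(axis=2)).max() < 1e-12
        assert np.abs(epochs.std(axis=2) - 1.0).max() < 1e-12

    def test_constant_signal_rejected(self):
        sig = EpochedSignal("A", "c", "target", 0.0, 250.0,
                            np.ones((3, 100)), np.arange(3))
        with pytest.raises(ValueError, match="variance"):
            preprocess_gc([sig])


class TestFit:
    def test_var2_coefficients_recovered(self):
        a = np.zeros((2, 2, 2))
        a[0] = [[0.5, 0.2], [0.0, 0.4]]
        a[1] = [[-0.2, 0.0], [0.1, -0.3]]
        epochs = _var_epochs(a, n_trials=200)
        model = fit_mvar(epochs, 250.0, order=8)
        assert np.abs(model.coefficients[:2] - a).max() < 0.05
        assert np.abs(model.coefficients[2:]).max() < 0.05

    def test_independent_channels_no_cross_terms(self):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.0], [0.0, 0.5]]
        model = fit_mvar(_var_epochs(a, seed=2), 250.0, order=8)
        cross = model.coefficients[:, [0, 1], [1, 0]]
        assert np.abs(cross).max() < 0.05

    def test_noise_cov_self_consistency(self):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.6, 0.3], [0.0, 0.5]]
        model = fit_mvar(_var_epochs(a, seed=3), 250.0, order=4)
        assert np.abs(model.noise_cov - np.eye(2)).max() < 0.05

    def test_aic_prefers_true_order_region(self):
        a = np.zeros((2, 2, 2))
        a[0] = [[0.5, 0.3], [0.0, 0.4]]
        a[1] = [[-0.3, 0.0], [0.2, -0.35]]
        model = fit_mvar(_var_epochs(a, seed=4, n_trials=100), 250.0,
                         order=8, compute_aic=True)
        best = min(model.aic_table, key=model.aic_table.get)
        assert best >= 2


class TestSpectralGC:
    def test_diagonal_var_no_causality(self):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.0], [0.0, 0.5]]
        g = fit_mvar(_var_epochs(a, seed=5), 250.0, 8,
                     channel_names=("X", "Y")).granger()
        assert g[("X", "Y")].max() < 0.01
        assert g[("Y", "X")].max() < 0.01

    def test_unit_lag_coupling_closed_form(self):
        a = np.zeros((1, 2, 2))
        a[0, 1, 0] = 1.0      # Y_t = X_{t-1} + eps
        g = fit_mvar(_var_epochs(a, seed=6), 250.0, 8,
                     channel_names=("X", "Y")).granger()
        assert abs(g[("X", "Y")].mean() - np.log(2.0)) < 0.1 * np.log(2.0)
        assert g[("Y", "X")].max() < 0.01

    def test_oscillatory_coupling_peaks_at_resonance(self):
        # X has a ~14 Hz resonance (complex pole pair) that feeds Y
        fs = 250.0
        rho, f0 = 0.9, 14.0
        th = 2 * np.pi * f0 / fs
        a = np.zeros((2, 2, 2))
        a[0, 0, 0] = 2 * rho * np.cos(th)
        a[1, 0, 0] = -rho ** 2
        a[0, 1, 0] = 0.8
        a[0, 1, 1] = 0.3
        g = fit_mvar(_var_epochs(a, seed=7), fs, 8,
                     channel_names=("X", "Y")).granger()
        peak = g.freqs_hz[np.argmax(g[("X", "Y")])]
        assert abs(peak - 14.0) <= 2.0


class TestConditionalGC:
    def test_chain_influence_removed(self):
        a = np.zeros((1, 3, 3))
        a[0, 2, 0] = 0.9      # Z <- X
        a[0, 1, 2] = 0.9      # Y <- Z
        model = fit_mvar(_var_epochs(a, seed=8), 250.0, 8,
                         channel_names=("X", "Y", "Z"))
        pair = model.granger()[("X", "Y")]
        cond = model.conditional_granger("X", "Y", "Z")[("X", "Y")]
        assert pair.max() > 0.1
        assert cond.max() < 0.02

    def test_irrelevant_conditioning_matches_pairwise(self):
        a = np.zeros((1, 3, 3))
        a[0, 1, 0] = 1.0
        model = fit_mvar(_var_epochs(a, seed=9), 250.0, 8,
                         channel_names=("X", "Y", "Z"))
        pair = model.granger()[("X", "Y")].mean()
        cond = model.conditional_granger("X", "Y", "Z")[("X", "Y")].mean()
        assert cond == pytest.approx(pair, rel=0.1)

    def test_no_coupling_all_small(self):
        a = np.zeros((1, 3, 3))
        a[0] = np.diag([0.4, 0.5, 0.6])
        model = fit_mvar(_var_epochs(a, seed=10), 250.0, 8,
                         channel_names=("X", "Y", "Z"))
        assert model.conditional_granger("X", "Y", "Z")[("X", "Y")].max() \
            < 0.01


class TestThetaBinnedGC:
    def _gated_setup(self, gate, seed=0, n_trials=800):
        trials = generate_trials(TaskConfig(n_trials=n_trials, seed=seed))
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.0], [0.9, 0.3]]
        cfg = CouplingConfig(var_coefficients=a, seed=seed + 1,
                             epoch_ms=(-600.0, 0.0),
                             gate_phase_deg=gate)
        sigs = synthesize_coupled_regions(trials, cfg, 2,
                                          rois=("X", "Y"))
        theta0 = sigs[0].meta["theta_phase0"]
        theta_ref = synthesize_lfp(
            trials, SignalConfig(seed=seed + 2, theta_amp=25.0,
                                 fractal_sd=3.0, alpha_amp=0.0,
                                 noise_sd=1.0, epoch_ms=(-600.0, 0.0)),
            roi="theta", theta_phase0=theta0)
        bins = ThetaBinDefinition(good_center_deg=gate if gate is not None
                                  else 90.0)
        return sigs, theta_ref, bins

    def test_gated_coupling_stronger_in_good_bin(self):
        sigs, theta_ref, bins = self._gated_setup(gate=90.0)
        out = theta_binned_granger(sigs, theta_ref, bins)
        band = slice(None)
        good = out["good"][("X", "Y")].mean()
        poor = out["poor"][("X", "Y")].mean()
        assert good > 2.0 * poor

    def test_relabeling_swaps_spectra(self):
        sigs, theta_ref, bins = self._gated_setup(gate=90.0, seed=5)
        out = theta_binned_granger(sigs, theta_ref, bins)
        flipped = ThetaBinDefinition(
            good_center_deg=bins.poor_center_deg,
            estimation_time_ms=bins.estimation_time_ms,
            wavelet_cycles=bins.wavelet_cycles)
        out2 = theta_binned_granger(sigs, theta_ref, flipped)
        assert np.allclose(out["good"][("X", "Y")],
                           out2["poor"][("X", "Y")])
        assert np.allclose(out["poor"][("X", "Y")],
                           out2["good"][("X", "Y")])


class TestGCPermutation:
    def test_detects_one_way_coupling(self):
        a = np.zeros((1, 2, 2))
        a[0, 1, 0] = 1.0
        epochs = _var_epochs(a, n_trials=100, seed=11)
        res = gc_permutation_test(epochs, 250.0, n_perm=200,
                                  freqs_hz=np.arange(5.0, 55.0, 5.0), seed=0)
        assert res["holm_significant"].any()
        assert res["observed"].mean() > 0

    def test_symmetric_coupling_has_no_directional_bias(self):
        """Equal-strength bidirectional coupling yields an asymmetry
        statistic centered on zero across realizations.  (The re-pairing
        null itself tests cross-channel independence, so its spread is
        tighter than the sampling noise of the observed asymmetry when
        true coupling is strong; the unbiasedness is the meaningful
        symmetric-null property.)"""
        a = np.zeros((1, 2, 2))
        a[0] = [[0.3, 0.4], [0.4, 0.3]]
        means = []
        for seed in range(8):
            epochs = _var_epochs(a, n_trials=80, seed=20 + seed)
            model = fit_mvar(epochs, 250.0, 8, channel_names=("X", "Y"))
            g = model.granger(np.arange(5.0, 55.0, 5.0))
            means.append((g[("X", "Y")] - g[("Y", "X")]).mean())
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-4

    def test_refuses_tiny_samples(self):
        with pytest.raises(ValueError, match="10 trials"):
            gc_permutation_test(np.zeros((4, 2, 100)), 250.0)
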