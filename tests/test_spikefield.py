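import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from rhythmnet import (SignalConfig, SpikeCouplingConfig, morlet_transform,
                       ppc, synthesize_lfp, synthesize_spikes,
                       condition_ppc_contrast, extract_spike_phases,
                       stratified_theta_ppc, theta_dependent_ppc)
from rhythmnet.spikefield import SpikePhaseSet, ppc_spectrum


class TestPPC:
    def test_identical_phases_give_one(self):
        assert ppc(np.full(17, 1.3)) == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_pair_gives_minus_one(self):
        assert ppc([0.0, np.pi]) == pytest.approx(-1.0, abs=1e-12)

    def test_four_cardinal_phases(self):
        # brute force over the 6 pairs: cos of differences sums to -2
        assert ppc([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]) == pytest.approx(
            -1.0 / 3.0, abs=1e-12)

    def test_undefined_below_two_spikes(self):
        assert np.isnan(ppc([0.5]))

    @settings(deadline=None, max_examples=40)
    @given(st.integers(min_value=2, max_value=200),
           st.integers(min_value=0, max_value=10 ** 6))
    def test_closed_form_equals_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        phases = rng.uniform(-np.pi, np.pi, n)
        brute = np.mean([np.cos(phases[i] - phases[j])
                         for i in range(n) for j in range(i + 1, n)])
        assert ppc(phases) == pytest.approx(brute, abs=1e-12)

    def test_invariant_to_global_rotation(self):
        rng = np.random.default_rng(0)
        phases = rng.vonmises(0.0, 1.0, 300)
        assert ppc(phases) == pytest.approx(ppc(phases + 1.234), abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0, 2.0])
    def test_von_mises_expectation(self, kappa):
        expected = (special.i1(kappa) / special.i0(kappa)) ** 2
        rng = np.random.default_rng(int(kappa * 10))
        vals = [ppc(rng.vonmises(0.0, kappa, 150)) for _ in range(200)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se


class TestExtractSpikePhases:
    def _setup(self, spike_times):
        from conftest import cosine_epochs
        from rhythmnet import SpikeTrain
        sig = cosine_epochs(10.0, n_trials=1, epoch_ms=(-1200.0, 400.0))
        spect = morlet_transform(sig, [10.0], 3.0)
        train = SpikeTrain("u", "B", "target",
                           [np.asarray(spike_times)], np.array([0]))
        return extract_spike_phases(train, spect)

    def test_spikes_at_cosine_peaks_have_zero_phase(self):
        # 10 Hz cosine peaks every 100 ms
        res = self._setup([-500.0, -400.0, -300.0, -200.0])
        assert np.abs(res.phases).max() < 0.1

    def test_alternating_peaks_and_troughs(self):
        res = self._setup([-500.0, -450.0, -400.0, -350.0])
        wrapped = np.abs(np.angle(np.exp(1j * res.phases.ravel())))
        assert wrapped[0] < 0.1 and wrapped[2] < 0.1
        assert wrapped[1] > np.pi - 0.1 and wrapped[3] > np.pi - 0.1

    def test_empty_window_flagged(self):
        res = self._setup([300.0])
        assert res.empty

    def test_recovers_preferred_phase(self, small_trials):
        cfg = SignalConfig(seed=0, alpha_band=(14.0, 16.0), alpha_amp=20.0,
                           pac_depth=0.0, fractal_sd=4.0, noise_sd=2.0)
        lfp = synthesize_lfp(small_trials, cfg)
        train = synthesize_spikes(
            lfp, SpikeCouplingConfig(target_band=(14.0, 16.0), kappa=2.0,
                                     preferred_phase_deg=60.0, seed=1), 30.0)
        spect = morlet_transform(lfp, [15.0], 5.0)
        res = extract_spike_phases(train, spect)
        mean_phase = np.rad2deg(np.angle(np.exp(1j * res.phases[:, 0]).mean()))
        err = abs((mean_phase - 60.0 + 180.0) % 360.0 - 180.0)
        assert err < 10.0


def _phase_set(phases, trial_idx, n_trials, freqs=(15.0,)):
    return SpikePhaseSet(
        unit_id="u", lfp_source=("A", "c"),
        freqs_hz=np.asarray(freqs, dtype=float),
        phases=np.asarray(phases, dtype=float).reshape(-1, len(freqs)),
        spike_trial_idx=np.asarray(trial_idx),
        trial_ids=np.arange(n_trials))


class TestConditionContrast:
    def _sets(self, kappa_a, kappa_b, n_trials=40, spikes_per_trial=8,
              seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for kappa in (kappa_a, kappa_b):
            ph = rng.vonmises(0.0, kappa, n_trials * spikes_per_trial)
            idx = np.repeat(np.arange(n_trials), spikes_per_trial)
            out.append(_phase_set(ph, idx, n_trials))
        return out

    def test_detects_condition_difference(self):
        a, b = self._sets(1.5, 0.0)
        res = condition_ppc_contrast(a, b, n_perm=300, seed=1)
        assert res.delta[0] > 0
        assert res.permutations[0].p < 0.01

    def test_swap_changes_sign_not_p(self):
        a, b = self._sets(1.0, 0.0, seed=2)
        fwd = condition_ppc_contrast(a, b, n_perm=300, seed=3)
        rev = condition_ppc_contrast(b, a, n_perm=300, seed=3)
        assert rev.delta[0] == pytest.approx(-fwd.delta[0], abs=1e-12)
        assert rev.permutations[0].p == pytest.approx(fwd.permutations[0].p,
                                                      abs=0.02)

    def test_empty_set_refused(self):
        a, _ = self._sets(1.0, 0.0)
        empty = _phase_set(np.empty((0, 1)), np.empty(0, dtype=int), 5)
        empty.empty = True
        with pytest.raises(ValueError, match="empty"):
            condition_ppc_contrast(a, empty)


class TestThetaDependentPPC:
    def _gated_set(self, gate_deg=90.0, kappa=2.0, n_spikes=4000, seed=0):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(-np.pi, np.pi, n_spikes)
        inside = np.abs(np.angle(np.exp(
            1j * (theta - np.deg2rad(gate_deg))))) <= np.pi / 2
        phases = np.where(inside, rng.vonmises(0.0, kappa, n_spikes),
                          rng.uniform(-np.pi, np.pi, n_spikes))
        spikes = _phase_set(phases, np.zeros(n_spikes, dtype=int), 1)
        return spikes, theta

    def test_gated_coupling_recovered(self):
        spikes, theta = self._gated_set()
        res = theta_dependent_ppc(spikes, theta, n_perm=300, seed=1)
        assert res.permutations[0].p < 0.01
        err = abs((res.fits[0].preferred_phase_deg - 90.0 + 180.0)
                  % 360.0 - 180.0)
        assert err <= 20.0

    def test_theta_rotation_equivariance(self):
        spikes, theta = self._gated_set(seed=3)
        base = theta_dependent_ppc(spikes, theta, n_perm=100, seed=2)
        rot = theta_dependent_ppc(spikes, theta + np.deg2rad(30.0),
                                  n_perm=100, seed=2)
        assert rot.fits[0].amplitude == pytest.approx(
            base.fits[0].amplitude, rel=1e-9)
        shift = (rot.fits[0].preferred_phase_deg
                 - base.fits[0].preferred_phase_deg) % 360.0
        assert shift == pytest.approx(30.0, abs=1e-6)

    def test_underpopulated_bins_refused(self):
        rng = np.random.default_rng(4)
        theta = rng.uniform(0.0, 0.5, 50)   # all spikes in a narrow sector
        spikes = _phase_set(rng.uniform(-np.pi, np.pi, 50),
                            np.zeros(50, dtype=int), 1)
        with pytest.raises(ValueError, match="bins"):
            theta_dependent_ppc(spikes, theta, n_perm=50)


class TestStratifiedPPC:
    def _spikes_with_power(self, power_shift, gated, n_trials=200,
                           per_trial=20, seed=0):
        rng = np.random.default_rng(seed)
        n = n_trials * per_trial
        idx = np.repeat(np.arange(n_trials), per_trial)
        theta = rng.uniform(-np.pi, np.pi, n)
        in_a = np.abs(np.angle(np.exp(1j * (theta - np.pi / 2)))) <= np.pi / 2
        if gated:
            phases = np.where(in_a, rng.vonmises(0.0, 2.0, n),
                              rng.uniform(-np.pi, np.pi, n))
        else:
            phases = rng.uniform(-np.pi, np.pi, n)
        power = rng.normal(0.0, 1.0, n_trials)
        spikes = _phase_set(phases, idx, n_trials)
        return spikes, theta, power + power_shift

    def test_true_gating_survives_stratification(self):
        spikes, theta, power = self._spikes_with_power(0.0, gated=True)
        res = stratified_theta_ppc(spikes, theta, power, n_iter=100, seed=1)
        diff = res.mean[0, 0] - res.mean[1, 0]
        assert diff > 0
        assert diff > 3 * res.sd[:, 0].max() / np.sqrt(res.n_iterations)

    def test_no_coupling_no_difference(self):
        spikes, theta, power = self._spikes_with_power(0.0, gated=False,
                                                       seed=2)
        res = stratified_theta_ppc(spikes, theta, power, n_iter=100, seed=3)
        diff = abs(res.mean[0, 0] - res.mean[1, 0])
        assert diff < 3 * max(res.sd[:, 0].max(), 1e-3)

    def test_equal_power_high_retention(self):
        spikes, theta, power = self._spikes_with_power(0.0, gated=False,
                                                       seed=4)
        res = stratified_theta_ppc(spikes, theta, power, n_iter=50, seed=5)
        assert res.mean_retention >= 0.8
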