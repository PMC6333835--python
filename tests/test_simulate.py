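import numpy as np
import pytest
from scipy import special

from rhythmnet import (BehaviorConfig, CouplingConfig, SignalConfig,
                       SpikeCouplingConfig, TaskConfig, generate_trials,
                       ppc, synthesize_behavior, synthesize_coupled_regions,
                       synthesize_lfp, synthesize_spikes)
from rhythmnet.simulate import theta_phase_at


class TestGenerateTrials:
    def test_condition_fractions_near_design(self):
        tt = generate_trials(TaskConfig(n_trials=10000, seed=1))
        cond = tt.df.condition
        for name, p in [("cued", 0.78), ("catch", 0.10)]:
            se = np.sqrt(p * (1 - p) / 10000)
            assert abs((cond == name).mean() - p) < 3 * se
        p = 0.12
        se = np.sqrt(p * (1 - p) / 10000)
        noncued = cond.isin(["same_object", "different_object"]).mean()
        assert abs(noncued - p) < 3 * se

    def test_degenerate_probabilities_all_cued(self):
        tt = generate_trials(TaskConfig(n_trials=200, p_valid=1.0,
                                        p_catch=0.0, p_noncued=0.0, seed=0))
        assert (tt.df.condition == "cued").all()
        assert (tt.df.target_quadrant == tt.df.cue_quadrant).all()

    def test_same_seed_identical(self):
        a = generate_trials(TaskConfig(n_trials=500, seed=9))
        b = generate_trials(TaskConfig(n_trials=500, seed=9))
        assert a.df.equals(b.df)

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError, match="must be 1"):
            TaskConfig(p_valid=0.8, p_catch=0.1, p_noncued=0.2)

    def test_delays_within_ranges(self):
        df = generate_trials(TaskConfig(n_trials=2000, seed=3)).df
        assert df.cue_target_delay_ms.between(300, 1600).all()
        assert df.fixation_delay_ms.between(500, 1200).all()

    def test_same_object_shares_bar(self):
        df = generate_trials(TaskConfig(n_trials=4000, seed=4)).df
        so = df[df.condition == "same_object"]
        horiz = so[so.bar_orientation == "horizontal"]
        same_bar = ((horiz.cue_quadrant <= 2) & (horiz.target_quadrant <= 2)) \
            | ((horiz.cue_quadrant >= 3) & (horiz.target_quadrant >= 3))
        assert same_bar.all()


class TestSynthesizeLFP:
    def test_theta_truth_matches_injected_oscillation(self, small_trials):
        cfg = SignalConfig(seed=0, fractal_sd=0.0, alpha_amp=0.0,
                           noise_sd=0.0, theta_amp=2.0)
        lfp = synthesize_lfp(small_trials, cfg)
        i = lfp.time_index(-250.0)
        expected = 2.0 * np.cos(theta_phase_at(lfp, -250.0))
        assert np.allclose(lfp.samples[:, i], expected, atol=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|outside"):
            SignalConfig(gamma_band=(300.0, 600.0))

    def test_deterministic_given_seed(self, small_trials):
        a = synthesize_lfp(small_trials, SignalConfig(seed=5))
        b = synthesize_lfp(small_trials, SignalConfig(seed=5))
        assert np.array_equal(a.samples, b.samples)


class TestSynthesizeSpikes:
    def test_zero_kappa_ppc_near_zero(self, small_lfp):
        vals = []
        for s in range(60):
            train = synthesize_spikes(
                small_lfp, SpikeCouplingConfig(kappa=0.0, seed=s), 20.0)
            phases = np.concatenate(train.meta["band_phase_at_spikes"])
            vals.append(ppc(phases))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-4

    def test_von_mises_ppc_expectation(self, small_lfp):
        """E[PPC] = (I1(k)/I0(k))^2 for intensity ~ exp(k cos(phase - mu))."""
        expected = (special.i1(1.0) / special.i0(1.0)) ** 2
        vals = []
        for s in range(60):
            train = synthesize_spikes(
                small_lfp, SpikeCouplingConfig(kappa=1.0, seed=100 + s), 20.0)
            phases = np.concatenate(train.meta["band_phase_at_spikes"])
            vals.append(ppc(phases))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            SpikeCouplingConfig(kappa=-1.0)

    def test_gated_spikes_uniform_outside_gate(self, small_lfp):
        train = synthesize_spikes(
            small_lfp, SpikeCouplingConfig(kappa=3.0, gate_phase_deg=90.0,
                                           seed=0), 20.0)
        theta = []
        for i, tt in enumerate(train.spike_times_ms):
            phase0 = small_lfp.meta["theta_phase0"][i]
            theta.append(2 * np.pi * 5.0 * tt / 1000.0 + phase0)
        theta = np.angle(np.exp(1j * np.concatenate(theta)))
        band = np.concatenate(train.meta["band_phase_at_spikes"])
        inside = np.abs(np.angle(np.exp(1j * (theta - np.pi / 2)))) <= np.pi / 2
        # strong phase preference inside the gate, none outside
        assert ppc(band[inside]) > 0.3
        assert abs(ppc(band[~inside])) < 0.05


class TestCoupledRegions:
    def test_unstable_var_rejected(self, small_trials):
        bad = np.zeros((1, 2, 2))
        bad[0] = [[1.05, 0.0], [0.0, 0.5]]
        with pytest.raises(ValueError, match="nstable"):
            synthesize_coupled_regions(
                small_trials, CouplingConfig(var_coefficients=bad), 2)

    def test_independent_channels_uncorrelated(self, small_trials):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.0], [0.0, 0.5]]
        sigs = synthesize_coupled_regions(
            small_trials, CouplingConfig(var_coefficients=a, seed=0), 2)
        x, y = sigs[0].samples.ravel(), sigs[1].samples.ravel()
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.02


class TestSynthesizeBehavior:
    def test_degenerate_all_hits(self, small_trials, small_lfp):
        out = synthesize_behavior(
            small_trials, small_lfp,
            BehaviorConfig(base_hit_rate=1.0, theta_mod_depth=0.0, seed=0))
        sel = out.df.condition != "catch"
        assert (out.df.loc[sel, "outcome"] == "hit").all()

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            BehaviorConfig(base_hit_rate=0.9, theta_mod_depth=0.2)

    def test_hit_rate_follows_theta_phase(self):
        trials = generate_trials(TaskConfig(n_trials=4000, seed=0))
        lfp = synthesize_lfp(trials, SignalConfig(seed=1))
        out = synthesize_behavior(
            trials, lfp, BehaviorConfig(base_hit_rate=0.5,
                                        theta_mod_depth=0.3,
                                        good_phase_deg=0.0, seed=2))
        phi = theta_phase_at(lfp, -250.0)
        df = out.df
        scored = df.outcome.isin(("hit", "miss")).to_numpy()
        hits = (df.outcome == "hit").to_numpy()
        good = np.abs(phi) < np.pi / 4
        bad = np.abs(np.angle(np.exp(1j * (phi - np.pi)))) < np.pi / 4
        hr_good = hits[scored & good].mean()
        hr_bad = hits[scored & bad].mean()
        assert hr_good > 0.68
        assert hr_bad < 0.32
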