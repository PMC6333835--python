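# rhythmnet

Analysis toolkit for **rhythmic spatial attention** electrophysiology: the
kind of experiment in which a monkey performs a cued target-detection task
(Egly–Driver two-object layout, 78% cue validity, 10% catch trials) while
LFPs and single units are recorded simultaneously from the mediodorsal
pulvinar (mdPul), the frontal eye fields (FEF), and the lateral
intraparietal area (LIP).  The scientific question is how a ~5 Hz (theta)
rhythm organizes attention: behavioral detection waxes and wanes with
pre-target theta phase, and the thalamo-cortical network's coupling —
alpha/low-beta power, spike–field locking, directed influence — follows
the same theta clock.

The package implements the full analysis chain for such sessions, and a
synthetic-session generator with the matching statistical structure so
every estimator can be validated by parameter recovery:

| stage | what it computes |
|---|---|
| `spikes` | Gaussian-kernel rates (σ = 10 ms), randomization test of cue/target responsiveness (5000 reps), max-normalized population PSTHs, Wilcoxon rank-sum delay contrasts |
| `spectral` | Morlet wavelet phase/power, Hanning-FFT power, IRASA fractal/oscillatory separation, z-scored high-frequency-band (HFB, 80–200 Hz) envelope |
| `behavior` | phase-detection functions: hit rate in 72 overlapping 180° phase bins, one-cycle sine fit, 1500-shuffle permutation inference, good/poor theta-bin split |
| `spikefield` | spike–LFP pairwise phase consistency (PPC), condition contrasts, theta-phase-resolved PPC, power-equating stratification control |
| `granger` | order-8 MVAR at 250 Hz, Geweke spectral Granger causality (pairwise, conditional, theta-binned), directional permutation tests |
| `pac` | phase–amplitude coupling as percent modulation: between-region phase→HFB, within-region theta→power, theta-binned alpha→gamma |
| `simulate` | the generative counterparts of all of the above, with ground truth recorded for recovery tests |

## Core statistics

**One-cycle sine fit.** Any quantity *y* evaluated in the 72 overlapping
180° phase bins (centers 0°, 5°, …, 355°) is reduced to the second Fourier
component of the 72-point sequence: amplitude *A* = (2/72)·|Y₁|, preferred
phase φ* = −arg Y₁.  Because each bin averages over a 180° boxcar, an
underlying modulation *m*·cos(φ−φ₀) is recovered as (2/π)·*m* — the boxcar
attenuation law the tests check explicitly.

**Pairwise phase consistency.**  For spike phases θ₁…θₙ,
PPC = (2/(n(n−1)))·Σᵢ<ⱼ cos(θᵢ−θⱼ) = (|Σ e^{iθ}|² − n)/(n(n−1)),
an unbiased coupling measure independent of spike count; under von Mises
phase locking with concentration κ, E[PPC] = (I₁(κ)/I₀(κ))².

**Spectral Granger causality.**  From a multi-trial least-squares VAR fit
with transfer H(f) and noise covariance Σ, the Geweke measure
F_{x→y}(f) = ln [ S_yy(f) / (S_yy(f) − (Σ_xx − Σ²_xy/Σ_yy)|H_yx(f)|²) ];
the conditional form derives the reduced (sink + conditioning) model from
the fitted model's analytic autocovariance and decomposes the reduced
innovation spectrum by the source's orthogonalized innovation.

**Permutation inference.**  All p-values use the +1 correction,
p = (1 + #{null ≥ observed})/(n_perm + 1), so 1500 shuffles give a floor of
1/1501 ≈ 0.00067; Holm's sequential Bonferroni controls the family-wise
error across frequencies.

## Worked example

```python
import numpy as np
import rhythmnet as rn

session, truth = rn.simulate_session(
    task=rn.TaskConfig(n_trials=400, seed=0),
    signal=rn.SignalConfig(seed=1, theta_amp=15.0),
    behavior=rn.BehaviorConfig(theta_mod_depth=0.2, good_phase_deg=90.0, seed=2),
    spikes={"u1": ("mdPul", rn.SpikeCouplingConfig(kappa=1.5, seed=3))},
    rois=("mdPul", "FEF"), seed=0)

valid = session.trials.valid_target_trials()
lfp = session.lfps[("mdPul", "ch1")].select_trials(valid.trial_id)
freqs = np.arange(3.0, 61.0, 1.0)
spect = rn.morlet_transform(lfp, freqs, n_cycles=3.0, times_ms=[-250.0])
phases = rn.pretarget_phase(spect, -250.0)
res = rn.phase_detection_spectrum(phases, (valid.outcome == "hit").to_numpy(),
                                  freqs, n_perm=1500, seed=4)
i5 = int(np.argmin(np.abs(freqs - 5.0)))
print(f"5 Hz sine-fit amplitude: {res.fits[i5].amplitude:.3f}")
print(f"5 Hz preferred phase: {res.fits[i5].preferred_phase_deg:.1f} deg")
print(f"5 Hz permutation p: {res.pvalues[i5]:.5f}")
bins = rn.define_theta_bins(res.fits[i5])
print(f"good theta phase: {bins.good_center_deg:.1f} deg")
```

prints

```
5 Hz sine-fit amplitude: 0.109
5 Hz preferred phase: 87.2 deg
5 Hz permutation p: 0.00067
good theta phase: 87.2 deg
```

The generator injected a hit-rate modulation of depth 0.2 peaking at a
theta phase of 90°: the estimator recovers the boxcar-attenuated amplitude
(2/π)·0.2 ≈ 0.127 (here 0.109 at 351 trials), the preferred phase within a
few degrees, and a p-value at the permutation floor.  The detected peak
then defines the "good" theta half-cycle used by the theta-binned PPC,
Granger, and PAC analyses.

The same chain is available end to end from a shell:

```sh
rhythm-net simulate --config sim.yaml --out session_dir --seed 3
rhythm-net validate session_dir
rhythm-net run session_dir --out report_dir --stages power,phase_detection
```

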