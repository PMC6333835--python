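"""Phase-detection functions: hit rate as a function of pre-target
oscillatory phase, the one-cycle sine-fit spectrum with permutation
inference, and the good/poor theta-bin split.

A "phase-detection function" is the hit rate inside each of 72 overlapping
180-degree phase bins; its one-cycle sine amplitude measures how strongly
detection depends on phase at that frequency.  Because each bin averages
the underlying ``p(hit | phase)`` over a 180-degree boxcar, an injected
cosine modulation of depth m is recovered with amplitude (2/pi) m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasebin import (N_BINS, PhaseBinnedFunction, SineFit,
                       ThetaBinDefinition, bin_values, circular_boxcar,
                       one_cycle_sine_amplitude, sector_index,
                       sine_amplitudes)
from .spectral import ComplexSpectrogram
from .stats import PermutationResult, holm_correct, permutation_result


def pretarget_phase(spect: ComplexSpectrogram,
                    t_est_ms: float = -250.0) -> np.ndarray:
    """Per-trial phase (radians) per frequency at the estimation time.

    Raises if the estimate would fall in an edge-contaminated sample at any
    requested frequency.
    """
    j = spect.time_index(t_est_ms)
    bad = ~spect.valid[:, j]
    if np.any(bad):
        raise ValueError(
            f"estimation time {t_est_ms} ms is edge-contaminated at "
            f"{spect.freqs_hz[bad][:5].tolist()} Hz")
    return np.angle(spect.coefficients[:, :, j])


def phase_binned_hit_rate(phases: np.ndarray, outcomes: np.ndarray,
                          freq_hz: float | None = None) -> PhaseBinnedFunction:
    """Hit rate within each overlapping 180-degree phase bin."""
    outcomes = np.asarray(outcomes, dtype=float)
    return bin_values(phases, outcomes, freq_hz=freq_hz)


@dataclass
class PhaseDetectionSpectrum:
    freqs_hz: np.ndarray
    fits: list                       # SineFit per frequency
    permutations: list               # PermutationResult per frequency
    holm_significant: np.ndarray

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([f.amplitude for f in self.fits])

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([p.p for p in self.permutations])

    def peak_freq(self) -> float:
        return float(self.freqs_hz[int(np.argmax(self.amplitudes))])


def phase_detection_spectrum(phases: np.ndarray, outcomes: np.ndarray,
                             freqs_hz: np.ndarray,
                             n_perm: int = 1500,
                             alpha: float = 0.05,
                             min_trials: int = 50,
                             seed: int = 0) -> PhaseDetectionSpectrum:
    """Sine-fit amplitude of the phase-detection function per frequency,
    with an outcome-shuffle permutation null and Holm correction.

    ``phases`` is (n_trials, n_freqs) radians; ``outcomes`` is boolean
    hits.  The same shuffles are applied at every frequency.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    outcomes = np.asarray(outcomes, dtype=float).ravel()
    n_tr, n_freq = phases.shape
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if n_freq != freqs_hz.size:
        raise ValueError("phases second axis must match freqs_hz")
    if n_tr < min_trials:
        raise ValueError(f"{n_tr} trials < required minimum {min_trials}")
    rng = np.random.default_rng(seed)
    perm = np.empty((n_perm, n_tr), dtype=np.intp)
    for k in range(n_perm):
        perm[k] = rng.permutation(n_tr)
    shuffled = outcomes[perm]                      # (n_perm, n_trials)

    fits, perms = [], []
    for i in range(n_freq):
        sectors = sector_index(phases[:, i])
        onehot = np.zeros((n_tr, N_BINS), dtype=np.float32)
        onehot[np.arange(n_tr), sectors] = 1.0
        counts = circular_boxcar(onehot.sum(axis=0))
        if np.any(counts == 0):
            # fall back to the flag-aware scalar path
            f_obs = phase_binned_hit_rate(phases[:, i], outcomes,
                                          freq_hz=freqs_hz[i])
            fit = one_cycle_sine_amplitude(f_obs)
            null = np.empty(n_perm)
            for k in range(n_perm):
                fk = phase_binned_hit_rate(phases[:, i], shuffled[k])
                null[k] = one_cycle_sine_amplitude(fk).amplitude
        else:
            hits = circular_boxcar(outcomes @ onehot)
            values = hits / counts
            fit = one_cycle_sine_amplitude(
                PhaseBinnedFunction(values, counts.astype(int),
                                    freq_hz=freqs_hz[i]))
            hits_null = circular_boxcar(
                (shuffled.astype(np.float32) @ onehot).astype(float))
            null = sine_amplitudes(hits_null / counts)
        fits.append(fit)
        perms.append(permutation_result(fit.amplitude, null, "greater"))
    holm = holm_correct([p.p for p in perms], alpha=alpha)
    for p, h in zip(perms, holm):
        p.holm_significant = bool(h)
    return PhaseDetectionSpectrum(freqs_hz=freqs_hz, fits=fits,
                                  permutations=perms, holm_significant=holm)


def define_theta_bins(fit_at_5hz: SineFit,
                      estimation_time_ms: float = -250.0,
                      wavelet_cycles: float = 2.0) -> ThetaBinDefinition:
    """Good bin centered on the 5 Hz phase-detection peak; poor 180 deg away."""
    return ThetaBinDefinition(
        good_center_deg=fit_at_5hz.preferred_phase_deg % 360.0,
        estimation_time_ms=estimation_time_ms,
        wavelet_cycles=wavelet_cycles)


@dataclass
class ThetaBinnedPhaseDetection:
    bins: ThetaBinDefinition
    good: PhaseDetectionSpectrum | None
    poor: PhaseDetectionSpectrum | None
    n_good: int = 0
    n_poor: int = 0


def theta_binned_phase_detection(theta_phases: np.ndarray,
                                 phases: np.ndarray, outcomes: np.ndarray,
                                 freqs_hz: np.ndarray,
                                 bins: ThetaBinDefinition,
                                 n_perm: int = 1500,
                                 alpha: float = 0.05,
                                 min_trials: int = 50,
                                 seed: int = 0) -> ThetaBinnedPhaseDetection:
    """Re-run the phase-detection analysis separately inside each
    theta-phase half-cycle (each with its own shuffle null)."""
    assign = bins.assign(np.asarray(theta_phases, dtype=float))
    out = {}
    for label, flag in (("good", 1), ("poor", -1)):
        sel = assign == flag
        if sel.sum() < min_trials:
            out[label] = None
            continue
        out[label] = phase_detection_spectrum(
            phases[sel], np.asarray(outcomes)[sel], freqs_hz,
            n_perm=n_perm, alpha=alpha, min_trials=min_trials,
            seed=seed + (0 if flag == 1 else 1))
    return ThetaBinnedPhaseDetection(bins=bins, good=out["good"],
                                     poor=out["poor"],
                                     n_good=int((assign == 1).sum()),
                                     n_poor=int((assign == -1).sum()))
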