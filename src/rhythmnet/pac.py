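"""Phase-amplitude coupling (PAC) by phase binning.

Power samples (pooled over trials and time points within the pre-target
window) are averaged within the 72 overlapping 180-degree phase bins,
normalized to percent modulation around the all-phase mean, and reduced to
a one-cycle sine amplitude per phase-providing frequency.  The permutation
null shuffles phase trials relative to power trials.

Flavors: between-region phase (9-35 Hz) -> HFB (80-200 Hz z-scored power),
within-region theta (5 Hz) phase -> 9-60 Hz power, and alpha/low-beta
phase -> gamma power computed separately per theta half-cycle and
attention condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phasebin import (N_BINS, PhaseBinnedFunction, SineFit,
                       ThetaBinDefinition, circular_boxcar,
                       one_cycle_sine_amplitude, sector_index,
                       sine_amplitudes)
from .stats import holm_correct, permutation_result

DEFAULT_PAC_WINDOW = (-750.0, -200.0)
DEFAULT_PAC_STEP_MS = 10.0


@dataclass
class PACEntry:
    binned: PhaseBinnedFunction       # percent-modulation values
    fit: SineFit
    phase_freq_hz: float

    @property
    def modulation_pct(self) -> float:
        return self.fit.amplitude

    @property
    def preferred_phase_deg(self) -> float:
        return self.fit.preferred_phase_deg


@dataclass
class PACMap:
    phase_freqs_hz: np.ndarray
    entries: list                     # PACEntry per phase frequency
    power_target: str = ""
    permutations: list | None = None
    holm_significant: np.ndarray | None = None
    theta_bin: str = "all"
    condition: str = "all"

    @property
    def modulation_pct(self) -> np.ndarray:
        return np.array([e.modulation_pct for e in self.entries])

    @property
    def pvalues(self) -> np.ndarray:
        return np.array([p.p for p in self.permutations])


def _normalize_pct(binned_power: np.ndarray) -> np.ndarray:
    """(bin - mean) / mean x 100: percent modulation around the all-phase
    mean (scale-invariant by construction)."""
    mean = binned_power.mean(axis=-1, keepdims=True)
    return (binned_power - mean) / mean * 100.0


def pac_phase_power(phase: np.ndarray, power: np.ndarray,
                    phase_freq_hz: float | None = None) -> PACEntry:
    """Percent-modulation PAC for one phase-frequency.

    ``phase`` and ``power`` are (n_trials, n_times) sampled on a common
    grid; samples are pooled over trials and times.
    """
    phase = np.asarray(phase, dtype=float)
    power = np.asarray(power, dtype=float)
    if phase.shape != power.shape:
        raise ValueError("phase and power must share shape")
    sectors = sector_index(phase.ravel())
    sums = np.bincount(sectors, weights=power.ravel(), minlength=N_BINS)
    counts = np.bincount(sectors, minlength=N_BINS)
    bin_sums = circular_boxcar(sums)
    bin_counts = circular_boxcar(counts.astype(float))
    if np.any(bin_counts == 0):
        raise ValueError("empty phase bin in PAC computation")
    vals = _normalize_pct(bin_sums / bin_counts)
    f = PhaseBinnedFunction(vals, bin_counts.astype(int),
                            freq_hz=phase_freq_hz)
    return PACEntry(binned=f, fit=one_cycle_sine_amplitude(f),
                    phase_freq_hz=phase_freq_hz or np.nan)


def _pac_permutation(phase: np.ndarray, power: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> tuple:
    """Observed percent-modulation amplitude and trial-shuffle null."""
    n_tr, n_t = phase.shape
    sectors = sector_index(phase).reshape(n_tr, n_t)
    obs = pac_phase_power(phase, power)
    counts = np.bincount(sectors.ravel(), minlength=N_BINS)
    bin_counts = circular_boxcar(counts.astype(float))
    # one-hot (sample x sector) matrix: a trial-level shuffle of power only
    # re-weights the sector sums, so every null draw is a single matmul
    onehot = np.zeros((n_tr * n_t, N_BINS), dtype=np.float32)
    onehot[np.arange(n_tr * n_t), sectors.ravel()] = 1.0
    null = np.empty(n_perm)
    chunk = max(1, int(2e7 // max(n_tr * n_t, 1)))
    pw32 = power.astype(np.float32)
    for k0 in range(0, n_perm, chunk):
        k1 = min(k0 + chunk, n_perm)
        block = np.empty((k1 - k0, n_tr * n_t), dtype=np.float32)
        for j in range(k0, k1):
            block[j - k0] = pw32[rng.permutation(n_tr)].ravel()
        sums = (block @ onehot).astype(float)
        vals = _normalize_pct(circular_boxcar(sums) / bin_counts)
        null[k0:k1] = sine_amplitudes(vals)
    return obs, null


def pac_with_null(phase: np.ndarray, power: np.ndarray,
                  phase_freqs_hz: np.ndarray, n_perm: int = 1500,
                  alpha: float = 0.05, seed: int = 0,
                  power_target: str = "") -> PACMap:
    """PAC per phase frequency with a trial-shuffle permutation null.

    ``phase`` is (n_freqs, n_trials, n_times); ``power`` is either shared
    across phase frequencies (n_trials, n_times) or per-frequency
    (n_freqs, n_trials, n_times).
    """
    phase = np.asarray(phase, dtype=float)
    if phase.ndim == 2:
        phase = phase[None]
    phase_freqs_hz = np.atleast_1d(np.asarray(phase_freqs_hz, dtype=float))
    power = np.asarray(power, dtype=float)
    per_freq_power = power.ndim == 3
    rng = np.random.default_rng(seed)
    entries, perms = [], []
    for i, f in enumerate(phase_freqs_hz):
        pw = power[i] if per_freq_power else power
        obs, null = _pac_permutation(phase[i], pw, n_perm, rng)
        obs.phase_freq_hz = f
        obs.binned.freq_hz = f
        entries.append(obs)
        perms.append(permutation_result(obs.modulation_pct, null, "greater"))
    holm = holm_correct([p.p for p in perms], alpha=alpha)
    for p, h in zip(perms, holm):
        p.holm_significant = bool(h)
    return PACMap(phase_freqs_hz=phase_freqs_hz, entries=entries,
                  permutations=perms, holm_significant=holm,
                  power_target=power_target)


def within_region_pac(theta_phase: np.ndarray, power_by_freq: np.ndarray,
                      power_freqs_hz: np.ndarray, n_perm: int = 1500,
                      alpha: float = 0.05, seed: int = 0) -> PACMap:
    """Theta-phase (5 Hz) to higher-frequency (9-60 Hz) PAC in one region.

    ``theta_phase`` is (n_trials, n_times); ``power_by_freq`` is
    (n_power_freqs, n_trials, n_times).  The map is indexed by power
    frequency here (phase frequency is fixed at 5 Hz).
    """
    power_by_freq = np.asarray(power_by_freq, dtype=float)
    phase = np.broadcast_to(theta_phase, power_by_freq.shape)
    pm = pac_with_null(phase, power_by_freq,
                       np.asarray(power_freqs_hz, dtype=float),
                       n_perm=n_perm, alpha=alpha, seed=seed,
                       power_target="per-frequency power 9-60 Hz")
    return pm


def between_region_pac_hfb(phase_by_freq: np.ndarray, hfb: np.ndarray,
                           phase_freqs_hz: np.ndarray, n_perm: int = 1500,
                           alpha: float = 0.05, seed: int = 0) -> PACMap:
    """Phase (9-35 Hz) in one region to z-scored HFB power in the other."""
    return pac_with_null(phase_by_freq, hfb, phase_freqs_hz, n_perm=n_perm,
                         alpha=alpha, seed=seed,
                         power_target="HFB 80-200 Hz (z)")


def theta_binned_pac(phase_by_freq: np.ndarray, power: np.ndarray,
                     phase_freqs_hz: np.ndarray,
                     trial_theta_phase: np.ndarray,
                     bins: ThetaBinDefinition,
                     conditions: np.ndarray | None = None,
                     n_perm: int = 1500, alpha: float = 0.05,
                     min_trials: int = 30, seed: int = 0) -> dict:
    """Alpha/low-beta-phase to gamma-power PAC per theta half-cycle (and,
    optionally, per attention condition), each with its own null.

    Returns {(bin, condition): PACMap}; bins with fewer than ``min_trials``
    trials are skipped with a None entry.
    """
    assign = bins.assign(np.asarray(trial_theta_phase, dtype=float))
    conditions = (np.asarray(conditions) if conditions is not None
                  else np.full(assign.size, "all"))
    out = {}
    offset = 0
    for label, flag in (("good", 1), ("poor", -1)):
        for cond in np.unique(conditions):
            sel = (assign == flag) & (conditions == cond)
            key = (label, str(cond))
            if sel.sum() < min_trials:
                out[key] = None
                continue
            pm = pac_with_null(phase_by_freq[:, sel], power[sel],
                               phase_freqs_hz, n_perm=n_perm, alpha=alpha,
                               seed=seed + offset,
                               power_target="gamma power")
            pm.theta_bin = label
            pm.condition = str(cond)
            out[key] = pm
            offset += 1
    return out
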