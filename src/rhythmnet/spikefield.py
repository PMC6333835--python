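"""Spike-LFP pairwise phase consistency (PPC) and its condition,
theta-phase, and power-stratification analyses.

PPC is the mean cosine of all pairwise differences between spike phases,
computed through the closed form ``(|sum exp(i theta)|^2 - n) / (n (n-1))``
-- an unbiased coupling measure independent of spike count.  Spikes are
pooled across trials within the -500 to -125 ms pre-target window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phasebin import (N_BINS, PhaseBinnedFunction, SineFit,
                       circular_boxcar, one_cycle_sine_amplitude,
                       sector_index)
from .session import SpikeTrain
from .spectral import ComplexSpectrogram
from .stats import (PermutationResult, StratifiedSample, holm_correct,
                    permutation_result, stratify)

DEFAULT_SPIKE_WINDOW = (-500.0, -125.0)


@dataclass
class SpikePhaseSet:
    unit_id: str
    lfp_source: tuple
    freqs_hz: np.ndarray
    phases: np.ndarray            # (n_spikes, n_freqs) radians
    spike_trial_idx: np.ndarray   # row index into trial_ids per spike
    trial_ids: np.ndarray
    spike_window_ms: tuple = DEFAULT_SPIKE_WINDOW
    empty: bool = False

    @property
    def n_spikes(self) -> int:
        return self.phases.shape[0]


def extract_spike_phases(train: SpikeTrain, spect: ComplexSpectrogram,
                         window: tuple = DEFAULT_SPIKE_WINDOW
                         ) -> SpikePhaseSet:
    """LFP phase at the nearest spectrogram sample to every spike time."""
    t = spect.times_ms
    in_win = (t >= window[0]) & (t < window[1])
    if not np.all(spect.valid[:, in_win]):
        raise ValueError("spike window overlaps edge-contaminated samples")
    id_to_row = {tid: i for i, tid in enumerate(spect.trial_ids)}
    phases, trial_idx = [], []
    step = t[1] - t[0] if t.size > 1 else 1.0
    for row, tid in enumerate(train.trial_ids):
        srow = id_to_row[tid]
        tt = train.spike_times_ms[row]
        tt = tt[(tt >= window[0]) & (tt < window[1])]
        if tt.size == 0:
            continue
        cols = np.clip(np.round((tt - t[0]) / step).astype(int), 0, t.size - 1)
        phases.append(np.angle(spect.coefficients[srow, :, cols]))
        trial_idx.extend([srow] * tt.size)
    if not phases:
        return SpikePhaseSet(train.unit_id, spect.source, spect.freqs_hz,
                             np.empty((0, spect.freqs_hz.size)),
                             np.empty(0, dtype=int), spect.trial_ids,
                             window, empty=True)
    return SpikePhaseSet(train.unit_id, spect.source, spect.freqs_hz,
                         np.vstack(phases), np.asarray(trial_idx),
                         spect.trial_ids, window)


def ppc(phases: np.ndarray) -> float:
    """Pairwise phase consistency of a set of phases (radians).

    Closed form of the mean pairwise cosine: for resultant ``R = |sum
    exp(i theta)|``, PPC = (R^2 - n) / (n (n - 1)).
    """
    phases = np.asarray(phases, dtype=float).ravel()
    n = phases.size
    if n < 2:
        return np.nan
    z = np.exp(1j * phases).sum()
    return float((np.abs(z) ** 2 - n) / (n * (n - 1)))


def ppc_spectrum(spikeset: SpikePhaseSet) -> np.ndarray:
    """PPC per frequency over all spikes in the set."""
    n = spikeset.n_spikes
    if n < 2:
        return np.full(spikeset.freqs_hz.size, np.nan)
    z = np.exp(1j * spikeset.phases).sum(axis=0)
    return (np.abs(z) ** 2 - n) / (n * (n - 1))


@dataclass
class ConditionPPCContrast:
    freqs_hz: np.ndarray
    ppc_a: np.ndarray
    ppc_b: np.ndarray
    permutations: list
    holm_significant: np.ndarray

    @property
    def delta(self) -> np.ndarray:
        return self.ppc_a - self.ppc_b


def _trial_sums(spikeset: SpikePhaseSet) -> tuple:
    """Per-trial complex resultants and spike counts, (n_trials, n_freqs)."""
    n_tr = spikeset.trial_ids.size
    z = np.zeros((n_tr, spikeset.freqs_hz.size), dtype=complex)
    e = np.exp(1j * spikeset.phases)
    np.add.at(z, spikeset.spike_trial_idx, e)
    counts = np.bincount(spikeset.spike_trial_idx, minlength=n_tr)
    return z, counts


def _pooled_ppc(z_sum: np.ndarray, n: int) -> np.ndarray:
    if n < 2:
        return np.full(z_sum.shape[-1], np.nan)
    return (np.abs(z_sum) ** 2 - n) / (n * (n - 1))


def condition_ppc_contrast(cued: SpikePhaseSet, noncued: SpikePhaseSet,
                           n_perm: int = 1500, alpha: float = 0.05,
                           seed: int = 0) -> ConditionPPCContrast:
    """Permutation test of the cued-minus-noncued PPC difference.

    Trials (not spikes) are shuffled between conditions, preserving the
    group sizes; two-sided p per frequency with Holm correction.
    """
    if cued.empty or noncued.empty:
        raise ValueError("cannot contrast an empty spike-phase set")
    za, ca = _trial_sums(cued)
    zb, cb = _trial_sums(noncued)
    z = np.concatenate([za, zb], axis=0)
    cnt = np.concatenate([ca, cb])
    n_a = za.shape[0]
    n_all = z.shape[0]
    obs_a = _pooled_ppc(za.sum(axis=0), int(ca.sum()))
    obs_b = _pooled_ppc(zb.sum(axis=0), int(cb.sum()))
    observed = obs_a - obs_b
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, cued.freqs_hz.size))
    for k in range(n_perm):
        pi = rng.permutation(n_all)
        sel = pi[:n_a]
        rest = pi[n_a:]
        null[k] = (_pooled_ppc(z[sel].sum(axis=0), int(cnt[sel].sum()))
                   - _pooled_ppc(z[rest].sum(axis=0), int(cnt[rest].sum())))
    perms = [permutation_result(observed[i], null[:, i], "two_sided")
             for i in range(observed.size)]
    holm = holm_correct([p.p for p in perms], alpha=alpha)
    for p, h in zip(perms, holm):
        p.holm_significant = bool(h)
    return ConditionPPCContrast(freqs_hz=cued.freqs_hz, ppc_a=obs_a,
                                ppc_b=obs_b, permutations=perms,
                                holm_significant=holm)


@dataclass
class ThetaDependentPPC:
    freqs_hz: np.ndarray
    binned: list                  # PhaseBinnedFunction per frequency
    fits: list                    # SineFit per frequency
    permutations: list
    holm_significant: np.ndarray


def _amp_projector(valid: np.ndarray) -> tuple:
    """Least-squares projector onto (1, cos, sin) over the valid bins."""
    theta = np.deg2rad(np.arange(N_BINS) * 5.0)[valid]
    design = np.column_stack([np.ones_like(theta), np.cos(theta),
                              np.sin(theta)])
    pinv = np.linalg.pinv(design)
    return pinv[1], pinv[2]


def theta_dependent_ppc(spikeset: SpikePhaseSet,
                        theta_phases_at_spikes: np.ndarray,
                        n_perm: int = 1500, min_per_bin: int = 10,
                        max_flagged: int = 4, alpha: float = 0.05,
                        seed: int = 0) -> ThetaDependentPPC:
    """PPC inside overlapping 180-degree theta bins, reduced per frequency
    to a one-cycle sine amplitude; the null shuffles the spikes' theta-bin
    assignments relative to their higher-frequency phases."""
    theta = np.asarray(theta_phases_at_spikes, dtype=float).ravel()
    n_spk = spikeset.n_spikes
    if theta.size != n_spk:
        raise ValueError("one theta phase required per spike")
    sectors = sector_index(theta)
    sector_counts = np.bincount(sectors, minlength=N_BINS).astype(float)
    n_b = circular_boxcar(sector_counts)
    flagged = n_b < min_per_bin
    if flagged.sum() > max_flagged:
        raise ValueError(
            f"{int(flagged.sum())} theta bins hold fewer than "
            f"{min_per_bin} spikes")
    valid = ~flagged
    c_cos, c_sin = _amp_projector(valid)

    rng = np.random.default_rng(seed)
    perm_sectors = np.empty((n_perm, n_spk), dtype=np.intp)
    for k in range(n_perm):
        perm_sectors[k] = sectors[rng.permutation(n_spk)]

    binned, fits, perms = [], [], []
    denom = n_b * (n_b - 1.0)
    for i in range(spikeset.freqs_hz.size):
        e = np.exp(1j * spikeset.phases[:, i])
        zsec = (np.bincount(sectors, weights=e.real, minlength=N_BINS)
                + 1j * np.bincount(sectors, weights=e.imag, minlength=N_BINS))
        zb = circular_boxcar(zsec.real) + 1j * circular_boxcar(zsec.imag)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(valid, (np.abs(zb) ** 2 - n_b) / denom, np.nan)
        f = PhaseBinnedFunction(vals, n_b.astype(int),
                                freq_hz=spikeset.freqs_hz[i])
        fit = one_cycle_sine_amplitude(f, max_flagged=max_flagged)
        null = np.empty(n_perm)
        vals_k = np.empty(N_BINS)
        for k in range(n_perm):
            sk = perm_sectors[k]
            zr = np.bincount(sk, weights=e.real, minlength=N_BINS)
            zi = np.bincount(sk, weights=e.imag, minlength=N_BINS)
            zbk = circular_boxcar(zr) + 1j * circular_boxcar(zi)
            with np.errstate(invalid="ignore", divide="ignore"):
                np.divide(np.abs(zbk) ** 2 - n_b, denom, out=vals_k)
            v = vals_k[valid]
            null[k] = np.hypot(v @ c_cos, v @ c_sin)
        binned.append(f)
        fits.append(fit)
        perms.append(permutation_result(fit.amplitude, null, "greater"))
    holm = holm_correct([p.p for p in perms], alpha=alpha)
    for p, h in zip(perms, holm):
        p.holm_significant = bool(h)
    return ThetaDependentPPC(freqs_hz=spikeset.freqs_hz, binned=binned,
                             fits=fits, permutations=perms,
                             holm_significant=holm)


@dataclass
class StratifiedPPC:
    freqs_hz: np.ndarray
    mean: np.ndarray              # (2, n_freqs): bins at 90 and 270 deg
    sd: np.ndarray
    n_iterations: int
    n_discarded: int
    mean_retention: float
    bin_centers_deg: tuple = (90.0, 270.0)


def stratified_theta_ppc(spikeset: SpikePhaseSet,
                         theta_phases_at_spikes: np.ndarray,
                         power_per_trial: np.ndarray,
                         n_iter: int = 1500, n_bins: int = 20,
                         seed: int = 0) -> StratifiedPPC:
    """Power-equating control: PPC in the 90- and 270-degree theta bins
    after subsampling spikes so alpha/low-beta power distributions match.

    ``power_per_trial`` aligns with ``spikeset.trial_ids``; each spike
    inherits its trial's power.  Reports mean and SD of the per-bin PPC
    across iterations.
    """
    theta = np.asarray(theta_phases_at_spikes, dtype=float).ravel()
    power = np.asarray(power_per_trial, dtype=float)[spikeset.spike_trial_idx]
    d = np.angle(np.exp(1j * (theta - np.pi / 2.0)))
    in_a = np.abs(d) <= np.pi / 2.0      # bin centered 90 deg
    idx_a = np.flatnonzero(in_a)
    idx_b = np.flatnonzero(~in_a)
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("a theta bin holds fewer than 2 spikes")
    e = np.exp(1j * spikeset.phases)
    rng = np.random.default_rng(seed)
    sums = np.zeros((2, spikeset.freqs_hz.size))
    sq = np.zeros_like(sums)
    kept_frac = []
    n_ok = 0
    for _ in range(n_iter):
        try:
            strat = stratify(power[idx_a], power[idx_b], n_bins=n_bins,
                             seed=rng, equated_variable="power")
        except ValueError:
            continue
        ka = idx_a[strat.kept_a]
        kb = idx_b[strat.kept_b]
        if ka.size < 2:
            continue
        pa = _pooled_ppc(e[ka].sum(axis=0), ka.size)
        pb = _pooled_ppc(e[kb].sum(axis=0), kb.size)
        sums[0] += pa
        sums[1] += pb
        sq[0] += pa ** 2
        sq[1] += pb ** 2
        kept_frac.append((ka.size + kb.size)
                         / float(min(idx_a.size, idx_b.size) * 2))
        n_ok += 1
    if n_ok < n_iter / 2.0:
        raise ValueError(
            f"only {n_ok}/{n_iter} stratification iterations usable")
    mean = sums / n_ok
    sd = np.sqrt(np.maximum(sq / n_ok - mean ** 2, 0.0))
    return StratifiedPPC(freqs_hz=spikeset.freqs_hz, mean=mean, sd=sd,
                         n_iterations=n_ok, n_discarded=n_iter - n_ok,
                         mean_retention=float(np.mean(kept_frac)))
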