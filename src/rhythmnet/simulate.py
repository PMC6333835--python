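"""Synthetic sessions with the statistical structure the analyses assume.

The generator emulates a cued spatial-attention task on two bar-shaped
objects (78% cue validity, 10% catch trials, 12% non-cued targets, variable
delays) and produces LFPs built from a 1/f fractal background, a 5 Hz theta
oscillation with a random phase per trial, theta-phase-gated alpha/low-beta
(10-20 Hz) bursts, alpha-gated gamma, spike trains phase-coupled to LFP
rhythms (optionally only within one theta half-cycle), directed
inter-regional influence via a vector autoregression, and hit/miss
outcomes whose probability is a one-cycle sinusoid of pre-target theta
phase.

Every generator is a pure function of its config (including the seed), and
ground-truth parameters are recorded in signal/spike ``meta`` dictionaries
and the session-level ``truth`` sidecar so recovery tests never re-derive
truth from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .session import EpochedSignal, Session, SpikeTrain, TrialTable


# --------------------------------------------------------------------------
# task structure

@dataclass
class TaskConfig:
    n_trials: int = 1000
    p_valid: float = 0.78
    p_catch: float = 0.10
    p_noncued: float = 0.12           # split equally same/different object
    fixation_delay_ms: tuple = (500.0, 1200.0)
    bar_cue_delay_ms: tuple = (500.0, 1200.0)
    cue_target_delay_ms: tuple = (300.0, 1600.0)
    base_hit_rate: float = 0.5
    p_abort: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.p_valid + self.p_catch + self.p_noncued
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"p_valid + p_catch + p_noncued must be 1, got {total}")


# quadrant layout: 1 = upper-right, 2 = upper-left, 3 = lower-left,
# 4 = lower-right.  Horizontal bars pair quadrants (1,2) and (3,4);
# vertical bars pair (1,4) and (2,3).
_SAME_OBJECT = {
    "horizontal": {1: 2, 2: 1, 3: 4, 4: 3},
    "vertical": {1: 4, 4: 1, 2: 3, 3: 2},
}
_DIFF_OBJECT = {
    "horizontal": {1: 4, 4: 1, 2: 3, 3: 2},
    "vertical": {1: 2, 2: 1, 3: 4, 4: 3},
}


def generate_trials(config: TaskConfig) -> TrialTable:
    """Draw a trial table with the task's condition mix and delay ranges."""
    rng = np.random.default_rng(config.seed)
    n = config.n_trials
    conds = rng.choice(
        ["cued", "catch", "same_object", "different_object"], size=n,
        p=[config.p_valid, config.p_catch,
           config.p_noncued / 2.0, config.p_noncued / 2.0])
    orientation = rng.choice(["horizontal", "vertical"], size=n)
    cue_q = rng.integers(1, 5, size=n)
    target_q = np.full(n, np.nan)
    for i in range(n):
        if conds[i] == "cued":
            target_q[i] = cue_q[i]
        elif conds[i] == "same_object":
            target_q[i] = _SAME_OBJECT[orientation[i]][int(cue_q[i])]
        elif conds[i] == "different_object":
            target_q[i] = _DIFF_OBJECT[orientation[i]][int(cue_q[i])]
    fix = rng.uniform(*config.fixation_delay_ms, size=n)
    barcue = rng.uniform(*config.bar_cue_delay_ms, size=n)
    ctd = rng.uniform(*config.cue_target_delay_ms, size=n)
    ctd[conds == "catch"] = 1600.0   # screen clears 1600 ms after the cue

    outcome = np.empty(n, dtype=object)
    rt = np.full(n, np.nan)
    aborted = rng.random(n) < config.p_abort
    hits = rng.random(n) < config.base_hit_rate
    for i in range(n):
        if aborted[i]:
            outcome[i] = "aborted"
        elif conds[i] == "catch":
            outcome[i] = "catch_correct"
        elif hits[i]:
            outcome[i] = "hit"
            rt[i] = rng.uniform(150.0, 650.0)
        else:
            outcome[i] = "miss"
    df = pd.DataFrame({
        "trial_id": np.arange(n), "bar_orientation": orientation,
        "cue_quadrant": cue_q, "target_quadrant": target_q,
        "condition": conds, "fixation_delay_ms": fix,
        "bar_cue_delay_ms": barcue, "cue_target_delay_ms": ctd,
        "outcome": outcome, "response_time_ms": rt,
    })
    return TrialTable(df)


# --------------------------------------------------------------------------
# LFP synthesis

@dataclass
class SignalConfig:
    fractal_exponent: float = 1.5     # power ~ 1/f^chi
    fractal_sd: float = 20.0          # microvolts
    theta_freq: float = 5.0
    theta_amp: float = 10.0
    pac_depth: float = 0.5            # theta -> alpha/low-beta envelope
    pac_preferred_phase_deg: float = 90.0
    alpha_band: tuple = (10.0, 20.0)
    alpha_amp: float = 5.0
    alpha_carrier: str = "sinusoid"   # or "noise"
    gamma_band: tuple = (30.0, 50.0)
    gamma_amp: float = 0.0
    gamma_pac_depth: float = 0.5      # alpha phase -> gamma envelope
    gamma_preferred_phase_deg: float = 0.0
    noise_sd: float = 5.0
    rate_hz: float = 1000.0
    epoch_ms: tuple = (-1300.0, 400.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.pac_depth, self.gamma_pac_depth):
            if not 0.0 <= d <= 1.0:
                raise ValueError("coupling depths must lie in [0, 1]")
        nyq = self.rate_hz / 2.0
        for band in (self.alpha_band, self.gamma_band):
            if not (0.0 < band[0] < band[1] < nyq):
                raise ValueError(f"band {band} outside (0, Nyquist)")


def _fractal_noise(rng: np.random.Generator, n_trials: int, n: int,
                  chi: float, sd: float, rate_hz: float) -> np.ndarray:
    """Frequency-domain shaped noise: amplitude ~ f^(-chi/2), random phase."""
    if sd == 0.0 or chi is None:
        return np.zeros((n_trials, n))
    f = np.fft.rfftfreq(n, 1.0 / rate_hz)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-chi / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, f.size))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n, axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def _band_noise(rng: np.random.Generator, n_trials: int, n: int,
                band: tuple, rate_hz: float) -> np.ndarray:
    """Unit-RMS band-limited noise (frequency-domain brick wall)."""
    f = np.fft.rfftfreq(n, 1.0 / rate_hz)
    mask = (f >= band[0]) & (f <= band[1])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_trials, f.size))
    spec = mask * np.exp(1j * phases)
    x = np.fft.irfft(spec, n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def synthesize_lfp(trials: TrialTable, config: SignalConfig,
                   roi: str = "mdPul", channel: str = "ch1",
                   alignment_event: str = "target",
                   theta_phase0: np.ndarray | None = None) -> EpochedSignal:
    """One LFP channel per trial: fractal + theta + theta-gated alpha
    (+ alpha-gated gamma) + white noise.

    The analytic theta phase (cosine convention) is ``2 pi f t / 1000 +
    phase0[trial]`` and is recorded in ``meta`` together with the alpha
    carrier's analytic phase when the carrier is sinusoidal.
    """
    rng = np.random.default_rng(config.seed)
    n_tr = len(trials)
    fs = config.rate_hz
    t0, t1 = config.epoch_ms
    n = int(round((t1 - t0) * fs / 1000.0))
    t_s = (t0 + np.arange(n) * 1000.0 / fs) / 1000.0

    if theta_phase0 is None:
        theta_phase0 = rng.uniform(0.0, 2.0 * np.pi, size=n_tr)
    else:
        theta_phase0 = np.asarray(theta_phase0, dtype=float)
    phi_theta = (2.0 * np.pi * config.theta_freq * t_s)[None, :] \
        + theta_phase0[:, None]

    x = _fractal_noise(rng, n_tr, n, config.fractal_exponent,
                       config.fractal_sd, fs)
    x += config.theta_amp * np.cos(phi_theta)

    pac_pref = np.deg2rad(config.pac_preferred_phase_deg)
    envelope = 1.0 + config.pac_depth * np.cos(phi_theta - pac_pref)
    alpha_f = 0.5 * (config.alpha_band[0] + config.alpha_band[1])
    alpha_phase0 = rng.uniform(0.0, 2.0 * np.pi, size=n_tr)
    if config.alpha_amp > 0:
        if config.alpha_carrier == "sinusoid":
            phi_alpha = (2.0 * np.pi * alpha_f * t_s)[None, :] \
                + alpha_phase0[:, None]
            carrier = np.cos(phi_alpha)
        elif config.alpha_carrier == "noise":
            carrier = _band_noise(rng, n_tr, n, config.alpha_band, fs)
            analytic = sp_signal.hilbert(carrier, axis=1)
            phi_alpha = np.unwrap(np.angle(analytic), axis=1)
        else:
            raise ValueError(f"unknown alpha carrier {config.alpha_carrier!r}")
        alpha = config.alpha_amp * envelope * carrier
        x += alpha
    else:
        phi_alpha = (2.0 * np.pi * alpha_f * t_s)[None, :] \
            + alpha_phase0[:, None]

    if config.gamma_amp > 0:
        g_pref = np.deg2rad(config.gamma_preferred_phase_deg)
        g_env = 1.0 + config.gamma_pac_depth * np.cos(phi_alpha - g_pref)
        g_carrier = _band_noise(rng, n_tr, n, config.gamma_band, fs)
        x += config.gamma_amp * g_env * g_carrier

    if config.noise_sd > 0:
        x += rng.normal(0.0, config.noise_sd, size=(n_tr, n))

    meta = {
        "theta_phase0": theta_phase0, "theta_freq": config.theta_freq,
        "alpha_phase0": alpha_phase0, "alpha_center_hz": alpha_f,
        "alpha_carrier": config.alpha_carrier,
        "truth": {k: v for k, v in asdict(config).items()},
    }
    return EpochedSignal(roi=roi, channel=channel,
                         alignment_event=alignment_event, t0_ms=t0,
                         rate_hz=fs, samples=x,
                         trial_ids=trials.trial_ids.copy(), meta=meta)


def theta_phase_at(lfp: EpochedSignal, t_ms: float) -> np.ndarray:
    """Ground-truth theta phase per trial at ``t_ms`` (radians, wrapped)."""
    phase0 = np.asarray(lfp.meta["theta_phase0"], dtype=float)
    f = float(lfp.meta["theta_freq"])
    phi = 2.0 * np.pi * f * t_ms / 1000.0 + phase0
    return np.angle(np.exp(1j * phi))


def alpha_phase_at(lfp: EpochedSignal, t_ms: float) -> np.ndarray:
    """Ground-truth alpha-carrier phase per trial at ``t_ms`` (sinusoid only)."""
    if lfp.meta.get("alpha_carrier") != "sinusoid":
        raise ValueError("analytic alpha phase requires the sinusoid carrier")
    phase0 = np.asarray(lfp.meta["alpha_phase0"], dtype=float)
    f = float(lfp.meta["alpha_center_hz"])
    phi = 2.0 * np.pi * f * t_ms / 1000.0 + phase0
    return np.angle(np.exp(1j * phi))


def synthesize_lfp_pair_hfb(trials: TrialTable, config: SignalConfig,
                            hfb_depth: float = 0.3,
                            hfb_preferred_phase_deg: float = 0.0,
                            rois: tuple = ("FEF", "LIP"),
                            seed: int = 0) -> tuple:
    """Two channels where region B's broadband (>=80 Hz) amplitude is
    modulated by region A's alpha-band phase -- the generative counterpart
    of the between-region phase-to-HFB coupling analysis."""
    cfg_a = SignalConfig(**{**asdict(config), "seed": seed})
    a = synthesize_lfp(trials, cfg_a, roi=rois[0], channel="ch1")
    rng = np.random.default_rng(seed + 1)
    n_tr, n = a.samples.shape
    fs = config.rate_hz
    t_s = a.times_ms / 1000.0
    phi_a = (2.0 * np.pi * a.meta["alpha_center_hz"] * t_s)[None, :] \
        + np.asarray(a.meta["alpha_phase0"])[:, None]
    env = 1.0 + hfb_depth * np.cos(phi_a - np.deg2rad(hfb_preferred_phase_deg))
    # broadband drive is elevated in the delay period relative to the
    # early-epoch baseline, as attention elevates HFB in vivo; the z-scored
    # HFB therefore has a positive mean in the analysis window, which the
    # percent-modulation normalization requires
    gain = np.where(a.times_ms >= a.t0_ms + 500.0, 2.0, 1.0)[None, :]
    broadband = _band_noise(rng, n_tr, n, (80.0, min(200.0, fs / 2 - 1)), fs)
    quiet = SignalConfig(**{**asdict(config), "seed": seed + 2,
                            "alpha_amp": 0.0, "theta_amp": 0.0})
    b = synthesize_lfp(trials, quiet, roi=rois[1], channel="ch1")
    b.samples = b.samples + 4.0 * gain * env * broadband
    b.meta["hfb_depth"] = hfb_depth
    b.meta["hfb_preferred_phase_deg"] = hfb_preferred_phase_deg
    return a, b


# --------------------------------------------------------------------------
# spikes

@dataclass
class SpikeCouplingConfig:
    target_band: tuple = (10.0, 20.0)
    kappa: float = 1.0                   # von Mises concentration
    preferred_phase_deg: float = 0.0
    gate_phase_deg: float | None = None  # theta half-cycle center, or None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class CouplingConfig:
    """Directed VAR influence between regions plus per-unit spike coupling."""

    var_coefficients: np.ndarray | None = None   # (order, n, n)
    noise_cov: np.ndarray | None = None
    spike_coupling: dict = field(default_factory=dict)
    rate_hz: float = 250.0
    epoch_ms: tuple = (-1000.0, 0.0)
    gate_phase_deg: float | None = None          # gate VAR cross-terms
    gate_estimation_time_ms: float = -250.0
    seed: int = 0


def _companion_spectral_radius(coefs: np.ndarray) -> float:
    p, n, _ = coefs.shape
    top = np.concatenate(list(coefs), axis=1)
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = top
    if p > 1:
        comp[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def _band_phase(lfp: EpochedSignal, band: tuple) -> np.ndarray:
    """Phase of the LFP's band component (analytic truth if available)."""
    center = 0.5 * (band[0] + band[1])
    meta = lfp.meta
    if abs(center - meta.get("theta_freq", -1)) < 1e-9:
        phase0 = np.asarray(meta["theta_phase0"], dtype=float)
        f = meta["theta_freq"]
    elif (meta.get("alpha_carrier") == "sinusoid"
          and abs(center - meta.get("alpha_center_hz", -1)) < 1e-9):
        phase0 = np.asarray(meta["alpha_phase0"], dtype=float)
        f = meta["alpha_center_hz"]
    else:
        sos = sp_signal.butter(4, band, btype="bandpass",
                               fs=lfp.rate_hz, output="sos")
        filtered = sp_signal.sosfiltfilt(sos, lfp.samples, axis=1)
        return np.angle(sp_signal.hilbert(filtered, axis=1))
    t_s = lfp.times_ms / 1000.0
    return np.angle(np.exp(1j * (
        (2.0 * np.pi * f * t_s)[None, :] + phase0[:, None])))


def synthesize_spikes(lfp: EpochedSignal,
                      config: SpikeCouplingConfig | CouplingConfig,
                      mean_rate_hz: float, unit_id: str = "u1",
                      roi: str | None = None) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes with intensity ~ exp(kappa cos(phi - mu)).

    The intensity is normalized per trial to ``mean_rate_hz``.  With a
    theta-half-cycle gate, the coupling applies only while the ground-truth
    theta phase lies within +-90 degrees of the gate center; elsewhere the
    process is homogeneous at the mean rate.
    """
    if isinstance(config, CouplingConfig):
        config = config.spike_coupling[unit_id]
    rng = np.random.default_rng(config.seed)
    phi = _band_phase(lfp, config.target_band)
    mu = np.deg2rad(config.preferred_phase_deg)
    lam = np.exp(config.kappa * np.cos(phi - mu))
    lam = mean_rate_hz * lam / lam.mean(axis=1, keepdims=True)
    if config.gate_phase_deg is not None:
        theta = _band_phase(lfp, (lfp.meta["theta_freq"],) * 2) \
            if "theta_phase0" in lfp.meta else None
        if theta is None:
            raise ValueError("gating requires ground-truth theta phase")
        d = np.angle(np.exp(1j * (theta - np.deg2rad(config.gate_phase_deg))))
        gated = np.abs(d) <= np.pi / 2.0
        lam = np.where(gated, lam, mean_rate_hz)
    dt = 1.0 / lfp.rate_hz
    counts = rng.poisson(lam * dt)
    times, phases = [], []
    step_ms = 1000.0 / lfp.rate_hz
    for i in range(lfp.n_trials):
        idx = np.repeat(np.nonzero(counts[i])[0], counts[i][counts[i] > 0])
        tt = lfp.t0_ms + idx * step_ms + rng.uniform(0, step_ms, size=idx.size)
        order = np.argsort(tt)
        times.append(tt[order])
        phases.append(phi[i, idx[order]])
    meta = {"truth": asdict(config), "mean_rate_hz": mean_rate_hz,
            "band_phase_at_spikes": phases}
    return SpikeTrain(unit_id=unit_id, roi=roi or lfp.roi,
                      alignment_event=lfp.alignment_event,
                      spike_times_ms=times,
                      trial_ids=lfp.trial_ids.copy(), meta=meta)


def homogeneous_poisson_train(n_trials: int, rate_hz: float, epoch_ms: tuple,
                              seed: int = 0, unit_id: str = "u1",
                              roi: str = "sim",
                              alignment_event: str = "cue") -> SpikeTrain:
    """Constant-rate Poisson control unit."""
    rng = np.random.default_rng(seed)
    t0, t1 = epoch_ms
    dur_s = (t1 - t0) / 1000.0
    times = []
    for _ in range(n_trials):
        k = rng.poisson(rate_hz * dur_s)
        times.append(np.sort(rng.uniform(t0, t1, size=k)))
    return SpikeTrain(unit_id=unit_id, roi=roi,
                      alignment_event=alignment_event, spike_times_ms=times,
                      trial_ids=np.arange(n_trials))


# --------------------------------------------------------------------------
# coupled regions (VAR)

def synthesize_coupled_regions(trials: TrialTable, config: CouplingConfig,
                               n_regions: int,
                               theta_phase0: np.ndarray | None = None,
                               rois: tuple | None = None,
                               alignment_event: str = "target",
                               burn_in: int = 200) -> list:
    """Per-trial multivariate series from the configured VAR.

    With ``gate_phase_deg`` set, the off-diagonal (cross-region) VAR
    coefficients are active only on trials whose ground-truth theta phase at
    the gate estimation time falls within +-90 degrees of the gate center;
    the per-trial gate truth is recorded in every signal's ``meta``.
    """
    coefs = np.asarray(config.var_coefficients, dtype=float)
    if coefs.ndim != 3 or coefs.shape[1] != n_regions:
        raise ValueError("var_coefficients must have shape (order, n, n)")
    if _companion_spectral_radius(coefs) >= 1.0:
        raise ValueError("unstable VAR: companion spectral radius >= 1")
    rng = np.random.default_rng(config.seed)
    n_tr = len(trials)
    fs = config.rate_hz
    t0, t1 = config.epoch_ms
    n = int(round((t1 - t0) * fs / 1000.0))
    p = coefs.shape[0]
    noise_cov = (np.eye(n_regions) if config.noise_cov is None
                 else np.asarray(config.noise_cov, dtype=float))
    chol = np.linalg.cholesky(noise_cov)

    gated = np.ones(n_tr, dtype=bool)
    if config.gate_phase_deg is not None:
        if theta_phase0 is None:
            theta_phase0 = rng.uniform(0.0, 2.0 * np.pi, size=n_tr)
        phi = 2.0 * np.pi * 5.0 * config.gate_estimation_time_ms / 1000.0 \
            + theta_phase0
        d = np.angle(np.exp(1j * (phi - np.deg2rad(config.gate_phase_deg))))
        gated = np.abs(d) <= np.pi / 2.0
    diag_only = coefs * np.eye(n_regions)[None, :, :]

    data = np.empty((n_tr, n_regions, n))
    total = n + burn_in
    eps = rng.standard_normal((n_tr, total, n_regions)) @ chol.T
    # time-stepped but vectorized across trials (per coefficient group)
    for a, sel in ((coefs, gated), (diag_only, ~gated)):
        if not np.any(sel):
            continue
        e = eps[sel]
        x = np.zeros((e.shape[0], total, n_regions))
        for t in range(p, total):
            acc = e[:, t].copy()
            for k in range(p):
                acc += x[:, t - 1 - k] @ a[k].T
            x[:, t] = acc
        data[sel] = np.swapaxes(x[:, burn_in:, :], 1, 2)

    rois = rois or tuple(f"R{i}" for i in range(n_regions))
    meta = {"gated": gated, "gate_phase_deg": config.gate_phase_deg,
            "theta_phase0": theta_phase0, "theta_freq": 5.0,
            "var_order": p}
    out = []
    for r in range(n_regions):
        out.append(EpochedSignal(
            roi=rois[r], channel="var", alignment_event=alignment_event,
            t0_ms=t0, rate_hz=fs, samples=data[:, r, :],
            trial_ids=trials.trial_ids.copy(), meta=dict(meta)))
    return out


# --------------------------------------------------------------------------
# behavior

@dataclass
class NestedModulation:
    depth: float = 0.3
    preferred_phase_deg: float = 0.0
    active_bin: str = "good"   # which theta half-cycle carries the nesting


@dataclass
class BehaviorConfig:
    base_hit_rate: float = 0.5       # p0
    theta_mod_depth: float = 0.2     # m_b, probability units
    good_phase_deg: float = 90.0
    estimation_time_ms: float = -250.0
    nested: NestedModulation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        worst = self.base_hit_rate + self.theta_mod_depth
        if self.nested is not None:
            worst *= 1.0 + self.nested.depth
        best = self.base_hit_rate - self.theta_mod_depth
        if self.nested is not None:
            best *= 1.0 - self.nested.depth
        if worst > 1.0 or best < 0.0:
            raise ValueError("hit probability leaves [0, 1] at some phase")


def synthesize_behavior(trials: TrialTable, lfp: EpochedSignal,
                        config: BehaviorConfig) -> TrialTable:
    """Redraw hit/miss outcomes as a sinusoidal function of theta phase.

    ``P(hit) = p0 + m_b cos(phi_theta(t_est) - phi_good)``; the optional
    nested modulation multiplies in only when the trial's theta phase lies
    in the configured half-cycle, using the alpha carrier's analytic phase.
    Catch and aborted trials keep their outcomes.
    """
    rng = np.random.default_rng(config.seed)
    phi = theta_phase_at(lfp, config.estimation_time_ms)
    good = np.deg2rad(config.good_phase_deg)
    p_hit = config.base_hit_rate + config.theta_mod_depth * np.cos(phi - good)
    if config.nested is not None:
        center = good if config.nested.active_bin == "good" else good + np.pi
        in_bin = np.abs(np.angle(np.exp(1j * (phi - center)))) <= np.pi / 2
        phi_a = alpha_phase_at(lfp, config.estimation_time_ms)
        factor = 1.0 + config.nested.depth * np.cos(
            phi_a - np.deg2rad(config.nested.preferred_phase_deg))
        p_hit = np.where(in_bin, p_hit * factor, p_hit)
    if np.any((p_hit < 0.0) | (p_hit > 1.0)):
        raise ValueError("hit probability outside [0, 1] on some trial")

    df = trials.df.copy()
    id_to_row = {tid: i for i, tid in enumerate(lfp.trial_ids)}
    hits = rng.random(len(df)) < p_hit[[id_to_row[t] for t in df["trial_id"]]]
    rts = rng.uniform(150.0, 650.0, size=len(df))
    updatable = ~df["outcome"].isin(("aborted", "catch_correct",
                                     "false_alarm"))
    df.loc[updatable, "outcome"] = np.where(hits[updatable], "hit", "miss")
    df.loc[updatable, "response_time_ms"] = np.where(
        hits[updatable], rts[updatable], np.nan)
    return TrialTable(df)


# --------------------------------------------------------------------------
# whole-session convenience

def simulate_session(task: TaskConfig | None = None,
                     signal: SignalConfig | None = None,
                     behavior: BehaviorConfig | None = None,
                     spikes: dict | None = None,
                     mean_rate_hz: float = 20.0,
                     rois: tuple = ("mdPul", "FEF", "LIP"),
                     seed: int = 0) -> tuple:
    """Generate a full synthetic session; returns ``(Session, truth)``.

    One LFP channel per region (independent draws of the same signal
    config) and, optionally, one spike train per entry of ``spikes``
    (unit_id -> (roi, SpikeCouplingConfig)).  All regions share per-trial
    theta phase so between-region analyses see a common rhythm.
    """
    task = task or TaskConfig(seed=seed)
    signal = signal or SignalConfig(seed=seed + 1)
    behavior = behavior or BehaviorConfig(seed=seed + 2)
    trials = generate_trials(task)
    rng = np.random.default_rng(seed + 3)
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=len(trials))
    lfps = {}
    for i, roi in enumerate(rois):
        cfg = SignalConfig(**{**asdict(signal), "seed": signal.seed + i})
        sig = synthesize_lfp(trials, cfg, roi=roi, channel="ch1",
                             theta_phase0=theta0)
        lfps[(roi, "ch1")] = sig
    first = lfps[(rois[0], "ch1")]
    trials = synthesize_behavior(trials, first, behavior)
    units = {}
    for uid, (roi, cfg) in (spikes or {}).items():
        units[uid] = synthesize_spikes(lfps[(roi, "ch1")], cfg, mean_rate_hz,
                                       unit_id=uid, roi=roi)
    session = Session(trials=trials, lfps=lfps, units=units,
                      meta={"synthetic": True, "seed": seed})
    session.validate()
    truth = {
        "task": asdict(task), "signal": asdict(signal),
        "behavior": asdict(behavior),
        "spikes": {u: asdict(c) for u, (_, c) in (spikes or {}).items()},
    }
    return session, truth
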