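"""Time-frequency decomposition of LFP epochs.

Morlet wavelet phase/power, Hanning-tapered FFT power, IRASA separation of
the fractal (1/f) and oscillatory spectral components, and the z-scored
high-frequency-band (HFB, 80-200 Hz) envelope used as a proxy for
population spiking.

Wavelets: ``w(t) = exp(i 2 pi f t) exp(-t^2 / (2 sigma_t^2))`` with
``sigma_t = n_cycles / (2 pi f)``, truncated to ``n_cycles`` full cycles
(+-n_cycles/(2f)).  Coefficients are scaled so a unit-amplitude sinusoid at
f yields |coefficient| = 1, and the phase follows the cosine convention
(phase 0 at the signal maximum).  Epochs are reflect-padded before
convolution; output samples whose wavelet support extends beyond the true
epoch are flagged as edge-contaminated and excluded from statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from .session import EpochedSignal, epoch_window


@dataclass
class ComplexSpectrogram:
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    coefficients: np.ndarray      # (n_trials, n_freqs, n_times) complex
    valid: np.ndarray             # (n_freqs, n_times) bool, False near edges
    n_cycles: np.ndarray
    source: tuple                 # (roi, channel)
    trial_ids: np.ndarray = field(default=None)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    def freq_index(self, f_hz: float) -> int:
        i = int(np.argmin(np.abs(self.freqs_hz - f_hz)))
        if abs(self.freqs_hz[i] - f_hz) > 1e-6:
            raise ValueError(f"frequency {f_hz} Hz not in spectrogram")
        return i

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times_ms - t_ms)))


def _wavelet(freq: float, n_cycles: float, rate_hz: float) -> np.ndarray:
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(round(rate_hz * n_cycles / (2.0 * freq)))
    t = np.arange(-half, half + 1) / rate_hz
    envelope = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    w = envelope * np.exp(2j * np.pi * freq * t)
    return w * (2.0 / envelope.sum())


def morlet_transform(signal: EpochedSignal, freqs: np.ndarray,
                     n_cycles: float | np.ndarray = 3.0,
                     times_ms: np.ndarray | None = None) -> ComplexSpectrogram:
    """Complex Morlet spectrogram of every trial.

    ``times_ms`` restricts the output time grid (e.g. a single pre-target
    estimate, or 10-ms steps for PAC); by default every sample is returned.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    n_cycles = np.broadcast_to(np.asarray(n_cycles, dtype=float),
                               freqs.shape).copy()
    fs = signal.rate_hz
    if np.any(freqs >= fs / 2):
        raise ValueError("requested frequency at or above Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")
    halves = np.round(fs * n_cycles / (2.0 * freqs)).astype(int)
    n = signal.n_samples
    if 2 * halves.max() + 1 > 2 * n - 1:
        raise ValueError("epoch too short for the widest requested wavelet")
    if times_ms is None:
        out_idx = np.arange(n)
    else:
        times_ms = np.atleast_1d(np.asarray(times_ms, dtype=float))
        out_idx = np.array([signal.time_index(t) for t in times_ms])
    pad = int(halves.max())
    xp = np.pad(signal.samples, ((0, 0), (pad, pad)), mode="reflect")

    n_tr = signal.n_trials
    coefs = np.empty((n_tr, freqs.size, out_idx.size), dtype=complex)
    nfft = sp_fft.next_fast_len(xp.shape[1] + 2 * pad + 1)
    X = None  # forward FFT of the padded epochs, computed on first use
    for i, (f, h) in enumerate(zip(freqs, halves)):
        w = _wavelet(f, n_cycles[i], fs)
        # c(t0) = sum_tau x(t0 + tau) w*(tau): correlation with the wavelet,
        # equal to convolution with w because w(-tau) = w*(tau)
        if out_idx.size * (2 * h + 1) < 8 * nfft:
            wc = w.conj()
            for j, t0 in enumerate(out_idx):
                seg = xp[:, t0 + pad - h: t0 + pad + h + 1]
                coefs[:, i, j] = seg @ wc
        else:
            if X is None:
                X = sp_fft.fft(xp, nfft, axis=1)
            W = sp_fft.fft(w, nfft)
            conv = sp_fft.ifft(X * W[None, :], axis=1)
            coefs[:, i, :] = conv[:, pad + h + out_idx]

    valid = np.empty((freqs.size, out_idx.size), dtype=bool)
    for i, h in enumerate(halves):
        valid[i] = (out_idx >= h) & (out_idx <= n - 1 - h)
    times_out = signal.t0_ms + out_idx * 1000.0 / fs
    return ComplexSpectrogram(
        freqs_hz=freqs, times_ms=times_out, coefficients=coefs, valid=valid,
        n_cycles=n_cycles, source=(signal.roi, signal.channel),
        trial_ids=signal.trial_ids.copy(),
    )


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    total_power: np.ndarray
    fractal_power: np.ndarray | None = None
    oscillatory_residual: np.ndarray | None = None
    window: tuple = (None, None)
    taper: str = "hann"


def hanning_fft_power(signal: EpochedSignal, window: tuple,
                      fmin: float = 3.0, fmax: float = 60.0) -> PowerSpectrum:
    """Trial-averaged Hanning-tapered FFT power, restricted to [fmin, fmax]."""
    sub = epoch_window(signal, *window)
    if sub.n_samples < signal.rate_hz / fmin:
        raise ValueError(
            f"window shorter than one cycle of {fmin} Hz")
    f, p = sp_signal.periodogram(sub.samples, fs=sub.rate_hz, window="hann",
                                 detrend=False, axis=1)
    keep = (f >= fmin) & (f <= fmax)
    return PowerSpectrum(freqs_hz=f[keep], total_power=p[:, keep].mean(axis=0),
                         window=window)


DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.9001, 0.05), 2))


def irasa(signal: EpochedSignal, window: tuple,
          h_set=DEFAULT_HSET, fmin: float = 3.0,
          fmax: float = 60.0) -> PowerSpectrum:
    """Irregular-resampling separation of fractal and oscillatory power.

    Each epoch is resampled by every pairwise non-integer factor h and 1/h;
    an oscillatory peak shifts under resampling while the 1/f background
    does not, so the median across h of the geometric mean of the h- and
    1/h-resampled spectra estimates the fractal component.  The oscillatory
    residual is total minus fractal.
    """
    h_set = np.asarray(h_set, dtype=float)
    if np.any(h_set <= 1.0) or np.any(np.isclose(h_set % 1.0, 0.0)):
        raise ValueError("resampling factors must be non-integer and > 1")
    total = hanning_fft_power(signal, window, fmin, fmax)
    sub = epoch_window(signal, *window)
    x = sub.samples
    fs = sub.rate_hz
    if not np.any(x):
        z = np.zeros_like(total.total_power)
        return PowerSpectrum(total.freqs_hz, z, z.copy(), z.copy(),
                             window=window)
    fractal_layers = []
    for h in h_set:
        frac = Fraction(h).limit_denominator(100)
        up, down = frac.numerator, frac.denominator
        layer = []
        for p_, q_ in ((up, down), (down, up)):
            xr = sp_signal.resample_poly(x, p_, q_, axis=1)
            fr, pr = sp_signal.periodogram(xr, fs=fs * p_ / q_, window="hann",
                                           detrend=False, axis=1)
            pr_mean = pr.mean(axis=0)
            layer.append(np.interp(total.freqs_hz, fr, pr_mean))
        fractal_layers.append(np.sqrt(layer[0] * layer[1]))
    fractal = np.median(fractal_layers, axis=0)
    fractal = np.maximum(fractal, 0.0)
    residual = total.total_power - fractal
    return PowerSpectrum(total.freqs_hz, total.total_power, fractal, residual,
                         window=window)


def fractal_slope(spectrum: PowerSpectrum) -> float:
    """Log-log slope of the fractal component (power ~ f^slope)."""
    f = spectrum.freqs_hz
    p = spectrum.fractal_power
    good = (p > 0) & (f > 0)
    coef = np.polyfit(np.log10(f[good]), np.log10(p[good]), 1)
    return float(coef[0])


HFB_FREQS = np.arange(80.0, 200.1, 10.0)


@dataclass
class HFBSeries:
    times_ms: np.ndarray
    zscored_hfb: np.ndarray       # (n_trials, n_times)
    band: tuple = (80.0, 200.0)
    baseline_window: tuple = (None, None)
    trial_ids: np.ndarray = None


def hfb_envelope(spect: ComplexSpectrogram,
                 baseline_window: tuple) -> HFBSeries:
    """Z-scored high-frequency-band power, averaged across 10-Hz steps.

    Power at each step frequency is z-scored against the pooled baseline
    distribution (all trials x baseline times) *before* averaging across
    steps, which neutralizes the 1/f drop-off across the 80-200 Hz range.
    """
    start, stop = baseline_window
    in_base = (spect.times_ms >= start) & (spect.times_ms < stop)
    base_ok = in_base[None, :] & spect.valid
    if not np.any(np.all(base_ok[:, in_base], axis=0)):
        raise ValueError("baseline window has no clean samples")
    power = spect.power  # (n_trials, n_freqs, n_times)
    z = np.empty_like(power)
    for i in range(spect.freqs_hz.size):
        cols = in_base & spect.valid[i]
        base = power[:, i, cols]
        mu, sd = base.mean(), base.std()
        if sd == 0:
            raise ValueError("degenerate baseline (zero variance)")
        z[:, i, :] = (power[:, i, :] - mu) / sd
    return HFBSeries(times_ms=spect.times_ms, zscored_hfb=z.mean(axis=1),
                     band=(float(spect.freqs_hz.min()),
                           float(spect.freqs_hz.max())),
                     baseline_window=baseline_window,
                     trial_ids=spect.trial_ids)
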