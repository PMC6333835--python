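"""Overlapping 180-degree phase binning and the one-cycle sine fit.

Several analyses in this package reduce "quantity as a function of
oscillatory phase" to a single modulation strength: hit rate vs. pre-target
phase, spike-field coupling vs. theta phase, and band power vs. phase
(phase-amplitude coupling).  All of them share the same machinery:

* sort samples into 72 overlapping 180-degree bins whose centers advance in
  5-degree steps (0, 5, ..., 355 degrees), each sample contributing to
  exactly 36 bins (half-open membership: a sample with phase ``p`` belongs
  to the bin centered at ``c`` iff ``(p - c) mod 360 in [-90, 90)``);
* fit a single-cycle cosine to the resulting 72-point function and keep its
  amplitude, preferred phase, and mean level.

Because bin edges fall on multiples of 5 degrees, binning is implemented by
first histogramming samples into 72 closed 5-degree sectors and then taking
a circular 36-sector boxcar sum -- exactly equivalent to testing each
sample against each bin, but O(n + 72) instead of O(72 n).

Phase convention throughout the package: phase 0 is the signal maximum
(cosine convention) and phase increases with time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_BINS = 72
BIN_STEP_DEG = 360.0 / N_BINS  # 5 degrees
BIN_HALFWIDTH_DEG = 90.0
SECTORS_PER_BIN = 36

BIN_CENTERS_DEG = np.arange(N_BINS) * BIN_STEP_DEG


@dataclass
class SineFit:
    """One-cycle cosine fit ``mean + amplitude * cos(phase - preferred)``."""

    mean_level: float
    amplitude: float
    preferred_phase_deg: float

    def predict(self, phase_deg: np.ndarray) -> np.ndarray:
        return self.mean_level + self.amplitude * np.cos(
            np.deg2rad(phase_deg - self.preferred_phase_deg)
        )


@dataclass
class PhaseBinnedFunction:
    """A quantity evaluated in the 72 overlapping 180-degree phase bins."""

    values: np.ndarray          # (72,); NaN where flagged
    n_per_bin: np.ndarray       # (72,) sample counts
    freq_hz: float | None = None
    bin_centers_deg: np.ndarray = field(
        default_factory=lambda: BIN_CENTERS_DEG.copy()
    )
    bin_halfwidth_deg: float = BIN_HALFWIDTH_DEG

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_per_bin = np.asarray(self.n_per_bin)
        if self.values.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.values.shape}")

    @property
    def flagged(self) -> np.ndarray:
        return ~np.isfinite(self.values)


def sector_index(phase_rad: np.ndarray) -> np.ndarray:
    """5-degree sector index (0..71) for each phase (radians)."""
    deg = np.rad2deg(np.asarray(phase_rad, dtype=float)) % 360.0
    idx = np.floor(deg / BIN_STEP_DEG).astype(np.intp)
    # guard against deg == 360.0 after rounding
    idx[idx == N_BINS] = 0
    return idx


def circular_boxcar(sector_totals: np.ndarray) -> np.ndarray:
    """Sum each run of 36 consecutive sectors ``b-18 .. b+17`` (circular).

    Works on the last axis, so stacked (e.g. per-permutation) sector
    histograms can be reduced in one call.
    """
    x = np.asarray(sector_totals, dtype=float)
    tiled = np.concatenate([x, x, x], axis=-1)
    cs = np.cumsum(tiled, axis=-1)
    b = np.arange(N_BINS) + N_BINS
    lo = b - SECTORS_PER_BIN // 2   # first sector in the window
    hi = b + SECTORS_PER_BIN // 2 - 1  # last sector (inclusive)
    return cs[..., hi] - cs[..., lo - 1]


def bin_values(phase_rad: np.ndarray, sample_values: np.ndarray,
               freq_hz: float | None = None,
               min_per_bin: int = 1) -> PhaseBinnedFunction:
    """Average ``sample_values`` within each overlapping 180-degree bin."""
    phase_rad = np.asarray(phase_rad, dtype=float).ravel()
    sample_values = np.asarray(sample_values, dtype=float).ravel()
    if phase_rad.shape != sample_values.shape:
        raise ValueError("phase and value arrays must have the same length")
    idx = sector_index(phase_rad)
    sums = np.bincount(idx, weights=sample_values, minlength=N_BINS)
    counts = np.bincount(idx, minlength=N_BINS)
    bin_sums = circular_boxcar(sums)
    bin_counts = circular_boxcar(counts.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(bin_counts >= min_per_bin, bin_sums / bin_counts, np.nan)
    return PhaseBinnedFunction(values=vals, n_per_bin=bin_counts.astype(int),
                               freq_hz=freq_hz)


_EXP = np.exp(-1j * np.deg2rad(BIN_CENTERS_DEG))


def one_cycle_sine_amplitude(f: PhaseBinnedFunction | np.ndarray,
                             max_flagged: int = 4) -> SineFit:
    """One-cycle cosine fit of a 72-bin function.

    On a complete grid this is the second FFT component: ``amplitude =
    2|F_1|/72``, ``preferred phase = -arg F_1``, ``mean = F_0/72``.  With up
    to ``max_flagged`` missing bins the same three parameters are obtained
    by least squares on the remaining bins (identical to the FFT on a
    complete grid, by orthogonality of the Fourier basis).
    """
    if isinstance(f, PhaseBinnedFunction):
        vals = f.values
    else:
        vals = np.asarray(f, dtype=float)
        if vals.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bin values")
    bad = ~np.isfinite(vals)
    n_bad = int(bad.sum())
    if n_bad > max_flagged:
        raise ValueError(
            f"{n_bad} flagged bins exceed the maximum of {max_flagged}"
        )
    if n_bad == 0:
        c1 = vals @ _EXP
        mean = float(vals.mean())
        amp = float(2.0 * np.abs(c1) / N_BINS)
        phase = float(np.rad2deg(-np.angle(c1)) % 360.0)
        return SineFit(mean, amp, phase)
    theta = np.deg2rad(BIN_CENTERS_DEG[~bad])
    design = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    beta, *_ = np.linalg.lstsq(design, vals[~bad], rcond=None)
    m, a_cos, a_sin = beta
    amp = float(np.hypot(a_cos, a_sin))
    phase = float(np.rad2deg(np.arctan2(a_sin, a_cos)) % 360.0)
    return SineFit(float(m), amp, phase)


def sine_amplitudes(values: np.ndarray) -> np.ndarray:
    """Vectorized one-cycle amplitude for stacked complete 72-bin functions.

    ``values`` has shape (..., 72); returns (...,) amplitudes.  Used on
    permutation stacks where no bins are flagged.
    """
    c1 = values @ _EXP
    return 2.0 * np.abs(c1) / N_BINS


@dataclass
class ThetaBinDefinition:
    """The 'good' and 'poor' 5 Hz half-cycles used to split analyses."""

    good_center_deg: float
    freq_hz: float = 5.0
    estimation_time_ms: float = -250.0
    wavelet_cycles: float = 2.0

    @property
    def poor_center_deg(self) -> float:
        return (self.good_center_deg + 180.0) % 360.0

    def assign(self, theta_phase_rad: np.ndarray) -> np.ndarray:
        """Map phases to bins: +1 good, -1 poor (half-open 180-degree bins)."""
        d = (np.rad2deg(theta_phase_rad) - self.good_center_deg) % 360.0
        return np.where((d < 90.0) | (d >= 270.0), 1, -1)
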