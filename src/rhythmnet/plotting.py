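"""Minimal diagnostic plots for the core result objects."""

from __future__ import annotations

import numpy as np

from .phasebin import PhaseBinnedFunction
from .granger import GrangerSpectrum
from .pac import PACMap


def plot_phase_binned(f: PhaseBinnedFunction, ax=None, label=None):
    """Value vs. phase-bin center, with the one-cycle fit overlaid."""
    import matplotlib.pyplot as plt
    from .phasebin import one_cycle_sine_amplitude
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(f.bin_centers_deg, f.values, ".", label=label)
    try:
        fit = one_cycle_sine_amplitude(f)
        ax.plot(f.bin_centers_deg, fit.predict(f.bin_centers_deg), "-",
                alpha=0.7)
    except ValueError:
        pass
    ax.set_xlabel("phase (deg)")
    ax.set_ylabel(f"value ({f.freq_hz:g} Hz)" if f.freq_hz else "value")
    return ax


def plot_granger(spec: GrangerSpectrum, ax=None):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    for (src, snk), gc in spec.values.items():
        ax.plot(spec.freqs_hz, gc, label=f"{src} → {snk}")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("Granger causality")
    ax.legend(fontsize="small")
    return ax


def plot_pac(pm: PACMap, ax=None):
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(pm.phase_freqs_hz, pm.modulation_pct, "-o", ms=3)
    if pm.holm_significant is not None and pm.holm_significant.any():
        sel = pm.holm_significant
        ax.plot(pm.phase_freqs_hz[sel], pm.modulation_pct[sel], "r*")
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("modulation (%)")
    ax.set_title(pm.power_target)
    return ax
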