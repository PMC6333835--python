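"""End-to-end orchestration of the analysis sequence on one session:
spiking -> power -> phase-detection -> theta bins -> spike-field coupling ->
Granger -> PAC, with per-stage isolation of failures and a structured
report."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .behavior import (define_theta_bins, phase_detection_spectrum,
                       pretarget_phase, theta_binned_phase_detection)
from .granger import fit_mvar, preprocess_gc, theta_binned_granger
from .pac import between_region_pac_hfb, within_region_pac
from .phasebin import ThetaBinDefinition
from .session import Session
from .spectral import HFB_FREQS, hfb_envelope, irasa, morlet_transform
from .spikefield import (condition_ppc_contrast, extract_spike_phases,
                         ppc_spectrum)
from .spikes import (delay_comparison, kernel_rate, population_psth,
                     pretarget_means, responsiveness_test)


@dataclass
class AnalysisConfig:
    """Declarative knobs for the full pipeline (schema-validated)."""

    rois: tuple = ("mdPul", "FEF", "LIP")
    phase_freqs_hz: tuple = (3.0, 60.0, 1.0)       # start, stop, step
    higher_freqs_hz: tuple = (9.0, 60.0, 1.0)
    pac_phase_freqs_hz: tuple = (9.0, 35.0, 1.0)
    estimation_time_ms: float = -250.0
    theta_freq_hz: float = 5.0
    theta_wavelet_cycles: float = 2.0
    wavelet_cycles: float = 3.0
    n_perm: int = 1500
    alpha: float = 0.05
    irasa_window_ms: tuple = (-500.0, 0.0)
    irasa_min_delay_ms: float = 750.0
    spike_window_ms: tuple = (-500.0, -125.0)
    pac_window_ms: tuple = (-750.0, -200.0)
    pac_step_ms: float = 10.0
    baseline_window_ms: tuple = (-350.0, 0.0)
    pretarget_mean_window_ms: float = 500.0
    min_trials: int = 50
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    def grid(self, which: tuple) -> np.ndarray:
        start, stop, step = which
        return np.arange(start, stop + step / 2.0, step)


@dataclass
class Report:
    results: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["pipeline report"]
        for k in self.results:
            lines.append(f"  [ok]      {k} ({self.timings_s.get(k, 0):.1f} s)")
        for k, v in self.skipped.items():
            lines.append(f"  [skipped] {k}: {v}")
        for k, v in self.errors.items():
            lines.append(f"  [error]   {k}: {v}")
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {"provenance": self.provenance,
                   "timings_s": self.timings_s,
                   "errors": self.errors, "skipped": self.skipped,
                   "results": _summarize(self.results)}
        (out / "report.json").write_text(json.dumps(payload, indent=1))


def _summarize(obj, depth=0):
    """JSON-safe digest of heterogenous result objects."""
    if depth > 6:
        return str(type(obj).__name__)
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if isinstance(obj, (np.integer, np.floating)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        if obj.size <= 256:
            return obj.tolist()
        return {"shape": list(obj.shape), "mean": float(np.nanmean(obj))}
    if isinstance(obj, dict):
        return {str(k): _summarize(v, depth + 1) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        if len(obj) > 32:
            return f"list[{len(obj)}]"
        return [_summarize(v, depth + 1) for v in obj]
    if hasattr(obj, "__dict__") or hasattr(obj, "__dataclass_fields__"):
        try:
            return _summarize({k: v for k, v in vars(obj).items()
                               if not k.startswith("_")}, depth + 1)
        except TypeError:
            return str(obj)
    return str(obj)


def run_pipeline(session: Session, config: AnalysisConfig | None = None,
                 only: set | None = None) -> Report:
    """Execute every analysis stage in dependency order.

    A stage that raises (e.g. a sample-size refusal) is recorded in the
    report and its dependents are skipped with a reason; independent
    stages still run.  ``only`` restricts execution to a stage subset
    (dependencies must be included by the caller).
    """
    cfg = config or AnalysisConfig()
    session.validate()
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = Report(provenance={"config_hash": cfg_hash, "seed": cfg.seed,
                                "version": __version__})

    def stage(name, fn, *deps):
        if only is not None and name not in only:
            report.skipped[name] = "not selected"
            return
        missing = [d for d in deps if d not in report.results]
        if missing:
            report.skipped[name] = f"requires {missing}"
            return
        t0 = time.time()
        try:
            report.results[name] = fn()
        except Exception as exc:   # noqa: BLE001 - stage isolation
            report.errors[name] = f"{type(exc).__name__}: {exc}"
        else:
            report.timings_s[name] = time.time() - t0

    trials = session.trials
    valid = trials.valid_target_trials()
    roi_lfps = {roi: sig for (roi, _), sig in session.lfps.items()
                if roi in cfg.rois}

    # ---- spikes ---------------------------------------------------------
    def do_spikes():
        if not session.units:
            raise ValueError("session has no spike trains")
        out = {}
        psth_rates = []
        for uid, train in session.units.items():
            rates = kernel_rate(train, epoch_ms=(-1000.0, 250.0))
            resp = responsiveness_test(rates, None, unit_id=uid,
                                       baseline_window=cfg.baseline_window_ms,
                                       seed=cfg.seed)
            row = {"responsiveness": resp}
            if resp.unit_class in ("visual", "visual_movement"):
                means = pretarget_means(rates, cfg.pretarget_mean_window_ms)
                id_to_row = {t: i for i, t in enumerate(rates.trial_ids)}
                cued = [means[id_to_row[t]] for t in
                        valid.loc[valid.condition == "cued", "trial_id"]]
                base = [means[id_to_row[t]] for t in valid.loc[
                    valid.condition == "different_object", "trial_id"]]
                if cued and base:
                    row["delay_comparison"] = delay_comparison(cued, base)
            out[uid] = row
            psth_rates.append(rates)
        out["population_psth"] = population_psth(psth_rates)
        return out

    stage("spikes", do_spikes)

    # ---- LFP power ------------------------------------------------------
    def do_power():
        out = {}
        long_ids = trials.analyzable().loc[
            trials.analyzable().cue_target_delay_ms >= cfg.irasa_min_delay_ms,
            "trial_id"]
        for roi, sig in roi_lfps.items():
            out[roi] = irasa(sig.select_trials(long_ids), cfg.irasa_window_ms)
        return out

    stage("power", do_power)

    # ---- phase-detection ------------------------------------------------
    first_roi = cfg.rois[0]

    def do_phase_detection():
        sig = roi_lfps[first_roi].select_trials(valid["trial_id"])
        freqs = cfg.grid(cfg.phase_freqs_hz)
        spect = morlet_transform(sig, freqs, cfg.wavelet_cycles,
                                 times_ms=[cfg.estimation_time_ms])
        phases = pretarget_phase(spect, cfg.estimation_time_ms)
        outcomes = (valid["outcome"] == "hit").to_numpy()
        return {"freqs": freqs,
                "spectrum": phase_detection_spectrum(
                    phases, outcomes, freqs, n_perm=cfg.n_perm,
                    alpha=cfg.alpha, min_trials=cfg.min_trials,
                    seed=cfg.seed)}

    stage("phase_detection", do_phase_detection)

    def do_theta_bins():
        res = report.results["phase_detection"]["spectrum"]
        i5 = int(np.argmin(np.abs(res.freqs_hz - cfg.theta_freq_hz)))
        return define_theta_bins(res.fits[i5],
                                 estimation_time_ms=cfg.estimation_time_ms,
                                 wavelet_cycles=cfg.theta_wavelet_cycles)

    stage("theta_bins", do_theta_bins, "phase_detection")

    def theta_phases_for(sig):
        spect = morlet_transform(sig, [cfg.theta_freq_hz],
                                 cfg.theta_wavelet_cycles,
                                 times_ms=[cfg.estimation_time_ms])
        return np.angle(spect.coefficients[:, 0, 0])

    def do_theta_binned_pd():
        bins = report.results["theta_bins"]
        sig = roi_lfps[first_roi].select_trials(valid["trial_id"])
        freqs = cfg.grid(cfg.higher_freqs_hz)
        spect = morlet_transform(sig, freqs, cfg.wavelet_cycles,
                                 times_ms=[cfg.estimation_time_ms])
        phases = pretarget_phase(spect, cfg.estimation_time_ms)
        outcomes = (valid["outcome"] == "hit").to_numpy()
        return theta_binned_phase_detection(
            theta_phases_for(sig), phases, outcomes, freqs, bins,
            n_perm=cfg.n_perm, alpha=cfg.alpha, min_trials=cfg.min_trials,
            seed=cfg.seed)

    stage("theta_binned_phase_detection", do_theta_binned_pd, "theta_bins")

    # ---- spike-field ----------------------------------------------------
    def do_ppc():
        if not session.units:
            raise ValueError("session has no spike trains")
        out = {}
        freqs = cfg.grid(cfg.phase_freqs_hz)[::2]
        ids = valid["trial_id"]
        for uid, train in session.units.items():
            for roi, sig in roi_lfps.items():
                if roi == train.roi:
                    continue
                sub = sig.select_trials(ids)
                spect = morlet_transform(sub, freqs, cfg.wavelet_cycles)
                phases = extract_spike_phases(train.select_trials(ids), spect,
                                              cfg.spike_window_ms)
                if phases.empty:
                    continue
                entry = {"freqs": freqs, "ppc": ppc_spectrum(phases)}
                cued_ids = valid.loc[valid.condition == "cued", "trial_id"]
                base_ids = valid.loc[valid.condition == "different_object",
                                     "trial_id"]
                if len(cued_ids) >= 10 and len(base_ids) >= 10:
                    pc = extract_spike_phases(
                        train.select_trials(cued_ids),
                        morlet_transform(sig.select_trials(cued_ids), freqs,
                                         cfg.wavelet_cycles),
                        cfg.spike_window_ms)
                    pb = extract_spike_phases(
                        train.select_trials(base_ids),
                        morlet_transform(sig.select_trials(base_ids), freqs,
                                         cfg.wavelet_cycles),
                        cfg.spike_window_ms)
                    if not pc.empty and not pb.empty:
                        entry["condition_contrast"] = condition_ppc_contrast(
                            pc, pb, n_perm=cfg.n_perm, alpha=cfg.alpha,
                            seed=cfg.seed)
                out[(uid, roi)] = entry
        if not out:
            raise ValueError("no spike-field pairs with spikes in window")
        return out

    stage("ppc", do_ppc)

    # ---- Granger --------------------------------------------------------
    def do_granger():
        rois = [r for r in cfg.rois if r in roi_lfps]
        if len(rois) < 2:
            raise ValueError("need at least two regions for Granger")
        sigs = [roi_lfps[r].select_trials(valid["trial_id"]) for r in rois]
        epochs, rate, _ = preprocess_gc(sigs)
        model = fit_mvar(epochs, rate, order=8,
                         channel_names=tuple(rois), compute_aic=True)
        out = {"model": model, "pairwise": model.granger()}
        if len(rois) >= 3:
            out["conditional"] = model.conditional_granger(
                rois[0], rois[1], rois[2])
        if "theta_bins" in report.results:
            out["theta_binned"] = theta_binned_granger(
                sigs[:2], sigs[0], report.results["theta_bins"])
        return out

    stage("granger", do_granger)

    # ---- PAC ------------------------------------------------------------
    def do_pac():
        rois = [r for r in cfg.rois if r in roi_lfps]
        ids = valid["trial_id"]
        t_grid = np.arange(cfg.pac_window_ms[0],
                           cfg.pac_window_ms[1] + 1e-9, cfg.pac_step_ms)
        out = {}
        sig0 = roi_lfps[rois[0]].select_trials(ids)
        theta_sp = morlet_transform(sig0, [cfg.theta_freq_hz],
                                    cfg.wavelet_cycles, times_ms=t_grid)
        pw_freqs = cfg.grid(cfg.higher_freqs_hz)[::3]
        pw_sp = morlet_transform(sig0, pw_freqs, cfg.wavelet_cycles,
                                 times_ms=t_grid)
        out["within"] = within_region_pac(
            np.angle(theta_sp.coefficients[:, 0, :]),
            np.moveaxis(pw_sp.power, 1, 0), pw_freqs,
            n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed)
        if len(rois) >= 2:
            sig1 = roi_lfps[rois[1]].select_trials(ids)
            ph_freqs = cfg.grid(cfg.pac_phase_freqs_hz)[::2]
            ph_sp = morlet_transform(sig0, ph_freqs, cfg.wavelet_cycles,
                                     times_ms=t_grid)
            hfb_sp = morlet_transform(sig1, HFB_FREQS, 7.0, times_ms=None)
            # baseline: earliest clean 300 ms of the epoch (pre-cue in
            # cue-aligned data, early delay in target-aligned data)
            hfb = hfb_envelope(hfb_sp,
                               (sig1.t0_ms + 100.0, sig1.t0_ms + 400.0))
            cols = [hfb_sp.time_index(t) for t in t_grid]
            out["between"] = between_region_pac_hfb(
                np.moveaxis(ph_sp.phase, 1, 0),
                hfb.zscored_hfb[:, cols], ph_freqs,
                n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed)
        return out

    stage("pac", do_pac)
    return report
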