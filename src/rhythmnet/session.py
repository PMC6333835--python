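"""Recording-session data model and on-disk layout.

A session directory holds:

* ``trials.csv`` -- the trial table (one row per trial, header row, UTF-8);
* ``signals.h5`` -- HDF5 container with groups ``/lfp/<roi>/<channel>``
  (per-trial LFP epochs, microvolts) and ``/spikes/<unit>`` (ragged spike
  times, milliseconds);
* ``meta.json`` -- free-form provenance;
* ``truth.json`` -- optional generator ground truth (synthetic sessions).

Times are in milliseconds, the alignment event is t = 0, and windows are
half-open ``[start, stop)``.  Aborted trials are loaded but excluded from
every analysis by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

TRIAL_COLUMNS = [
    "trial_id", "bar_orientation", "cue_quadrant", "target_quadrant",
    "condition", "fixation_delay_ms", "bar_cue_delay_ms",
    "cue_target_delay_ms", "outcome", "response_time_ms",
]

CONDITIONS = ("cued", "same_object", "different_object", "catch")
OUTCOMES = ("hit", "miss", "false_alarm", "catch_correct", "aborted")


class SessionValidationError(ValueError):
    pass


class TrialTable:
    """Thin validating wrapper around a pandas DataFrame of trials."""

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise SessionValidationError(f"trial table missing columns {missing}")
        self.df = df.reset_index(drop=True)
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.df
        if df["trial_id"].duplicated().any():
            dup = df.loc[df["trial_id"].duplicated(), "trial_id"].tolist()
            raise SessionValidationError(f"duplicate trial ids {dup}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise SessionValidationError(f"unknown conditions {sorted(bad_cond)}")
        bad_out = set(df["outcome"]) - set(OUTCOMES)
        if bad_out:
            raise SessionValidationError(f"unknown outcomes {sorted(bad_out)}")
        is_catch = df["condition"] == "catch"
        has_target = df["target_quadrant"].notna()
        if (is_catch & has_target).any() or (~is_catch & ~has_target).any():
            raise SessionValidationError(
                "condition=catch must coincide with absent target_quadrant")
        ctd = df.loc[~is_catch, "cue_target_delay_ms"]
        if len(ctd) and ((ctd < 300) | (ctd > 1600)).any():
            raise SessionValidationError("cue-target delay outside [300, 1600] ms")
        for col in ("fixation_delay_ms", "bar_cue_delay_ms"):
            v = df[col]
            if ((v < 500) | (v > 1200)).any():
                raise SessionValidationError(f"{col} outside [500, 1200] ms")
        hits = df["outcome"] == "hit"
        rt = df.loc[hits, "response_time_ms"]
        if rt.isna().any() or ((rt < 150) | (rt > 650)).any():
            raise SessionValidationError(
                "hit trials require response_time_ms in [150, 650]")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.df[TRIAL_COLUMNS], other.df[TRIAL_COLUMNS],
                check_dtype=False)
        except AssertionError:
            return False
        return True

    @property
    def trial_ids(self) -> np.ndarray:
        return self.df["trial_id"].to_numpy()

    def analyzable(self) -> pd.DataFrame:
        """Non-aborted trials (the default analysis set)."""
        return self.df[self.df["outcome"] != "aborted"]

    def valid_target_trials(self) -> pd.DataFrame:
        """Non-aborted, non-catch trials with a hit/miss outcome."""
        df = self.df
        return df[df["outcome"].isin(("hit", "miss"))]

    def to_csv(self, path: Path | str) -> None:
        self.df[TRIAL_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Path | str) -> "TrialTable":
        return cls(pd.read_csv(path))


@dataclass
class EpochedSignal:
    """Per-trial LFP epochs aligned to one task event."""

    roi: str
    channel: str
    alignment_event: str       # "cue" or "target"
    t0_ms: float               # time of the first sample
    rate_hz: float
    samples: np.ndarray        # (n_trials, n_samples), microvolts
    trial_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_trials, n_samples)")
        if self.samples.shape[0] != self.trial_ids.size:
            raise ValueError("trial_ids length must match samples rows")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_trials(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_samples) * 1000.0 / self.rate_hz

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        idx = int(round((t_ms - self.t0_ms) * self.rate_hz / 1000.0))
        if not 0 <= idx < self.n_samples:
            raise IndexError(f"time {t_ms} ms outside epoch")
        return idx

    def select_trials(self, trial_ids: Iterable[int]) -> "EpochedSignal":
        wanted = np.asarray(list(trial_ids))
        pos = {tid: i for i, tid in enumerate(self.trial_ids)}
        missing = [int(t) for t in wanted if t not in pos]
        if missing:
            raise SessionValidationError(
                f"signal {self.roi}/{self.channel} missing trials {missing[:10]}")
        rows = [pos[t] for t in wanted]
        return EpochedSignal(self.roi, self.channel, self.alignment_event,
                             self.t0_ms, self.rate_hz,
                             self.samples[rows], wanted, dict(self.meta))


def epoch_window(signal: EpochedSignal, start_ms: float,
                 stop_ms: float) -> EpochedSignal:
    """Sub-epoch over the half-open window ``[start_ms, stop_ms)``."""
    if start_ms >= stop_ms:
        raise ValueError("start must precede stop")
    step = 1000.0 / signal.rate_hz
    i0 = int(round((start_ms - signal.t0_ms) / step))
    n = int(round((stop_ms - start_ms) / step))
    if i0 < 0 or i0 + n > signal.n_samples:
        raise ValueError(
            f"window [{start_ms}, {stop_ms}) outside epoch "
            f"[{signal.t0_ms}, {signal.t0_ms + signal.n_samples * step})")
    return EpochedSignal(signal.roi, signal.channel, signal.alignment_event,
                         signal.t0_ms + i0 * step, signal.rate_hz,
                         signal.samples[:, i0:i0 + n],
                         signal.trial_ids.copy(), dict(signal.meta))


@dataclass
class SpikeTrain:
    """Per-trial sorted spike times (ms) for one isolated unit."""

    unit_id: str
    roi: str
    alignment_event: str
    spike_times_ms: list            # list of 1-D arrays, one per trial
    trial_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trial_ids = np.asarray(self.trial_ids)
        self.spike_times_ms = [np.asarray(t, dtype=float)
                               for t in self.spike_times_ms]
        if len(self.spike_times_ms) != self.trial_ids.size:
            raise ValueError("one spike array required per trial id")
        for i, t in enumerate(self.spike_times_ms):
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError(f"spike times not sorted in trial row {i}")

    @property
    def n_trials(self) -> int:
        return self.trial_ids.size

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times_ms))

    def select_trials(self, trial_ids: Iterable[int]) -> "SpikeTrain":
        wanted = np.asarray(list(trial_ids))
        pos = {tid: i for i, tid in enumerate(self.trial_ids)}
        missing = [int(t) for t in wanted if t not in pos]
        if missing:
            raise SessionValidationError(
                f"unit {self.unit_id} missing trials {missing[:10]}")
        return SpikeTrain(self.unit_id, self.roi, self.alignment_event,
                          [self.spike_times_ms[pos[t]] for t in wanted],
                          wanted, dict(self.meta))


@dataclass
class Session:
    """A recording session: trials plus aligned LFPs and spike trains."""

    trials: TrialTable
    lfps: dict = field(default_factory=dict)    # (roi, channel) -> EpochedSignal
    units: dict = field(default_factory=dict)   # unit_id -> SpikeTrain
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.trials.validate()
        ids = set(int(t) for t in self.trials.trial_ids)
        for key, sig in self.lfps.items():
            extra = sorted(set(int(t) for t in sig.trial_ids) - ids)
            if extra:
                raise SessionValidationError(
                    f"signal {key} references unknown trials {extra[:10]}")
            missing = sorted(ids - set(int(t) for t in sig.trial_ids))
            if missing:
                raise SessionValidationError(
                    f"signal {key} missing trials {missing[:10]}")
        for uid, train in self.units.items():
            extra = sorted(set(int(t) for t in train.trial_ids) - ids)
            if extra:
                raise SessionValidationError(
                    f"unit {uid} references unknown trials {extra[:10]}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Session):
            return NotImplemented
        if self.trials != other.trials:
            return False
        if set(self.lfps) != set(other.lfps) or set(self.units) != set(other.units):
            return False
        for key, a in self.lfps.items():
            b = other.lfps[key]
            if (a.roi, a.channel, a.alignment_event) != (b.roi, b.channel,
                                                         b.alignment_event):
                return False
            if abs(a.t0_ms - b.t0_ms) > 1e-9 or a.rate_hz != b.rate_hz:
                return False
            if a.samples.shape != b.samples.shape or not np.allclose(
                    a.samples, b.samples, atol=1e-9):
                return False
            if not np.array_equal(a.trial_ids, b.trial_ids):
                return False
        for uid, a in self.units.items():
            b = other.units[uid]
            if not np.array_equal(a.trial_ids, b.trial_ids):
                return False
            for ta, tb in zip(a.spike_times_ms, b.spike_times_ms):
                if ta.size != tb.size or not np.allclose(ta, tb, atol=1e-9):
                    return False
        return True


def save_session(session: Session, path: Path | str) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(path / "trials.csv")
    with h5py.File(path / "signals.h5", "w") as h5:
        for (roi, channel), sig in session.lfps.items():
            g = h5.require_group(f"lfp/{roi}/{channel}")
            g.create_dataset("samples", data=sig.samples)
            g.create_dataset("trial_ids", data=np.asarray(sig.trial_ids,
                                                          dtype=np.int64))
            g.attrs["roi"] = sig.roi
            g.attrs["channel"] = sig.channel
            g.attrs["alignment_event"] = sig.alignment_event
            g.attrs["t0_ms"] = sig.t0_ms
            g.attrs["rate_hz"] = sig.rate_hz
            g.attrs["meta_json"] = json.dumps(_jsonable(sig.meta))
        for uid, train in session.units.items():
            g = h5.require_group(f"spikes/{uid}")
            flat = (np.concatenate(train.spike_times_ms)
                    if train.n_trials else np.empty(0))
            counts = np.array([t.size for t in train.spike_times_ms],
                              dtype=np.int64)
            g.create_dataset("times", data=flat)
            g.create_dataset("counts", data=counts)
            g.create_dataset("trial_ids", data=np.asarray(train.trial_ids,
                                                          dtype=np.int64))
            g.attrs["unit_id"] = train.unit_id
            g.attrs["roi"] = train.roi
            g.attrs["alignment_event"] = train.alignment_event
            g.attrs["meta_json"] = json.dumps(_jsonable(train.meta))
    (path / "meta.json").write_text(json.dumps(_jsonable(session.meta),
                                               indent=1))


def load_session(path: Path | str) -> Session:
    path = Path(path)
    trials_file = path / "trials.csv"
    if not trials_file.exists():
        raise FileNotFoundError(f"missing trial table {trials_file}")
    trials = TrialTable.from_csv(trials_file)
    lfps, units = {}, {}
    h5file = path / "signals.h5"
    if h5file.exists():
        with h5py.File(h5file, "r") as h5:
            for roi in h5.get("lfp", {}):
                for channel in h5[f"lfp/{roi}"]:
                    g = h5[f"lfp/{roi}/{channel}"]
                    sig = EpochedSignal(
                        roi=str(g.attrs["roi"]), channel=str(g.attrs["channel"]),
                        alignment_event=str(g.attrs["alignment_event"]),
                        t0_ms=float(g.attrs["t0_ms"]),
                        rate_hz=float(g.attrs["rate_hz"]),
                        samples=g["samples"][()],
                        trial_ids=g["trial_ids"][()],
                        meta=json.loads(g.attrs.get("meta_json", "{}")),
                    )
                    lfps[(sig.roi, sig.channel)] = sig
            for uid in h5.get("spikes", {}):
                g = h5[f"spikes/{uid}"]
                counts = g["counts"][()]
                flat = g["times"][()]
                offsets = np.concatenate([[0], np.cumsum(counts)])
                trains = [flat[offsets[i]:offsets[i + 1]]
                          for i in range(counts.size)]
                train = SpikeTrain(
                    unit_id=str(g.attrs["unit_id"]), roi=str(g.attrs["roi"]),
                    alignment_event=str(g.attrs["alignment_event"]),
                    spike_times_ms=trains, trial_ids=g["trial_ids"][()],
                    meta=json.loads(g.attrs.get("meta_json", "{}")),
                )
                units[train.unit_id] = train
    meta_file = path / "meta.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    session = Session(trials=trials, lfps=lfps, units=units, meta=meta)
    session.validate()
    return session


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
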