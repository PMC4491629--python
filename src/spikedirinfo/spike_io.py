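"""Data model and file I/O for spike trains, LFPs, behavior, and sessions.

Containers are lightweight frozen dataclasses over numpy arrays. Spike tables
travel as CSV (``unit_id,region,time_s``, times in seconds) so they are
independent of any acquisition system's sampling rate; whole recording
sessions round-trip through a single HDF5 container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

REGIONS = ("SNr", "VA", "other")
CONDITIONS = ("control", "hPD", "DBS")

_SESSION_FORMAT_VERSION = 1


class SessionIOError(RuntimeError):
    """Raised when a session container cannot be read or is inconsistent."""


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times of one unit within an observation window.

    Parameters
    ----------
    unit_id : str
        Unit label, unique within a session.
    region : str
        Anatomical region, one of ``SNr`` (basal-ganglia output), ``VA``
        (motor thalamus), or ``other``.
    times : array of float
        Strictly increasing spike times, seconds.
    t_start, t_stop : float
        Observation window, seconds; all spikes must lie inside it.
    """

    unit_id: str
    region: str
    times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self):
        object.__setattr__(self, "times", _as_float_array(self.times))
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if not self.t_stop > self.t_start:
            raise ValueError("t_stop must exceed t_start")
        t = self.times
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"spike times of unit {self.unit_id!r} must be strictly increasing")
            if t[0] < self.t_start or t[-1] > self.t_stop:
                raise ValueError(
                    f"unit {self.unit_id!r}: spike times outside window "
                    f"[{self.t_start}, {self.t_stop}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def with_times(self, times: np.ndarray) -> "SpikeTrain":
        return replace(self, times=np.asarray(times, dtype=float))


@dataclass(frozen=True)
class LFPSignal:
    """Regularly sampled local field potential trace.

    ``fs`` must exceed 1350 Hz if the standard 675 Hz lowpass is to be
    applied (Nyquist); validation here only requires positivity and finite
    samples so that already-decimated traces remain representable.
    """

    samples: np.ndarray
    fs: float
    channel_id: str
    region: str = "other"

    def __post_init__(self):
        object.__setattr__(self, "samples", _as_float_array(self.samples))
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"LFP {self.channel_id!r} contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class BehaviorTrack:
    """Tracked position (cm) and heading (degrees, wrapped to [0, 360)).

    Sampling is nominally 5-10 samples/s from overhead video tracking; a 20%
    tolerance on the median rate is accepted so dropped frames do not reject
    otherwise valid tracks.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray

    def __post_init__(self):
        for name in ("t", "x", "y", "heading"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name)))
        n = self.t.size
        if not (self.x.size == self.y.size == self.heading.size == n):
            raise ValueError("t, x, y, heading must have equal length")
        if n >= 2:
            if np.any(np.diff(self.t) <= 0):
                raise ValueError("behavior sample times must be strictly increasing")
            fs = 1.0 / np.median(np.diff(self.t))
            if not (5.0 * 0.8 <= fs <= 10.0 * 1.2):
                raise ValueError(f"behavior sample rate {fs:.2f} Hz outside 5-10 Hz (±20%)")
        object.__setattr__(self, "heading", np.mod(self.heading, 360.0))


@dataclass
class RecordingSession:
    """One electrophysiology trial: spike trains, LFPs, optional stimulation
    pulse times and behavior, under a single experimental condition."""

    condition: str
    trains: list = field(default_factory=list)
    lfps: list = field(default_factory=list)
    stim_pulse_times: Optional[np.ndarray] = None
    behavior: Optional[BehaviorTrack] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.stim_pulse_times is not None:
            self.stim_pulse_times = _as_float_array(self.stim_pulse_times)

    def units(self, region: Optional[str] = None) -> list:
        if region is None:
            return list(self.trains)
        return [tr for tr in self.trains if tr.region == region]


# ---------------------------------------------------------------------------
# CSV spike tables
# ---------------------------------------------------------------------------

def read_spike_table(path, t_start: Optional[float] = None,
                     t_stop: Optional[float] = None) -> list:
    """Read a CSV spike table into one :class:`SpikeTrain` per unit.

    The file must have header columns ``unit_id, region, time_s``. The
    observation window defaults to the min/max time over the whole file so
    that simultaneously recorded units share a common window. Duplicate
    timestamps within one unit are collapsed to a single event with a
    warning (two detections within numerical identity cannot be two action
    potentials of one cell).
    """
    df = pd.read_csv(path)
    required = {"unit_id", "region", "time_s"}
    if not required.issubset(df.columns):
        raise ValueError(f"spike table {path} missing columns {required - set(df.columns)}")
    if df.empty:
        raise ValueError(f"spike table {path} contains no events")
    times_all = pd.to_numeric(df["time_s"], errors="raise").to_numpy(dtype=float)
    if t_start is None:
        t_start = float(times_all.min())
    if t_stop is None:
        t_stop = float(times_all.max())
    trains = []
    for unit_id, grp in df.groupby("unit_id", sort=True):
        regions = grp["region"].unique()
        if len(regions) > 1:
            raise ValueError(f"unit {unit_id!r} has inconsistent region labels {list(regions)}")
        t = np.sort(grp["time_s"].to_numpy(dtype=float))
        uniq = np.unique(t)
        if uniq.size < t.size:
            warnings.warn(
                f"unit {unit_id!r}: collapsed {t.size - uniq.size} duplicate timestamp(s)",
                stacklevel=2,
            )
        trains.append(SpikeTrain(str(unit_id), str(regions[0]), uniq, t_start, t_stop))
    return trains


def write_spike_table(trains: Sequence[SpikeTrain], path) -> None:
    """Write spike trains to the CSV table format read by :func:`read_spike_table`."""
    frames = [
        pd.DataFrame({"unit_id": tr.unit_id, "region": tr.region, "time_s": tr.times})
        for tr in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# HDF5 session container
# ---------------------------------------------------------------------------

def write_session(session: RecordingSession, path) -> None:
    """Write a :class:`RecordingSession` to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _SESSION_FORMAT_VERSION
        f.attrs["condition"] = session.condition
        for key, val in session.meta.items():
            f.attrs[f"meta_{key}"] = val
        g = f.create_group("trains")
        for tr in session.trains:
            d = g.create_dataset(tr.unit_id, data=tr.times)
            d.attrs["region"] = tr.region
            d.attrs["t_start"] = tr.t_start
            d.attrs["t_stop"] = tr.t_stop
        g = f.create_group("lfps")
        for lfp in session.lfps:
            d = g.create_dataset(lfp.channel_id, data=lfp.samples)
            d.attrs["fs"] = lfp.fs
            d.attrs["region"] = lfp.region
        if session.stim_pulse_times is not None:
            f.create_dataset("stim_pulse_times", data=session.stim_pulse_times)
        if session.behavior is not None:
            g = f.create_group("behavior")
            for name in ("t", "x", "y", "heading"):
                g.create_dataset(name, data=getattr(session.behavior, name))


def read_session(path) -> RecordingSession:
    """Read a session container written by :func:`write_session`.

    A corrupt or wrong-version file raises :class:`SessionIOError`; no
    partially populated session is ever returned.
    """
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("format_version")
            if version != _SESSION_FORMAT_VERSION:
                raise SessionIOError(
                    f"{path}: unsupported session format version {version!r}"
                )
            if "trains" not in f or "lfps" not in f:
                raise SessionIOError(f"{path}: missing required groups")
            condition = str(f.attrs["condition"])
            meta = {
                k[len("meta_"):]: _attr_to_py(v)
                for k, v in f.attrs.items() if k.startswith("meta_")
            }
            trains = [
                SpikeTrain(
                    unit_id=name,
                    region=str(d.attrs["region"]),
                    times=d[()],
                    t_start=float(d.attrs["t_start"]),
                    t_stop=float(d.attrs["t_stop"]),
                )
                for name, d in sorted(f["trains"].items())
            ]
            lfps = [
                LFPSignal(samples=d[()], fs=float(d.attrs["fs"]),
                          channel_id=name, region=str(d.attrs["region"]))
                for name, d in sorted(f["lfps"].items())
            ]
            stim = f["stim_pulse_times"][()] if "stim_pulse_times" in f else None
            behavior = None
            if "behavior" in f:
                g = f["behavior"]
                behavior = BehaviorTrack(t=g["t"][()], x=g["x"][()],
                                         y=g["y"][()], heading=g["heading"][()])
    except (OSError, KeyError) as exc:
        raise SessionIOError(f"{path}: not a readable session container ({exc})") from exc
    return RecordingSession(condition=condition, trains=trains, lfps=lfps,
                            stim_pulse_times=stim, behavior=behavior, meta=meta)


def _attr_to_py(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v
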