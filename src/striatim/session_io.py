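"""Session containers and validated on-disk I/O.

A *session* is one behavioral recording: timestamped port entries/exits,
licks, cue onsets and reward deliveries, plus the sorted spike trains of
simultaneously recorded units and (optionally) a 3-axis accelerometer trace.
All timestamps are seconds from session start.

On disk a session is a directory of plain-text tables:

* ``meta.yaml`` — session metadata (:class:`SessionMeta` fields),
* ``events.csv`` — ``timestamp_s,event_type`` with ``event_type`` one of
  ``port_entry``, ``port_exit``, ``lick``, ``cue_on``, ``reward``,
* ``spikes_<unit_id>.csv`` — one ``timestamp_s`` column per unit,
* ``accel.csv`` — ``timestamp_s,ax,ay,az`` (optional).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

EVENT_TYPES = ("port_entry", "port_exit", "lick", "cue_on", "reward")

AGE_GROUPS = ("adolescent", "adult")
TASK_VARIANTS = ("wt2.5", "wt5", "wt2.5-5")

#: Maximum allowed session length (sessions stop at 120 min).
MAX_SESSION_S = 7200.0

#: Spike timestamps closer than this are treated as duplicates of one event.
DUPLICATE_TOL_S = 1e-6


class SchemaError(Exception):
    """A required file or column is missing or malformed."""


class ValidationError(Exception):
    """Session content violates a structural invariant."""


@dataclass(frozen=True)
class SessionMeta:
    """Metadata describing one recording session.

    Parameters
    ----------
    subject_id:
        Animal identifier.
    age_group:
        ``"adolescent"`` or ``"adult"``.
    task_variant:
        ``"wt2.5"`` (2.5 s criterion), ``"wt5"`` (5 s criterion) or
        ``"wt2.5-5"`` (2.5 s criterion with a 5 s upper cutoff).
    criterion_s:
        Minimum waiting time (previous exit to next entry) for a trial to
        be eligible for reward.
    cutoff_s:
        Upper waiting-time limit (cutoff variant only); waits beyond it are
        "late" and unrewarded.
    session_index:
        1-based position of the session in the animal's training sequence.
    accel_sampling_hz:
        Accelerometer sampling rate, if an accelerometer was recorded.
    """

    subject_id: str
    age_group: str = "adult"
    task_variant: str = "wt2.5"
    criterion_s: float = 2.5
    cutoff_s: float | None = None
    session_index: int = 1
    accel_sampling_hz: float | None = None

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"age_group must be one of {AGE_GROUPS}")
        if self.task_variant not in TASK_VARIANTS:
            raise ValueError(f"task_variant must be one of {TASK_VARIANTS}")
        if self.criterion_s <= 0:
            raise ValueError("criterion_s must be positive")
        if self.cutoff_s is not None and self.cutoff_s <= self.criterion_s:
            raise ValueError("cutoff_s must exceed criterion_s")
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")


@dataclass(frozen=True)
class SessionEvents:
    """Sorted behavioral event streams (seconds from session start)."""

    port_entries: np.ndarray
    port_exits: np.ndarray
    licks: np.ndarray
    cue_onsets: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        for name in ("port_entries", "port_exits", "licks", "cue_onsets", "rewards"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit."""

    unit_id: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        if times.size:
            diffs = np.diff(times)
            if np.any(diffs < 0):
                raise ValidationError(f"unit {self.unit_id}: spike times not sorted")
            dup = diffs < DUPLICATE_TOL_S
            if np.any(dup):
                logger.warning(
                    "unit %s: collapsing %d duplicate spike times (tol %.0e s)",
                    self.unit_id, int(dup.sum()), DUPLICATE_TOL_S,
                )
                keep = np.concatenate(([True], ~dup))
                times = times[keep]
        object.__setattr__(self, "spike_times", times)


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled 3-axis accelerometer trace (device units)."""

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        for name in ("timestamps", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.timestamps)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValidationError("accelerometer axes must have equal length")

    @property
    def sampling_hz(self) -> float:
        dt = np.median(np.diff(self.timestamps))
        return 1.0 / dt


@dataclass(frozen=True)
class Session:
    """One complete session: metadata, events, spike trains, accelerometer."""

    meta: SessionMeta
    events: SessionEvents
    units: tuple[SpikeTrain, ...] = ()
    accel: AccelTrace | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))

    @property
    def t_end(self) -> float:
        """Latest timestamp in the session (events, spikes, accel)."""
        candidates = [0.0]
        for name in ("port_entries", "port_exits", "licks", "cue_onsets", "rewards"):
            arr = getattr(self.events, name)
            if arr.size:
                candidates.append(float(arr[-1]))
        for u in self.units:
            if u.spike_times.size:
                candidates.append(float(u.spike_times[-1]))
        if self.accel is not None and self.accel.timestamps.size:
            candidates.append(float(self.accel.timestamps[-1]))
        return max(candidates)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_session`."""

    field: str
    index: int
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}[{self.index}]: {self.rule}"


def _check_sorted(name: str, arr: np.ndarray, out: list[Violation]) -> None:
    bad = np.nonzero(np.diff(arr) < 0)[0]
    for i in bad:
        out.append(Violation(name, int(i) + 1, "not non-decreasing"))


def validate_session(session: Session) -> list[Violation]:
    """Check every structural invariant; return a list of violations.

    An empty list means the session is valid. Checks: each event stream is
    sorted; entries and exits strictly interleave (entry_i < exit_i <
    entry_{i+1}); every lick/cue/reward falls inside some entry–exit
    interval; all timestamps lie in ``[0, t_end]`` with ``t_end`` within the
    120-min session limit.
    """
    out: list[Violation] = []
    ev = session.events
    for name in ("port_entries", "port_exits", "licks", "cue_onsets", "rewards"):
        _check_sorted(f"events.{name}", getattr(ev, name), out)
        arr = getattr(ev, name)
        for i in np.nonzero(arr < 0)[0]:
            out.append(Violation(f"events.{name}", int(i), "negative timestamp"))

    entries, exits = ev.port_entries, ev.port_exits
    n = min(len(entries), len(exits))
    for i in range(n):
        if not entries[i] < exits[i]:
            out.append(Violation("events.port_exits", i, "exit not after its entry"))
        if i + 1 < len(entries) and not exits[i] < entries[i + 1]:
            out.append(Violation("events.port_entries", i + 1, "entry not after previous exit"))
    if len(exits) > len(entries):
        out.append(Violation("events.port_exits", len(entries), "more exits than entries"))

    # containment of in-trial events
    if n:
        starts, stops = entries[:n], exits[:n]
        for name in ("licks", "cue_onsets", "rewards"):
            arr = getattr(ev, name)
            if not arr.size:
                continue
            idx = np.searchsorted(starts, arr, side="right") - 1
            ok = (idx >= 0) & (arr <= stops[np.clip(idx, 0, n - 1)])
            for i in np.nonzero(~ok)[0]:
                out.append(Violation(f"events.{name}", int(i), "outside any entry-exit interval"))
    else:
        for name in ("licks", "cue_onsets", "rewards"):
            arr = getattr(ev, name)
            for i in range(len(arr)):
                out.append(Violation(f"events.{name}", i, "outside any entry-exit interval"))

    for u in session.units:
        _check_sorted(f"units.{u.unit_id}", u.spike_times, out)

    t_end = session.t_end
    if t_end > MAX_SESSION_S:
        out.append(Violation("session", 0, f"t_end {t_end:.1f}s exceeds {MAX_SESSION_S:.0f}s limit"))
    return out


def _require(session_valid: bool, violations: list[Violation]) -> None:
    if not session_valid:
        first = violations[0]
        raise ValidationError(str(first))


# ---------------------------------------------------------------------------
# readers / writers

_TS_FMT = "%.6f"


def write_session(session: Session, path: str | Path) -> list[Path]:
    """Write a session directory readable by :func:`read_session`.

    Timestamps are serialized with microsecond precision. Returns the list
    of files written.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    meta = session.meta
    meta_dict = {
        "subject_id": meta.subject_id,
        "age_group": meta.age_group,
        "task_variant": meta.task_variant,
        "criterion_s": float(meta.criterion_s),
        "session_index": int(meta.session_index),
    }
    if meta.cutoff_s is not None:
        meta_dict["cutoff_s"] = float(meta.cutoff_s)
    if meta.accel_sampling_hz is not None:
        meta_dict["accel_sampling_hz"] = float(meta.accel_sampling_hz)
    meta_path = path / "meta.yaml"
    meta_path.write_text(yaml.safe_dump(meta_dict, sort_keys=True), encoding="utf-8")
    written.append(meta_path)

    ev = session.events
    rows = []
    for name, etype in (
        ("port_entries", "port_entry"),
        ("port_exits", "port_exit"),
        ("licks", "lick"),
        ("cue_onsets", "cue_on"),
        ("rewards", "reward"),
    ):
        for t in getattr(ev, name):
            rows.append((float(t), etype))
    rows.sort(key=lambda r: (r[0], EVENT_TYPES.index(r[1])))
    ev_path = path / "events.csv"
    with ev_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("timestamp_s,event_type\n")
        for t, etype in rows:
            fh.write(f"{t:.6f},{etype}\n")
    written.append(ev_path)

    for unit in session.units:
        sp_path = path / f"spikes_{unit.unit_id}.csv"
        with sp_path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("timestamp_s\n")
            for t in unit.spike_times:
                fh.write(f"{t:.6f}\n")
        written.append(sp_path)

    if session.accel is not None:
        acc = session.accel
        ac_path = path / "accel.csv"
        with ac_path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("timestamp_s,ax,ay,az\n")
            for t, x, y, z in zip(acc.timestamps, acc.ax, acc.ay, acc.az):
                fh.write(f"{t:.6f},{x:.6g},{y:.6g},{z:.6g}\n")
        written.append(ac_path)
    return written


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory.

    Raises
    ------
    SchemaError
        If a required file or column is missing.
    ValidationError
        If the content violates a structural invariant (the message names
        the first offending field and index).
    """
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise SchemaError(f"missing required file: {meta_path}")
    raw = yaml.safe_load(meta_path.read_text(encoding="utf-8")) or {}
    try:
        meta = SessionMeta(
            subject_id=str(raw["subject_id"]),
            age_group=raw.get("age_group", "adult"),
            task_variant=raw.get("task_variant", "wt2.5"),
            criterion_s=float(raw.get("criterion_s", 2.5)),
            cutoff_s=(float(raw["cutoff_s"]) if raw.get("cutoff_s") is not None else None),
            session_index=int(raw.get("session_index", 1)),
            accel_sampling_hz=(
                float(raw["accel_sampling_hz"]) if raw.get("accel_sampling_hz") is not None else None
            ),
        )
    except KeyError as exc:
        raise SchemaError(f"meta.yaml missing key {exc}") from exc

    ev_path = path / "events.csv"
    if not ev_path.exists():
        raise SchemaError(f"missing required file: {ev_path}")
    df = pd.read_csv(ev_path)
    for col in ("timestamp_s", "event_type"):
        if col not in df.columns:
            raise SchemaError(f"events.csv missing column {col!r}")
    unknown = set(df["event_type"]) - set(EVENT_TYPES)
    if unknown:
        raise SchemaError(f"events.csv has unknown event types: {sorted(unknown)}")
    by_type = {
        etype: np.sort(df.loc[df["event_type"] == etype, "timestamp_s"].to_numpy(dtype=float))
        for etype in EVENT_TYPES
    }
    events = SessionEvents(
        port_entries=by_type["port_entry"],
        port_exits=by_type["port_exit"],
        licks=by_type["lick"],
        cue_onsets=by_type["cue_on"],
        rewards=by_type["reward"],
    )

    units = []
    for sp_path in sorted(path.glob("spikes_*.csv")):
        unit_id = sp_path.stem[len("spikes_"):]
        sdf = pd.read_csv(sp_path)
        if "timestamp_s" not in sdf.columns:
            raise SchemaError(f"{sp_path.name} missing column 'timestamp_s'")
        units.append(SpikeTrain(unit_id=unit_id, spike_times=sdf["timestamp_s"].to_numpy(dtype=float)))

    accel = None
    ac_path = path / "accel.csv"
    if ac_path.exists():
        adf = pd.read_csv(ac_path)
        for col in ("timestamp_s", "ax", "ay", "az"):
            if col not in adf.columns:
                raise SchemaError(f"accel.csv missing column {col!r}")
        accel = AccelTrace(
            timestamps=adf["timestamp_s"].to_numpy(dtype=float),
            ax=adf["ax"].to_numpy(dtype=float),
            ay=adf["ay"].to_numpy(dtype=float),
            az=adf["az"].to_numpy(dtype=float),
        )

    session = Session(meta=meta, events=events, units=tuple(units), accel=accel)
    violations = validate_session(session)
    if violations:
        raise ValidationError(str(violations[0]))
    return session
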