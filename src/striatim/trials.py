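"""Trial segmentation, taxonomy and behavioral metrics.

A trial is one port-entry→port-exit episode. Its *waiting time* is the
interval between the previous trial's port exit and this trial's entry —
the quantity the task conditions reward on. Each trial carries three
orthogonal labels:

* ``timing``: ``premature`` (wait below the criterion), ``timely`` (at or
  above the criterion, and at or below the cutoff when one exists) or
  ``late`` (beyond the cutoff; cutoff-task variant only),
* ``structure``: ``seq8`` if the trial contains the complete 8-lick
  sequence (>= 8 licks), else ``sub8``,
* ``outcome``: ``rewarded`` / ``unrewarded`` for timely seq8 trials
  (reward is delivered pseudo-randomly on half of them), ``none``
  otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .session_io import Session, SessionMeta

logger = logging.getLogger(__name__)

TIMING_LABELS = ("premature", "timely", "late")
STRUCTURE_LABELS = ("seq8", "sub8")
OUTCOME_LABELS = ("rewarded", "unrewarded", "none")

#: The four behavior-report trial classes: timely/premature × seq8/sub8.
TRIAL_TYPE_KEYS = ("T×8L", "T<8L", "P×8L", "P<8L")


@dataclass(frozen=True)
class Trial:
    entry_s: float
    exit_s: float
    waiting_s: float
    lick_times: np.ndarray
    timing: str
    structure: str
    outcome: str
    cue_shown: bool
    first_trial: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "lick_times", np.asarray(self.lick_times, dtype=float))

    @property
    def n_licks(self) -> int:
        return int(self.lick_times.size)


@dataclass(frozen=True)
class TrialTable:
    """Temporally ordered trials of one session."""

    trials: tuple[Trial, ...]
    meta: SessionMeta
    session_duration_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i):
        return self.trials[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry_s": [t.entry_s for t in self.trials],
                "exit_s": [t.exit_s for t in self.trials],
                "waiting_s": [t.waiting_s for t in self.trials],
                "n_licks": [t.n_licks for t in self.trials],
                "timing": [t.timing for t in self.trials],
                "structure": [t.structure for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "cue_shown": [t.cue_shown for t in self.trials],
                "first_trial": [t.first_trial for t in self.trials],
            }
        )


def classify_timing(waiting_s: float, meta: SessionMeta) -> str:
    """Label a waiting time as premature / timely / late.

    The boundary is inclusive on the timely side: a wait exactly at the
    criterion is timely, and exactly at the cutoff (cutoff variant) is
    still timely.
    """
    if waiting_s < 0:
        raise ValueError("waiting_s must be >= 0")
    if waiting_s < meta.criterion_s:
        return "premature"
    if meta.cutoff_s is not None and waiting_s > meta.cutoff_s:
        return "late"
    return "timely"


def classify_structure(n_licks: int) -> str:
    """seq8 iff the trial reaches the reward-triggering 8th lick."""
    return "seq8" if n_licks >= 8 else "sub8"


def segment_trials(session: Session) -> TrialTable:
    """Segment a session into trials and assign the full taxonomy.

    Licks, cues and rewards are assigned to a trial by containment in its
    ``[entry, exit]`` interval. The first trial's waiting time is measured
    from session start (time 0) and flagged ``first_trial``; it is excluded
    from waiting-time analyses downstream. A final entry without a matching
    exit is dropped with a warning.
    """
    ev = session.events
    entries = ev.port_entries
    exits = ev.port_exits
    n = min(len(entries), len(exits))
    if len(entries) > n:
        logger.warning("dropping %d unpaired final entry(ies)", len(entries) - n)

    trials: list[Trial] = []
    for i in range(n):
        entry, exit_ = float(entries[i]), float(exits[i])
        prev_exit = float(exits[i - 1]) if i >= 1 else 0.0
        waiting = entry - prev_exit
        in_trial = lambda arr: arr[(arr >= entry) & (arr <= exit_)]
        licks = in_trial(ev.licks)
        cues = in_trial(ev.cue_onsets)
        rewards = in_trial(ev.rewards)
        timing = classify_timing(waiting, session.meta)
        structure = classify_structure(len(licks))
        if rewards.size:
            outcome = "rewarded"
        elif timing == "timely" and structure == "seq8":
            outcome = "unrewarded"
        else:
            outcome = "none"
        trials.append(
            Trial(
                entry_s=entry,
                exit_s=exit_,
                waiting_s=waiting,
                lick_times=licks,
                timing=timing,
                structure=structure,
                outcome=outcome,
                cue_shown=bool(cues.size),
                first_trial=(i == 0),
            )
        )
    return TrialTable(trials=tuple(trials), meta=session.meta, session_duration_s=session.t_end)


@dataclass(frozen=True)
class BehavioralMetrics:
    """Per-trial timing metrics and session-level performance summaries."""

    trial_duration_s: np.ndarray
    latency_first_lick_s: np.ndarray
    seq8_duration_s: np.ndarray
    ili_cv: np.ndarray
    reward_rate_per_min: float
    premature_per_reward: float
    premature8_per_reward: float
    fraction_by_type: dict[str, float]


def _trial_type_key(trial: Trial) -> str | None:
    if trial.timing == "timely":
        return "T×8L" if trial.structure == "seq8" else "T<8L"
    if trial.timing == "premature":
        return "P×8L" if trial.structure == "seq8" else "P<8L"
    return None  # late trials (cutoff variant) fall outside the 2x2 report


def behavioral_metrics(table: TrialTable) -> BehavioralMetrics:
    """Compute the behavioral report for one session.

    Per-trial arrays are NaN where undefined (no licks, or fewer than 8
    licks for seq8 metrics). ``ili_cv`` is the coefficient of variation of
    the 7 inter-lick intervals among the first 8 licks. Reward rate is
    rewards per minute of session time. The premature/reward ratios are
    +inf when the session produced no rewards.
    """
    if not len(table):
        raise ValueError("behavioral_metrics requires at least one trial")
    dur, lat, seqd, cv = [], [], [], []
    counts = {k: 0 for k in TRIAL_TYPE_KEYS}
    n_rewards = n_premature = n_premature8 = 0
    for t in table:
        dur.append(t.exit_s - t.entry_s)
        lat.append(t.lick_times[0] - t.entry_s if t.n_licks else math.nan)
        if t.n_licks >= 8:
            first8 = t.lick_times[:8]
            seqd.append(first8[7] - first8[0])
            ilis = np.diff(first8)
            m = ilis.mean()
            cv.append(ilis.std(ddof=0) / m if m > 0 else math.nan)
        else:
            seqd.append(math.nan)
            cv.append(math.nan)
        key = _trial_type_key(t)
        if key is not None:
            counts[key] += 1
        if t.outcome == "rewarded":
            n_rewards += 1
        if t.timing == "premature":
            n_premature += 1
            if t.structure == "seq8":
                n_premature8 += 1

    total = sum(counts.values())
    fractions = {k: (counts[k] / total if total else 0.0) for k in TRIAL_TYPE_KEYS}
    minutes = table.session_duration_s / 60.0
    reward_rate = n_rewards / minutes if minutes > 0 else math.nan
    if n_rewards == 0:
        logger.warning("session has zero rewards; premature/reward ratios set to +inf")
        pr = pr8 = math.inf
    else:
        pr = n_premature / n_rewards
        pr8 = n_premature8 / n_rewards
    return BehavioralMetrics(
        trial_duration_s=np.asarray(dur),
        latency_first_lick_s=np.asarray(lat),
        seq8_duration_s=np.asarray(seqd),
        ili_cv=np.asarray(cv),
        reward_rate_per_min=reward_rate,
        premature_per_reward=pr,
        premature8_per_reward=pr8,
        fraction_by_type=fractions,
    )


def waiting_times(table: TrialTable, structure: str | None = None) -> np.ndarray:
    """Waiting times of non-first trials, optionally filtered by structure."""
    return np.asarray(
        [
            t.waiting_s
            for t in table
            if not t.first_trial and (structure is None or t.structure == structure)
        ]
    )


def waiting_histogram(
    table: TrialTable,
    bin_s: float = 0.1,
    max_wait_s: float | None = None,
    smooth: bool = False,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Peak-normalized waiting-time histograms per structure class.

    Waiting times are binned at ``bin_s`` (default 100 ms) and each curve
    is scaled so its peak bin equals 1. With ``smooth=True`` a 4-bin moving
    average is applied (display only). Returns
    ``{structure: (bin_edges, curve)}``.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    all_waits = waiting_times(table)
    if max_wait_s is None:
        max_wait_s = float(all_waits.max()) if all_waits.size else bin_s
    n_bins = max(1, int(np.ceil(max_wait_s / bin_s)))
    edges = np.arange(n_bins + 1) * bin_s
    for structure in STRUCTURE_LABELS:
        waits = waiting_times(table, structure)
        counts, _ = np.histogram(waits, bins=edges)
        curve = counts.astype(float)
        if smooth and curve.size >= 4:
            curve = np.convolve(curve, np.ones(4) / 4.0, mode="same")
        peak = curve.max()
        if peak > 0:
            curve = curve / peak
        out[structure] = (edges, curve)
    return out


def cumulative_initiation_curve(
    tables: Sequence[TrialTable],
    structure: str = "seq8",
    per_session: bool = False,
):
    """Empirical cumulative distribution of trial-initiation waiting times.

    Pools seq8 (default) waiting times across sessions and returns the
    step-function support and cumulative fractions ``(x, F)`` with ``F``
    rising from 1/n to 1. ``per_session=True`` returns one curve per table.
    """
    if per_session:
        return [cumulative_initiation_curve([t], structure) for t in tables]
    pooled = np.concatenate([waiting_times(t, structure) for t in tables]) if tables else np.array([])
    if pooled.size == 0:
        raise ValueError("no trials with requested structure")
    x = np.sort(pooled)
    frac = np.arange(1, x.size + 1) / x.size
    return x, frac


def timely_seq8_fraction(table: TrialTable) -> float:
    """Fraction of trials that are timely with a complete 8-lick sequence."""
    n = len(table)
    if n == 0:
        return 0.0
    good = sum(1 for t in table if t.timing == "timely" and t.structure == "seq8")
    return good / n


def stage_sessions(tables: Sequence[TrialTable]) -> list[str]:
    """Assign training-stage labels (early / intermediate / late) to sessions.

    Sessions are 'late' once the animal has reached a timely-seq8 fraction
    of at least 0.80 on two consecutive sessions; the second of those two
    sessions is the first late session. The same number of sessions from
    the start of training are 'early' (truncated to the sessions available
    before the late block); the rest are 'intermediate'. If the criterion
    is never met, no session is late.
    """
    fractions = [timely_seq8_fraction(t) for t in tables]
    n = len(fractions)
    late_start = None
    for i in range(1, n):
        if fractions[i - 1] >= 0.80 and fractions[i] >= 0.80:
            late_start = i
            break
    labels = ["intermediate"] * n
    if late_start is None:
        logger.warning("training criterion never met: no sessions labeled late")
        n_late = 0
    else:
        for i in range(late_start, n):
            labels[i] = "late"
        n_late = n - late_start
    n_early = min(n_late, late_start if late_start is not None else 0)
    if late_start is not None and n_late > late_start:
        logger.warning(
            "late sessions (%d) exceed preceding sessions (%d); early = all preceding",
            n_late, late_start,
        )
    for i in range(n_early):
        labels[i] = "early"
    return labels
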