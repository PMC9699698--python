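"""Rule-based classification of units into task-response categories.

Every rule is a threshold on the mean z-scored firing rate in a fixed
window around a task event, with the z score computed against the unit's
40-s port-entry-centered normalization statistics:

* port entry: mean z in (-640, -80) ms before entry > 1 SD,
* port exit: mean z in (-240, +320) ms around exit > 1 SD,
* lick: mean z in (-200, +200) ms around the first-8 licks > 1 SD,
* visual cue: mean z in (+160, +400) ms after entry > 2 SD,
* inside port: mean z in (+400, +1520) ms after entry > 1 SD,
* tonic waiting: mean z over the whole inter-trial waiting periods > 1 SD,
* outcome: mean z in (+160, +560) ms after the 8th lick must exceed the
  unit's own (-640, -160) ms pre-lick-8 activity by 0.5 SD *and* exceed
  2 SD absolute, in at least one trial-outcome condition; the subtype
  (reward / no-reward / expected no-reward responsive) follows from which
  conditions differ from the rewarded condition by more than 1.5 SD.

Entry/exit/cue/lick rules are evaluated on timely trials (the cue exists
only there); outcome rules compare timely rewarded, timely unrewarded and
premature 8-lick trials. The discrimination index (DI) is the absolute
difference of outcome-window z between timely unrewarded and premature
8-lick trials.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .peth import (
    DEFAULT_BIN_S,
    NormalizationStats,
    baseline_stats,
    compute_peth,
    window_mean_z,
    znormalize,
)
from .session_io import Session, SpikeTrain
from .trials import Trial, TrialTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassificationConfig:
    """Windows (seconds, relative to the anchor) and SD thresholds."""

    entry_window_s: tuple[float, float] = (-0.640, -0.080)
    exit_window_s: tuple[float, float] = (-0.240, 0.320)
    lick_window_s: tuple[float, float] = (-0.200, 0.200)
    cue_window_s: tuple[float, float] = (0.160, 0.400)
    inside_window_s: tuple[float, float] = (0.400, 1.520)
    outcome_window_s: tuple[float, float] = (0.160, 0.560)
    outcome_baseline_s: tuple[float, float] = (-0.640, -0.160)
    thr_main_sd: float = 1.0
    thr_cue_sd: float = 2.0
    thr_outcome_rel_sd: float = 0.5
    thr_outcome_abs_sd: float = 2.0
    thr_subtype_sd: float = 1.5
    anticipatory_amp_window_s: tuple[float, float] = (-0.640, -0.080)
    min_trials: int = 10
    bin_s: float = DEFAULT_BIN_S


@dataclass(frozen=True)
class UnitClass:
    """Category assignment of one unit (boundary trio exclusive, rest free)."""

    unit_id: str
    boundary: str = "none"        # entry_only | exit_only | both | none
    inside_port: bool = False
    tonic_wait: bool = False
    cue: bool = False
    lick: bool = False
    outcome: str = "none"         # reward_resp | noreward_resp | expected_noreward_resp | none
    di: float = math.nan
    z_entry: float = math.nan
    z_exit: float = math.nan
    z_cue: float = math.nan
    z_inside: float = math.nan
    z_lick: float = math.nan
    z_tonic: float = math.nan
    z_outcome_rewarded: float = math.nan
    z_outcome_unrewarded: float = math.nan
    z_outcome_premature: float = math.nan
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiscriminationResult:
    unit_id: str
    di: float
    z_unrewarded: float
    z_premature: float


def discrimination_index(z_unrewarded: float, z_premature: float, unit_id: str = "") -> DiscriminationResult:
    """DI = |z(timely unrewarded) - z(premature)| in the outcome window."""
    return DiscriminationResult(
        unit_id=unit_id,
        di=abs(z_unrewarded - z_premature),
        z_unrewarded=z_unrewarded,
        z_premature=z_premature,
    )


def classify_boundary(z_entry_window: float, z_exit_window: float, cfg: ClassificationConfig) -> str:
    entry_flag = z_entry_window > cfg.thr_main_sd
    exit_flag = z_exit_window > cfg.thr_main_sd
    if entry_flag and exit_flag:
        return "both"
    if entry_flag:
        return "entry_only"
    if exit_flag:
        return "exit_only"
    return "none"


def classify_outcome(
    z_after: dict[str, float],
    z_before: dict[str, float],
    cfg: ClassificationConfig,
) -> str:
    """Assign the outcome subtype from per-condition outcome-window z values.

    ``z_after``/``z_before`` map condition names (``rewarded``,
    ``unrewarded``, ``premature``) to mean z in the post/pre 8th-lick
    windows; absent conditions (too few trials) may be missing.
    """
    responsive = any(
        (z_after[c] - z_before[c] > cfg.thr_outcome_rel_sd)
        and (z_after[c] > cfg.thr_outcome_abs_sd)
        for c in z_after
    )
    if not responsive:
        return "none"
    zr = z_after.get("rewarded", math.nan)
    zu = z_after.get("unrewarded", math.nan)
    zp = z_after.get("premature", math.nan)
    thr = cfg.thr_subtype_sd
    if not math.isnan(zp) and not math.isnan(zr) and zp - zr > thr and (math.isnan(zu) or zp > zu):
        return "expected_noreward_resp"
    if not math.isnan(zu) and not math.isnan(zr):
        if ((zu - zr > thr) or (not math.isnan(zp) and zp - zr > thr)) and (math.isnan(zp) or zu >= zp):
            return "noreward_resp"
        others = [z for z in (zu, zp) if not math.isnan(z)]
        if others and all(zr - z > thr for z in others):
            return "reward_resp"
    return "none"


def _mean_rate_z(
    spikes: SpikeTrain, intervals: list[tuple[float, float]], stats: NormalizationStats
) -> float:
    """Mean z of the firing rate over arbitrary intervals (per-bin scale)."""
    zs = []
    times = spikes.spike_times
    for lo, hi in intervals:
        if hi <= lo:
            continue
        n = np.searchsorted(times, hi) - np.searchsorted(times, lo)
        rate_per_bin = n / (hi - lo) * stats.bin_s
        zs.append((rate_per_bin - stats.mean) / stats.sd)
    if not zs:
        return math.nan
    return float(np.mean(zs))


def classify_units(
    session: Session,
    table: TrialTable,
    cfg: ClassificationConfig | None = None,
) -> dict[str, UnitClass]:
    """Classify every unit of a session against the full rule set."""
    if cfg is None:
        cfg = ClassificationConfig()
    t_end = session.t_end
    trials = [t for t in table]
    timely = [t for t in trials if t.timing == "timely"]
    entry_anchors = np.array([t.entry_s for t in timely])
    exit_anchors = np.array([t.exit_s for t in timely])
    lick_anchors = np.concatenate([t.lick_times[:8] for t in timely if t.n_licks > 0]) if timely else np.array([])
    wait_intervals = [
        (trials[i - 1].exit_s, trials[i].entry_s) for i in range(1, len(trials))
    ]
    lick8 = {
        "rewarded": np.array([t.lick_times[7] for t in trials if t.outcome == "rewarded" and t.n_licks >= 8]),
        "unrewarded": np.array([t.lick_times[7] for t in trials if t.outcome == "unrewarded" and t.n_licks >= 8]),
        "premature": np.array([t.lick_times[7] for t in trials if t.timing == "premature" and t.n_licks >= 8]),
    }
    all_entries = np.array([t.entry_s for t in trials])

    out: dict[str, UnitClass] = {}
    for unit in session.units:
        notes: list[str] = []
        try:
            stats = baseline_stats(unit, all_entries, t_end, bin_s=cfg.bin_s)
        except ValueError as exc:
            out[unit.unit_id] = UnitClass(unit_id=unit.unit_id, notes=(f"no baseline: {exc}",))
            continue
        if stats.degenerate:
            out[unit.unit_id] = UnitClass(unit_id=unit.unit_id, notes=("degenerate stats (sd=0)",))
            continue

        def window_z(anchors: np.ndarray, window: tuple[float, float], sub: tuple[float, float]) -> float:
            peth = znormalize(
                compute_peth(unit, anchors, window, bin_s=cfg.bin_s, t_end=t_end), stats
            )
            return window_mean_z(peth, sub)

        enough_timely = len(timely) >= cfg.min_trials
        if not enough_timely:
            notes.append(f"only {len(timely)} timely trials: entry/exit/cue/inside/lick undetermined")
        z_entry = window_z(entry_anchors, (-1.0, 2.0), cfg.entry_window_s) if enough_timely else math.nan
        z_exit = window_z(exit_anchors, (-0.5, 0.6), cfg.exit_window_s) if enough_timely else math.nan
        z_cue = window_z(entry_anchors, (-1.0, 2.0), cfg.cue_window_s) if enough_timely else math.nan
        z_inside = window_z(entry_anchors, (-1.0, 2.0), cfg.inside_window_s) if enough_timely else math.nan
        z_lick = (
            window_z(lick_anchors, (-0.3, 0.3), cfg.lick_window_s)
            if enough_timely and lick_anchors.size >= cfg.min_trials
            else math.nan
        )
        z_tonic = (
            _mean_rate_z(unit, wait_intervals, stats)
            if len(wait_intervals) >= cfg.min_trials
            else math.nan
        )

        boundary = (
            classify_boundary(z_entry, z_exit, cfg) if enough_timely else "none"
        )
        inside_flag = (not math.isnan(z_inside)) and z_inside > cfg.thr_main_sd
        tonic_flag = (not math.isnan(z_tonic)) and z_tonic > cfg.thr_main_sd
        cue_flag = (not math.isnan(z_cue)) and z_cue > cfg.thr_cue_sd
        lick_flag = (not math.isnan(z_lick)) and z_lick > cfg.thr_main_sd

        z_after: dict[str, float] = {}
        z_before: dict[str, float] = {}
        for cond, anchors in lick8.items():
            if anchors.size < cfg.min_trials:
                notes.append(f"outcome condition {cond}: only {anchors.size} trials")
                continue
            z_after[cond] = window_z(anchors, (-1.0, 1.0), cfg.outcome_window_s)
            z_before[cond] = window_z(anchors, (-1.0, 1.0), cfg.outcome_baseline_s)
        outcome = classify_outcome(z_after, z_before, cfg) if z_after else "none"

        di = math.nan
        if "unrewarded" in z_after and "premature" in z_after:
            di = discrimination_index(z_after["unrewarded"], z_after["premature"], unit.unit_id).di

        out[unit.unit_id] = UnitClass(
            unit_id=unit.unit_id,
            boundary=boundary,
            inside_port=inside_flag,
            tonic_wait=tonic_flag,
            cue=cue_flag,
            lick=lick_flag,
            outcome=outcome,
            di=di,
            z_entry=z_entry,
            z_exit=z_exit,
            z_cue=z_cue,
            z_inside=z_inside,
            z_lick=z_lick,
            z_tonic=z_tonic,
            z_outcome_rewarded=z_after.get("rewarded", math.nan),
            z_outcome_unrewarded=z_after.get("unrewarded", math.nan),
            z_outcome_premature=z_after.get("premature", math.nan),
            notes=tuple(notes),
        )
    return out
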