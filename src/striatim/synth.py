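"""Synthetic session generator with known ground truth.

Emulates a self-initiated waiting (DRL-style) task: the animal must wait a
criterion interval (measured from the previous port exit) before entering
the port; timely entries are cued 200 ms after entry and an 8-lick sequence
is rewarded on a pseudo-random balanced half of timely 8-lick trials;
premature entries are uncued, unrewarded and implicitly reset the timer.

Waiting times are a two-component mixture: a premature component
(log-normal truncated below the criterion) and a timely component
(criterion + gamma), reproducing the premature and post-criterion peaks of
empirical waiting-time distributions.

Spike trains are inhomogeneous Poisson processes built by superposition:
a homogeneous baseline plus event-anchored Gaussian rate bumps whose
placement depends on the unit's role (port entry, port exit, inside-port,
cue, lick, outcome type, tonic-waiting). Entry-anchored bump amplitudes can
be scaled by a logistic function of the trial's waiting time,
``p1 / (1 + exp(-p2 * (w - p3)))``, which is the ground truth the
waiting-modulation analysis must recover.

The accelerometer trace is Gaussian noise with variance bursts starting a
fixed lead before each port entry (and around exits); true movement-onset
times are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .session_io import (
    AccelTrace,
    Session,
    SessionEvents,
    SessionMeta,
    SpikeTrain,
    write_session,
)

logger = logging.getLogger(__name__)

MAX_RATE_HZ = 500.0

UNIT_ROLES = (
    "entry",
    "exit",
    "both",
    "inside_port",
    "tonic_wait",
    "cue",
    "reward_resp",
    "noreward_resp",
    "expected_noreward_resp",
    "lick",
    "nonresponsive",
)


def logistic(x, p1: float, p2: float, p3: float):
    """Three-parameter logistic ``p1 / (1 + exp(-p2 * (x - p3)))``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return p1 / (1.0 + np.exp(-p2 * (x - p3)))


@dataclass(frozen=True)
class WaitMixture:
    """Waiting-time mixture: premature log-normal + (criterion + gamma)."""

    w_premature: float = 0.3
    lognorm_mu: float = 0.26   # log-seconds; median ~1.3 s premature wait
    lognorm_sigma: float = 0.45
    gamma_shape: float = 1.3
    gamma_scale: float = 1.2   # seconds beyond the criterion

    def sample(self, criterion_s: float, rng: np.random.Generator) -> float:
        if rng.random() < self.w_premature:
            for _ in range(1000):
                w = float(rng.lognormal(self.lognorm_mu, self.lognorm_sigma))
                if 0.0 < w < criterion_s:
                    return w
            return float(rng.uniform(0.0, criterion_s))
        return criterion_s + float(rng.gamma(self.gamma_shape, self.gamma_scale))


@dataclass(frozen=True)
class UnitSpec:
    """Generator specification of one unit's firing behavior."""

    unit_id: str
    role: str
    baseline_hz: float = 5.0
    bump_amp_hz: float = 20.0
    bump_center_s: float = -0.5   # offset from the role's anchor event
    exit_bump_center_s: float = 0.04  # exit-anchored bump offset for "both" units
    bump_sd_s: float = 0.15
    wait_modulation: tuple[float, float, float] | None = None
    #: auxiliary amplitude ratios for outcome roles: rate in the secondary
    #: no-reward condition relative to the primary one.
    secondary_amp_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.role not in UNIT_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.baseline_hz < 0 or self.bump_sd_s <= 0:
            raise ValueError("baseline_hz must be >= 0 and bump_sd_s > 0")


@dataclass(frozen=True)
class AccelSpec:
    """Accelerometer noise/burst model (device units).

    Quiet periods are white noise at ``noise_sd`` per axis. Movement bursts
    are two-component 3–6 Hz sinusoids of amplitude ``burst_amp`` with
    random frequencies and phases per axis — head movements live inside the
    0.25–6 Hz analysis band, unlike wide-band sensor noise.
    """

    noise_sd: float = 1.0
    burst_amp: float = 40.0
    burst_freq_hz: tuple[float, float] = (3.0, 6.0)
    burst_lead_s: float = 0.4
    burst_after_entry_s: float = 0.3
    exit_burst_span_s: tuple[float, float] = (-0.1, 0.3)


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of one synthetic session."""

    meta: SessionMeta
    n_trials: int = 300
    wait_dist: WaitMixture = field(default_factory=WaitMixture)
    p_complete_seq8: float = 0.75
    ili_mean_s: float = 0.14
    ili_cv: float = 0.15
    first_lick_latency_s: float = 0.35
    post_reward_extra_licks: int = 12
    post_noreward_extra_licks: int = 3
    dwell_after_last_lick_s: float = 0.3
    unit_specs: tuple[UnitSpec, ...] = ()
    accel: AccelSpec = field(default_factory=AccelSpec)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_complete_seq8 <= 1.0):
            raise ValueError("p_complete_seq8 must be in [0, 1]")
        if not (0.0 <= self.wait_dist.w_premature <= 1.0):
            raise ValueError("w_premature must be in [0, 1]")
        object.__setattr__(self, "unit_specs", tuple(self.unit_specs))


@dataclass
class TrialTruth:
    """Intended labels of one generated trial."""

    entry_s: float
    exit_s: float
    waiting_s: float
    n_licks: int
    timing: str
    structure: str
    outcome: str
    cue_shown: bool
    lick8_s: float | None


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    trials: list[TrialTruth] = field(default_factory=list)
    unit_specs: tuple[UnitSpec, ...] = ()
    movement_onsets_s: np.ndarray = field(default_factory=lambda: np.array([]))


def _timing_label(wait: float, meta: SessionMeta) -> str:
    if wait < meta.criterion_s:
        return "premature"
    if meta.cutoff_s is not None and wait > meta.cutoff_s:
        return "late"
    return "timely"


def simulate_behavior(cfg: SynthConfig, rng: np.random.Generator) -> tuple[SessionEvents, GroundTruth]:
    """Generate the behavioral event streams of one session.

    Trials are generated sequentially; each waiting time is drawn from the
    mixture and measured from the previous port exit, so timer-reset
    semantics hold by construction. Reward is assigned to a balanced
    shuffled half of timely seq8 trials (blocks of two; an odd remainder is
    a fair coin flip).
    """
    meta = cfg.meta
    # skeletons: (wait, completes_seq8, n_sub8_licks)
    waits = [cfg.wait_dist.sample(meta.criterion_s, rng) for _ in range(cfg.n_trials)]
    completes = rng.random(cfg.n_trials) < cfg.p_complete_seq8
    timings = [_timing_label(w, meta) for w in waits]

    # balanced pseudo-random reward assignment over timely seq8 trials
    ts8 = [i for i in range(cfg.n_trials) if timings[i] == "timely" and completes[i]]
    rewarded = np.zeros(cfg.n_trials, dtype=bool)
    for start in range(0, len(ts8) - 1, 2):
        pair = [True, False]
        rng.shuffle(pair)
        rewarded[ts8[start]] = pair[0]
        rewarded[ts8[start + 1]] = pair[1]
    if len(ts8) % 2:
        rewarded[ts8[-1]] = rng.random() < 0.5

    ili_shape = 1.0 / cfg.ili_cv**2
    ili_scale = cfg.ili_mean_s * cfg.ili_cv**2

    entries, exits, licks, cues, rewards = [], [], [], [], []
    truth = GroundTruth()
    prev_exit = 0.0
    for i in range(cfg.n_trials):
        entry = prev_exit + waits[i]
        timing = timings[i]
        cue_shown = timing == "timely"
        if cue_shown:
            cues.append(entry + 0.2)
        if completes[i]:
            extra_mean = (
                cfg.post_reward_extra_licks if rewarded[i] else cfg.post_noreward_extra_licks
            )
            n_licks = 8 + int(rng.poisson(extra_mean))
        else:
            n_licks = int(rng.integers(0, 8))
        t_lick = entry + rng.gamma(4.0, cfg.first_lick_latency_s / 4.0)
        trial_licks = []
        for _ in range(n_licks):
            trial_licks.append(t_lick)
            t_lick += rng.gamma(ili_shape, ili_scale)
        lick8 = trial_licks[7] if n_licks >= 8 else None
        if rewarded[i]:
            rewards.append(lick8)
        last_event = max([entry + (0.3 if cue_shown else 0.0)] + trial_licks)
        exit_ = last_event + rng.gamma(4.0, cfg.dwell_after_last_lick_s / 4.0)
        licks.extend(trial_licks)
        entries.append(entry)
        exits.append(exit_)
        truth.trials.append(
            TrialTruth(
                entry_s=entry,
                exit_s=exit_,
                waiting_s=waits[i],
                n_licks=n_licks,
                timing=timing,
                structure="seq8" if n_licks >= 8 else "sub8",
                outcome=(
                    "rewarded"
                    if rewarded[i]
                    else ("unrewarded" if (timing == "timely" and completes[i]) else "none")
                ),
                cue_shown=cue_shown,
                lick8_s=lick8,
            )
        )
        prev_exit = exit_

    events = SessionEvents(
        port_entries=np.asarray(entries),
        port_exits=np.asarray(exits),
        licks=np.sort(np.asarray(licks)),
        cue_onsets=np.asarray(cues),
        rewards=np.asarray(rewards),
    )
    truth.unit_specs = cfg.unit_specs
    return events, truth


def _bump_anchors(spec: UnitSpec, events: SessionEvents, truth: GroundTruth):
    """(anchor_time, amplitude_hz) pairs for every Gaussian bump of a unit."""
    pairs: list[tuple[float, float]] = []

    def entry_amp(t: TrialTruth) -> float:
        if spec.wait_modulation is None:
            return spec.bump_amp_hz
        p1, p2, p3 = spec.wait_modulation
        return spec.bump_amp_hz * float(logistic(t.waiting_s, p1, p2, p3))

    if spec.role in ("entry", "both"):
        for t in truth.trials:
            pairs.append((t.entry_s + spec.bump_center_s, entry_amp(t)))
    if spec.role in ("exit", "both"):
        exit_center = spec.exit_bump_center_s if spec.role == "both" else spec.bump_center_s
        for t in truth.trials:
            pairs.append((t.exit_s + exit_center, spec.bump_amp_hz))
    if spec.role == "inside_port":
        for t in truth.trials:
            pairs.append((t.entry_s + spec.bump_center_s, spec.bump_amp_hz))
    if spec.role == "cue":
        for c in events.cue_onsets:
            pairs.append((float(c) + spec.bump_center_s, spec.bump_amp_hz))
    if spec.role == "lick":
        # one bump per lick, first 8 licks of each trial
        lick_times = events.licks
        for t in truth.trials:
            in_trial = lick_times[(lick_times >= t.entry_s) & (lick_times <= t.exit_s)]
            for lt in in_trial[:8]:
                pairs.append((float(lt) + spec.bump_center_s, spec.bump_amp_hz))
    if spec.role in ("reward_resp", "noreward_resp", "expected_noreward_resp"):
        for t in truth.trials:
            if t.lick8_s is None:
                continue
            anchor = t.lick8_s + spec.bump_center_s
            if spec.role == "reward_resp" and t.outcome == "rewarded":
                pairs.append((anchor, spec.bump_amp_hz))
            elif spec.role == "noreward_resp":
                if t.outcome == "unrewarded":
                    pairs.append((anchor, spec.bump_amp_hz))
                elif t.timing == "premature":
                    pairs.append((anchor, spec.bump_amp_hz * spec.secondary_amp_frac))
            elif spec.role == "expected_noreward_resp":
                if t.timing == "premature":
                    pairs.append((anchor, spec.bump_amp_hz))
                elif t.outcome == "unrewarded":
                    pairs.append((anchor, spec.bump_amp_hz * spec.secondary_amp_frac))
    return pairs


def simulate_spikes(
    cfg: SynthConfig,
    events: SessionEvents,
    truth: GroundTruth,
    rng: np.random.Generator,
    t_end: float | None = None,
) -> list[SpikeTrain]:
    """Generate each unit as an inhomogeneous Poisson process.

    The rate is ``baseline + sum of Gaussian bumps``; the process is
    realized exactly by superposition: a homogeneous baseline train, one
    Poisson-count normal cloud per bump, and homogeneous segments over the
    inter-trial intervals for tonic-waiting units.
    """
    if t_end is None:
        t_end = float(events.port_exits[-1]) + 2.0 if events.port_exits.size else 10.0
    trains: list[SpikeTrain] = []
    for spec in cfg.unit_specs:
        pairs = _bump_anchors(spec, events, truth)
        # crude peak-rate check: baseline + amplitudes of bumps overlapping
        # within 2 sd of each other
        if pairs:
            centers = np.array([c for c, _ in pairs])
            amps = np.array([a for _, a in pairs])
            order = np.argsort(centers)
            centers, amps = centers[order], amps[order]
            peak = spec.baseline_hz
            j0 = 0
            run = 0.0
            for j in range(len(centers)):
                while centers[j] - centers[j0] > 2 * spec.bump_sd_s:
                    j0 += 1
                peak = max(peak, spec.baseline_hz + amps[j0 : j + 1].sum())
            if peak > MAX_RATE_HZ:
                raise ValueError(
                    f"unit {spec.unit_id}: peak rate {peak:.0f} Hz exceeds {MAX_RATE_HZ:.0f} Hz"
                )

        parts = []
        n_base = rng.poisson(spec.baseline_hz * t_end)
        parts.append(rng.uniform(0.0, t_end, size=n_base))
        for center, amp in pairs:
            if amp <= 0:
                continue
            expected = amp * spec.bump_sd_s * math.sqrt(2.0 * math.pi)
            n = rng.poisson(expected)
            if n:
                parts.append(rng.normal(center, spec.bump_sd_s, size=n))
        if spec.role == "tonic_wait":
            prev_exit = 0.0
            for t in truth.trials:
                dur = t.entry_s - prev_exit
                if dur > 0:
                    n = rng.poisson(spec.bump_amp_hz * dur)
                    if n:
                        parts.append(rng.uniform(prev_exit, t.entry_s, size=n))
                prev_exit = t.exit_s
        times = np.concatenate(parts) if parts else np.array([])
        times = np.sort(times[(times >= 0.0) & (times <= t_end)])
        if times.size > 1:  # enforce strict ordering within duplicate tolerance
            keep = np.concatenate(([True], np.diff(times) >= 1e-6))
            times = times[keep]
        trains.append(SpikeTrain(unit_id=spec.unit_id, spike_times=times))
    return trains


def simulate_accel(
    cfg: SynthConfig,
    events: SessionEvents,
    truth: GroundTruth,
    rng: np.random.Generator,
    t_end: float | None = None,
) -> AccelTrace:
    """Generate a 3-axis accelerometer trace with pre-entry variance bursts.

    Each axis is white Gaussian noise at ``noise_sd``; in burst intervals —
    from ``burst_lead_s`` before each port entry to shortly after it, and
    around each port exit — the sample SD becomes ``burst_sd``. The true
    movement onsets (``entry - burst_lead_s``) are logged in the ground
    truth.
    """
    fs = cfg.meta.accel_sampling_hz
    if fs is None:
        raise ValueError("accel_sampling_hz must be set in session metadata")
    if t_end is None:
        t_end = float(events.port_exits[-1]) + 2.0 if events.port_exits.size else 10.0
    n = int(math.ceil(t_end * fs)) + 1
    ts = np.arange(n) / fs
    spec = cfg.accel
    axes = [rng.normal(0.0, spec.noise_sd, size=n) for _ in range(3)]
    onsets = []

    def add_burst(t0: float, t1: float) -> None:
        lo = max(0, int(math.floor(t0 * fs)))
        hi = min(n, int(math.ceil(t1 * fs)))
        if hi <= lo:
            return
        seg = ts[lo:hi]
        # two incommensurate components per axis so the within-window
        # variation never collapses at a sinusoid extremum
        for ax in axes:
            comp = np.zeros_like(seg)
            for _ in range(2):
                f = rng.uniform(*spec.burst_freq_hz)
                phi = rng.uniform(0.0, 2.0 * math.pi)
                comp += np.sin(2.0 * math.pi * f * (seg - t0) + phi)
            ax[lo:hi] += spec.burst_amp / math.sqrt(2.0) * comp

    for t in truth.trials:
        onset = t.entry_s - spec.burst_lead_s
        onsets.append(onset)
        if spec.burst_amp > 0:
            add_burst(onset, t.entry_s + spec.burst_after_entry_s)
            add_burst(t.exit_s + spec.exit_burst_span_s[0], t.exit_s + spec.exit_burst_span_s[1])
    truth.movement_onsets_s = np.asarray(onsets)
    return AccelTrace(timestamps=ts, ax=axes[0], ay=axes[1], az=axes[2])


def simulate_session(
    cfg: SynthConfig,
    seed: int | np.random.Generator,
    with_accel: bool | None = None,
) -> tuple[Session, GroundTruth]:
    """Generate one full session (behavior, spikes, optional accelerometer)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events, truth = simulate_behavior(cfg, rng)
    t_end = float(events.port_exits[-1]) + 2.0 if events.port_exits.size else 10.0
    units = simulate_spikes(cfg, events, truth, rng, t_end=t_end)
    if with_accel is None:
        with_accel = cfg.meta.accel_sampling_hz is not None
    accel = simulate_accel(cfg, events, truth, rng, t_end=t_end) if with_accel else None
    session = Session(meta=cfg.meta, events=events, units=tuple(units), accel=accel)
    return session, truth


def generate_dataset(
    cfgs: Sequence[SynthConfig],
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[Session], list[GroundTruth]]:
    """Generate several sessions deterministically from one seed.

    With ``out_dir`` set, each session is written to
    ``out_dir/session_<k>/`` via :func:`striatim.session_io.write_session`
    and its trial-level ground truth to ``ground_truth.csv`` alongside.
    """
    rng = np.random.default_rng(seed)
    sessions, truths = [], []
    for k, cfg in enumerate(cfgs):
        session, truth = simulate_session(cfg, rng)
        sessions.append(session)
        truths.append(truth)
        if out_dir is not None:
            sdir = Path(out_dir) / f"session_{k:03d}"
            write_session(session, sdir)
            _write_truth(truth, sdir / "ground_truth.csv")
    return sessions, truths


def _write_truth(truth: GroundTruth, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("entry_s,exit_s,waiting_s,n_licks,timing,structure,outcome,cue_shown\n")
        for t in truth.trials:
            fh.write(
                f"{t.entry_s:.6f},{t.exit_s:.6f},{t.waiting_s:.6f},{t.n_licks},"
                f"{t.timing},{t.structure},{t.outcome},{int(t.cue_shown)}\n"
            )
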