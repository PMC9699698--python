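"""Synthetic unit populations calibrated to the classification thresholds.

The classification rules threshold the mean z-scored rate in fixed windows,
with z computed against each unit's 40-s port-entry-centered statistics.
Because a unit's own event-locked bumps inflate those statistics (they
raise both the mean and the SD of the pooled per-bin counts), the bump
amplitude that realizes a given windowed z must be solved for, not read off
a Poisson formula. This module does that calibration analytically:

* the time-averaged bump rate and its temporal variance over a typical
  trial cycle give the inflated per-bin mean and SD,
* the window-mean factor maps a bump amplitude to the mean rate elevation
  over the detection window,
* the amplitude is found by bisection so the expected windowed z lands at
  ``threshold + margin``.

For tonically waiting-active units the achievable z saturates at
``sqrt((1-p)/p)`` where ``p`` is the fraction of session time spent
waiting: when waiting dominates the cycle the unit's own elevation absorbs
the normalization statistics and no amplitude can push the waiting z past
the threshold. The builder caps the amplitude and reports the realized
expectation so callers can see when a role is structurally undetectable
under the session's timing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np


from .classify import ClassificationConfig
from .synth import SynthConfig, UnitSpec, logistic

logger = logging.getLogger(__name__)

BIN_S = 0.08
MAX_AMP_HZ = 200.0


@dataclass(frozen=True)
class CycleModel:
    """Representative trial-cycle timing used for amplitude calibration.

    The cycle runs from the previous port exit (t = 0) through the waiting
    period to entry, cue, the 8-lick sequence, and the next exit. Event
    times are the configuration's means; trial-type frequencies weight how
    often a role's bumps actually occur.
    """

    cycle_s: float
    wait_s: float
    timely_fraction: float
    seq8_fraction: float
    entry_s: float
    cue_s: float
    lick_times_s: tuple[float, ...]
    exit_s: float

    @property
    def waiting_fraction(self) -> float:
        return self.wait_s / self.cycle_s

    @classmethod
    def from_config(cls, cfg: SynthConfig) -> "CycleModel":
        wd = cfg.wait_dist
        mean_prem = math.exp(wd.lognorm_mu + 0.5 * wd.lognorm_sigma**2)
        mean_prem = min(mean_prem, 0.8 * cfg.meta.criterion_s)
        mean_timely = cfg.meta.criterion_s + wd.gamma_shape * wd.gamma_scale
        w = wd.w_premature
        mean_wait = w * mean_prem + (1 - w) * mean_timely
        entry = mean_wait
        licks = tuple(
            entry + cfg.first_lick_latency_s + k * cfg.ili_mean_s for k in range(8)
        )
        mean_extra = 0.5 * cfg.post_reward_extra_licks + 0.5 * cfg.post_noreward_extra_licks
        p8 = cfg.p_complete_seq8
        seq8_exit = licks[-1] + mean_extra * cfg.ili_mean_s + cfg.dwell_after_last_lick_s
        sub8_exit = entry + cfg.first_lick_latency_s + 3 * cfg.ili_mean_s + cfg.dwell_after_last_lick_s
        exit_ = p8 * seq8_exit + (1 - p8) * sub8_exit
        return cls(
            cycle_s=exit_,
            wait_s=mean_wait,
            timely_fraction=1 - w,
            seq8_fraction=p8,
            entry_s=entry,
            cue_s=entry + 0.2,
            lick_times_s=licks,
            exit_s=exit_,
        )


#: role -> (bump_center_s relative to its anchor event, bump_sd_s)
ROLE_GEOMETRY = {
    "entry": (-0.5, 0.15),
    "exit": (0.04, 0.15),
    "both": (-0.5, 0.15),
    "inside_port": (0.96, 0.35),
    "cue": (0.08, 0.06),
    "lick": (0.0, 0.05),
    "reward_resp": (0.36, 0.10),
    "noreward_resp": (0.36, 0.10),
    "expected_noreward_resp": (0.36, 0.10),
    "tonic_wait": (0.0, 0.15),
    "nonresponsive": (0.0, 0.15),
}


def _role_cycle_layout(role: str, cyc: CycleModel, secondary_frac: float):
    """Bump centers (cycle time), detection anchors, occurrence variants.

    Returns ``(centers, anchors, variants)`` where ``variants`` is a list of
    ``(probability_per_cycle, amplitude_fraction)`` pairs describing how
    often and how strongly the occurrence fires (e.g. a reward-responsive
    unit fires at full amplitude only on the rewarded half of timely seq8
    trials). ``anchors`` are the cycle times of the detection-window anchor
    events.
    """
    center, sd = ROLE_GEOMETRY[role]
    ts8 = cyc.timely_fraction * cyc.seq8_fraction
    if role == "entry":
        return [cyc.entry_s + center], [cyc.entry_s], [(1.0, 1.0)]
    if role == "exit":
        return [cyc.exit_s + center], [cyc.exit_s], [(1.0, 1.0)]
    if role == "both":
        return [cyc.entry_s - 0.5, cyc.exit_s + 0.04], [cyc.entry_s], [(1.0, 1.0)]
    if role == "inside_port":
        return [cyc.entry_s + center], [cyc.entry_s], [(1.0, 1.0)]
    if role == "cue":
        # detection window is entry-anchored (+160..+400 ms); cue at +200 ms
        return [cyc.cue_s + center], [cyc.entry_s], [(cyc.timely_fraction, 1.0)]
    if role == "lick":
        return (
            [t + center for t in cyc.lick_times_s],
            list(cyc.lick_times_s),
            [(cyc.seq8_fraction, 1.0)],
        )
    lick8 = cyc.lick_times_s[-1]
    if role == "reward_resp":
        return [lick8 + center], [lick8], [(0.5 * ts8, 1.0)]
    if role == "noreward_resp":
        return (
            [lick8 + center],
            [lick8],
            [(0.5 * ts8, 1.0), ((1 - cyc.timely_fraction) * cyc.seq8_fraction, secondary_frac)],
        )
    if role == "expected_noreward_resp":
        return (
            [lick8 + center],
            [lick8],
            [((1 - cyc.timely_fraction) * cyc.seq8_fraction, 1.0), (0.5 * ts8, secondary_frac)],
        )
    raise ValueError(f"role {role!r} has no bump layout")


_DETECTION_WINDOW = {
    "entry": "entry_window_s",
    "both": "entry_window_s",
    "exit": "exit_window_s",
    "inside_port": "inside_window_s",
    "cue": "cue_window_s",
    "lick": "lick_window_s",
    "reward_resp": "outcome_window_s",
    "noreward_resp": "outcome_window_s",
    "expected_noreward_resp": "outcome_window_s",
}


def expected_window_z(
    role: str,
    amp_hz: float,
    baseline_hz: float,
    cyc: CycleModel,
    cfg: ClassificationConfig,
    secondary_frac: float = 0.5,
    dt: float = 0.004,
) -> float:
    """Expected detection-window z at amplitude A.

    Works on a representative cycle: the unit-amplitude bump profile g(t)
    is laid out on a grid; its time average and temporal variance (weighted
    by occurrence probability) inflate the per-bin normalization mean and
    SD; the window factor maps A to the mean rate elevation over the
    detection window. Grid evaluation makes overlapping bumps (licks) exact.
    """
    if role == "nonresponsive":
        return 0.0
    if role == "tonic_wait":
        p = cyc.waiting_fraction
        mu = (baseline_hz + p * amp_hz) * BIN_S
        var_t = p * (1 - p) * amp_hz**2
        sigma = math.sqrt(mu + var_t * BIN_S**2)
        return (1 - p) * amp_hz * BIN_S / sigma

    _, sd = ROLE_GEOMETRY[role]
    if role == "both":
        sd = 0.15
    centers, anchors, variants = _role_cycle_layout(role, cyc, secondary_frac)
    pad = 4 * sd + 1.0
    grid = np.arange(-pad, cyc.cycle_s + pad, dt)
    g = np.zeros_like(grid)
    for c in centers:
        g += np.exp(-0.5 * ((grid - c) / sd) ** 2)
    I1 = float(np.trapezoid(g, grid))
    I2 = float(np.trapezoid(g**2, grid))
    mean_frac = sum(q * a for q, a in variants)
    sq_frac = sum(q * a**2 for q, a in variants)
    time_avg = mean_frac * I1 * amp_hz / cyc.cycle_s
    e2 = sq_frac * I2 * amp_hz**2 / cyc.cycle_s
    var_t = max(e2 - time_avg**2, 0.0)
    mu = (baseline_hz + time_avg) * BIN_S
    sigma = math.sqrt(mu + var_t * BIN_S**2)

    w0, w1 = getattr(cfg, _DETECTION_WINDOW[role])
    fs = []
    for a in anchors:
        mask = (grid >= a + w0) & (grid < a + w1)
        fs.append(float(g[mask].mean()) if mask.any() else 0.0)
    f = float(np.mean(fs))
    elevation = f * amp_hz * BIN_S   # counts/bin in the detection window
    return elevation / sigma - (time_avg * BIN_S) / sigma


def amp_for_margin(
    role: str,
    baseline_hz: float,
    cyc: CycleModel,
    cfg: ClassificationConfig,
    margin_sd: float = 1.0,
    secondary_frac: float = 0.5,
) -> float:
    """Bump amplitude whose expected detection-window z is threshold+margin.

    Bisection on the analytic expectation; capped at ``MAX_AMP_HZ`` with a
    warning when the target is unreachable (e.g. tonic units in sessions
    where waiting dominates the cycle).
    """
    thr = {
        "cue": cfg.thr_cue_sd,
    }.get(role, cfg.thr_main_sd)
    if role in ("reward_resp", "noreward_resp", "expected_noreward_resp"):
        thr = cfg.thr_outcome_abs_sd
    target = thr + margin_sd
    lo, hi = 0.0, MAX_AMP_HZ
    if expected_window_z(role, hi, baseline_hz, cyc, cfg, secondary_frac) < target:
        logger.warning(
            "role %s: expected z %.2f at amplitude cap %.0f Hz < target %.2f "
            "(structurally limited under this session timing)",
            role,
            expected_window_z(role, hi, baseline_hz, cyc, cfg, secondary_frac),
            hi,
            target,
        )
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected_window_z(role, mid, baseline_hz, cyc, cfg, secondary_frac) < target:
            lo = mid
        else:
            hi = mid
    return hi


#: category flags implied by each generator role (ground truth for
#: sensitivity/specificity); a lick unit's per-lick bumps genuinely elevate
#: the inside-port window, so it is inside-port positive by construction.
EXPECTED_FLAGS = {
    "entry": {"boundary": "entry_only"},
    "exit": {"boundary": "exit_only"},
    "both": {"boundary": "both"},
    "inside_port": {"inside_port": True, "lick": True},
    "tonic_wait": {"tonic_wait": True},
    "cue": {"cue": True},
    "lick": {"lick": True, "inside_port": True},
    "reward_resp": {"outcome": "reward_resp"},
    "noreward_resp": {"outcome": "noreward_resp"},
    "expected_noreward_resp": {"outcome": "expected_noreward_resp"},
    "nonresponsive": {},
}


def expected_flags(spec: UnitSpec) -> dict:
    """Full expected category assignment for a generated unit."""
    base = {
        "boundary": "none",
        "inside_port": False,
        "tonic_wait": False,
        "cue": False,
        "lick": False,
        "outcome": "none",
    }
    base.update(EXPECTED_FLAGS[spec.role])
    return base


def build_population(
    counts: dict[str, int],
    cfg: SynthConfig,
    margin_sd: float = 1.0,
    baseline_hz: float = 5.0,
    wait_modulation: tuple[float, float, float] | None = None,
    cls_cfg: ClassificationConfig | None = None,
) -> tuple[UnitSpec, ...]:
    """Build unit specs with amplitudes calibrated to threshold + margin.

    ``counts`` maps roles to unit numbers. Entry-role units receive
    ``wait_modulation`` when given; their base amplitude is then rescaled
    so the *timely-trial* expected z still lands on target (the logistic
    attenuates the bump at each trial's waiting time).
    """
    if cls_cfg is None:
        cls_cfg = ClassificationConfig()
    cyc = CycleModel.from_config(cfg)
    specs: list[UnitSpec] = []
    k = 0
    amp_cache: dict[str, float] = {}
    for role, n in counts.items():
        for _ in range(n):
            if role == "nonresponsive":
                amp = 0.0
            elif role in amp_cache:
                amp = amp_cache[role]
            else:
                amp = amp_cache[role] = amp_for_margin(role, baseline_hz, cyc, cls_cfg, margin_sd)
            center, sd = ROLE_GEOMETRY[role]
            wm = None
            if role == "entry" and wait_modulation is not None:
                wm = wait_modulation
                p1, p2, p3 = wait_modulation
                typical_timely = cfg.meta.criterion_s + cfg.wait_dist.gamma_shape * cfg.wait_dist.gamma_scale
                atten = float(logistic(typical_timely, p1, p2, p3))
                if atten > 1e-6:
                    amp = min(amp / atten, MAX_AMP_HZ)
            specs.append(
                UnitSpec(
                    unit_id=f"u{k:03d}_{role}",
                    role=role,
                    baseline_hz=baseline_hz,
                    bump_amp_hz=amp,
                    bump_center_s=center,
                    bump_sd_s=sd,
                    wait_modulation=wm,
                )
            )
            k += 1
    return tuple(specs)


def default_counts(n_units: int) -> dict[str, int]:
    """Role mix loosely following the reported category proportions."""
    weights = {
        "entry": 0.19,
        "exit": 0.18,
        "both": 0.12,
        "inside_port": 0.12,
        "lick": 0.08,
        "cue": 0.05,
        "reward_resp": 0.05,
        "noreward_resp": 0.05,
        "expected_noreward_resp": 0.04,
        "nonresponsive": 0.12,
    }
    counts = {r: int(round(w * n_units)) for r, w in weights.items()}
    diff = n_units - sum(counts.values())
    counts["nonresponsive"] += diff
    return counts
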