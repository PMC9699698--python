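"""Accelerometer movement-onset detection.

Pipeline: band-pass each axis 0.25–6 Hz (4th-order Butterworth, applied
forward-backward so onsets are not delayed by group delay), take the
Euclidean norm across axes, segment the norm into 10-sample windows at a
step giving 80-ms time resolution (no overlap at 125 Hz, 80% overlap at
25 Hz), and compute each window's sample standard deviation. Windows with
SD below 3.5 (device units) count as no-movement; the rest are movement.

The movement onset attributed to a port entry is the start of the
contiguous run of movement windows that leads into the entry. Onsets more
than 1.2 s before the entry are discarded (the movement is then not an
approach to the port), and only trials with waiting times under 5 s are
analyzed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .session_io import AccelTrace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AccelConfig:
    band_hz: tuple[float, float] = (0.25, 6.0)
    filter_order: int = 4
    window_samples: int = 10
    resolution_s: float = 0.08
    sd_threshold: float = 3.5
    max_lead_s: float = 1.2
    max_wait_s: float = 5.0
    #: movement runs may contain short sub-threshold dropouts: the windowed
    #: SD of a band-limited signal has ~1 effective dof per 80-ms window,
    #: so single windows inside a genuine movement dip below threshold
    max_gap_windows: int = 2


@dataclass(frozen=True)
class MovementSeries:
    """Windowed SD of the filtered acceleration norm and movement flags."""

    window_times: np.ndarray   # window center times, seconds
    window_sd: np.ndarray
    moving: np.ndarray         # window_sd >= threshold
    step_s: float
    window_span_s: float

    def window_starts(self) -> np.ndarray:
        return self.window_times - 0.5 * self.window_span_s


def preprocess(trace: AccelTrace, cfg: AccelConfig | None = None) -> MovementSeries:
    """Filter, take the norm, and compute windowed SD movement flags.

    The window step is chosen from the sampling rate so consecutive windows
    are ``resolution_s`` apart (10 samples with no overlap at 125 Hz; 80%
    overlap at 25 Hz). Raises if the sampling rate is below twice the upper
    band edge.
    """
    if cfg is None:
        cfg = AccelConfig()
    fs = trace.sampling_hz
    if fs < 2.0 * cfg.band_hz[1]:
        raise ValueError(f"sampling rate {fs:.1f} Hz below 2x upper band edge {cfg.band_hz[1]} Hz")
    sos = signal.butter(cfg.filter_order, cfg.band_hz, btype="bandpass", fs=fs, output="sos")
    filtered = [signal.sosfiltfilt(sos, a) for a in (trace.ax, trace.ay, trace.az)]
    norm = np.sqrt(sum(f**2 for f in filtered))

    step = max(1, int(round(cfg.resolution_s * fs)))
    w = cfg.window_samples
    n = norm.size
    starts = np.arange(0, n - w + 1, step)
    if starts.size == 0:
        raise ValueError("trace shorter than one window")
    # sample SD (ddof=1) per window
    windows = np.lib.stride_tricks.sliding_window_view(norm, w)[starts]
    sd = windows.std(axis=1, ddof=1)
    t0 = float(trace.timestamps[0])
    span = (w - 1) / fs
    times = t0 + starts / fs + 0.5 * span
    return MovementSeries(
        window_times=times,
        window_sd=sd,
        moving=sd >= cfg.sd_threshold,
        step_s=step / fs,
        window_span_s=span,
    )


def movement_onset_before_entry(
    series: MovementSeries,
    entry_s: float,
    waiting_s: float,
    cfg: AccelConfig | None = None,
    prev_exit_s: float | None = None,
) -> float | None:
    """Movement-onset time for one port entry, or None.

    Finds the run of movement windows leading into the entry and returns
    the onset of its first window. A run may bridge sub-threshold dropouts
    of up to ``max_gap_windows`` consecutive windows. With overlapping
    windows the movement must begin in the trailing step of the run's first
    window (an earlier start would have triggered the previous window), so
    the onset is stamped there.

    Returns None when the trial's waiting time is 5 s or more, when no
    movement window abuts the entry, when the run starts more than 1.2 s
    before the entry, or — if ``prev_exit_s`` is given — when the run
    reaches back to the previous port exit (continuous movement since the
    last trial has no initiation to time).
    """
    if cfg is None:
        cfg = AccelConfig()
    if waiting_s >= cfg.max_wait_s:
        return None
    starts = series.window_starts()
    moving = series.moving
    gap = cfg.max_gap_windows
    j = int(np.searchsorted(starts, entry_s, side="right")) - 1
    if j < 0:
        return None
    if not moving[j]:
        back = next((k for k in range(1, gap + 2) if j - k >= 0 and moving[j - k]), None)
        if back is None:
            return None
        j -= back
    while j >= 1:
        back = next((k for k in range(1, gap + 2) if j - k >= 0 and moving[j - k]), None)
        if back is None:
            break
        j -= back
    onset = float(starts[j]) + max(0.0, series.window_span_s - series.step_s)
    if entry_s - onset > cfg.max_lead_s:
        return None
    if prev_exit_s is not None and onset <= prev_exit_s + series.step_s:
        return None
    return onset


def detect_onsets(
    series: MovementSeries,
    entries_s: np.ndarray,
    waits_s: np.ndarray,
    cfg: AccelConfig | None = None,
) -> list[float | None]:
    """Vectorized convenience wrapper over all port entries of a session."""
    return [
        movement_onset_before_entry(series, float(e), float(w), cfg)
        for e, w in zip(entries_s, waits_s)
    ]
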