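"""Peri-event time histograms (PETHs) and z-score normalization.

Spike counts are binned at 80 ms in windows aligned to a behavioral event
(port entry, port exit, a given lick, ...). Each unit's normalization
statistics — per-bin mean and SD of spike counts — come from the 40-s
windows centered on port entries (20 s before and after entry), whatever
the PETH's own anchor is, so that z-scored traces from different anchors
share one scale per unit.

Bins are half-open ``[a, b)``; the anchor sits at the left edge of the bin
containing time 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .session_io import SpikeTrain

logger = logging.getLogger(__name__)

DEFAULT_BIN_S = 0.08
BASELINE_HALF_WINDOW_S = 20.0


class DegenerateUnitError(Exception):
    """The unit's normalization SD is zero (e.g. silent unit)."""


@dataclass(frozen=True)
class NormalizationStats:
    """Per-bin spike-count mean and SD over the entry-centered 40-s windows."""

    unit_id: str
    mean: float
    sd: float
    bin_s: float = DEFAULT_BIN_S
    n_windows: int = 0

    @property
    def degenerate(self) -> bool:
        return self.sd <= 0


@dataclass(frozen=True)
class PETH:
    """Event-aligned binned spike counts, optionally z-normalized.

    ``counts[i, j]`` is the number of spikes of trial ``i`` in
    ``[anchor_i + t0 + j*bin_s, anchor_i + t0 + (j+1)*bin_s)``.
    """

    unit_id: str
    anchor: str
    bin_s: float
    window: tuple[float, float]
    counts: np.ndarray
    z: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def bin_centers(self) -> np.ndarray:
        t0 = self.window[0]
        return t0 + (np.arange(self.n_bins) + 0.5) * self.bin_s

    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=0)


def compute_peth(
    spikes: SpikeTrain,
    anchor_times: np.ndarray,
    window: tuple[float, float],
    bin_s: float = DEFAULT_BIN_S,
    anchor: str = "event",
    t_end: float | None = None,
) -> PETH:
    """Bin spike counts around each anchor event.

    The number of bins is ``round((t1 - t0)/bin_s)``. Anchors whose window
    extends past the session bounds ``[0, t_end]`` are dropped with a
    warning (only when ``t_end`` is given).
    """
    anchor_times = np.asarray(anchor_times, dtype=float)
    if anchor_times.size == 0:
        raise ValueError("compute_peth requires at least one anchor")
    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_s))
    if n_bins < 1:
        raise ValueError("window shorter than one bin")

    if t_end is not None:
        ok = (anchor_times + t0 >= 0) & (anchor_times + t1 <= t_end)
        if not ok.all():
            logger.warning(
                "dropping %d/%d anchors with windows outside [0, %.1f]",
                int((~ok).sum()), anchor_times.size, t_end,
            )
        anchor_times = anchor_times[ok]
        if anchor_times.size == 0:
            raise ValueError("all anchor windows fall outside the session")

    times = spikes.spike_times
    edges = t0 + np.arange(n_bins + 1) * bin_s
    counts = np.empty((anchor_times.size, n_bins), dtype=np.int64)
    for i, a in enumerate(anchor_times):
        idx = np.searchsorted(times, a + edges, side="left")
        counts[i] = np.diff(idx)
    return PETH(
        unit_id=spikes.unit_id,
        anchor=anchor,
        bin_s=bin_s,
        window=(float(t0), float(t1)),
        counts=counts,
    )


def baseline_stats(
    spikes: SpikeTrain,
    entry_times: np.ndarray,
    t_end: float,
    bin_s: float = DEFAULT_BIN_S,
    half_window_s: float = BASELINE_HALF_WINDOW_S,
) -> NormalizationStats:
    """Per-bin count mean and SD over the ±20 s entry-centered windows.

    Entries whose 40-s window is truncated by the session bounds are
    excluded from the statistics. Raises if every window is truncated.
    A silent unit yields ``mean = sd = 0`` and is flagged degenerate by
    :attr:`NormalizationStats.degenerate`.
    """
    entry_times = np.asarray(entry_times, dtype=float)
    if entry_times.size == 0:
        raise ValueError("baseline_stats requires at least one entry")
    ok = (entry_times - half_window_s >= 0) & (entry_times + half_window_s <= t_end)
    kept = entry_times[ok]
    if kept.size == 0:
        raise ValueError("insufficient baseline: all entry windows truncated by session bounds")
    peth = compute_peth(spikes, kept, (-half_window_s, half_window_s), bin_s=bin_s)
    flat = peth.counts.ravel().astype(float)
    stats = NormalizationStats(
        unit_id=spikes.unit_id,
        mean=float(flat.mean()),
        sd=float(flat.std(ddof=0)),
        bin_s=bin_s,
        n_windows=int(kept.size),
    )
    if stats.degenerate:
        logger.warning("unit %s: degenerate baseline stats (sd = 0)", spikes.unit_id)
    return stats


def znormalize(peth: PETH, stats: NormalizationStats) -> PETH:
    """Attach the z-scored mean trace: ``z[j] = (mean_i counts[i,j] − μ)/σ``."""
    if stats.degenerate:
        raise DegenerateUnitError(f"unit {stats.unit_id}: sd = 0, excluded from normalization")
    z = (peth.mean_counts() - stats.mean) / stats.sd
    return replace(peth, z=z)


def window_mean_z(peth: PETH, window: tuple[float, float]) -> float:
    """Mean of the z trace over the bins whose centers fall in ``window``."""
    if peth.z is None:
        raise ValueError("PETH is not normalized")
    centers = peth.bin_centers()
    mask = (centers >= window[0]) & (centers <= window[1])
    if not mask.any():
        raise ValueError("window contains no bins")
    return float(peth.z[mask].mean())


def smooth_display(trace: np.ndarray, span: int = 5) -> np.ndarray:
    """Centered moving average for display; edges shrink symmetrically.

    Analysis code never calls this — it exists so plotted traces match the
    smoothing convention (5-point window) without touching the statistics.
    """
    if span % 2 == 0:
        raise ValueError("span must be odd")
    trace = np.asarray(trace, dtype=float)
    half = span // 2
    out = np.empty_like(trace)
    n = trace.size
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = trace[i - k : i + k + 1].mean()
    return out


def lick_peth(
    licks: np.ndarray,
    anchor_times: np.ndarray,
    window: tuple[float, float],
    bin_s: float = 0.01,
    session_duration_s: float | None = None,
) -> np.ndarray:
    """Z-scored lick-rate trace around the anchors (10-ms bins).

    Per-bin lick counts averaged over anchors are z-scored against the
    session-wide per-bin lick statistics (mean and SD of 10-ms-bin lick
    counts over the whole session).
    """
    licks = np.asarray(licks, dtype=float)
    if licks.size == 0:
        raise ValueError("lick_peth requires at least one lick in the session")
    dur = session_duration_s if session_duration_s is not None else float(licks[-1])
    n_sess_bins = max(1, int(np.ceil(dur / bin_s)))
    sess_counts, _ = np.histogram(licks, bins=n_sess_bins, range=(0.0, n_sess_bins * bin_s))
    mu = sess_counts.mean()
    sd = sess_counts.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate session lick statistics")
    train = SpikeTrain(unit_id="licks", spike_times=licks)
    peth = compute_peth(train, np.asarray(anchor_times, dtype=float), window, bin_s=bin_s)
    return (peth.mean_counts() - mu) / sd
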