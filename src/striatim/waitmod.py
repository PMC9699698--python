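"""Waiting-time modulation of anticipatory activity and logistic fits.

Anticipatory activity — the z-scored firing of port-entry-responsive units
in the (-640, -80) ms window before entry — is computed per waiting-time
interval and summarized as one modulation curve per group. The curve is
fitted with the three-parameter logistic

    y = p1 / (1 + exp(-p2 * (x - p3)))

where ``p2`` (1/s) sets the steepness of the transition around the midpoint
``p3`` (s) and ``p1`` the plateau. Uncertainty on ``p2`` is a 95%
profile-likelihood interval: the set of fixed ``p2*`` whose re-optimized
SSE stays below ``SSE_min * (1 + F(0.95; 1, n-3)/(n-3))``. Groups are
compared with an extra-sum-of-squares F test on a shared-p2 null model.

Two fixed waiting-interval schemes are provided, built so each interval
holds a comparable number of trials (initiations pile up just after the
criterion): a 10-interval scheme and an 11-interval scheme with finer
resolution at short waits. Trials waiting less than 450 ms are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .classify import ClassificationConfig
from .peth import baseline_stats, compute_peth, window_mean_z, znormalize
from .session_io import Session
from .synth import logistic
from .trials import Trial, TrialTable

logger = logging.getLogger(__name__)

#: Minimum waiting time (ms) for a trial to enter the neural analysis.
MIN_WAIT_MS = 450.0

#: 10-interval scheme (begin, end in ms, right-closed).
PAPER_INTERVALS_10_MS: tuple[tuple[float, float], ...] = (
    (451, 1915), (1916, 2499), (2500, 3131), (3132, 3803), (3804, 4999),
    (5000, 6084), (6085, 8421), (8422, 12621), (12622, 22013), (22014, 1710755),
)

#: 11-interval scheme with more resolution at short waiting times.
PAPER_INTERVALS_11_MS: tuple[tuple[float, float], ...] = (
    (451, 1699), (1700, 2199), (2200, 2699), (2700, 3199), (3200, 3799),
    (3800, 4999), (5000, 6084), (6085, 8421), (8422, 12621), (12622, 22013),
    (22014, 1710755),
)


@dataclass(frozen=True)
class WaitingBinScheme:
    """Ordered waiting-time intervals; ``(begin, end]`` in milliseconds."""

    intervals: tuple[tuple[float, float], ...]
    mode: str = "fixed"

    @classmethod
    def paper10(cls) -> "WaitingBinScheme":
        return cls(intervals=PAPER_INTERVALS_10_MS, mode="fixed_paper_10")

    @classmethod
    def paper11(cls) -> "WaitingBinScheme":
        return cls(intervals=PAPER_INTERVALS_11_MS, mode="fixed_paper_11")

    @classmethod
    def quantile(cls, waits_s: np.ndarray, n_bins: int = 10) -> "WaitingBinScheme":
        """Equal-count intervals built from the supplied waiting times."""
        w = np.sort(np.asarray(waits_s, dtype=float) * 1000.0)
        w = w[w > MIN_WAIT_MS]
        if w.size < n_bins:
            raise ValueError("not enough trials for the requested number of quantile bins")
        edges = np.quantile(w, np.linspace(0, 1, n_bins + 1))
        edges[0] = MIN_WAIT_MS
        edges[-1] = w[-1] + 1.0
        intervals = tuple((float(edges[i]), float(edges[i + 1])) for i in range(n_bins))
        return cls(intervals=intervals, mode="quantile")

    def edges_ms(self) -> np.ndarray:
        """Right-closed bin edges: interval i is (edges[i], edges[i+1]]."""
        begins = [b for b, _ in self.intervals]
        ends = [e for _, e in self.intervals]
        return np.asarray([begins[0] - 1.0] + ends, dtype=float)


def bin_trials_by_waiting(
    table: TrialTable, scheme: WaitingBinScheme
) -> list[list[Trial]]:
    """Assign trials to waiting-time intervals; waits <= 450 ms are dropped.

    Returns one (possibly empty) trial list per interval; the first trial
    of the session (undefined waiting reference) is never included.
    """
    edges = scheme.edges_ms()
    groups: list[list[Trial]] = [[] for _ in scheme.intervals]
    for t in table:
        if t.first_trial:
            continue
        w_ms = t.waiting_s * 1000.0
        if w_ms <= edges[0]:
            continue
        idx = int(np.searchsorted(edges, w_ms, side="left")) - 1
        if 0 <= idx < len(groups):
            groups[idx].append(t)
    return groups


@dataclass(frozen=True)
class ModulationCurve:
    """Mean anticipatory z per waiting interval."""

    x: np.ndarray            # representative (median) waiting time, s
    y: np.ndarray            # mean windowed z over units
    n_trials: np.ndarray
    group: str = ""


def anticipatory_curve(
    sessions_tables: Sequence[tuple[Session, TrialTable]],
    unit_ids_per_session: Sequence[Sequence[str]],
    scheme: WaitingBinScheme,
    cfg: ClassificationConfig | None = None,
    min_trials: int = 3,
    group: str = "",
) -> ModulationCurve:
    """Anticipatory-window z versus waiting time, pooled over units.

    For each waiting interval, every selected (entry-responsive) unit
    contributes the mean z of its entry-aligned PETH over the anticipatory
    window, computed from that interval's trials only; the curve value is
    the mean over units and the representative x is the median waiting time
    of the interval's trials pooled over sessions. Intervals with fewer
    than ``min_trials`` trials in a session contribute no unit values from
    that session; intervals with no contributions at all are dropped.
    """
    if cfg is None:
        cfg = ClassificationConfig()
    n_int = len(scheme.intervals)
    unit_vals: list[list[float]] = [[] for _ in range(n_int)]
    waits: list[list[float]] = [[] for _ in range(n_int)]

    for (session, table), unit_ids in zip(sessions_tables, unit_ids_per_session):
        groups = bin_trials_by_waiting(table, scheme)
        t_end = session.t_end
        all_entries = np.array([t.entry_s for t in table])
        units = {u.unit_id: u for u in session.units}
        stats_by_unit = {}
        for uid in unit_ids:
            stats_by_unit[uid] = baseline_stats(units[uid], all_entries, t_end, bin_s=cfg.bin_s)
        for k, trials_k in enumerate(groups):
            waits[k].extend(t.waiting_s for t in trials_k)
            if len(trials_k) < min_trials:
                if trials_k:
                    logger.debug("interval %d: only %d trials in a session, skipped", k, len(trials_k))
                continue
            anchors = np.array([t.entry_s for t in trials_k])
            for uid in unit_ids:
                st = stats_by_unit[uid]
                if st.degenerate:
                    continue
                peth = znormalize(
                    compute_peth(units[uid], anchors, (-1.0, 0.5), bin_s=cfg.bin_s, t_end=t_end),
                    stats_by_unit[uid],
                )
                unit_vals[k].append(window_mean_z(peth, cfg.anticipatory_amp_window_s))

    xs, ys, ns = [], [], []
    for k in range(n_int):
        if not unit_vals[k]:
            continue
        xs.append(float(np.median(waits[k])))
        ys.append(float(np.mean(unit_vals[k])))
        ns.append(len(waits[k]))
    return ModulationCurve(x=np.asarray(xs), y=np.asarray(ys), n_trials=np.asarray(ns), group=group)


# ---------------------------------------------------------------------------
# logistic fitting


@dataclass(frozen=True)
class LogisticFit:
    """Least-squares logistic fit with optional profile-likelihood CI on p2."""

    p1: float
    p2: float
    p3: float
    sse: float
    r2: float
    n: int
    ci_p2: tuple[float, float] | None = None
    ci_open_lower: bool = False
    ci_open_upper: bool = False

    def predict(self, x) -> np.ndarray:
        return logistic(x, self.p1, self.p2, self.p3)


class FitError(Exception):
    pass


def _sse(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((y - logistic(x, *params)) ** 2))


def _multistart_starts(x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    p1_0 = float(y.max()) if y.max() > 0 else 1.0
    half = y.min() + 0.5 * (y.max() - y.min())
    above = np.nonzero(y >= half)[0]
    p3_0 = float(x[above[0]]) if above.size else float(np.median(x))
    return [np.array([p1_0, p2_0, p3_0]) for p2_0 in (0.3, 1.0, 3.0)]


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    positive_p2: bool = True,
) -> LogisticFit:
    """Fit ``y = p1/(1+exp(-p2(x-p3)))`` by multistart least squares.

    The SSE surface is multimodal in ``p2``, so three slope starts (0.3, 1,
    3) are tried with ``p1`` initialized at max(y) and ``p3`` at the
    half-range crossing; the best SSE wins. ``p2`` is constrained positive
    by default (the neural and behavioral curves are increasing).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise FitError("need at least 4 (x, y) points")
    if np.allclose(y, y[0]):
        raise FitError("degenerate: y is constant")
    if np.allclose(x, x[0]):
        raise FitError("degenerate: x is constant")

    lo = np.array([-np.inf, 1e-9 if positive_p2 else -np.inf, -np.inf])
    hi = np.array([np.inf, np.inf, np.inf])
    best = None
    for start in _multistart_starts(x, y):
        start = np.clip(start, lo, hi)
        try:
            res = optimize.least_squares(
                lambda p: y - logistic(x, *p), start, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        raise FitError("logistic fit failed from every start")
    sse, params = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    return LogisticFit(
        p1=float(params[0]), p2=float(params[1]), p3=float(params[2]),
        sse=sse, r2=r2, n=int(x.size),
    )


def _profile_sse(p2_fixed: float, x: np.ndarray, y: np.ndarray, p1_0: float, p3_0: float) -> float:
    """SSE at fixed p2 with p1, p3 re-optimized (profile objective)."""
    def resid(q):
        return y - logistic(x, q[0], p2_fixed, q[1])

    best = math.inf
    for start in ((p1_0, p3_0), (float(y.max()) or 1.0, float(np.median(x)))):
        try:
            res = optimize.least_squares(resid, np.asarray(start, dtype=float), xtol=1e-13, ftol=1e-13)
            best = min(best, float(np.sum(res.fun**2)))
        except Exception:  # pragma: no cover
            continue
    return best


def profile_ci_p2(
    fit: LogisticFit,
    x: np.ndarray,
    y: np.ndarray,
    level: float = 0.95,
    rel_tol: float = 1e-6,
) -> LogisticFit:
    """Attach the profile-likelihood CI for p2 to a fit.

    The interval is ``{p2*: SSE(p2*) <= SSE_min * (1 + F(level; 1, n-3) /
    (n-3))}`` where ``SSE(p2*)`` re-optimizes p1 and p3. Bounds are located
    by geometric expansion followed by bisection. A side whose SSE never
    crosses the threshold within a wide search range is reported open.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n <= 3:
        raise FitError("profile CI requires n > 3")
    dfe = n - 3
    fcrit = stats.f.ppf(level, 1, dfe)
    threshold = fit.sse * (1.0 + fcrit / dfe)

    def above(p2v: float) -> bool:
        return _profile_sse(p2v, x, y, fit.p1, fit.p3) > threshold

    def bisect(inside: float, outside: float) -> float:
        for _ in range(200):
            mid = 0.5 * (inside + outside)
            if above(mid):
                outside = mid
            else:
                inside = mid
            if abs(outside - inside) <= rel_tol * max(abs(fit.p2), 1e-12):
                break
        return inside

    p2_hat = fit.p2
    # upper bound
    hi = p2_hat
    step = max(abs(p2_hat), 1e-6)
    open_upper = True
    for _ in range(60):
        cand = hi + step
        if above(cand):
            hi = bisect(hi, cand)
            open_upper = False
            break
        hi = cand
        step *= 2.0
    # lower bound
    lo = p2_hat
    open_lower = True
    cand = p2_hat
    for _ in range(60):
        cand = cand / 2.0
        if cand < 1e-12:
            break
        if above(cand):
            lo = bisect(lo, cand)
            open_lower = False
            break
        lo = cand
    if open_lower:
        lo = 0.0
    return replace(fit, ci_p2=(float(lo), float(hi)), ci_open_lower=open_lower, ci_open_upper=open_upper)


def compare_p2(
    xA: np.ndarray, yA: np.ndarray, xB: np.ndarray, yB: np.ndarray,
    positive_p2: bool = True,
) -> tuple[float, float]:
    """Extra-sum-of-squares F test for a common logistic slope p2.

    Null model: groups share p2 but have their own p1 and p3 (5
    parameters); full model: six free parameters (independent fits). F =
    ((SSE_null - SSE_full)/1) / (SSE_full/(n_total - 6)). Returns (F, p).
    """
    xA, yA = np.asarray(xA, float), np.asarray(yA, float)
    xB, yB = np.asarray(xB, float), np.asarray(yB, float)
    fitA = fit_logistic(xA, yA, positive_p2)
    fitB = fit_logistic(xB, yB, positive_p2)
    sse_full = fitA.sse + fitB.sse

    def resid(q):
        p1a, p3a, p1b, p3b, p2 = q
        return np.concatenate(
            [yA - logistic(xA, p1a, p2, p3a), yB - logistic(xB, p1b, p2, p3b)]
        )

    lo = np.array([-np.inf, -np.inf, -np.inf, -np.inf, 1e-9 if positive_p2 else -np.inf])
    hi = np.full(5, np.inf)
    best = math.inf
    for p2_0 in (fitA.p2, fitB.p2, 0.5 * (fitA.p2 + fitB.p2)):
        start = np.array([fitA.p1, fitA.p3, fitB.p1, fitB.p3, max(p2_0, 1e-6)])
        try:
            res = optimize.least_squares(resid, np.clip(start, lo, hi), bounds=(lo, hi), xtol=1e-14, ftol=1e-14)
            best = min(best, float(np.sum(res.fun**2)))
        except Exception:  # pragma: no cover
            continue
    sse_null = max(best, sse_full)
    df_full = xA.size + xB.size - 6
    if df_full <= 0:
        raise FitError("not enough points for the extra-sum-of-squares test")
    if sse_full <= 0.0:
        # noiseless data: any detectable difference is infinitely significant
        if sse_null - sse_full <= 1e-12:
            return 0.0, 1.0
        return math.inf, 0.0
    fstat = (sse_null - sse_full) / (sse_full / df_full)
    p = float(stats.f.sf(fstat, 1, df_full))
    return float(fstat), p


def behavioral_logistic(
    tables: Sequence[TrialTable],
    structure: str = "seq8",
    positive_p2: bool = True,
    with_ci: bool = True,
) -> LogisticFit:
    """Fit the logistic to the pooled cumulative initiation-time curve.

    The empirical cumulative fraction of seq8 trial initiations is
    evaluated at each trial's waiting time and fitted with the same
    logistic used for the neural curves, giving a behavioral p2 comparable
    with the neural one.
    """
    from .trials import cumulative_initiation_curve

    x, frac = cumulative_initiation_curve(tables, structure=structure)
    if x.size < 4:
        raise FitError("need at least 4 trials for the behavioral fit")
    fit = fit_logistic(x, frac, positive_p2)
    if with_ci:
        fit = profile_ci_p2(fit, x, frac)
    return fit


def p2_correlation(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, int]:
    """OLS correlation between per-subject neural and behavioral p2.

    Returns ``(r2, p, n)`` where p tests a nonzero slope.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 (neural, behavioral) p2 pairs")
    xs = np.array([a for a, _ in pairs], dtype=float)
    ys = np.array([b for _, b in pairs], dtype=float)
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2), float(res.pvalue), len(pairs)
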