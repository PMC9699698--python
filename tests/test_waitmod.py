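import dataclasses
import itertools

import numpy as np
import pytest
from scipy import optimize

from striatim.classify import classify_units
from striatim.population import build_population
from striatim.session_io import SessionMeta
from striatim.synth import SynthConfig, simulate_session, logistic
from striatim.trials import Trial, TrialTable, segment_trials
from striatim.waitmod import (
    FitError,
    WaitingBinScheme,
    anticipatory_curve,
    behavioral_logistic,
    bin_trials_by_waiting,
    compare_p2,
    fit_logistic,
    p2_correlation,
    profile_ci_p2,
)

META = SessionMeta(subject_id="w")


def _trial(wait, first=False):
    return Trial(
        entry_s=100.0, exit_s=102.0, waiting_s=wait,
        lick_times=100.3 + 0.14 * np.arange(8),
        timing="timely", structure="seq8", outcome="none", cue_shown=True,
        first_trial=first,
    )


def _table(waits):
    return TrialTable(
        trials=tuple(_trial(w, first=(i == 0)) for i, w in enumerate([1.0] + list(waits))),
        meta=META, session_duration_s=3600.0,
    )


@pytest.mark.parametrize(
    "wait_ms, expected_interval",
    [
        (2499.0, 1),    # right edge of the second interval
        (2500.0, 2),    # first ms of the third interval
        (451.0, 0),
        (400.0, None),  # below the 450 ms exclusion
        (30000.0, 9),   # the top-heavy last interval
    ],
)
def test_fixed_interval_assignment(wait_ms, expected_interval):
    scheme = WaitingBinScheme.paper10()
    groups = bin_trials_by_waiting(_table([wait_ms / 1000.0]), scheme)
    hit = [k for k, g in enumerate(groups) if g]
    assert hit == ([] if expected_interval is None else [expected_interval])


def test_paper11_has_11_intervals_starting_at_451():
    scheme = WaitingBinScheme.paper11()
    assert len(scheme.intervals) == 11
    assert scheme.intervals[0][0] == 451


def test_quantile_bins_equal_counts(rng):
    waits = rng.gamma(2.0, 1.5, size=1000) + 0.5
    scheme = WaitingBinScheme.quantile(waits, n_bins=10)
    groups = bin_trials_by_waiting(_table(waits), scheme)
    counts = [len(g) for g in groups]
    kept = np.sort(waits[waits * 1000 > 450])
    assert sum(counts) == kept.size
    assert max(counts) - min(counts) <= 1


def test_fit_logistic_exact_recovery():
    x = np.arange(0.5, 10.5, 0.5)
    y = logistic(x, 1.0, 0.5, 2.5)
    fit = fit_logistic(x, y)
    assert fit.p1 == pytest.approx(1.0, abs=1e-6)
    assert fit.p2 == pytest.approx(0.5, abs=1e-6)
    assert fit.p3 == pytest.approx(2.5, abs=1e-6)
    assert fit.sse < 1e-12


def test_fit_logistic_step_limit():
    x = np.linspace(0, 5, 30)
    y = np.where(x > 2.5, 1.0, 0.0)
    fit = fit_logistic(x, y)
    assert fit.p2 > 10
    assert fit.r2 >= 0.99


def test_fit_logistic_degenerate_and_short():
    with pytest.raises(FitError):
        fit_logistic(np.arange(4.0), np.ones(4))
    with pytest.raises(FitError):
        fit_logistic(np.arange(3.0), np.array([0.0, 0.5, 1.0]))


def test_fit_sse_beats_grid_oracle(rng):
    """Optimizer SSE never exceeds a dense grid-search oracle's best SSE."""
    x = np.linspace(0.5, 10, 12)
    for _ in range(20):
        p = (rng.uniform(0.5, 3), rng.uniform(0.3, 2), rng.uniform(1, 4))
        y = logistic(x, *p) + rng.normal(0, 0.1, x.size)
        fit = fit_logistic(x, y)
        grid_best = min(
            float(np.sum((y - logistic(x, p1, p2, p3)) ** 2))
            for p1, p2, p3 in itertools.product(
                np.linspace(0.2, 4, 24), np.linspace(0.05, 5, 40), np.linspace(0, 6, 25)
            )
        )
        assert fit.sse <= grid_best + 1e-6


def test_profile_ci_noiseless_degenerate():
    x = np.linspace(0.5, 10, 20)
    y = logistic(x, 1.0, 0.5, 2.5)
    fit = profile_ci_p2(fit_logistic(x, y), x, y)
    lo, hi = fit.ci_p2
    assert hi - lo < 1e-4
    assert lo <= fit.p2 <= hi


def test_profile_ci_contains_estimate(rng):
    x = np.linspace(0.5, 12, 11)
    for _ in range(10):
        y = logistic(x, 2.0, 0.8, 3.0) + rng.normal(0, 0.15, x.size)
        fit = profile_ci_p2(fit_logistic(x, y), x, y)
        lo, hi = fit.ci_p2
        assert lo <= fit.p2 <= hi


def test_profile_ci_width_shrinks_with_noise(rng):
    x = np.linspace(0.5, 12, 11)
    widths = []
    for sigma in (0.3, 0.05):
        y = logistic(x, 2.0, 0.8, 3.0) + rng.normal(0, sigma, x.size)
        fit = profile_ci_p2(fit_logistic(x, y), x, y)
        widths.append(fit.ci_p2[1] - fit.ci_p2[0])
    assert widths[1] < widths[0]


def test_compare_p2_identical_groups():
    x = np.linspace(0.5, 12, 11)
    y = logistic(x, 2.0, 0.7, 2.5)
    fstat, p = compare_p2(x, y, x, y.copy())
    assert fstat == pytest.approx(0.0, abs=1e-6)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_compare_p2_matches_sse_arithmetic_oracle(rng):
    """F equals the extra-sum-of-squares formula computed from independently
    minimized SSEs (scipy.optimize.minimize as the oracle optimizer)."""
    from scipy.stats import f as fdist

    x = np.linspace(0.5, 12, 11)
    ya = logistic(x, 2.0, 0.5, 2.5) + rng.normal(0, 0.05, x.size)
    yb = logistic(x, 2.2, 1.2, 2.4) + rng.normal(0, 0.05, x.size)
    fstat, p = compare_p2(x, ya, x, yb)

    def sse3(params, y):
        return float(np.sum((y - logistic(x, *params)) ** 2))

    resa = optimize.minimize(sse3, [2.0, 0.5, 2.5], args=(ya,), method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    resb = optimize.minimize(sse3, [2.2, 1.2, 2.4], args=(yb,), method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    sse_full = resa.fun + resb.fun

    def sse_null(q):
        p1a, p3a, p1b, p3b, p2 = q
        return float(
            np.sum((ya - logistic(x, p1a, p2, p3a)) ** 2)
            + np.sum((yb - logistic(x, p1b, p2, p3b)) ** 2)
        )

    resn = optimize.minimize(sse_null, [2.0, 2.5, 2.2, 2.4, 0.8], method="Nelder-Mead",
                             options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    df = 2 * x.size - 6
    f_oracle = (resn.fun - sse_full) / (sse_full / df)
    assert fstat == pytest.approx(f_oracle, rel=0.02)
    assert p == pytest.approx(float(fdist.sf(f_oracle, 1, df)), abs=1e-3)


def test_compare_p2_power(rng):
    """Groups with p2 = 0.45 vs 1.08 at sigma = 0.1 separate reliably."""
    x = np.array([1.0, 1.95, 2.45, 2.95, 3.5, 4.4, 5.5, 7.2, 10.0, 16.0, 30.0])
    hits = 0
    for _ in range(15):
        ya = logistic(x, 3.0, 0.45, 2.5) + rng.normal(0, 0.1, x.size)
        yb = logistic(x, 3.0, 1.08, 2.5) + rng.normal(0, 0.1, x.size)
        _, p = compare_p2(x, ya, x, yb)
        hits += p < 0.05
    assert hits >= 14


def test_behavioral_logistic_recovers_cdf_slope(rng):
    """Waits drawn from logistic CDFs are recovered to ~15% and ordered by
    steepness (ECDF residuals are correlated, so the recovery band is wider
    than the nominal CI)."""
    fitted = {}
    for p2_true in (1.2, 2.4):
        p3_true = 4.0
        u = rng.uniform(0.01, 0.99, 800)
        waits = p3_true + np.log(u / (1 - u)) / p2_true
        assert waits.min() > 0
        fit = behavioral_logistic([_table(waits)], with_ci=False)
        assert abs(fit.p2 - p2_true) / p2_true < 0.15
        assert fit.r2 > 0.98
        fitted[p2_true] = fit.p2
    assert fitted[2.4] > fitted[1.2]


def test_behavioral_logistic_identical_waits_degenerate():
    with pytest.raises((FitError, ValueError)):
        behavioral_logistic([_table([2.0] * 20)])


def test_p2_correlation():
    pairs = [(0.4, 0.9), (0.6, 1.3), (0.8, 1.7), (1.0, 2.1)]
    r2, p, n = p2_correlation(pairs)
    assert r2 == pytest.approx(1.0)
    assert n == 4
    with pytest.raises(ValueError):
        p2_correlation(pairs[:2])
    # closed-form Pearson oracle on a fixed fixture
    pairs = [(0.2, 0.5), (0.5, 0.4), (0.7, 1.2), (1.1, 1.0), (1.3, 1.9)]
    xs = np.array([a for a, _ in pairs])
    ys = np.array([b for _, b in pairs])
    r_oracle = np.corrcoef(xs, ys)[0, 1]
    r2, _, _ = p2_correlation(pairs)
    assert r2 == pytest.approx(r_oracle**2)


def test_anticipatory_curve_matches_brute_force(small_session, small_table):
    """Curve values equal a per-interval brute-force recomputation."""
    from striatim.peth import baseline_stats, compute_peth, window_mean_z, znormalize

    cfg, session, truth = small_session
    classes = classify_units(session, small_table)
    entry_ids = [u for u, c in classes.items() if c.boundary in ("entry_only", "both")]
    scheme = WaitingBinScheme.paper10()
    curve = anticipatory_curve([(session, small_table)], [entry_ids], scheme, min_trials=3)

    groups = bin_trials_by_waiting(small_table, scheme)
    units = {u.unit_id: u for u in session.units}
    all_entries = np.array([t.entry_s for t in small_table])
    k_out = 0
    for g in groups:
        if len(g) < 3:
            continue
        anchors = np.array([t.entry_s for t in g])
        vals = []
        for uid in entry_ids:
            stats = baseline_stats(units[uid], all_entries, session.t_end)
            peth = znormalize(
                compute_peth(units[uid], anchors, (-1.0, 0.5), t_end=session.t_end), stats
            )
            vals.append(window_mean_z(peth, (-0.640, -0.080)))
        assert curve.y[k_out] == pytest.approx(np.mean(vals))
        assert curve.x[k_out] == pytest.approx(np.median([t.waiting_s for t in g]))
        k_out += 1
    assert k_out == curve.x.size


def test_neural_modulation_recovery_end_to_end():
    """Units whose anticipatory bump follows a logistic of waiting time
    yield a fitted p2 close to the generating slope, and steeper generators
    produce steeper fits."""
    fitted = {}
    for p2_true in (0.45, 1.08):
        meta = SessionMeta(subject_id=f"g{p2_true}")
        cfg0 = SynthConfig(meta=meta, n_trials=300)
        specs = build_population({"entry": 25}, cfg0, wait_modulation=(1.0, p2_true, 2.5))
        cfg = dataclasses.replace(cfg0, unit_specs=specs)
        session, _ = simulate_session(cfg, 404, with_accel=False)
        table = segment_trials(session)
        classes = classify_units(session, table)
        ids = [u for u, c in classes.items() if c.boundary in ("entry_only", "both")]
        curve = anticipatory_curve([(session, table)], [ids], WaitingBinScheme.paper11())
        fit = fit_logistic(curve.x, curve.y)
        fitted[p2_true] = fit.p2
        assert abs(fit.p2 - p2_true) / p2_true < 0.25
    assert fitted[1.08] > fitted[0.45]
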