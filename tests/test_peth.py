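import numpy as np
import pytest

from striatim.peth import (
    DegenerateUnitError,
    baseline_stats,
    compute_peth,
    lick_peth,
    smooth_display,
    window_mean_z,
    znormalize,
)
from striatim.session_io import SpikeTrain


def brute_force_counts(spike_times, anchors, window, bin_s):
    """Independent double-loop binning oracle (half-open bins)."""
    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_s))
    out = np.zeros((len(anchors), n_bins), dtype=int)
    for i, a in enumerate(anchors):
        for s in spike_times:
            rel = s - a - t0
            j = int(np.floor(rel / bin_s))
            # careful half-open assignment at edges
            if 0 <= j < n_bins and a + t0 + j * bin_s <= s < a + t0 + (j + 1) * bin_s:
                out[i, j] += 1
    return out


def test_peth_matches_brute_force_on_random_fixtures(rng):
    """compute_peth equals the double-loop counting oracle exactly."""
    for _ in range(120):
        n_spikes = rng.integers(0, 120)
        spikes = np.sort(rng.uniform(0, 60, n_spikes))
        anchors = np.sort(rng.uniform(5, 55, rng.integers(1, 8)))
        bin_s = float(rng.choice([0.05, 0.08, 0.1]))
        half = float(rng.choice([0.4, 0.8, 1.6]))
        peth = compute_peth(SpikeTrain("u", spikes), anchors, (-half, half), bin_s=bin_s)
        oracle = brute_force_counts(spikes, anchors, (-half, half), bin_s)
        np.testing.assert_array_equal(peth.counts, oracle)
        # conservation: every spike inside the window is counted once
        in_window = sum(
            int(np.sum((spikes >= a - half) & (spikes < a + half))) for a in anchors
        )
        assert peth.counts.sum() == in_window


def test_spike_at_anchor_lands_in_center_bin():
    peth = compute_peth(SpikeTrain("u", np.array([100.0])), np.array([100.0]), (-1.0, 1.0))
    assert peth.n_bins == 25
    assert peth.counts[0, 12] == 1
    assert peth.counts.sum() == 1


def test_spike_at_bin_edge_goes_right():
    # bin edges at ...,-0.08, 0.0, 0.08,...: spike exactly at +0.08 belongs
    # to the bin starting at +0.08 (half-open convention)
    peth = compute_peth(SpikeTrain("u", np.array([10.08])), np.array([10.0]), (-0.8, 0.8))
    j = peth.counts[0].nonzero()[0]
    centers = peth.bin_centers()
    assert centers[j[0]] == pytest.approx(0.08 + 0.04)


def test_compute_peth_requires_anchor():
    with pytest.raises(ValueError):
        compute_peth(SpikeTrain("u", np.array([1.0])), np.array([]), (-1, 1))


def test_baseline_stats_poisson_rate(rng):
    """Homogeneous 10 Hz unit: per-bin mean ~ 0.8 counts within 3 SE."""
    t_end = 600.0
    n = rng.poisson(10.0 * t_end)
    spikes = np.sort(rng.uniform(0, t_end, n))
    entries = np.arange(30.0, 570.0, 45.0)
    stats = baseline_stats(SpikeTrain("u", spikes), entries, t_end)
    n_bins = stats.n_windows * 500
    se = np.sqrt(0.8 / n_bins)
    assert abs(stats.mean - 0.8) < 3 * max(se, 0.8 / np.sqrt(n))
    assert stats.sd == pytest.approx(np.sqrt(0.8), rel=0.1)


def test_baseline_stats_hand_placed_spikes():
    """Single window with counted-by-hand spikes reproduces mean and SD."""
    entries = np.array([30.0])
    spikes = np.array([10.04, 10.05, 29.99, 49.3])
    stats = baseline_stats(SpikeTrain("u", spikes), entries, t_end=60.0)
    counts = np.zeros(500)
    counts[int((10.04 - 10.0) / 0.08)] += 1
    counts[int((10.05 - 10.0) / 0.08)] += 1
    counts[int((29.99 - 10.0) / 0.08)] += 1
    counts[int((49.3 - 10.0) / 0.08)] += 1
    assert stats.mean == pytest.approx(counts.mean())
    assert stats.sd == pytest.approx(counts.std())


def test_baseline_stats_silent_unit_degenerate():
    stats = baseline_stats(SpikeTrain("u", np.array([])), np.array([30.0]), t_end=60.0)
    assert stats.mean == 0.0 and stats.sd == 0.0 and stats.degenerate


def test_baseline_stats_all_windows_truncated():
    with pytest.raises(ValueError, match="insufficient baseline"):
        baseline_stats(SpikeTrain("u", np.array([1.0])), np.array([5.0]), t_end=30.0)


def test_znormalize_arithmetic():
    from striatim.peth import NormalizationStats, PETH

    counts = np.full((4, 10), 2)
    peth = PETH(unit_id="u", anchor="e", bin_s=0.08, window=(0.0, 0.8), counts=counts)
    stats = NormalizationStats(unit_id="u", mean=0.8, sd=0.4)
    z = znormalize(peth, stats).z
    np.testing.assert_allclose(z, (2 - 0.8) / 0.4)
    stats0 = NormalizationStats(unit_id="u", mean=2.0, sd=0.5)
    np.testing.assert_allclose(znormalize(peth, stats0).z, 0.0)


def test_znormalize_degenerate_raises():
    from striatim.peth import NormalizationStats, PETH

    peth = PETH("u", "e", 0.08, (0, 0.8), np.zeros((1, 10), dtype=int))
    with pytest.raises(DegenerateUnitError):
        znormalize(peth, NormalizationStats("u", 0.0, 0.0))


def test_znormalize_stationary_unit_near_zero(rng):
    """A stationary Poisson unit z-normalizes to ~0 everywhere."""
    t_end = 2000.0
    spikes = np.sort(rng.uniform(0, t_end, rng.poisson(8.0 * t_end)))
    entries = np.arange(25.0, t_end - 25.0, 9.5)[:200]
    train = SpikeTrain("u", spikes)
    stats = baseline_stats(train, entries, t_end)
    peth = znormalize(compute_peth(train, entries, (-1.0, 1.0), t_end=t_end), stats)
    assert abs(peth.z.mean()) < 0.1


def test_window_mean_z_selects_bins():
    from striatim.peth import NormalizationStats, PETH

    counts = np.zeros((1, 25), dtype=int)
    counts[0, 12] = 4
    peth = znormalize(
        PETH("u", "e", 0.08, (-1.0, 1.0), counts), NormalizationStats("u", 0.0, 1.0)
    )
    assert window_mean_z(peth, (-0.04, 0.04)) == pytest.approx(4.0)


def test_smooth_display_properties(rng):
    x = np.full(20, 3.3)
    np.testing.assert_allclose(smooth_display(x), x)
    impulse = np.zeros(21)
    impulse[10] = 1.0
    sm = smooth_display(impulse)
    np.testing.assert_allclose(sm[8:13], 0.2)
    # interior equals centered convolution oracle
    y = rng.normal(size=50)
    sm = smooth_display(y)
    conv = np.convolve(y, np.ones(5) / 5, mode="valid")
    np.testing.assert_allclose(sm[2:-2], conv)
    with pytest.raises(ValueError):
        smooth_display(y, span=4)


def test_lick_peth_periodicity_and_oracle(rng):
    """7 Hz rhythmic licking yields a periodic z trace matching the oracle."""
    period = 1 / 7.0
    licks = np.arange(0.0, 600.0, period)
    anchors = licks[::50][5:25]
    trace = lick_peth(licks, anchors, window=(-0.5, 0.5), session_duration_s=600.0)
    # oracle: brute-force counts z-scored against session-wide stats
    sess_counts, _ = np.histogram(licks, bins=60000, range=(0, 600))
    mu, sd = sess_counts.mean(), sess_counts.std()
    oracle = brute_force_counts(licks, anchors, (-0.5, 0.5), 0.01).mean(axis=0)
    np.testing.assert_allclose(trace, (oracle - mu) / sd, atol=1e-9)
    # peaks spaced ~0.14 s apart
    peaks = np.nonzero(trace > trace.max() * 0.5)[0]
    assert np.all(np.diff(peaks) >= 13)


def test_lick_peth_no_nearby_licks_negative():
    licks = np.arange(0.0, 100.0, 0.14)
    anchors = np.array([300.0, 400.0])
    trace = lick_peth(licks, anchors, window=(-0.5, 0.5), session_duration_s=500.0)
    assert np.all(trace < 0)


def test_lick_peth_zero_licks_error():
    with pytest.raises(ValueError):
        lick_peth(np.array([]), np.array([1.0]), window=(-0.5, 0.5))
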