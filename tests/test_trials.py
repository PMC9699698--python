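import math

import numpy as np
import pytest

from striatim.session_io import Session, SessionEvents, SessionMeta
from striatim.trials import (
    Trial,
    TrialTable,
    behavioral_metrics,
    classify_timing,
    classify_structure,
    cumulative_initiation_curve,
    segment_trials,
    stage_sessions,
    waiting_histogram,
    waiting_times,
)

WT25 = SessionMeta(subject_id="s", task_variant="wt2.5", criterion_s=2.5)
CUTOFF = SessionMeta(
    subject_id="s", task_variant="wt2.5-5", criterion_s=2.5, cutoff_s=5.0
)


@pytest.mark.parametrize(
    "waiting, meta, expected",
    [
        (2.4, WT25, "premature"),
        (2.5, WT25, "timely"),        # boundary closed on the timely side
        (8.0, WT25, "timely"),        # no cutoff in the standard task
        (2.0, CUTOFF, "premature"),
        (3.0, CUTOFF, "timely"),
        (5.0, CUTOFF, "timely"),      # cutoff boundary inclusive
        (6.0, CUTOFF, "late"),
    ],
)
def test_classify_timing(waiting, meta, expected):
    assert classify_timing(waiting, meta) == expected


def test_classify_structure_eight_lick_rule():
    assert classify_structure(7) == "sub8"
    assert classify_structure(8) == "seq8"
    assert classify_structure(9) == "seq8"


def _session_from_events(**kw):
    defaults = dict(
        port_entries=np.array([]), port_exits=np.array([]), licks=np.array([]),
        cue_onsets=np.array([]), rewards=np.array([]),
    )
    defaults.update({k: np.asarray(v, dtype=float) for k, v in kw.items()})
    return Session(meta=WT25, events=SessionEvents(**defaults))


def test_segment_waiting_from_previous_exit():
    session = _session_from_events(port_entries=[10.0, 20.0], port_exits=[12.0, 22.0])
    table = segment_trials(session)
    assert table[0].first_trial and table[0].waiting_s == 10.0
    assert table[1].waiting_s == pytest.approx(8.0)


def test_segment_lick_containment_and_structure():
    licks = [10.1 + 0.1 * k for k in range(9)]
    session = _session_from_events(
        port_entries=[10.0], port_exits=[12.0], licks=licks
    )
    table = segment_trials(session)
    assert table[0].n_licks == 9
    assert table[0].structure == "seq8"


def test_segment_unpaired_final_entry_dropped():
    session = _session_from_events(port_entries=[10.0, 20.0], port_exits=[12.0])
    table = segment_trials(session)
    assert len(table) == 1


def test_segment_waits_match_diff_oracle(small_session, small_table):
    """Waiting times equal an independent diff-of-sorted-arrays oracle."""
    _, session, _ = small_session
    entries = session.events.port_entries
    exits = session.events.port_exits
    oracle = entries[1:] - exits[:-1]
    got = np.array([t.waiting_s for t in small_table])[1:]
    np.testing.assert_allclose(got, oracle, atol=1e-12)


def test_labels_match_generator_truth(small_session, small_table):
    _, _, truth = small_session
    for trial, tt in zip(small_table, truth.trials):
        assert (trial.timing, trial.structure, trial.outcome) == (
            tt.timing, tt.structure, tt.outcome,
        )
        assert trial.cue_shown == tt.cue_shown


def test_rewarded_trials_obey_task_contingency(small_table):
    for t in small_table:
        if t.outcome == "rewarded":
            assert t.timing == "timely" and t.n_licks >= 8


def _table(trials, duration, meta=WT25):
    return TrialTable(trials=tuple(trials), meta=meta, session_duration_s=duration)


def _mk_trial(entry, wait, licks, timing="timely", outcome="none", first=False):
    licks = np.asarray(licks, dtype=float)
    return Trial(
        entry_s=entry, exit_s=entry + 2.0, waiting_s=wait, lick_times=licks,
        timing=timing, structure="seq8" if licks.size >= 8 else "sub8",
        outcome=outcome, cue_shown=timing == "timely", first_trial=first,
    )


def test_behavioral_metrics_hand_computed():
    licks = [100.2 + 0.1 * k for k in range(8)]
    trials = [
        _mk_trial(100.0, 3.0, licks, outcome="rewarded", first=True),
        _mk_trial(110.0, 3.0, [], timing="premature"),
    ]
    m = behavioral_metrics(_table(trials, duration=1200.0))
    assert m.seq8_duration_s[0] == pytest.approx(0.7)
    assert m.ili_cv[0] == pytest.approx(0.0, abs=1e-9)
    assert m.latency_first_lick_s[0] == pytest.approx(0.2)
    assert math.isnan(m.latency_first_lick_s[1])
    assert m.reward_rate_per_min == pytest.approx(1 / 20.0)
    assert m.premature_per_reward == pytest.approx(1.0)
    assert sum(m.fraction_by_type.values()) == pytest.approx(1.0, abs=1e-9)


def test_behavioral_metrics_zero_rewards_inf():
    m = behavioral_metrics(_table([_mk_trial(10.0, 1.0, [], timing="premature")], 600.0))
    assert math.isinf(m.premature_per_reward)


def test_behavioral_metrics_match_per_trial_oracle(small_session, small_table):
    """Session metrics agree with an independent per-trial recomputation."""
    m = behavioral_metrics(small_table)
    n_rew = n_prem = n_prem8 = 0
    for k, t in enumerate(small_table):
        assert m.trial_duration_s[k] == pytest.approx(t.exit_s - t.entry_s)
        if t.n_licks >= 8:
            ilis = np.diff(t.lick_times[:8])
            assert m.seq8_duration_s[k] == pytest.approx(t.lick_times[7] - t.lick_times[0])
            assert m.ili_cv[k] == pytest.approx(np.std(ilis) / np.mean(ilis))
        else:
            assert math.isnan(m.seq8_duration_s[k])
        n_rew += t.outcome == "rewarded"
        n_prem += t.timing == "premature"
        n_prem8 += t.timing == "premature" and t.structure == "seq8"
    assert m.reward_rate_per_min == pytest.approx(n_rew / (small_table.session_duration_s / 60))
    assert m.premature_per_reward == pytest.approx(n_prem / n_rew)
    assert m.premature8_per_reward == pytest.approx(n_prem8 / n_rew)
    assert sum(m.fraction_by_type.values()) == pytest.approx(1.0, abs=1e-9)


def test_waiting_histogram_peak_normalized(small_table):
    hists = waiting_histogram(small_table)
    for structure in ("seq8", "sub8"):
        edges, curve = hists[structure]
        assert curve.max() == pytest.approx(1.0)
        # counts before normalization match direct histogram
        waits = waiting_times(small_table, structure)
        counts, _ = np.histogram(waits, bins=edges)
        np.testing.assert_allclose(curve * counts.max(), counts)


def test_waiting_histogram_single_bin():
    trials = [_mk_trial(10.0 * k, 1.23, [0.0] * 8, timing="premature") for k in range(1, 6)]
    hists = waiting_histogram(_table(trials, 100.0), max_wait_s=3.0)
    edges, curve = hists["seq8"]
    assert curve[12] == 1.0
    assert curve.sum() == 1.0


def test_cumulative_curve_is_ecdf(small_table):
    x, frac = cumulative_initiation_curve([small_table])
    waits = np.sort(waiting_times(small_table, "seq8"))
    np.testing.assert_allclose(x, waits)
    np.testing.assert_allclose(frac, np.arange(1, waits.size + 1) / waits.size)
    assert np.all(np.diff(frac) >= 0) and frac[-1] == pytest.approx(1.0)


def test_cumulative_curve_small_example():
    trials = [_mk_trial(10.0 * k, float(k), [0.0] * 8) for k in (1, 2, 3)]
    # mark none as first so all three waits count
    x, frac = cumulative_initiation_curve([_table(trials, 100.0)])
    np.testing.assert_allclose(frac, [1 / 3, 2 / 3, 1.0])


def _table_with_fraction(frac, n=20):
    n_good = int(round(frac * n))
    trials = [
        _mk_trial(10.0 * k, 3.0, [0.1 * j for j in range(8)])
        for k in range(n_good)
    ] + [
        _mk_trial(10.0 * (n_good + k) + 5.0, 1.0, [], timing="premature")
        for k in range(n - n_good)
    ]
    return _table(trials, 600.0)


def test_stage_sessions_rule():
    tables = [_table_with_fraction(f) for f in (0.5, 0.85, 0.9, 0.92)]
    assert stage_sessions(tables) == ["early", "early", "late", "late"]


def test_stage_sessions_never_met():
    tables = [_table_with_fraction(0.5) for _ in range(4)]
    assert stage_sessions(tables) == ["intermediate"] * 4


def test_stage_sessions_matches_scan_oracle(rng):
    """Random fraction sequences labeled identically by a direct scan."""
    for _ in range(50):
        fracs = rng.choice([0.4, 0.6, 0.85, 0.95], size=rng.integers(2, 9))
        tables = [_table_with_fraction(f) for f in fracs]
        got = stage_sessions(tables)
        # oracle: find second index of first consecutive >=0.8 pair
        late_start = None
        for i in range(1, len(fracs)):
            got_f = [len([t for t in tb if t.timing == "timely" and t.structure == "seq8"]) / len(tb) for tb in (tables[i - 1], tables[i])]
            if got_f[0] >= 0.8 and got_f[1] >= 0.8:
                late_start = i
                break
        expected = ["intermediate"] * len(fracs)
        if late_start is not None:
            for i in range(late_start, len(fracs)):
                expected[i] = "late"
            for i in range(min(len(fracs) - late_start, late_start)):
                expected[i] = "early"
        assert got == expected
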