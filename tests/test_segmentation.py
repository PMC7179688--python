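"""Bout segmentation: oracle examples, conservation, debounce behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from opariant import SessionWindow, segment_trace, bout_summary
from opariant.segmentation import WALK, PAUSE
from conftest import trace_from_mask

DT = 0.01


def make_trace(mask, **kw):
    return trace_from_mask(np.asarray(mask, dtype=bool), dt=DT, **kw)


def test_constant_position_is_one_pause_bout():
    trace = make_trace(np.zeros(500, dtype=bool))
    seg = segment_trace(trace)
    bouts = seg.bouts
    assert len(bouts) == 1
    assert bouts[0].state == PAUSE
    assert bouts[0].duration == pytest.approx(trace.duration)


def test_steady_advance_is_one_walk_bout():
    trace = make_trace(np.ones(500, dtype=bool))
    seg = segment_trace(trace, speed_threshold=1.0)
    bouts = seg.bouts
    assert len(bouts) == 1
    assert bouts[0].state == WALK
    assert bouts[0].duration == pytest.approx(trace.duration)


def test_short_stationary_blip_is_merged_into_walk():
    """2 s walk + 0.05 s blip + 2 s walk with 0.2 s debounce -> one 4.05 s
    walk bout (hand-computed merge)."""
    mask = np.concatenate([np.ones(200), np.zeros(5), np.ones(200)]) > 0
    trace = make_trace(mask)
    seg = segment_trace(trace, min_bout=0.2)
    bouts = seg.bouts
    assert len(bouts) == 1
    assert bouts[0].state == WALK
    assert bouts[0].duration == pytest.approx(4.05)


def test_short_walk_blip_is_merged_into_pause():
    mask = np.concatenate([np.zeros(200), np.ones(5), np.zeros(200)]) > 0
    seg = segment_trace(make_trace(mask), min_bout=0.2)
    assert len(seg.bouts) == 1
    assert seg.bouts[0].state == PAUSE


@given(st.lists(st.booleans(), min_size=10, max_size=300),
       st.sampled_from([0.0, 0.05, 0.2, 0.5]))
def test_partition_conservation_and_alternation(bits, min_bout):
    """Bouts are contiguous, alternating, and their durations sum exactly to
    the trace duration, whatever the debounce."""
    mask = np.array(bits, dtype=bool)
    mask[-1] = mask[-2]
    trace = make_trace(mask)
    seg = segment_trace(trace, min_bout=min_bout)
    bouts = seg.bouts
    assert bouts[0].start == 0.0
    assert bouts[-1].end == pytest.approx(trace.duration)
    for a, b in zip(bouts, bouts[1:]):
        assert a.end == pytest.approx(b.start)
        assert a.state != b.state
    assert sum(b.duration for b in bouts) == pytest.approx(trace.duration)
    # every surviving bout respects the debounce (whole-trace runs exempt)
    if len(bouts) > 1 and min_bout > 0:
        assert min(b.duration for b in bouts) >= min_bout - 1e-9


@given(st.lists(st.booleans(), min_size=10, max_size=300))
def test_segmentation_idempotent_on_clean_traces(bits):
    """Re-running the debounce on an already debounced mask changes nothing."""
    mask = np.array(bits, dtype=bool)
    mask[-1] = mask[-2]
    trace = make_trace(mask)
    first = segment_trace(trace, min_bout=0.2)
    clean = trace_from_mask(first.walk_mask, dt=DT)
    second = segment_trace(clean, min_bout=0.2)
    np.testing.assert_array_equal(first.walk_mask, second.walk_mask)


@given(st.integers(0, 2**31 - 1))
def test_total_walk_time_monotone_in_threshold(seed):
    """Raising the speed threshold never increases total walk time."""
    rng = np.random.default_rng(seed)
    n = 300
    pos = np.cumsum(rng.choice([0.0, 0.005, 0.02], size=n))
    from opariant import PositionTrace
    from conftest import five_windows
    trace = PositionTrace("f0", DT, pos, np.zeros(n, dtype=np.uint8),
                          five_windows(n))
    walks = []
    for threshold in (0.4, 1.0, 1.6, 2.5):
        seg = segment_trace(trace, speed_threshold=threshold, min_bout=0.0)
        walks.append(seg.walk_mask.sum())
    assert all(a >= b for a, b in zip(walks, walks[1:]))


def test_bout_summary_all_pause_window():
    trace = make_trace(np.zeros(500, dtype=bool))
    seg = segment_trace(trace)
    summary = bout_summary(seg, SessionWindow("Pre-test", 0, 100))
    assert summary["walk_bouts"] == 0
    assert summary["pause_duration"] == pytest.approx(1.0)


def test_bout_summary_clips_split_bouts_exactly_once():
    mask = np.concatenate([np.ones(100), np.zeros(100), np.ones(100)]) > 0
    trace = make_trace(mask)
    seg = segment_trace(trace)
    w = SessionWindow("Train1", 50, 250)  # splits both walk bouts
    summary = bout_summary(seg, w)
    assert summary["walk_duration"] + summary["pause_duration"] == \
        pytest.approx(w.n_samples * DT)
    assert summary["walk_bouts"] == 2


def test_bout_summary_alternating_seconds():
    """1 s walk / 1 s pause over 10 s -> 5 walk bouts totalling 5 s."""
    mask = np.tile(np.concatenate([np.ones(100), np.zeros(100)]), 5) > 0
    mask[-1] = mask[-2]
    trace = make_trace(mask)
    seg = segment_trace(trace, min_bout=0.2)
    summary = bout_summary(seg, SessionWindow("Train1", 0, 1000))
    assert summary["walk_bouts"] == 5
    assert summary["walk_duration"] == pytest.approx(5.0)


def test_too_short_trace_and_empty_window_rejected():
    trace = make_trace(np.zeros(100, dtype=bool))
    seg = segment_trace(trace)
    with pytest.raises(ValueError):
        bout_summary(seg, SessionWindow("Train1", 10, 10))
    from opariant import PositionTrace
    with pytest.raises(Exception):
        single = PositionTrace("f0", DT, np.array([1.0]),
                               np.array([0], dtype=np.uint8), [])
        segment_trace(single)
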