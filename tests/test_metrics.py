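"""Behavioral metrics: worked examples, counting oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from opariant import (SessionWindow, activity_difference, activity_level,
                      conditional_heat_likelihood, cumulative_active_duration,
                      exposure_differential, metrics_table, per_fly_summary,
                      segment_trace, AnalysisConfig)
from opariant.segmentation import StateSegmentation
from conftest import make_record, trace_from_mask

DT = 0.01


def seg_from_mask(mask, fly_id="f0"):
    return StateSegmentation(fly_id=fly_id, dt=DT, n_samples=len(mask),
                             walk_mask=np.asarray(mask, dtype=bool),
                             speed_threshold=1.0, min_bout=0.0)


def test_exposure_differential_worked_examples():
    """A fly heated 80% of walking time and 30% of pause time has ED 0.5;
    equal likelihoods give ED 0."""
    assert exposure_differential(0.80, 0.30) == pytest.approx(0.5)
    assert exposure_differential(0.50, 0.50) == pytest.approx(0.0)
    assert exposure_differential(1.0, 0.0) == pytest.approx(1.0)


def test_exposure_differential_domain_and_missing():
    with pytest.raises(ValueError):
        exposure_differential(1.2, 0.0)
    with pytest.raises(ValueError):
        exposure_differential(0.5, -0.1)
    assert math.isnan(exposure_differential(math.nan, 0.5))
    assert math.isnan(exposure_differential(0.5, math.nan))


def test_activity_difference_worked_example():
    """Pre-test level 70%, Test level 40% -> AD -0.3 (a number, not a %)."""
    assert activity_difference(0.40, 0.70) == pytest.approx(-0.30)
    assert activity_difference(0.55, 0.55) == 0.0
    assert activity_difference(0.0, 1.0) == -1.0
    with pytest.raises(ValueError):
        activity_difference(1.4, 0.5)


def test_conditional_heat_likelihood_counting_oracle():
    """5 s of walking with the laser on for 4 of those 5 s -> 0.8."""
    mask = np.concatenate([np.ones(500), np.zeros(500)]) > 0
    laser = np.zeros(1000, dtype=np.uint8)
    laser[100:500] = 1  # 4 s of the 5 walking seconds
    laser[700:750] = 1  # 0.5 s of the 5 pause seconds
    trace = trace_from_mask(mask, laser=laser)
    seg = seg_from_mask(mask)
    w = SessionWindow("Train1", 0, 1000)
    assert conditional_heat_likelihood(trace, seg, w, "walk") == \
        pytest.approx(0.8)
    assert conditional_heat_likelihood(trace, seg, w, "pause") == \
        pytest.approx(0.1)


def test_conditional_likelihood_missing_when_state_unoccupied():
    mask = np.ones(200, dtype=bool)  # never pauses
    trace = trace_from_mask(mask)
    seg = seg_from_mask(mask)
    w = SessionWindow("Train1", 0, 200)
    assert math.isnan(conditional_heat_likelihood(trace, seg, w, "pause"))
    assert conditional_heat_likelihood(trace, seg, w, "walk") == 0.0


def test_conditional_likelihood_rejects_mismatched_fly():
    mask = np.ones(200, dtype=bool)
    trace = trace_from_mask(mask, fly_id="a")
    seg = seg_from_mask(mask, fly_id="b")
    with pytest.raises(ValueError, match="mismatch"):
        conditional_heat_likelihood(trace, seg,
                                    SessionWindow("Train1", 0, 200), "walk")


def test_cad_examples():
    w = SessionWindow("Train1", 0, 20000)
    assert cumulative_active_duration(
        seg_from_mask(np.zeros(20000, dtype=bool)), w, 163.0) == 0.0
    assert cumulative_active_duration(
        seg_from_mask(np.ones(20000, dtype=bool)), w, 163.0) == \
        pytest.approx(163.0)
    alternating = np.tile(np.concatenate([np.ones(100), np.zeros(100)]),
                          100) > 0
    assert cumulative_active_duration(
        seg_from_mask(alternating), SessionWindow("Train1", 0, 20000),
        10.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        cumulative_active_duration(seg_from_mask(alternating), w, -1.0)


@given(st.integers(0, 2**31 - 1))
def test_cad_monotone_and_lipschitz(seed):
    """CAD never decreases with the cut and gains at most delta per delta."""
    rng = np.random.default_rng(seed)
    mask = rng.random(2000) < rng.random()
    seg = seg_from_mask(mask)
    w = SessionWindow("Train1", 0, 2000)
    cuts = np.linspace(0, 20, 41)
    values = [cumulative_active_duration(seg, w, c) for c in cuts]
    diffs = np.diff(values)
    steps = np.diff(cuts)
    assert np.all(diffs >= -1e-12)
    assert np.all(diffs <= steps + 1e-9)
    assert values[-1] <= 20.0 + 1e-12


def test_activity_level_equals_cad_over_window_length():
    rng = np.random.default_rng(8)
    mask = rng.random(1500) < 0.4
    seg = seg_from_mask(mask)
    w = SessionWindow("Test1", 200, 1400)
    level = activity_level(seg, w)
    duration = w.n_samples * DT
    assert level * duration == pytest.approx(
        cumulative_active_duration(seg, w, duration), abs=1e-12)
    assert 0.0 <= level <= 1.0


def test_activity_level_fraction_example():
    """342 s of walking in a 600 s test window is an activity level of 0.57."""
    mask = np.zeros(60000, dtype=bool)
    mask[:34200] = True
    assert activity_level(seg_from_mask(mask),
                          SessionWindow("Pre-test", 0, 60000)) == \
        pytest.approx(0.57)


def test_metrics_invariant_under_time_reorigin():
    """The same walk/laser content yields the same metrics wherever the
    window sits on the time axis."""
    content = np.tile(np.concatenate([np.ones(120), np.zeros(80)]), 5) > 0
    laser = np.tile(
        np.concatenate([np.zeros(60), np.ones(90), np.zeros(50)]), 5
    ).astype(np.uint8)
    for offset in (0, 300):
        mask = np.zeros(2000, dtype=bool)
        mask[offset:offset + 1000] = content
        las = np.zeros(2000, dtype=np.uint8)
        las[offset:offset + 1000] = laser
        mask[-1] = mask[-2]
        trace = trace_from_mask(mask, laser=las)
        seg = seg_from_mask(mask)
        w = SessionWindow("Train1", offset, offset + 1000)
        result = (activity_level(seg, w),
                  cumulative_active_duration(seg, w, 5.0),
                  conditional_heat_likelihood(trace, seg, w, "walk"))
        if offset == 0:
            reference = result
    assert result == pytest.approx(reference)


def test_state_independent_laser_gives_zero_mean_ed():
    """When heat is a Bernoulli process independent of behavior, cohort mean
    ED converges to 0."""
    rng = np.random.default_rng(123)
    eds = []
    for _ in range(300):
        mask = rng.random(3000) < 0.5
        laser = (rng.random(3000) < 0.4).astype(np.uint8)
        p_w = laser[mask].mean() if mask.any() else math.nan
        p_p = laser[~mask].mean() if (~mask).any() else math.nan
        eds.append(exposure_differential(float(p_w), float(p_p)))
    eds = np.array(eds)
    assert np.all(np.abs(eds) <= 1.0)
    assert abs(np.nanmean(eds)) < 3 * np.nanstd(eds) / np.sqrt(len(eds)) + 1e-3


def _two_fly_tables():
    mask = np.tile(np.concatenate([np.ones(150), np.zeros(150)]), 10) > 0
    n = len(mask)
    sizes = [600, 600, 600, 600, 600]
    laser = np.zeros(n, dtype=np.uint8)
    laser[600:900] = 1   # heat inside Train1 only
    heated = trace_from_mask(mask, fly_id="x_train", laser=laser, sizes=sizes)
    blank = trace_from_mask(mask, fly_id="x_blank", sizes=sizes)
    records = [make_record("x_train", "train", "x"),
               make_record("x_blank", "blank", "x")]
    return [heated, blank], records


def test_metrics_table_blank_fly_has_missing_ed():
    traces, records = _two_fly_tables()
    table = metrics_table(traces, records, AnalysisConfig())
    blank = table[table["fly_id"] == "x_blank"]
    assert blank["exposure_differential"].isna().all()
    assert blank["ed_overall"].isna().all()
    assert (blank["heat_exposure_total"] == 0).all()
    heated = table[(table["fly_id"] == "x_train")
                   & (table["session"] == "Train1")]
    assert not heated["exposure_differential"].isna().any()


def test_metrics_table_requires_records_and_sessions():
    traces, records = _two_fly_tables()
    with pytest.raises(ValueError, match="record"):
        metrics_table(traces, records[:1], AnalysisConfig())


def test_per_fly_summary_carries_ad_columns():
    traces, records = _two_fly_tables()
    table = metrics_table(traces, records, AnalysisConfig())
    per_fly = per_fly_summary(table)
    assert set(per_fly.columns) >= {"ad_test1", "ad_test2", "ed_overall",
                                    "pretest_activity", "group"}
    assert len(per_fly) == 2
    # identical masks in every session -> AD 0 for both flies
    assert per_fly["ad_test1"].abs().max() == pytest.approx(0.0)
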