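"""Per-fly behavioral statistics.

All quantities reduce to sample counting over the walk/pause mask and the
laser channel:

* activity level — fraction of a session spent walking;
* CAD — cumulative active (walk) duration from session start up to a cut,
  compared across flies at a common cut (the cohort-minimum Train length);
* P(heated|state) — fraction of the time spent in a state during which the
  laser was on; undefined (``NaN``) when the state is never occupied;
* ED (exposure differential) — P(heated|walking) − P(heated|pause), the
  contingency of heat on walking; NaN propagates;
* AD (activity difference) — a Test session's activity level minus the
  Pre-test activity level, reported as a plain number in [−1, 1].

Never-heated (blank) flies get NaN EDs: their conditionals are degenerate and
the contingency analyses concern heated flies only.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, TRAIN_SESSIONS, TEST_SESSIONS, SESSION_ORDER
from .segmentation import StateSegmentation, segment_trace
from .trace import FlyRecord, PositionTrace, SessionWindow


def _check_pair(trace: PositionTrace, seg: StateSegmentation) -> None:
    if trace.fly_id != seg.fly_id:
        raise ValueError(
            f"trace/segmentation fly_id mismatch: "
            f"{trace.fly_id!r} vs {seg.fly_id!r}")
    if trace.n_samples != seg.n_samples:
        raise ValueError("trace/segmentation length mismatch")


def conditional_heat_likelihood(trace: PositionTrace, seg: StateSegmentation,
                                window: SessionWindow, state: str) -> float:
    """P(heated | behavioral state) within a window; NaN if never in state."""
    _check_pair(trace, seg)
    if state not in ("walk", "pause"):
        raise ValueError("state must be 'walk' or 'pause'")
    sl = slice(window.start, window.stop)
    in_state = seg.walk_mask[sl] if state == "walk" else ~seg.walk_mask[sl]
    occupancy = int(in_state.sum())
    if occupancy == 0:
        return math.nan
    heated = int(trace.laser_on[sl][in_state].sum())
    return heated / occupancy


def exposure_differential(p_heat_walk: float, p_heat_pause: float) -> float:
    """ED = P(heated|walking) − P(heated|pause); NaN propagates."""
    if math.isnan(p_heat_walk) or math.isnan(p_heat_pause):
        return math.nan
    for name, value in (("p_heat_walk", p_heat_walk),
                        ("p_heat_pause", p_heat_pause)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name}={value} outside [0, 1]")
    return p_heat_walk - p_heat_pause


def cumulative_active_duration(seg: StateSegmentation, window: SessionWindow,
                               cut: float) -> float:
    """Walk time accumulated in ``[window start, window start + cut)``."""
    if cut < 0:
        raise ValueError("cut must be non-negative")
    stop = min(window.stop, window.start + int(round(cut / seg.dt)))
    return float(seg.walk_mask[window.start:stop].sum()) * seg.dt


def cad_curve(seg: StateSegmentation, window: SessionWindow) -> np.ndarray:
    """Full CAD step function over a window (one value per sample)."""
    return np.cumsum(seg.walk_mask[window.start:window.stop]) * seg.dt


def activity_level(seg: StateSegmentation, window: SessionWindow) -> float:
    """Fraction of the window spent walking."""
    n = window.n_samples
    if n <= 0:
        raise ValueError("window length must be positive")
    return float(seg.walk_mask[window.start:window.stop].sum()) / n


def activity_difference(level_test: float, level_pretest: float) -> float:
    """AD = test activity level − Pre-test activity level, in [−1, 1]."""
    for name, value in (("level_test", level_test),
                        ("level_pretest", level_pretest)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name}={value} outside [0, 1]")
    return level_test - level_pretest


def _pooled_conditional(trace, seg, windows, state) -> float:
    occ = heated = 0
    for w in windows:
        sl = slice(w.start, w.stop)
        in_state = seg.walk_mask[sl] if state == "walk" else ~seg.walk_mask[sl]
        occ += int(in_state.sum())
        heated += int(trace.laser_on[sl][in_state].sum())
    return heated / occ if occ else math.nan


def common_train_cut(traces: Iterable[PositionTrace],
                     cfg: AnalysisConfig) -> float:
    """The common cut: configured value, or the cohort-minimum Train length."""
    if cfg.common_train_cut is not None:
        return cfg.common_train_cut
    lengths = [t.window(s).duration(t.dt)
               for t in traces for s in TRAIN_SESSIONS]
    if not lengths:
        raise ValueError("no traces given")
    return min(lengths)


def metrics_table(traces: Iterable[PositionTrace],
                  records: Iterable[FlyRecord],
                  cfg: Optional[AnalysisConfig] = None,
                  segs: Optional[Mapping[str, StateSegmentation]] = None,
                  ) -> pd.DataFrame:
    """One row per fly per session, plus per-fly AD and whole-experiment ED.

    Train-session CAD is evaluated at the common cut (see
    :func:`common_train_cut`); ``total_heat_exposure`` sums laser time over
    both Train sessions; ``ed_overall`` pools occupancy and heat time across
    both Train sessions before dividing.  Output includes ``group`` and
    ``triplet_id`` from the attribute records.
    """
    cfg = cfg or AnalysisConfig()
    traces = list(traces)
    by_id = {r.fly_id: r for r in records}
    for t in traces:
        if t.fly_id not in by_id:
            raise ValueError(f"no attribute record for fly {t.fly_id}")
        missing = [s for s in SESSION_ORDER
                   if s not in [w.label for w in t.sessions]]
        if missing:
            raise ValueError(f"fly {t.fly_id} lacks sessions {missing}")
    if segs is None:
        segs = {t.fly_id: segment_trace(t, cfg.speed_threshold, cfg.min_bout)
                for t in traces}
    cut = common_train_cut(traces, cfg)

    rows = []
    for t in traces:
        seg = segs[t.fly_id]
        _check_pair(t, seg)
        rec = by_id[t.fly_id]
        pre_level = activity_level(seg, t.window("Pre-test"))
        train_windows = [t.window(s) for s in TRAIN_SESSIONS]
        heat_total = sum(float(t.laser_on[w.start:w.stop].sum()) * t.dt
                         for w in train_windows)
        p_walk_all = _pooled_conditional(t, seg, train_windows, "walk")
        p_pause_all = _pooled_conditional(t, seg, train_windows, "pause")
        ever_heated = heat_total > 0
        ed_overall = (exposure_differential(p_walk_all, p_pause_all)
                      if ever_heated else math.nan)

        for label in SESSION_ORDER:
            w = t.window(label)
            level = activity_level(seg, w)
            is_train = label in TRAIN_SESSIONS
            sess_cut = cut if is_train else w.duration(t.dt)
            session_heat = float(t.laser_on[w.start:w.stop].sum()) * t.dt
            if is_train and ever_heated:
                p_hw = conditional_heat_likelihood(t, seg, w, "walk")
                p_hp = conditional_heat_likelihood(t, seg, w, "pause")
                ed = exposure_differential(p_hw, p_hp)
            else:
                p_hw = p_hp = ed = math.nan
            laser = t.laser_on[w.start:w.stop]
            episode_count = int(
                ((laser[1:] == 1) & (laser[:-1] == 0)).sum()
                + (laser[0] == 1)) if len(laser) else 0
            rows.append({
                "fly_id": t.fly_id, "group": rec.group,
                "triplet_id": rec.triplet_id, "session": label,
                "activity_level": level,
                "cad_at_cut": cumulative_active_duration(seg, w, sess_cut),
                "p_heat_walk": p_hw, "p_heat_pause": p_hp,
                "exposure_differential": ed,
                "total_heat_exposure": session_heat,
                "episode_count": episode_count,
                "session_length": w.duration(t.dt),
                "ad": (activity_difference(level, pre_level)
                       if label in TEST_SESSIONS[1:] else math.nan),
                "ed_overall": ed_overall,
                "heat_exposure_total": heat_total,
                "common_cut": cut,
            })
    return pd.DataFrame(rows)


def per_fly_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-fly view: AD columns, overall ED, total exposure."""
    flies = table[["fly_id", "group", "triplet_id", "ed_overall",
                   "heat_exposure_total"]].drop_duplicates("fly_id")
    for label, col in (("Test1", "ad_test1"), ("Test2", "ad_test2")):
        sub = table.loc[table["session"] == label, ["fly_id", "ad"]]
        flies = flies.merge(sub.rename(columns={"ad": col}), on="fly_id")
    pre = table.loc[table["session"] == "Pre-test",
                    ["fly_id", "activity_level"]]
    flies = flies.merge(
        pre.rename(columns={"activity_level": "pretest_activity"}),
        on="fly_id")
    return flies.reset_index(drop=True)
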