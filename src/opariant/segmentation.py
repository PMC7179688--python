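"""Walk/pause bout segmentation of position traces.

Every downstream metric rests on an exclusive, exhaustive dichotomy of the
trace into walk and pause bouts.  A sample is classed as walking when its
first-difference speed ``|Δposition|/dt`` reaches the speed threshold
(default 1.0 mm/s — well below typical fly walking speeds, well above sensor
jitter).  Runs shorter than the debounce length ``min_bout`` (default 0.2 s)
are absorbed into their neighbours, shortest run first, so single-sample
blips do not fragment bouts.  The result is a contiguous, alternating,
half-open partition whose durations sum exactly to the trace duration.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .trace import PositionTrace, SessionWindow

WALK = "walk"
PAUSE = "pause"


@dataclass(frozen=True)
class Bout:
    state: str
    start: float  # seconds, inclusive
    end: float    # seconds, exclusive

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class StateSegmentation:
    """Alternating walk/pause bouts covering one trace."""

    fly_id: str
    dt: float
    n_samples: int
    #: per-sample walk flag after debouncing
    walk_mask: np.ndarray
    speed_threshold: float
    min_bout: float

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt

    @property
    def bouts(self) -> List[Bout]:
        out = []
        for state, a, b in self._runs():
            out.append(Bout(state, a * self.dt, b * self.dt))
        return out

    def _runs(self) -> List[Tuple[str, int, int]]:
        return _mask_runs(self.walk_mask)

    def bout_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"fly_id": self.fly_id, "state": b.state,
              "start_s": b.start, "end_s": b.end} for b in self.bouts])


def _mask_runs(mask: np.ndarray) -> List[Tuple[str, int, int]]:
    """Maximal runs of a boolean mask as (state, start, stop) sample tuples."""
    n = len(mask)
    if n == 0:
        return []
    change = np.flatnonzero(mask[1:] != mask[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [n]))
    return [(WALK if mask[a] else PAUSE, int(a), int(b))
            for a, b in zip(starts, stops)]


def _debounce(mask: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge runs shorter than ``min_samples`` into their neighbours.

    Shortest run first; ties broken in favour of pause runs, then earlier
    runs.  Uses a doubly linked list of runs with a lazy heap.
    """
    if min_samples <= 1:
        return mask
    runs = _mask_runs(mask)
    if len(runs) <= 1:
        return mask
    state = [r[0] for r in runs]
    length = [r[2] - r[1] for r in runs]
    prev = list(range(-1, len(runs) - 1))
    nxt = list(range(1, len(runs) + 1))
    nxt[-1] = -1
    alive = [True] * len(runs)
    n_alive = len(runs)

    def priority(i):
        return (length[i], 0 if state[i] == PAUSE else 1, i)

    heap = [priority(i) for i in range(len(runs)) if length[i] < min_samples]
    heapq.heapify(heap)

    while heap and n_alive > 1:
        _, _, i = heapq.heappop(heap)
        if not alive[i] or length[i] >= min_samples:
            continue
        # absorb run i into its neighbour(s): flipping its state merges it
        # with whichever neighbours exist (they share the opposite state)
        p, q = prev[i], nxt[i]
        target = p if p != -1 else q
        state[i] = state[target]
        for j in (p, q):
            if j == -1 or not alive[j]:
                continue
            # merge j into i
            length[i] += length[j]
            alive[j] = False
            n_alive -= 1
            if j == p:
                prev[i] = prev[j]
                if prev[j] != -1:
                    nxt[prev[j]] = i
            else:
                nxt[i] = nxt[j]
                if nxt[j] != -1:
                    prev[nxt[j]] = i
        if length[i] < min_samples:
            heapq.heappush(heap, priority(i))

    out = np.empty_like(mask)
    cursor = 0
    i = 0
    while i != -1 and not alive[i]:
        i += 1
    # rebuild in list order
    order = [j for j in range(len(runs)) if alive[j]]
    for j in order:
        out[cursor:cursor + length[j]] = state[j] == WALK
        cursor += length[j]
    assert cursor == len(mask)
    return out


def segment_trace(trace: PositionTrace, speed_threshold: float = 1.0,
                  min_bout: float = 0.2) -> StateSegmentation:
    """Segment a trace into walk/pause bouts.

    Per-sample speed is the forward difference ``|Δx|/dt``; the last sample
    inherits the preceding speed so every sample is classified.
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    if min_bout < 0:
        raise ValueError("min_bout must be non-negative")
    if trace.n_samples < 2:
        raise ValueError("trace must have at least 2 samples")
    speed = np.abs(np.diff(trace.position)) / trace.dt
    walk = np.empty(trace.n_samples, dtype=bool)
    walk[:-1] = speed >= speed_threshold
    walk[-1] = walk[-2]
    min_samples = int(round(min_bout / trace.dt))
    walk = _debounce(walk, min_samples)
    return StateSegmentation(
        fly_id=trace.fly_id, dt=trace.dt, n_samples=trace.n_samples,
        walk_mask=walk, speed_threshold=speed_threshold, min_bout=min_bout)


def bout_summary(seg: StateSegmentation, window: SessionWindow) -> dict:
    """Counts and total durations of walk/pause bouts clipped to a window."""
    if window.stop <= window.start:
        raise ValueError("empty window")
    if window.start < 0 or window.stop > seg.n_samples:
        raise ValueError("window outside trace")
    counts = {WALK: 0, PAUSE: 0}
    durations = {WALK: 0.0, PAUSE: 0.0}
    for state, a, b in seg._runs():
        lo, hi = max(a, window.start), min(b, window.stop)
        if lo < hi:
            counts[state] += 1
            durations[state] += (hi - lo) * seg.dt
    return {
        "walk_bouts": counts[WALK], "pause_bouts": counts[PAUSE],
        "walk_duration": durations[WALK], "pause_duration": durations[PAUSE],
        "window_duration": window.n_samples * seg.dt,
    }
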