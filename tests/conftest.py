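"""Shared fixtures: hand-built traces and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from opariant import (AnalysisConfig, ProtocolSpec, SimConfig, FlyRecord,
                      PositionTrace, SessionWindow, simulate_cohort,
                      SESSION_ORDER)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def five_windows(n: int, sizes=None):
    """Split ``n`` samples into the five protocol sessions."""
    if sizes is None:
        base = n // 5
        sizes = [base] * 4 + [n - 4 * base]
    assert sum(sizes) == n and all(s > 0 for s in sizes)
    windows, cursor = [], 0
    for label, size in zip(SESSION_ORDER, sizes):
        windows.append(SessionWindow(label, cursor, cursor + size))
        cursor += size
    return windows


def trace_from_mask(mask, dt: float = 0.01, fly_id: str = "f0",
                    laser=None, sizes=None, step: float = 0.05,
                    chamber: float = 48.7) -> PositionTrace:
    """Build a trace whose segmentation reproduces ``mask`` exactly.

    Walking samples move ``step`` mm per sample (zig-zagging inside the
    chamber), paused samples stay put.  The caller must make the last two
    mask entries equal (the final sample inherits the preceding speed).
    """
    mask = np.asarray(mask, dtype=bool)
    n = len(mask)
    assert n >= 2 and mask[-1] == mask[-2]
    pos = np.empty(n)
    pos[0] = chamber / 2
    direction = 1.0
    for i in range(n - 1):
        delta = step * direction if mask[i] else 0.0
        nxt = pos[i] + delta
        if nxt <= 0 or nxt >= chamber:
            direction = -direction
            nxt = pos[i] + (step * direction if mask[i] else 0.0)
        pos[i + 1] = nxt
    if laser is None:
        laser = np.zeros(n, dtype=np.uint8)
    return PositionTrace(fly_id=fly_id, dt=dt, position=pos,
                         laser_on=np.asarray(laser, dtype=np.uint8),
                         sessions=five_windows(n, sizes))


def mask_with_fraction(n: int, frac: float) -> np.ndarray:
    """One leading walk run occupying ``frac`` of ``n`` samples."""
    mask = np.zeros(n, dtype=bool)
    mask[:int(round(frac * n))] = True
    if n >= 2:
        mask[-1] = mask[-2]
    return mask


def make_record(fly_id, group="train", triplet_id="t000", **kw) -> FlyRecord:
    defaults = dict(genotype="CS", sex="f", eclosion_date="2019-06-01")
    defaults.update(kw)
    return FlyRecord(fly_id=fly_id, group=group, triplet_id=triplet_id,
                     **defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """Six triplets under default study conditions (shared, read-only)."""
    sim = SimConfig(n_triplets=6, seed=11)
    traces, records, episodes = simulate_cohort(sim)
    return {"sim": sim, "traces": traces, "records": records,
            "episodes": episodes, "protocol": ProtocolSpec(),
            "analysis": AnalysisConfig()}
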