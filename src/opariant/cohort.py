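"""Closed-loop cohort simulation: train / yoked / blank triplets.

Each triplet is three flies run through the 5-session protocol with shared
session timing.  The train fly is simulated first under the closed-loop
controller (its walking, with operator latency, drives the laser; edge-zone
heating applies to it only); its Train sessions end at the episode quota or
the stationary cutoff and define the triplet's Train windows.  The yoked fly
then receives the train fly's laser channel sample-for-sample, and the blank
fly receives no heat anywhere.  All three share the same learning rule: heat
while walking accrues suppression of the pause-to-walk hazard, heat while
pausing erodes it, so net learning follows the heat-walking contingency.

The per-sample loop runs in a numba kernel; the Python-level
:func:`opariant.agent.step_fly` implements the identical update rule and is
used for single-step reasoning and cross-checks.  Reproducibility: one root
seed spawns per-fly child streams, so enlarging the cohort never perturbs
earlier flies.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .config import ProtocolSpec, SimConfig, ConfigurationError, GROUPS
from .trace import FlyRecord, PositionTrace, SessionWindow

# parameter-vector layout for the kernel
_P_DT = 0
_P_SPEED = 1
_P_LAMBDA_W = 2      # pause -> walk
_P_LAMBDA_P = 3      # walk -> pause
_P_ALPHA = 4         # learning gain
_P_TAU_S = 5
_P_BETA = 6
_P_HAB = 7
_P_LAT_LO = 8
_P_LAT_HI = 9
_P_CHAMBER = 10
_P_EDGE = 11
_P_TRIGGER = 12
_P_TEST_DUR = 13
_P_STATIONARY = 14
_P_MAX_EPISODES = 15
_P_MAX_TRAIN = 16
_P_ALPHA2 = 17       # unlearning gain (heat while pausing)
_N_PARAMS = 18

MODE_TRAIN = 0
MODE_YOKED = 1
MODE_BLANK = 2


def _params_vector(sim: SimConfig, protocol: ProtocolSpec) -> np.ndarray:
    p = np.empty(_N_PARAMS, dtype=np.float64)
    p[_P_DT] = sim.dt
    p[_P_SPEED] = sim.walk_speed
    p[_P_LAMBDA_W] = sim.pause_to_walk_rate
    p[_P_LAMBDA_P] = sim.walk_to_pause_rate
    p[_P_ALPHA] = sim.learning_gain
    p[_P_TAU_S] = sim.suppression_decay
    p[_P_BETA] = sim.suppression_effect
    p[_P_HAB] = sim.habituation_rate
    p[_P_LAT_LO] = sim.controller_latency - sim.controller_latency_jitter
    p[_P_LAT_HI] = sim.controller_latency + sim.controller_latency_jitter
    p[_P_CHAMBER] = protocol.chamber_length
    p[_P_EDGE] = protocol.edge_zone
    p[_P_TRIGGER] = protocol.trigger_walk_duration
    p[_P_TEST_DUR] = protocol.test_duration
    p[_P_STATIONARY] = protocol.stationary_cutoff
    p[_P_MAX_EPISODES] = protocol.max_heat_episodes
    p[_P_MAX_TRAIN] = sim.max_train_duration
    p[_P_ALPHA2] = sim.unlearning_gain
    return p


@njit(cache=True)
def _run_protocol(seed, mode, train1_laser, train2_laser, p):  # pragma: no cover - compiled
    np.random.seed(seed)
    dt = p[_P_DT]
    test_n = int(round(p[_P_TEST_DUR] / dt))
    if mode == MODE_TRAIN:
        t1cap = int(round(p[_P_MAX_TRAIN] / dt))
        t2cap = t1cap
    else:
        t1cap = train1_laser.shape[0]
        t2cap = train2_laser.shape[0]
    total = 3 * test_n + t1cap + t2cap
    pos = np.empty(total, dtype=np.float64)
    laser = np.zeros(total, dtype=np.uint8)
    sess_len = np.zeros(5, dtype=np.int64)
    episodes = np.zeros(2, dtype=np.int64)

    x = np.random.random() * p[_P_CHAMBER]
    stationary_prob = p[_P_LAMBDA_W] / (p[_P_LAMBDA_W] + p[_P_LAMBDA_P])
    state = 1 if np.random.random() < stationary_prob else 0
    heading = 1 if np.random.random() < 0.5 else -1
    S = 0.0
    t_glob = 0.0
    decay = np.exp(-dt / p[_P_TAU_S])
    idx = 0

    for sess in range(5):
        is_train = sess == 1 or sess == 3
        if not is_train:
            n = test_n
        elif mode == MODE_TRAIN:
            n = t1cap
        elif sess == 1:
            n = train1_laser.shape[0]
        else:
            n = train2_laser.shape[0]

        walk_run = 0.0
        pause_run = 0.0
        actual = 0
        desired = 0
        pending_t = 1.0e18
        eps = 0
        t_sess = 0.0
        i = 0
        while i < n:
            t_sess += dt
            lz = 0
            if is_train:
                if mode == MODE_TRAIN:
                    if state == 1:
                        walk_run += dt
                        pause_run = 0.0
                    else:
                        walk_run = 0.0
                        pause_run += dt
                    at_edge = (x <= p[_P_EDGE]
                               or x >= p[_P_CHAMBER] - p[_P_EDGE])
                    d = 1 if (walk_run > p[_P_TRIGGER] or at_edge) else 0
                    if d != desired:
                        desired = d
                        if d != actual:
                            pending_t = t_sess + p[_P_LAT_LO] + \
                                np.random.random() * (p[_P_LAT_HI] - p[_P_LAT_LO])
                        else:
                            pending_t = 1.0e18
                    if t_sess >= pending_t:
                        actual = desired
                        pending_t = 1.0e18
                        if actual == 0:
                            eps += 1
                    lz = actual
                elif mode == MODE_YOKED:
                    lz = train1_laser[i] if sess == 1 else train2_laser[i]

            pos[idx] = x
            laser[idx] = lz
            idx += 1
            i += 1

            # learning / forgetting
            if lz == 1 and state == 1:
                S += p[_P_ALPHA] * dt
            elif lz == 1:
                S = max(0.0, S - p[_P_ALPHA2] * dt)
            else:
                S *= decay
            # position (reflecting walls)
            if state == 1:
                x += p[_P_SPEED] * dt * heading
                if x < 0.0:
                    x = -x
                    heading = -heading
                if x > p[_P_CHAMBER]:
                    x = 2.0 * p[_P_CHAMBER] - x
                    heading = -heading
            # state transition
            if state == 1:
                if np.random.random() < -np.expm1(-p[_P_LAMBDA_P] * dt):
                    state = 0
            else:
                hz = p[_P_LAMBDA_W] * np.exp(-p[_P_BETA] * S) * \
                    np.exp(-p[_P_HAB] * t_glob)
                if np.random.random() < -np.expm1(-hz * dt):
                    state = 1
                    heading = 1 if np.random.random() < 0.5 else -1
            t_glob += dt

            if is_train and mode == MODE_TRAIN:
                if eps >= int(p[_P_MAX_EPISODES]) or \
                        pause_run >= p[_P_STATIONARY]:
                    break

        if is_train and mode == MODE_TRAIN:
            if actual == 1:
                eps += 1  # final ON run counts as an episode
            episodes[0 if sess == 1 else 1] = eps
        sess_len[sess] = i

    return pos[:idx], laser[:idx], sess_len, episodes


def _windows(sess_len, order) -> List[SessionWindow]:
    windows, cursor = [], 0
    for label, n in zip(order, sess_len):
        windows.append(SessionWindow(label, cursor, cursor + int(n)))
        cursor += int(n)
    return windows


def _fly_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, np.uint32)[0] % (2 ** 31))


def simulate_triplet(triplet_seed_seq: np.random.SeedSequence,
                     triplet_id: str, sim: SimConfig,
                     protocol: ProtocolSpec) -> dict:
    """Simulate one train/yoked/blank triplet with shared Train windows."""
    seeds = triplet_seed_seq.spawn(3)
    p = _params_vector(sim, protocol)
    empty = np.zeros(0, dtype=np.uint8)

    out = {}
    pos, laser, sess_len, episodes = _run_protocol(
        _fly_seed(seeds[0]), MODE_TRAIN, empty, empty, p)
    windows = _windows(sess_len, protocol.session_order)
    t1 = np.ascontiguousarray(laser[windows[1].start:windows[1].stop])
    t2 = np.ascontiguousarray(laser[windows[3].start:windows[3].stop])
    out["train"] = PositionTrace(f"{triplet_id}_train", sim.dt, pos, laser,
                                 windows)
    out["episodes"] = episodes

    pos, laser, sess_len, _ = _run_protocol(
        _fly_seed(seeds[1]), MODE_YOKED, t1, t2, p)
    out["yoked"] = PositionTrace(f"{triplet_id}_yoked", sim.dt, pos, laser,
                                 _windows(sess_len, protocol.session_order))

    pos, laser, sess_len, _ = _run_protocol(
        _fly_seed(seeds[2]), MODE_BLANK, t1, t2, p)
    out["blank"] = PositionTrace(f"{triplet_id}_blank", sim.dt, pos, laser,
                                 _windows(sess_len, protocol.session_order))
    return out


def simulate_cohort(sim: SimConfig, protocol: ProtocolSpec | None = None,
                    genotype: str = "CS",
                    ) -> Tuple[List[PositionTrace], List[FlyRecord],
                               pd.DataFrame]:
    """Simulate ``sim.n_triplets`` triplets through the full protocol.

    Returns ``(traces, records, episode_table)`` where ``episode_table`` has
    one row per triplet with the train fly's Train-session episode counts.
    Identical ``sim`` (including seed) gives bit-identical output.
    """
    if protocol is None:
        protocol = ProtocolSpec()
    if sim.n_triplets < 1 or sim.dt <= 0:
        raise ConfigurationError("n_triplets and dt must be positive")

    root = np.random.SeedSequence(sim.seed)
    triplet_seqs = root.spawn(sim.n_triplets)
    attr_rng = np.random.default_rng(root.spawn(1)[0])

    traces: List[PositionTrace] = []
    records: List[FlyRecord] = []
    episode_rows = []
    for k, seq in enumerate(triplet_seqs):
        triplet_id = f"t{k:03d}"
        result = simulate_triplet(seq, triplet_id, sim, protocol)
        episode_rows.append({
            "triplet_id": triplet_id,
            "episodes_train1": int(result["episodes"][0]),
            "episodes_train2": int(result["episodes"][1]),
        })
        for group in GROUPS:
            trace = result[group]
            traces.append(trace)
            records.append(FlyRecord(
                fly_id=trace.fly_id, group=group, triplet_id=triplet_id,
                genotype=genotype,
                sex="f" if attr_rng.random() < 0.5 else "m",
                eclosion_date="2019-06-01",
                procedure_error=bool(
                    attr_rng.random() < sim.procedure_error_rate),
            ))
    return traces, records, pd.DataFrame(episode_rows)
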