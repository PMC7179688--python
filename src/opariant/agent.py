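"""Single-fly locomotion and learning model.

A fly is a two-state (walk/pause) process with constant hazards, so bout
durations are exponential.  Heat delivered while walking accrues a
suppression variable ``S`` which multiplies the pause-to-walk hazard by
``exp(-beta * S)`` — the mechanistic stand-in for learned suppression of
walking.  A slow habituation factor ``exp(-habituation_rate * t)`` applies to
all flies regardless of heat.

:func:`step_fly` is the per-sample reference implementation of the update
rule; cohort simulation runs the same rule in a compiled kernel
(:mod:`opariant.cohort`), and the two are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import SimConfig

WALK = 1
PAUSE = 0


@dataclass(frozen=True)
class FlyState:
    """Instantaneous state of one simulated fly."""

    position: float
    behavioral_state: int  # WALK or PAUSE
    heading: int  # +1 or -1
    suppression: float = 0.0
    body_temperature: float = 21.5
    time: float = 0.0  # seconds since experiment start (drives habituation)

    def __post_init__(self):
        if self.suppression < 0:
            raise ValueError("suppression must be non-negative")
        if self.heading not in (+1, -1):
            raise ValueError("heading must be +1 or -1")
        if self.behavioral_state not in (WALK, PAUSE):
            raise ValueError("behavioral_state must be WALK or PAUSE")


def pause_to_walk_hazard(sim: SimConfig, suppression: float,
                         time: float) -> float:
    """Effective pause->walk hazard under suppression and habituation."""
    return (sim.pause_to_walk_rate
            * math.exp(-sim.suppression_effect * suppression)
            * math.exp(-sim.habituation_rate * time))


def step_fly(state: FlyState, laser_on: bool, sim: SimConfig,
             chamber_length: float, rng: np.random.Generator) -> FlyState:
    """Advance a fly by one sampling step ``sim.dt``.

    Order of updates within a step: suppression, position (walking flies
    advance ``walk_speed * dt * heading`` and reflect at the walls; paused
    flies do not move), then the stochastic state transition.
    """
    dt = sim.dt

    if laser_on and state.behavioral_state == WALK:
        suppression = state.suppression + sim.learning_gain * dt
    elif laser_on:  # heat while pausing erodes the association
        suppression = max(0.0, state.suppression - sim.unlearning_gain * dt)
    else:
        suppression = state.suppression * math.exp(-dt / sim.suppression_decay)

    position, heading = state.position, state.heading
    if state.behavioral_state == WALK:
        position += sim.walk_speed * dt * heading
        if position < 0:
            position, heading = -position, -heading
        if position > chamber_length:
            position = 2 * chamber_length - position
            heading = -heading
        position = min(max(position, 0.0), chamber_length)

    behavioral_state = state.behavioral_state
    if state.behavioral_state == WALK:
        if rng.random() < -math.expm1(-sim.walk_to_pause_rate * dt):
            behavioral_state = PAUSE
    else:
        hazard = pause_to_walk_hazard(sim, suppression, state.time)
        if rng.random() < -math.expm1(-hazard * dt):
            behavioral_state = WALK
            heading = 1 if rng.random() < 0.5 else -1

    temperature = state.body_temperature
    th = sim.thermal
    if laser_on:
        temperature = th.t_target + (temperature - th.t_target) * math.exp(
            -dt / th.tau_heat)
    else:
        temperature = th.t_room + (temperature - th.t_room) * math.exp(
            -dt / th.tau_cool)

    return replace(state, position=position, heading=heading,
                   behavioral_state=behavioral_state, suppression=suppression,
                   body_temperature=temperature, time=state.time + dt)
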