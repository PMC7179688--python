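"""Virtual operator controlling the laser during Train sessions.

The laser is armed when the train fly has walked continuously for longer than
the trigger duration, or whenever it sits within the edge zone at either end
of the chamber (edge heating discourages wall-hugging).  The operator acts
with a latency: each commanded switch takes effect after a uniformly jittered
delay, and a command is cancelled if the trigger condition reverts before the
operator has acted.  With latency disabled (``latency_rng=None``) the laser
follows the trigger conditions instantaneously — the deterministic contract
used in tests.

Test sessions never heat: :meth:`LaserController.update` returns OFF there.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ProtocolSpec, SimConfig, TRAIN_SESSIONS


def session_terminated(episodes_completed: int, current_pause_length: float,
                       protocol: ProtocolSpec) -> bool:
    """Whether a Train session ends now.

    True once the fly has completed the episode quota or has been pausing
    continuously for the stationary cutoff (one uninterrupted pause, not
    cumulative pause time).
    """
    if episodes_completed < 0 or current_pause_length < 0:
        raise ValueError("counters must be non-negative")
    return (episodes_completed >= protocol.max_heat_episodes
            or current_pause_length >= protocol.stationary_cutoff)


class LaserController:
    """Stateful laser logic for one train fly.

    Parameters
    ----------
    protocol : trigger rules and zone geometry.
    latency_rng : RNG used to draw operator latencies, or ``None`` for an
        idealized zero-latency operator.
    latency, jitter : latency is drawn uniformly from
        ``[latency - jitter, latency + jitter]`` per commanded switch.
    """

    def __init__(self, protocol: ProtocolSpec,
                 latency_rng: np.random.Generator | None = None,
                 latency: float = 0.55, jitter: float = 0.25):
        self.protocol = protocol
        self.latency_rng = latency_rng
        self.latency = latency
        self.jitter = jitter
        self.reset()

    def reset(self) -> None:
        """Arm the controller for a fresh session."""
        self.walk_run = 0.0
        self.laser_on = False
        self.desired = False
        self.pending_time = math.inf
        self.episodes_completed = 0
        self.time = 0.0

    def _draw_latency(self) -> float:
        if self.latency_rng is None:
            return 0.0
        return self.latency_rng.uniform(self.latency - self.jitter,
                                        self.latency + self.jitter)

    def update(self, walking: bool, position: float, session: str,
               dt: float) -> bool:
        """Advance one sample; return the laser flag for this sample."""
        self.time += dt
        if session not in TRAIN_SESSIONS:
            if self.laser_on:
                self.episodes_completed += 1
            self.laser_on = False
            self.desired = False
            self.pending_time = math.inf
            self.walk_run = 0.0
            return False

        self.walk_run = self.walk_run + dt if walking else 0.0
        p = self.protocol
        at_edge = (position <= p.edge_zone
                   or position >= p.chamber_length - p.edge_zone)
        desired = self.walk_run > p.trigger_walk_duration or at_edge
        if desired != self.desired:
            self.desired = desired
            if desired != self.laser_on:
                self.pending_time = self.time + self._draw_latency()
            else:
                # condition reverted before the operator acted
                self.pending_time = math.inf
        if self.time >= self.pending_time:
            self.laser_on = self.desired
            self.pending_time = math.inf
            if not self.laser_on:
                self.episodes_completed += 1
        return self.laser_on

    def finish_session(self) -> int:
        """Force the laser off at session end; return completed episodes."""
        if self.laser_on:
            self.episodes_completed += 1  # the ON run that just ended counts
            self.laser_on = False
        self.pending_time = math.inf
        self.desired = False
        self.walk_run = 0.0
        return self.episodes_completed


def heat_controller(recent_states, position: float, session: str,
                    protocol: ProtocolSpec,
                    latency_rng: np.random.Generator | None = None,
                    dt: float | None = None) -> bool:
    """Functional wrapper: laser flag given a recent walk/pause history.

    ``recent_states`` is a sequence of per-sample walk flags (most recent
    last) spanning at least the trigger window; ``dt`` defaults to
    ``SimConfig().dt``.  Stateless convenience over :class:`LaserController`
    for single queries; closed-loop simulation uses the stateful class.
    """
    if dt is None:
        dt = SimConfig().dt
    ctrl = LaserController(protocol, latency_rng=latency_rng)
    flag = False
    for walking in recent_states:
        flag = ctrl.update(bool(walking), position, session, dt)
    return flag
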