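"""Configuration objects for the simulator, protocol and analysis.

Every run of the pipeline is fully determined by a (:class:`ProtocolSpec`,
:class:`SimConfig`, :class:`AnalysisConfig`) triple plus a root seed.  All
three serialize to/from a flat key-value YAML document so that a single
scenario file reproduces a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: The five protocol sessions, in fixed order.
SESSION_ORDER = ("Pre-test", "Train1", "Test1", "Train2", "Test2")

#: Sessions in which locomotion can trigger the laser.
TRAIN_SESSIONS = ("Train1", "Train2")

#: Heat-free sessions of fixed length.
TEST_SESSIONS = ("Pre-test", "Test1", "Test2")

GROUPS = ("train", "yoked", "blank")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and trigger rules of the 5-session operant protocol.

    Test sessions (Pre-test, Test1, Test2) last ``test_duration`` seconds with
    the laser permanently off.  Train sessions run until the fly has completed
    ``max_heat_episodes`` laser episodes or has paused continuously for
    ``stationary_cutoff`` seconds.  The laser is armed once the fly has walked
    continuously for more than ``trigger_walk_duration`` seconds, or whenever
    it sits within ``edge_zone`` millimetres of either chamber wall.
    """

    test_duration: float = 600.0
    max_heat_episodes: int = 20
    stationary_cutoff: float = 480.0
    trigger_walk_duration: float = 0.5
    edge_zone: float = 3.0
    chamber_length: float = 48.7
    session_order: tuple = SESSION_ORDER

    def __post_init__(self):
        for name in ("test_duration", "stationary_cutoff",
                     "trigger_walk_duration", "edge_zone", "chamber_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.max_heat_episodes < 1:
            raise ConfigurationError("max_heat_episodes must be >= 1")
        if self.edge_zone >= self.chamber_length / 2:
            raise ConfigurationError("edge_zone must be < chamber_length/2")
        if tuple(self.session_order) != SESSION_ORDER:
            raise ConfigurationError(
                f"session_order is fixed to {SESSION_ORDER}")


@dataclass(frozen=True)
class ThermalModel:
    """First-order body-temperature response to the laser.

    Temperature relaxes exponentially toward ``t_target`` while the laser is
    on and toward ``t_room`` while it is off; the trajectory is bounded by the
    two set-points.  Diagnostic only — learning couples to the laser flag.
    """

    t_room: float = 21.5
    t_target: float = 26.5
    tau_heat: float = 3.0
    tau_cool: float = 5.0

    def __post_init__(self):
        if self.t_target <= self.t_room:
            raise ConfigurationError("t_target must exceed t_room")
        if self.tau_heat <= 0 or self.tau_cool <= 0:
            raise ConfigurationError("thermal time constants must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-state locomotion and learning model.

    A fly alternates walk and pause bouts with exponential durations
    (hazards ``walk_to_pause_rate`` out of walking and ``pause_to_walk_rate``
    out of pausing).  Heat received while walking accrues a suppression
    variable ``S`` at ``learning_gain`` per second; heat received while
    pausing erodes it at ``unlearning_gain`` (floored at zero), so net
    suppression tracks the contingency of heat on walking rather than the
    amount of heat.  Without heat, ``S`` decays with time constant
    ``suppression_decay``; it multiplies the pause-to-walk hazard by
    ``exp(-suppression_effect * S)``.  A slow shared
    ``habituation_rate`` makes all groups a little less active over the
    experiment, independent of heat.

    Defaults are chosen so a naive fly walks ~55% of the time at typical
    walking speed, and a conditioned fly's activity collapses to roughly a
    third of baseline by the last test session.
    """

    dt: float = 0.01
    walk_speed: float = 10.0
    pause_to_walk_rate: float = 0.30
    walk_to_pause_rate: float = 0.25
    learning_gain: float = 0.02
    unlearning_gain: float = 0.02
    suppression_decay: float = 3600.0
    suppression_effect: float = 1.0
    habituation_rate: float = 1.1e-4
    controller_latency: float = 0.55
    controller_latency_jitter: float = 0.25
    max_train_duration: float = 3600.0
    procedure_error_rate: float = 0.0
    n_triplets: int = 60
    seed: int = 0
    thermal: ThermalModel = field(default_factory=ThermalModel)

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.n_triplets < 1:
            raise ConfigurationError("n_triplets must be >= 1")
        for name in ("walk_speed", "pause_to_walk_rate", "walk_to_pause_rate",
                     "learning_gain", "unlearning_gain", "suppression_effect",
                     "habituation_rate", "procedure_error_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.suppression_decay <= 0:
            raise ConfigurationError("suppression_decay must be positive")
        if self.controller_latency < self.controller_latency_jitter:
            raise ConfigurationError(
                "controller_latency_jitter exceeds controller_latency")
        if self.max_train_duration <= 0:
            raise ConfigurationError("max_train_duration must be positive")


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the metric and curation stage.

    ``common_train_cut`` is the common time point at which Train-session
    metrics are compared across flies; ``None`` means "use the cohort minimum
    Train-session length", which the pipeline computes and logs.  163 s is the
    reproduction default for the original cohort.
    """

    common_train_cut: Optional[float] = None
    test_session_length: float = 600.0
    speed_threshold: float = 1.0
    min_bout: float = 0.2
    inactivity_threshold: float = 0.90
    n_resamples: int = 10000
    ci_level: float = 0.95

    def __post_init__(self):
        if self.common_train_cut is not None and self.common_train_cut <= 0:
            raise ConfigurationError("common_train_cut must be positive")
        if self.speed_threshold <= 0:
            raise ConfigurationError("speed_threshold must be positive")
        if self.min_bout < 0:
            raise ConfigurationError("min_bout must be non-negative")
        if not 0 < self.inactivity_threshold <= 1:
            raise ConfigurationError("inactivity_threshold must be in (0, 1]")


#: Parameter presets.  The dopamine-receptor-mutant presets follow the
#: qualitative phenotype only (reduced learning gain); they are illustrative
#: simulator settings, not biological parameter estimates.
PRESETS = {
    "wild_type": {},
    "dop1r1": {"learning_gain": 0.02 * 0.25,
               "unlearning_gain": 0.02 * 0.25},
    "dop2r": {"learning_gain": 0.02 * 0.25,
              "unlearning_gain": 0.02 * 0.25},
}


def preset_sim_config(name: str, **overrides) -> SimConfig:
    """Return a :class:`SimConfig` for a named preset, with overrides."""
    if name not in PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------------------
# Flat YAML (de)serialization

_PREFIXES = {
    "protocol": ProtocolSpec,
    "sim": SimConfig,
    "thermal": ThermalModel,
    "analysis": AnalysisConfig,
}


def to_flat_dict(protocol: ProtocolSpec, sim: SimConfig,
                 analysis: AnalysisConfig) -> dict:
    """Flatten the three config objects into one ``prefix.field`` mapping."""
    out = {}
    for prefix, obj in (("protocol", protocol), ("sim", sim),
                        ("analysis", analysis)):
        for f in dataclasses.fields(obj):
            value = getattr(obj, f.name)
            if f.name == "thermal":
                for tf in dataclasses.fields(value):
                    out[f"thermal.{tf.name}"] = getattr(value, tf.name)
                continue
            if f.name == "session_order":
                value = list(value)
            out[f"{prefix}.{f.name}"] = value
    return out


def from_flat_dict(flat: dict) -> tuple:
    """Rebuild ``(ProtocolSpec, SimConfig, AnalysisConfig)`` from a flat map."""
    groups: dict = {name: {} for name in _PREFIXES}
    for key, value in flat.items():
        prefix, _, fname = key.partition(".")
        if prefix not in _PREFIXES or not fname:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        valid = {f.name for f in dataclasses.fields(_PREFIXES[prefix])}
        if fname not in valid:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        groups[prefix][fname] = value
    if "session_order" in groups["protocol"]:
        groups["protocol"]["session_order"] = tuple(
            groups["protocol"]["session_order"])
    thermal = ThermalModel(**groups["thermal"])
    sim = SimConfig(thermal=thermal, **groups["sim"])
    return (ProtocolSpec(**groups["protocol"]), sim,
            AnalysisConfig(**groups["analysis"]))


def save_config(path, protocol: ProtocolSpec, sim: SimConfig,
                analysis: AnalysisConfig) -> None:
    Path(path).write_text(
        yaml.safe_dump(to_flat_dict(protocol, sim, analysis),
                       sort_keys=True))


def load_config(path) -> tuple:
    flat = yaml.safe_load(Path(path).read_text())
    if not isinstance(flat, dict):
        raise ConfigurationError(f"{path}: expected a flat key-value mapping")
    return from_flat_dict(flat)
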