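"""Body-temperature dynamics under laser irradiation.

The laser heats the fly directly; its body temperature relaxes exponentially
toward the active set-point (laser on: ``t_target``, off: ``t_room``).  This
is a diagnostic model of the measured temperature profile — learning in the
behavioral model couples to the laser flag, not to temperature.
"""

from __future__ import annotations

import math

import numpy as np

from .config import ThermalModel


def body_temperature_step(temperature: float, laser_on: bool,
                          thermal: ThermalModel, dt: float) -> float:
    """Advance body temperature by one step of first-order relaxation.

    Uses the exact one-step solution of ``dT/dt = (T_set - T)/tau`` so the
    output is bounded by ``[t_room, t_target]`` for any ``dt > 0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if laser_on:
        setpoint, tau = thermal.t_target, thermal.tau_heat
    else:
        setpoint, tau = thermal.t_room, thermal.tau_cool
    return setpoint + (temperature - setpoint) * math.exp(-dt / tau)


def temperature_profile(laser: np.ndarray, thermal: ThermalModel,
                        dt: float, t0: float | None = None) -> np.ndarray:
    """Temperature trajectory for a whole laser time-series.

    Parameters
    ----------
    laser : array of {0, 1}, one entry per sample.
    t0 : starting temperature; defaults to room temperature.
    """
    temperature = thermal.t_room if t0 is None else t0
    out = np.empty(len(laser), dtype=float)
    for i, flag in enumerate(laser):
        temperature = body_temperature_step(temperature, bool(flag),
                                            thermal, dt)
        out[i] = temperature
    return out
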