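"""The closed-loop oxygen-titration controller.

The device consumes one pulse-oximeter SpO2 reading per sampling period
(3 s) and holds, opens or closes the flow valve:

* SpO2 above the target band -> close: flow decreases by 0.5 L/min, with at
  least 2 s between consecutive decreases;
* SpO2 below the target band -> open: flow increases by 2.0 L/min, with at
  least 5 s between consecutive increases;
* SpO2 inside the band -> hold.

Commanded flow is clamped to [0, 30] L/min and quantized to the valve's
0.1 L/min resolution.  Target bands follow the clinical guideline split:
88-92 % SpO2 for hypercapnic patients (CO2-retention risk under hyperoxia)
and 92-96 % for purely hypoxemic patients.  An audio-alarm flag is raised
whenever the reading crosses clinician-set low/high thresholds.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import configio
from .physiology import Phenotype

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "SignalFault",
    "default_config",
    "step",
    "run_controller_trace",
]


class SignalFault(ValueError):
    """An SpO2 reading outside [0, 100] %: a probe/signal failure, not a
    physiological alarm.  The caller should hold flow and log the event."""


_CONFIG_KEYS = (
    "target_low",
    "target_high",
    "decrease_step",
    "decrease_interval",
    "increase_step",
    "increase_interval",
    "sample_period",
    "flow_min",
    "flow_max",
    "flow_quantum",
    "alarm_low",
    "alarm_high",
)


@dataclass(frozen=True)
class ControllerConfig:
    """Device constants for one titration session.

    Attributes
    ----------
    target_low, target_high : float
        SpO2 target band bounds, percent.
    decrease_step : float
        Flow decrement per closing adjustment, L/min.
    decrease_interval : float
        Minimum time between closing adjustments, s.
    increase_step : float
        Flow increment per opening adjustment, L/min.
    increase_interval : float
        Minimum time between opening adjustments, s.
    sample_period : float
        SpO2 sampling cadence, s (one reading consumed per period).
    flow_min, flow_max : float
        Commanded-flow range, L/min.
    flow_quantum : float
        Valve flow resolution, L/min; commands are rounded to this grid.
    alarm_low, alarm_high : float
        Clinician-set audio-alarm thresholds, percent SpO2.
    """

    target_low: float
    target_high: float
    decrease_step: float = 0.5
    decrease_interval: float = 2.0
    increase_step: float = 2.0
    increase_interval: float = 5.0
    sample_period: float = 3.0
    flow_min: float = 0.0
    flow_max: float = 30.0
    flow_quantum: float = 0.1
    alarm_low: float = 0.0
    alarm_high: float = 100.0

    def __post_init__(self) -> None:
        if not self.target_low < self.target_high:
            raise ValueError("target_low must be < target_high")
        if not self.alarm_low < self.target_low:
            raise ValueError("alarm_low must be below target_low")
        if not self.alarm_high > self.target_high:
            raise ValueError("alarm_high must be above target_high")
        if not 0 <= self.flow_min < self.flow_max:
            raise ValueError("need 0 <= flow_min < flow_max")
        if not self.flow_quantum > 0:
            raise ValueError("flow_quantum must be positive")
        for name in ("decrease_interval", "increase_interval", "sample_period"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.decrease_step <= 0 or self.increase_step <= 0:
            raise ValueError("adjustment steps must be positive")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "ControllerConfig":
        """Load a config from a flat key=value file (all 12 keys required)."""
        raw = configio.read_kv(path)
        missing = [k for k in _CONFIG_KEYS if k not in raw]
        if missing:
            raise ValueError(f"{path}: missing controller config keys: {missing}")
        extra = [k for k in raw if k not in _CONFIG_KEYS]
        if extra:
            raise ValueError(f"{path}: unknown controller config keys: {extra}")
        return cls(**{k: float(raw[k]) for k in _CONFIG_KEYS})

    def to_file(self, path: str | os.PathLike) -> None:
        configio.write_kv(path, {k: getattr(self, k) for k in _CONFIG_KEYS})


@dataclass
class ControllerState:
    """Internal device state between samples.

    ``last_increase_t`` / ``last_decrease_t`` default to -inf so that the
    first adjustment of a session is never rate-limited.
    """

    flow: float = 0.0
    last_increase_t: float = -math.inf
    last_decrease_t: float = -math.inf
    alarm_active: bool = False


def default_config(phenotype: Phenotype) -> ControllerConfig:
    """The device's default configuration for an ARF phenotype.

    Hypercapnic patients get the 88-92 % band, purely hypoxemic patients
    92-96 %.  Alarm thresholds default to 3 % outside the band; in clinical
    use they are set per patient.
    """
    if phenotype is Phenotype.HYPERCAPNIC:
        low, high = 88.0, 92.0
    elif phenotype is Phenotype.PURELY_HYPOXEMIC:
        low, high = 92.0, 96.0
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown phenotype {phenotype!r}")
    return ControllerConfig(
        target_low=low,
        target_high=high,
        alarm_low=low - 3.0,
        alarm_high=high + 3.0,
    )


def _quantize(flow: float, quantum: float) -> float:
    # round to nearest quantum, ties away from zero
    q = math.floor(abs(flow) / quantum + 0.5) * quantum
    return round(math.copysign(q, flow), 9)


def step(
    cfg: ControllerConfig, st: ControllerState, spo2_measured: float, t: float
) -> ControllerState:
    """Consume one SpO2 reading at time ``t`` and return the next state.

    Raises :class:`SignalFault` for readings outside [0, 100] %; the state is
    untouched in that case.
    """
    if not 0.0 <= spo2_measured <= 100.0:
        raise SignalFault(
            f"SpO2 reading {spo2_measured} outside [0, 100] at t={t} s"
        )
    flow = st.flow
    last_inc = st.last_increase_t
    last_dec = st.last_decrease_t
    if spo2_measured > cfg.target_high and t - last_dec >= cfg.decrease_interval:
        flow = _quantize(
            min(max(flow - cfg.decrease_step, cfg.flow_min), cfg.flow_max),
            cfg.flow_quantum,
        )
        last_dec = t
    elif spo2_measured < cfg.target_low and t - last_inc >= cfg.increase_interval:
        flow = _quantize(
            min(max(flow + cfg.increase_step, cfg.flow_min), cfg.flow_max),
            cfg.flow_quantum,
        )
        last_inc = t
    alarm = spo2_measured <= cfg.alarm_low or spo2_measured >= cfg.alarm_high
    return ControllerState(
        flow=flow, last_increase_t=last_inc, last_decrease_t=last_dec, alarm_active=alarm
    )


def run_controller_trace(
    cfg: ControllerConfig, spo2_series: Sequence[float]
) -> np.ndarray:
    """Run the controller open-loop over a recorded SpO2 series.

    Readings are consumed at ``cfg.sample_period`` cadence starting at t=0
    from an initial flow of ``cfg.flow_min`` (valve closed).  Returns the
    commanded flow after each sample; deterministic.
    """
    if len(spo2_series) == 0:
        raise ValueError("spo2_series must be nonempty")
    st = ControllerState(flow=cfg.flow_min)
    flows = np.empty(len(spo2_series), dtype=float)
    for i, s in enumerate(spo2_series):
        try:
            st = step(cfg, st, float(s), i * cfg.sample_period)
        except SignalFault as exc:
            raise SignalFault(f"sample {i}: {exc}") from exc
        flows[i] = st.flow
    return flows
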