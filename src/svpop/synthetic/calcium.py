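"""Presynaptic Ca2+ transient forward model with a saturating sensor.

Free concentration follows constant influx during AP trains with first-order
clearance; the sensor converts concentration to fluorescence through a Hill
function, which reproduces both the rapid rise / partial decay during the
stimulus and sensor saturation at long trains.  Ionomycin drives the sensor
to its maximum, providing the per-bouton normalization reference.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator

from ..protocol import StimProtocol

__all__ = ["CaParams", "simulate_ca_trace"]


class CaParams(BaseModel):
    influx_rate: float = 2.0  # concentration units / s during stimulation
    tau_clear: float = 4.0  # s
    kd: float = 10.0  # sensor half-saturation, same units as concentration
    hill: float = 2.0
    group_scale: float = 1.0
    f_rest: float = 0.05  # resting sensor fluorescence (fraction of max)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "CaParams":
        if self.hill <= 0:
            raise ValueError("hill must be positive")
        for name in ("influx_rate", "group_scale"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("tau_clear", "kd"):
            if getattr(self, name) <= 0 or not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and positive")
        if not 0 <= self.f_rest < 1:
            raise ValueError("f_rest must be in [0, 1)")
        return self


def free_concentration(ca: CaParams, protocol: StimProtocol, times: np.ndarray) -> np.ndarray:
    """Exact piecewise solution of dc/dt = a*stim(t) - c/tau."""
    a = ca.influx_rate * ca.group_scale
    tau = ca.tau_clear
    events = sorted(
        {0.0, protocol.total_duration}
        | {t for w in protocol.train_windows() for t in w if t <= protocol.total_duration}
    )
    c = np.empty_like(times, dtype=float)
    c0 = 0.0
    idx = 0
    for t0, t1 in zip(events, events[1:]):
        mid = 0.5 * (t0 + t1)
        on = any(w0 <= mid < w1 for w0, w1 in protocol.train_windows())
        c_inf = a * tau if on else 0.0
        while idx < times.size and times[idx] < t1 - 1e-12:
            dt = times[idx] - t0
            c[idx] = c_inf + (c0 - c_inf) * np.exp(-dt / tau)
            idx += 1
        c0 = c_inf + (c0 - c_inf) * np.exp(-(t1 - t0) / tau)
    while idx < times.size:
        c[idx] = c0
        idx += 1
    return c


def sensor_response(ca: CaParams, conc: np.ndarray) -> np.ndarray:
    """Hill saturation of the sensor, in fractions of its dynamic range."""
    ch = np.power(np.maximum(conc, 0.0), ca.hill)
    return ch / (ca.kd**ca.hill + ch)


def simulate_ca_trace(ca: CaParams, protocol: StimProtocol) -> np.ndarray:
    """Per-frame sensor fluorescence (fraction of sensor maximum).

    The trace sits at ``f_rest`` without influx, rises during trains, decays
    between them, and equals 1 (sensor maximum) from ``ionomycin_time`` on.
    """
    if protocol.ionomycin_time is None:
        raise ValueError("protocol must define ionomycin_time for Ca traces")
    times = protocol.frame_times()
    conc = free_concentration(ca, protocol, times)
    f = ca.f_rest + (1.0 - ca.f_rest) * sensor_response(ca, conc)
    f = np.where(times >= protocol.ionomycin_time, 1.0, f)
    return f
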