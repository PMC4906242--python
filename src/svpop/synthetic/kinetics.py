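"""Forward model of the synaptic vesicle (SV) reporter cycle.

The reporter is distributed over four pools whose fractions sum (with the
non-releasable remainder) to one:

``q``  quenched reporter in not-yet-released vesicles (releasable pool),
``s``  surface reporter (fluorescent) after exocytosis,
``i``  internalized reporter that has not yet re-acidified (fluorescent),
``r``  internalized reporter that has re-acidified (quenched again).

During an AP train, exocytosis drains ``q`` with first-order rate ``k_exo``;
endocytosis is first-order in ``s`` at all times; internalized reporter
re-acidifies with time constant ``tau_reacid``.  Bafilomycin blocks
re-acidification from ``baf_time`` onward.  Recycled vesicles do not rejoin
the releasable pool within a train, so cumulative exocytosis of the first
train follows the closed form
``releasable_fraction * (1 - exp(-k_exo * t_stim))`` and saturates at the
releasable fraction under a depleting stimulus.

At each train onset the releasable pool recovers: re-acidified recycled
reporter rejoins it, and reserve-pool vesicles (quenched reporter) top it
back up to ``releasable_fraction``.  Every train therefore starts from a
full pool while within-train exocytosis stays a single exponential drain,
and the reserve is never mobilized mid-train (the depletion plateau equals
the releasable fraction).

Within each segment of the protocol (train on/off, Baf on/off) the system is
linear time-invariant, so pool fractions are propagated exactly with matrix
exponentials rather than by Euler stepping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator
from scipy.linalg import expm

from ..protocol import StimProtocol

__all__ = ["KineticParams", "PoolTraces", "simulate_pools"]


class KineticParams(BaseModel):
    """Rate constants of the SV cycle forward model.

    ``quench_ratio`` is the brightness of quenched relative to unquenched
    reporter (~20-fold unquenching gives the default 1/20).
    """

    k_exo: float = 0.05
    k_endo: float = 0.03
    tau_reacid: float = 4.0  # seconds; np.inf disables re-acidification
    releasable_fraction: float = 0.3
    quench_ratio: float = 0.05

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check(self) -> "KineticParams":
        for name in ("k_exo", "k_endo", "tau_reacid", "releasable_fraction", "quench_ratio"):
            v = getattr(self, name)
            if np.isnan(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v!r})")
        if not 0 < self.releasable_fraction <= 1:
            raise ValueError("releasable_fraction must be in (0, 1]")
        if not 0 < self.quench_ratio < 1:
            raise ValueError("quench_ratio must be in (0, 1)")
        if self.tau_reacid <= 0:
            raise ValueError("tau_reacid must be positive (np.inf allowed)")
        if not np.isfinite(self.k_exo) or not np.isfinite(self.k_endo):
            raise ValueError("rate constants must be finite")
        return self


@dataclass
class PoolTraces:
    """Per-frame pool fractions and cumulative fluxes of one simulated bouton."""

    times: np.ndarray  # frame timestamps (s)
    q: np.ndarray  # quenched releasable fraction (unreleased + re-acidified)
    s: np.ndarray  # surface fraction
    i: np.ndarray  # internalized, still fluorescent
    exo: np.ndarray  # cumulative exocytosis
    endo: np.ndarray  # cumulative endocytosis
    reacid: np.ndarray  # re-acidified fraction; rejoins q at train onsets
    reserve: np.ndarray  # quenched reserve pool (steps down at train onsets)
    f: np.ndarray  # fluorescent fraction incl. quench residual and NH4Cl step
    params: KineticParams = field(repr=False, default=None)
    protocol: StimProtocol = field(repr=False, default=None)


def _segment_matrix(k_exo: float, k_endo: float, rho: float) -> np.ndarray:
    """Generator of the 6-state linear system (q, s, i, r, cum_exo, cum_endo)."""
    A = np.zeros((6, 6))
    A[0, 0] = -k_exo
    A[1, 0] = k_exo
    A[1, 1] = -k_endo
    A[2, 1] = k_endo
    A[2, 2] = -rho
    A[3, 2] = rho
    A[4, 0] = k_exo  # cumulative exocytosis
    A[5, 1] = k_endo  # cumulative endocytosis
    return A


def simulate_pools(kinetics: KineticParams, protocol: StimProtocol) -> PoolTraces:
    """Simulate reporter pool fractions over the frames of ``protocol``.

    Returns exact (piecewise matrix-exponential) pool trajectories sampled at
    frame times, together with the fluorescent fraction

        f(t) = s + i + quench_ratio * (q_unreleased + q_reacidified + nonreleasable)

    which jumps to 1 after NH4Cl.
    """
    R = kinetics.releasable_fraction
    rho0 = 0.0 if np.isinf(kinetics.tau_reacid) else 1.0 / kinetics.tau_reacid

    # segment boundaries: train edges and baf application
    events = {0.0, protocol.total_duration}
    for t0, t1 in protocol.train_windows():
        events.add(t0)
        events.add(min(t1, protocol.total_duration))
    if protocol.baf_time is not None:
        events.add(protocol.baf_time)
    bounds = sorted(events)

    def stim_on(t: float) -> bool:
        return any(t0 <= t < t1 for t0, t1 in protocol.train_windows())

    times = protocol.frame_times()
    n = times.size
    # state: q_unreleased, s, i, r(cum reacid), cum_exo, cum_endo
    out = np.empty((n, 6))
    x = np.array([R, 0.0, 0.0, 0.0, 0.0, 0.0])
    onsets = {t0 for t0, _ in protocol.train_windows()}
    reserve = 1.0 - R
    reserve_trace = np.empty(n)
    frame_reserve_start = 0
    frame = 0
    for seg_start, seg_end in zip(bounds, bounds[1:]):
        if seg_start in onsets:
            # recovered (re-acidified) reporter rejoins the releasable pool,
            # then reserve vesicles top it back up to the full pool size
            x[0] += x[3]
            x[3] = 0.0
            topup = min(reserve, max(R - x[0], 0.0))
            x[0] += topup
            reserve -= topup
        mid = 0.5 * (seg_start + seg_end)
        k_e = kinetics.k_exo if stim_on(mid) else 0.0
        rho = 0.0 if (protocol.baf_time is not None and mid >= protocol.baf_time) else rho0
        A = _segment_matrix(k_e, kinetics.k_endo, rho)
        # frames inside [seg_start, seg_end)
        in_seg = []
        while frame < n and times[frame] < seg_end - 1e-12:
            in_seg.append(frame)
            frame += 1
        if in_seg:
            offsets = times[np.array(in_seg)] - seg_start
            P = expm(A * offsets[0])
            xi = P @ x
            out[in_seg[0]] = xi
            if len(in_seg) > 1:
                M = expm(A * protocol.frame_interval)
                for j in in_seg[1:]:
                    xi = M @ xi
                    out[j] = xi
        x = expm(A * (seg_end - seg_start)) @ x
        reserve_trace[frame_reserve_start:frame] = reserve
        frame_reserve_start = frame
    # trailing frame exactly at total_duration
    while frame < n:
        out[frame] = x
        frame += 1
    reserve_trace[frame_reserve_start:] = reserve

    qs, s, i, r = out[:, 0], out[:, 1], out[:, 2], out[:, 3]
    exo, endo = out[:, 4], out[:, 5]
    quenched = qs + r + reserve_trace
    f = s + i + kinetics.quench_ratio * quenched
    if protocol.nh4cl_time is not None:
        f = np.where(times >= protocol.nh4cl_time, 1.0, f)
    return PoolTraces(
        times=times,
        q=qs + r,
        s=s,
        i=i,
        exo=exo,
        endo=endo,
        reacid=r,
        reserve=reserve_trace,
        f=f,
        params=kinetics,
        protocol=protocol,
    )
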