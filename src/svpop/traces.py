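"""Per-bouton trace extraction, normalization, QC and rate estimation.

Raw traces are per-frame means over each bouton's label pixels, normalized by
the NH4Cl plateau to cancel expression differences.  Exocytic rates are OLS
slopes over the first six in-train frames of the bafilomycin train; the
endocytic component is the onset-aligned difference between the bafilomycin
train and the first train, fit over a six-frame window placed late in the
train where endocytosis dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import StimProtocol
from .segmentation import BoutonMap

logger = logging.getLogger(__name__)

__all__ = [
    "TraceSet",
    "CaSummary",
    "ols_slope",
    "extract_traces",
    "qc_filter",
    "exo_rate",
    "endo_trace",
    "endo_rate",
    "pool_plateau",
    "rate_table",
    "ca_summaries",
    "percent_inhibition",
]

KEPT = "kept"
EXCL_DRIFT = "excluded:baseline_drift"
EXCL_NH4CL = "excluded:nh4cl_invalid"


@dataclass
class TraceSet:
    """Per-bouton raw and normalized traces with provenance and QC status."""

    raw: np.ndarray  # (B, T)
    norm: np.ndarray  # (B, T), raw / F_NH4Cl
    f_nh4cl: np.ndarray  # (B,)
    qc_status: np.ndarray  # (B,) object array of status strings
    prep_id: str = ""
    field_id: str = ""
    group: str = ""
    bouton_ids: np.ndarray | None = None
    protocol: StimProtocol | None = field(repr=False, default=None)

    @property
    def n_boutons(self) -> int:
        return self.raw.shape[0]

    @property
    def kept(self) -> np.ndarray:
        return self.qc_status == KEPT

    def to_frame(self) -> pd.DataFrame:
        t = self.protocol.frame_times() if self.protocol is not None else np.arange(self.raw.shape[1])
        rows = []
        for b in range(self.n_boutons):
            rows.append(
                {
                    "prep_id": self.prep_id,
                    "field_id": self.field_id,
                    "group": self.group,
                    "bouton_id": self.bouton_ids[b] if self.bouton_ids is not None else b,
                    "qc_status": self.qc_status[b],
                    **{f"t{tt:g}": v for tt, v in zip(t, self.norm[b])},
                }
            )
        return pd.DataFrame(rows)


def ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of y on t and the fit's R^2."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    tc = t - t.mean()
    yc = y - y.mean()
    stt = np.dot(tc, tc)
    if stt == 0:
        raise ValueError("degenerate time axis")
    slope = np.dot(tc, yc) / stt
    ss_tot = np.dot(yc, yc)
    resid = yc - slope * tc
    r2 = 1.0 - np.dot(resid, resid) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def extract_traces(
    stack: np.ndarray,
    boutons: BoutonMap,
    protocol: StimProtocol,
    n_norm_frames: int = 5,
    prep_id: str = "",
    field_id: str = "",
    group: str = "",
) -> TraceSet:
    """Extract per-bouton mean-intensity traces and normalize by NH4Cl.

    Boutons whose NH4Cl plateau does not exceed their pre-stimulation
    baseline are marked ``excluded:nh4cl_invalid``.
    """
    stack = np.asarray(stack, dtype=float)
    post = protocol.post_nh4cl_frames()
    if post.size < n_norm_frames:
        raise ValueError(
            f"NH4Cl window has {post.size} frames; need >= {n_norm_frames}"
        )
    norm_frames = post[-n_norm_frames:]
    pre = protocol.prestim_frames()

    n_b = boutons.n_boutons
    n_t = stack.shape[0]
    raw = np.empty((n_b, n_t))
    flat = stack.reshape(n_t, -1)
    labels_flat = boutons.labels.ravel()
    for k in range(n_b):
        idx = np.nonzero(labels_flat == k + 1)[0]
        if idx.size == 0:
            raise ValueError(f"label {k + 1} has no pixels")
        raw[k] = flat[:, idx].mean(axis=1)

    f_nh4cl = raw[:, norm_frames].mean(axis=1)
    baseline = raw[:, pre].mean(axis=1)
    qc = np.full(n_b, KEPT, dtype=object)
    bad = f_nh4cl <= baseline
    qc[bad] = EXCL_NH4CL
    safe = np.where(f_nh4cl > 0, f_nh4cl, np.nan)
    norm = raw / safe[:, None]
    return TraceSet(
        raw=raw,
        norm=norm,
        f_nh4cl=f_nh4cl,
        qc_status=qc,
        prep_id=prep_id,
        field_id=field_id,
        group=group,
        bouton_ids=np.array([f"{field_id}_b{k}" for k in range(n_b)], dtype=object),
        protocol=protocol,
    )


def _pre_train2_frames(protocol: StimProtocol) -> np.ndarray:
    """Baseline window before the second train: post-Baf frames when Baf is
    present, otherwise the same number of frames as the pre-train-1 window."""
    t2 = protocol.train_windows()[1][0]
    if protocol.baf_time is not None:
        return protocol.frames_in(protocol.baf_time, t2)
    n = protocol.prestim_frames().size
    before = protocol.frames_in(0, t2)
    return before[-n:]


def qc_filter(traces: TraceSet, drift_tol: float = 0.10) -> TraceSet:
    """Flag traces with significant baseline drift between the two trains.

    A trace is excluded when the median baselines before the two trains
    differ by more than ``drift_tol`` normalized units, or when the OLS slope
    of the post-Baf segment, integrated over that segment, exceeds it.
    """
    protocol = traces.protocol
    if protocol is None or len(protocol.train_onsets) < 2:
        raise ValueError("qc_filter needs a two-train protocol")
    pre1 = protocol.prestim_frames()
    pre2 = _pre_train2_frames(protocol)
    t = protocol.frame_times()
    qc = traces.qc_status.copy()
    for b in range(traces.n_boutons):
        if qc[b] != KEPT:
            continue
        y = traces.norm[b]
        jump = abs(np.median(y[pre2]) - np.median(y[pre1]))
        drift = 0.0
        if pre2.size >= 3:
            slope, _ = ols_slope(t[pre2], y[pre2])
            drift = abs(slope) * (t[pre2][-1] - t[pre2][0])
        if jump > drift_tol or drift > drift_tol:
            qc[b] = EXCL_DRIFT
            logger.debug("bouton %d excluded: jump=%.3f drift=%.3f", b, jump, drift)
    out = TraceSet(**{**traces.__dict__, "qc_status": qc})
    return out


def _train_segment(trace: np.ndarray, protocol: StimProtocol, which: int) -> np.ndarray:
    """Frames from the train onset up to the next protocol event."""
    onset = protocol.onset_frame(which)
    windows = protocol.train_windows()
    if which + 1 < len(windows):
        end_t = windows[which + 1][0]
        if protocol.baf_time is not None and protocol.baf_time > windows[which][1]:
            end_t = min(end_t, protocol.baf_time)
    elif protocol.nh4cl_time is not None:
        end_t = protocol.nh4cl_time
    elif protocol.ionomycin_time is not None:
        end_t = protocol.ionomycin_time
    else:
        end_t = np.inf
    end = int(np.searchsorted(protocol.frame_times(), end_t - 1e-12, side="left"))
    return trace[onset:end]


def exo_rate(
    trace: np.ndarray,
    protocol: StimProtocol,
    train_index: int = 1,
    n_points: int = 6,
) -> tuple[float, float]:
    """Slope (per second) of the normalized rise at the start of a train.

    Uses the first ``n_points`` frames from the first frame at-or-after the
    train onset.  With Baf active during the train this is the exocytic rate.
    """
    onset = protocol.onset_frame(train_index)
    t0, t1 = protocol.train_windows()[train_index]
    times = protocol.frame_times()
    in_window = np.nonzero((times >= t0) & (times <= t1))[0]
    if in_window.size < n_points:
        raise ValueError(f"only {in_window.size} frames in train window; need {n_points}")
    idx = np.arange(onset, onset + n_points)
    if idx[-1] >= len(trace):
        raise ValueError("trace too short for rate window")
    return ols_slope(times[idx], np.asarray(trace)[idx])


def _onset_baseline(trace: np.ndarray, protocol: StimProtocol, which: int, n_ref: int = 3) -> float:
    onset = protocol.onset_frame(which)
    lo = max(0, onset - n_ref)
    return float(np.median(trace[lo:onset])) if onset > lo else float(trace[onset])


def endo_trace(
    first_train_trace: np.ndarray,
    baf_train_trace: np.ndarray,
    protocol: StimProtocol,
    baseline_reference: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Onset-aligned difference (Baf minus first train): cumulative endocytosis.

    Both inputs are full normalized traces of the same movie; each train's
    segment runs from its onset frame to the next protocol event, truncated
    to the shorter of the two.  By default each segment is referenced to its
    own immediate pre-onset baseline before subtraction, so residual baseline
    offsets between the trains do not masquerade as endocytosis.
    Returns (times from onset, difference).
    """
    first = np.asarray(first_train_trace, dtype=float)
    baf = np.asarray(baf_train_trace, dtype=float)
    seg1 = _train_segment(first, protocol, 0)
    seg2 = _train_segment(baf, protocol, 1)
    if baseline_reference:
        seg1 = seg1 - _onset_baseline(first, protocol, 0)
        seg2 = seg2 - _onset_baseline(baf, protocol, 1)
    n = min(seg1.size, seg2.size)
    if seg1.size != seg2.size:
        logger.debug("unequal train segments (%d vs %d); truncating", seg1.size, seg2.size)
    t_rel = np.arange(n) * protocol.frame_interval
    return t_rel, seg2[:n] - seg1[:n]


def endo_rate(
    diff: np.ndarray,
    protocol: StimProtocol,
    onset_offset_frames: int = 9,
    n_points: int = 6,
) -> tuple[float, float]:
    """Slope of the endocytosis difference trace late in the train.

    Fits ``n_points`` frames starting ``onset_offset_frames`` after the train
    onset (default 18 s into a 30 s train at 0.5 Hz).
    """
    diff = np.asarray(diff, dtype=float)
    if diff.size < onset_offset_frames + n_points:
        raise ValueError(
            f"difference trace has {diff.size} frames; need "
            f">= {onset_offset_frames + n_points}"
        )
    idx = np.arange(onset_offset_frames, onset_offset_frames + n_points)
    t = idx * protocol.frame_interval
    return ols_slope(t, diff[idx])


def pool_plateau(
    trace: np.ndarray,
    protocol: StimProtocol,
    n_frames: int = 10,
    slope_tol: float = 1e-3,
) -> tuple[float, bool]:
    """Releasable-pool estimate: baseline-subtracted mean of the last frames
    before NH4Cl under a depleting (long train + Baf) protocol.

    Returns (plateau, plateaued); ``plateaued`` is False when the terminal
    segment still has slope above ``slope_tol`` per second (reported anyway).
    """
    trace = np.asarray(trace, dtype=float)
    end_t = protocol.nh4cl_time if protocol.nh4cl_time is not None else np.inf
    in_proto = protocol.frames_in(0, end_t)
    last = in_proto[-n_frames:]
    if last.size < 2:
        raise ValueError("not enough frames for plateau estimate")
    baseline = np.median(trace[protocol.prestim_frames()])
    plateau = trace[last].mean() - baseline
    slope, _ = ols_slope(protocol.frame_times()[last], trace[last])
    plateaued = abs(slope) <= slope_tol
    if not plateaued:
        logger.warning("plateau slope %.2g/s exceeds tolerance %.2g/s", slope, slope_tol)
    return float(plateau), plateaued


def rate_table(
    traces: TraceSet,
    endo_offset_frames: int = 9,
    n_points: int = 6,
) -> pd.DataFrame:
    """Per-bouton rates and amplitudes (the unit of statistical analysis).

    Rows for excluded boutons carry NaN rates and their QC status so counts
    reconcile downstream.
    """
    protocol = traces.protocol
    pre1 = protocol.prestim_frames()
    pre2 = _pre_train2_frames(protocol)
    rows = []
    for b in range(traces.n_boutons):
        y = traces.norm[b]
        rec = {
            "prep_id": traces.prep_id,
            "field_id": traces.field_id,
            "group": traces.group,
            "bouton_id": traces.bouton_ids[b] if traces.bouton_ids is not None else b,
            "qc_status": traces.qc_status[b],
            "exo_rate": np.nan,
            "exo_r2": np.nan,
            "endo_rate": np.nan,
            "endo_r2": np.nan,
            "exo_amplitude": np.nan,
            "net_amplitude": np.nan,
        }
        if traces.qc_status[b] == KEPT:
            slope, r2 = exo_rate(y, protocol, train_index=1, n_points=n_points)
            _, diff = endo_trace(y, y, protocol)
            e_slope, e_r2 = endo_rate(diff, protocol, endo_offset_frames, n_points)
            seg1 = _train_segment(y, protocol, 0)
            seg2 = _train_segment(y, protocol, 1)
            rec.update(
                exo_rate=slope,
                exo_r2=r2,
                endo_rate=e_slope,
                endo_r2=e_r2,
                exo_amplitude=float(seg2.max() - np.median(y[pre2])),
                net_amplitude=float(seg1.max() - np.median(y[pre1])),
            )
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclass
class CaSummary:
    peaks: np.ndarray  # per-bouton normalized peak, NaN where excluded
    excluded: np.ndarray  # bool mask of boutons with invalid ionomycin level
    grid: np.ndarray
    cdf: np.ndarray

    def __post_init__(self):
        d = np.diff(self.cdf)
        assert np.all(d >= -1e-12), "CDF must be nondecreasing"


def ca_summaries(
    raw_traces: np.ndarray,
    protocol: StimProtocol,
    grid: np.ndarray | None = None,
    n_iono_frames: int = 3,
) -> CaSummary:
    """Per-bouton stimulation peaks normalized to the ionomycin maximum.

    peak_b = max_t (F_b(t) - F_base) / (F_iono - F_base) over the train
    windows; boutons with F_iono <= F_base are excluded (logged).
    """
    if protocol.ionomycin_time is None:
        raise ValueError("protocol has no ionomycin_time")
    raw = np.atleast_2d(np.asarray(raw_traces, dtype=float))
    pre = protocol.prestim_frames()
    iono = protocol.frames_in(protocol.ionomycin_time, np.inf)[-n_iono_frames:]
    train_frames = np.concatenate([protocol.train_frames(i) for i in range(len(protocol.train_onsets))])
    f_base = raw[:, pre].mean(axis=1)
    f_iono = raw[:, iono].mean(axis=1)
    excluded = f_iono <= f_base
    if excluded.any():
        logger.info("%d boutons excluded: ionomycin level below baseline", int(excluded.sum()))
    peaks = np.full(raw.shape[0], np.nan)
    ok = ~excluded
    peaks[ok] = (raw[ok][:, train_frames].max(axis=1) - f_base[ok]) / (f_iono[ok] - f_base[ok])
    valid = peaks[ok]
    if grid is None:
        hi = max(1.0, valid.max()) if valid.size else 1.0
        grid = np.linspace(0.0, hi, 256)
    cdf = (
        np.searchsorted(np.sort(valid), grid, side="right") / valid.size
        if valid.size
        else np.zeros_like(grid)
    )
    return CaSummary(peaks=peaks, excluded=excluded, grid=grid, cdf=cdf)


def percent_inhibition(mean_control: float, mean_condition: float) -> float:
    """100 * (1 - condition / control) for group-level mean rates."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (1.0 - mean_condition / mean_control)


def occlusion(inhibition_before: float, inhibition_after: float) -> float:
    """Change in percent inhibition after channel blockade."""
    return inhibition_before - inhibition_after
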