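"""Stimulation protocol description shared by the simulator and the analysis stages.

A protocol fixes the timing skeleton of a recording: frame interval, one or
more action-potential (AP) train windows, and the optional bafilomycin (Baf),
NH4Cl and ionomycin events.  All times are in seconds from the start of the
recording.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator


class StimProtocol(BaseModel):
    """Timing of stimulation trains and pharmacology events.

    The default protocol is two consecutive trains of 300 APs at 10 Hz imaged
    at 0.5 Hz, with Baf applied 30 s before the second train and NH4Cl at the
    end of the series.
    """

    frame_interval: float = 2.0
    train_onsets: list[float] = [60.0, 390.0]
    train_n_aps: list[int] = [300, 300]
    train_freq: float = 10.0
    baf_time: float | None = 360.0
    nh4cl_time: float | None = 440.0
    ionomycin_time: float | None = None
    total_duration: float = 470.0

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_windows(self) -> "StimProtocol":
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if len(self.train_onsets) != len(self.train_n_aps):
            raise ValueError("train_onsets and train_n_aps must have equal length")
        if self.train_freq <= 0:
            raise ValueError("train_freq must be positive")
        windows = self.train_windows()
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("train windows must be disjoint and ordered")
        for t0, t1 in windows:
            if t0 < 0 or t1 > self.total_duration:
                raise ValueError("train window outside total_duration")
        if self.baf_time is not None and len(windows) >= 2:
            if self.baf_time > windows[1][0]:
                raise ValueError("baf_time must not follow the second train onset")
        last_train_end = windows[-1][1] if windows else 0.0
        for name in ("nh4cl_time", "ionomycin_time"):
            t = getattr(self, name)
            if t is not None:
                if t < last_train_end:
                    raise ValueError(f"{name} must follow all trains")
                if t > self.total_duration:
                    raise ValueError(f"{name} outside total_duration")
        return self

    # -- derived timing helpers -------------------------------------------

    def train_windows(self) -> list[tuple[float, float]]:
        """(onset, end) of every AP train, in seconds."""
        return [
            (t0, t0 + n / self.train_freq)
            for t0, n in zip(self.train_onsets, self.train_n_aps)
        ]

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.total_duration / self.frame_interval)) + 1

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frames_in(self, t0: float, t1: float) -> np.ndarray:
        """Indices of frames with t0 <= t < t1."""
        t = self.frame_times()
        return np.nonzero((t >= t0) & (t < t1))[0]

    def prestim_frames(self) -> np.ndarray:
        return self.frames_in(0.0, self.train_onsets[0])

    def train_frames(self, which: int) -> np.ndarray:
        t0, t1 = self.train_windows()[which]
        # include the frame landing exactly on the train end
        t = self.frame_times()
        return np.nonzero((t >= t0) & (t <= t1))[0]

    def onset_frame(self, which: int) -> int:
        """Index of the first frame at-or-after the train onset."""
        t0 = self.train_windows()[which][0]
        return int(np.searchsorted(self.frame_times(), t0, side="left"))

    def post_nh4cl_frames(self) -> np.ndarray:
        if self.nh4cl_time is None:
            raise ValueError("protocol has no nh4cl_time")
        return self.frames_in(self.nh4cl_time, np.inf)
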