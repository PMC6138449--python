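"""Labeled multichannel time-series container for one resting-state run.

A run holds a time × channel matrix in which every channel is tagged with a
role: ``parcel`` (gray-matter parcel-averaged signal), ``WM``/``CSF``
(tissue reference channels), ``global`` (whole-brain mean), plus six
motion realignment parameters, a framewise-displacement (FD) trace and a
censoring mask.  Denoising operators act on copies and append to a step
trace so that the executed order is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RunTimeSeries", "RUN_LABELS", "SIGNAL_ROLES"]

RUN_LABELS = ("REST1_LR", "REST1_RL", "REST2_LR", "REST2_RL")

#: channel roles carrying BOLD-like signal (as opposed to motion metadata)
SIGNAL_ROLES = ("parcel", "WM", "CSF", "global")


@dataclass
class RunTimeSeries:
    subject_id: str
    run_label: str
    channels: np.ndarray            # time x n_channels
    channel_roles: list[str]        # per-channel tag
    motion_params: np.ndarray       # time x 6
    fd: np.ndarray                  # time, mm
    tr_s: float = 0.72
    censor_mask: np.ndarray = field(default=None)  # True = retained
    trace: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=float)
        t = self.channels.shape[0]
        if len(self.channel_roles) != self.channels.shape[1]:
            raise ValueError("channel_roles length must match channel count")
        if self.motion_params.shape != (t, 6):
            raise ValueError("motion_params must be time x 6")
        if self.fd.shape != (t,):
            raise ValueError("fd length must match time")
        if np.any(self.fd < 0):
            raise ValueError("fd must be non-negative")
        if self.censor_mask is None:
            self.censor_mask = np.ones(t, dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape != (t,):
            raise ValueError("censor_mask length must match time")

    @property
    def n_timepoints(self) -> int:
        return self.channels.shape[0]

    def role_idx(self, *roles: str) -> np.ndarray:
        """Column indices of channels whose role is in `roles`."""
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r in roles],
            dtype=int,
        )

    def parcels(self) -> np.ndarray:
        return self.channels[:, self.role_idx("parcel")]

    def with_channels(self, channels: np.ndarray, step: str | None = None,
                      **kw) -> "RunTimeSeries":
        """Copy with replaced channel data, appending `step` to the trace."""
        new = replace(self, channels=np.array(channels, dtype=float),
                      channel_roles=list(self.channel_roles),
                      trace=list(self.trace), **kw)
        if step:
            new.trace.append(step)
        return new

    def dvars(self) -> np.ndarray:
        """Per-timepoint variance of the backward-differenced parcel signal.

        The first time point, which has no backward difference, is assigned
        a value of 0 so it is never censored by the DVARS criterion.
        """
        p = self.parcels()
        d = np.diff(p, axis=0)
        out = np.zeros(self.n_timepoints)
        out[1:] = d.var(axis=1)
        return out
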