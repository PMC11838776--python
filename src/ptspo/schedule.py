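"""Dynamic PET frame schedules.

A schedule is the list of frame start times and durations (minutes) of a
dynamic acquisition. Frames must be non-overlapping and in temporal order;
gaps are allowed. Mid-frame times are the reference abscissa for every
TAC-level computation in the package (interpolation, K1 fitting, plotting).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ScheduleError

__all__ = ["FrameSchedule", "PRESET_SCHEDULES"]

_SPEC_TOKEN = re.compile(r"^\s*(\d+)\s*x\s*([0-9.]+)\s*(s|sec|min|m)\s*$")


@dataclass(frozen=True)
class FrameSchedule:
    """Frame start times and durations of a dynamic acquisition, in minutes."""

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.start_times, dtype=float)
        durs = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", starts)
        object.__setattr__(self, "durations", durs)
        if starts.ndim != 1 or durs.ndim != 1 or starts.size != durs.size:
            raise ScheduleError("start_times and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ScheduleError("schedule needs at least one frame")
        if np.any(durs <= 0):
            raise ScheduleError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ScheduleError("frame start times must be strictly increasing")
        # non-overlap: frame i must end at or before frame i+1 starts
        ends = starts + durs
        if np.any(ends[:-1] - starts[1:] > 1e-9):
            raise ScheduleError("frames overlap")

    # -- derived quantities -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.start_times.size)

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def total_minutes(self) -> float:
        return float(self.end_times[-1])

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_durations(cls, durations, start: float = 0.0) -> "FrameSchedule":
        durs = np.asarray(durations, dtype=float)
        starts = start + np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def from_string(cls, spec: str) -> "FrameSchedule":
        """Parse a compact frame spec like ``"8x15s, 3x1min, 5x2min"``."""
        durations: list[float] = []
        for token in spec.split(","):
            m = _SPEC_TOKEN.match(token)
            if m is None:
                raise ScheduleError(f"cannot parse frame token {token!r}")
            count, value, unit = int(m.group(1)), float(m.group(2)), m.group(3)
            minutes = value / 60.0 if unit in ("s", "sec") else value
            durations.extend([minutes] * count)
        return cls.from_durations(durations)

    # -- helpers ------------------------------------------------------------
    def frames_within(self, window_minutes: float) -> np.ndarray:
        """Indices of frames whose mid-time is <= ``window_minutes``."""
        return np.flatnonzero(self.mid_times <= window_minutes + 1e-12)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameSchedule)
            and np.array_equal(self.start_times, other.start_times)
            and np.array_equal(self.durations, other.durations)
        )

    def __hash__(self):
        return hash((self.start_times.tobytes(), self.durations.tobytes()))


#: Acquisition presets used throughout the package. Human PBR28 protocols are
#: 90-min, 26-frame; the shortened 60-min variant drops the last three 10-min
#: frames; DPA-714 and PK11195 are 60-min protocols.
PRESET_SCHEDULES: dict[str, FrameSchedule] = {
    "pbr28_90min": FrameSchedule.from_string("8x15s, 3x1min, 5x2min, 5x5min, 5x10min"),
    "pbr28_60min": FrameSchedule.from_string("8x15s, 3x1min, 5x2min, 5x5min, 2x10min"),
    "dpa714_60min": FrameSchedule.from_string("1x1min, 8x15s, 3x1min, 5x2min, 9x5min"),
    "pk11195_60min": FrameSchedule.from_string("4x15s, 4x1min, 7x5min, 2x10min"),
}
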