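"""Dynamic-PET frame schedules.

A frame schedule is the ordered list of acquisition frame start times and
durations of a dynamic scan.  All downstream operations (time-activity curve
extraction, kinetic-class resampling, time-window restriction) are defined in
terms of frame *mid-times*, the standard convention for associating one
activity value with one frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["FrameSchedule", "make_frame_schedule", "builtin_schedules"]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered frame timing of a dynamic scan.

    Parameters
    ----------
    starts_s
        Frame start times in seconds from injection, strictly increasing.
    durations_s
        Frame durations in seconds, all positive.
    """

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        if starts.ndim != 1 or starts.size == 0:
            raise ValueError("schedule needs at least one frame")
        if starts.shape != durs.shape:
            raise ValueError("starts and durations must have equal length")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if starts.size > 1 and np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)

    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.mid_times_s / 60.0

    @property
    def total_duration_s(self) -> float:
        return float(self.ends_s[-1] - self.starts_s[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.starts_s.shape == other.starts_s.shape
            and bool(np.array_equal(self.starts_s, other.starts_s))
            and bool(np.array_equal(self.durations_s, other.durations_s))
        )

    def __hash__(self) -> int:
        return hash((self.starts_s.tobytes(), self.durations_s.tobytes()))

    def to_dict(self) -> dict:
        return {
            "starts_s": self.starts_s.tolist(),
            "durations_s": self.durations_s.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["starts_s"], float), np.asarray(d["durations_s"], float))


def make_frame_schedule(spec: Iterable[Sequence[float]]) -> FrameSchedule:
    """Build a contiguous schedule from ``(count, duration_s)`` blocks.

    The first frame starts at t = 0 and each frame begins where the previous
    one ends, e.g. ``[(10, 30), (5, 60)]`` gives ten 30-s frames followed by
    five 60-s frames.
    """
    blocks = list(spec)
    if not blocks:
        raise ValueError("empty schedule spec")
    durations: list[float] = []
    for count, dur in blocks:
        if int(count) != count or count < 1:
            raise ValueError(f"frame count must be a positive integer, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    durs = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return FrameSchedule(starts, durs)


def builtin_schedules() -> dict[str, FrameSchedule]:
    """The three acquisition protocols the kinetic classes were defined on.

    ``hammersmith_31``
        95-min breast-cancer protocol, 31 frames
        (10x30, 5x60, 5x120, 5x180, 6x600 s).
    ``vumc_dev_40``
        60.5-min NSCLC development protocol, 40 frames
        (1x30, 6x5, 6x10, 3x20, 5x30, 5x60, 8x150, 6x300 s).
    ``vumc_trt_39``
        60-min NSCLC test-retest protocol, 39 frames
        (6x5, 6x10, 3x20, 5x30, 5x60, 8x150, 6x300 s).
    """
    return {
        "hammersmith_31": make_frame_schedule(
            [(10, 30), (5, 60), (5, 120), (5, 180), (6, 600)]
        ),
        "vumc_dev_40": make_frame_schedule(
            [(1, 30), (6, 5), (6, 10), (3, 20), (5, 30), (5, 60), (8, 150), (6, 300)]
        ),
        "vumc_trt_39": make_frame_schedule(
            [(6, 5), (6, 10), (3, 20), (5, 30), (5, 60), (8, 150), (6, 300)]
        ),
    }
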