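"""Observation-window schedule around a catastrophic turnover event.

Networks are built from fixed-length observation windows (default five days).
Windows are indexed 1..n_pre (pre-event) and n_pre+1..n_pre+n_post
(post-event); the event itself sits in an excluded gap between the last
pre-event and the first post-event window, so no window ever contains the
event instant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

DAY_S = 86_400.0


class ScheduleError(ValueError):
    """Raised when a window schedule is inconsistent with the event time."""


@dataclass(frozen=True)
class TimeWindow:
    """One observation window.

    Parameters
    ----------
    index : int
        1-based window index; pre-event windows come first.
    start, end : float
        Window span in epoch seconds, half-open ``[start, end)``.
    phase : str
        ``"pre"`` or ``"post"`` relative to the event.
    """

    index: int
    start: float
    end: float
    phase: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ScheduleError(f"window {self.index}: end <= start")
        if self.phase not in ("pre", "post"):
            raise ScheduleError(f"window {self.index}: phase {self.phase!r}")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class WindowSchedule:
    """Ordered, non-overlapping windows with an excluded event gap."""

    windows: tuple[TimeWindow, ...]
    event_time: float

    def __post_init__(self) -> None:
        idx = [w.index for w in self.windows]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ScheduleError("window indices must be unique and ordered")
        for a, b in zip(self.windows, self.windows[1:]):
            if b.start < a.end:
                raise ScheduleError(f"windows {a.index} and {b.index} overlap")
        for w in self.windows:
            if w.start <= self.event_time < w.end:
                raise ScheduleError(
                    f"event time {self.event_time} falls inside window {w.index}; "
                    "windows must exclude the event gap"
                )
        pre = [w for w in self.windows if w.phase == "pre"]
        post = [w for w in self.windows if w.phase == "post"]
        if pre and max(w.end for w in pre) > self.event_time:
            raise ScheduleError("a pre-event window ends after the event")
        if post and min(w.start for w in post) < self.event_time:
            raise ScheduleError("a post-event window starts before the event")

    def __iter__(self) -> Iterator[TimeWindow]:
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __getitem__(self, index: int) -> TimeWindow:
        """Look up a window by its schedule index (not list position)."""
        for w in self.windows:
            if w.index == index:
                return w
        raise KeyError(f"no window with index {index}")

    @property
    def indices(self) -> list[int]:
        return [w.index for w in self.windows]

    @property
    def pre_indices(self) -> list[int]:
        return [w.index for w in self.windows if w.phase == "pre"]

    @property
    def post_indices(self) -> list[int]:
        return [w.index for w in self.windows if w.phase == "post"]

    @property
    def last_pre_index(self) -> int:
        """Index of the baseline window (immediately before the event)."""
        pre = self.pre_indices
        if not pre:
            raise ScheduleError("schedule has no pre-event window")
        return pre[-1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "event_time": self.event_time,
            "windows": [
                {"index": w.index, "start": w.start, "end": w.end, "phase": w.phase}
                for w in self.windows
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "WindowSchedule":
        payload = json.loads(Path(path).read_text())
        return cls(
            windows=tuple(TimeWindow(**w) for w in payload["windows"]),
            event_time=payload["event_time"],
        )


def build_schedule(
    n_pre: int,
    n_post: int,
    window_length_days: float = 5.0,
    event_gap_days: float = 2.0,
    origin: float = 0.0,
) -> WindowSchedule:
    """Lay out ``n_pre`` pre-event and ``n_post`` post-event windows.

    Consecutive windows are back to back except for an excluded gap of
    ``event_gap_days`` (the "event weekend") between the last pre-event and
    first post-event window.  The event time is placed at the middle of
    that gap.
    """
    if n_pre < 1 or n_post < 1:
        raise ScheduleError("need at least one pre- and one post-event window")
    length = window_length_days * DAY_S
    gap = event_gap_days * DAY_S
    windows = []
    t = origin
    for i in range(1, n_pre + 1):
        windows.append(TimeWindow(i, t, t + length, "pre"))
        t += length
    event_time = t + gap / 2.0
    t += gap
    for i in range(n_pre + 1, n_pre + n_post + 1):
        windows.append(TimeWindow(i, t, t + length, "post"))
        t += length
    return WindowSchedule(windows=tuple(windows), event_time=event_time)
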