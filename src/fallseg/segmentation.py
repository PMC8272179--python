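"""Window configurations around a potential fall event and segment cutting.

Three coupled windows are placed relative to the event instant t0: the
pre-impact window W2 on [t0-t1, t0-t3), the impact window W1 on
[t0-t3, t0+t4) and the post-impact window W3 on [t0+t4, t0+t2).  The four
timing parameters are swept over a grid (t1, t2 from 0 to 4 s in 0.5 s steps;
t3 from 0 to t1 and t4 from 0 to t2 in 0.25 s steps), which yields 6560
non-degenerate configurations.  Depending on which windows are non-empty a
configuration uses one, two or three windows; the class criteria are:

========== =====================================================
W1         t1 = t3 and t2 = t4
W1+W2      t2 = t4 and t1 > t3 and (t3 > 0 or t4 > 0)
W1+W3      t1 = t3 and t2 > t4 and (t3 > 0 or t4 > 0)
W2+W3      t3 = 0 and t4 = 0 and t1 > 0 and t2 > 0
W1+W2+W3   t1 > 0, t2 > 0, t1 > t3, t2 > t4 and (t3 > 0 or t4 > 0)
========== =====================================================

Two further single-window classes fall through these criteria and are
classified here explicitly: W2 alone (t1 > 0, t2 = t3 = t4 = 0) and W3 alone
(t2 > 0, t1 = t3 = t4 = 0), eight grid tuples each.  The all-zero tuple is
degenerate (no window has any samples) and is the single grid point excluded
from the sweep.

Window boundaries are half-open in time, so adjacent windows never share a
sample; the t0 sample lands in W1 when t4 > 0, otherwise in W3 when W3 is
present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .events import EventCenteredRecord, _samples

DEGENERATE = "degenerate"
#: the five multi-criteria classes of the sweep, in canonical order
TABLE_CLASSES = ("W1", "W1+W2", "W1+W3", "W2+W3", "W1+W2+W3")
#: all non-degenerate classes, including the two fall-through singletons
WINDOW_CLASSES = TABLE_CLASSES + ("W2", "W3")

#: time-ordered window membership of each class
_CLASS_WINDOWS = {
    "W1": ("W1",),
    "W1+W2": ("W2", "W1"),
    "W1+W3": ("W1", "W3"),
    "W2+W3": ("W2", "W3"),
    "W1+W2+W3": ("W2", "W1", "W3"),
    "W2": ("W2",),
    "W3": ("W3",),
}


def classify_config(t1: float, t2: float, t3: float, t4: float) -> str:
    """Window class of a (t1, t2, t3, t4) tuple (criteria applied in order)."""
    if not (0 <= t3 <= t1 and 0 <= t4 <= t2):
        raise ValueError(f"invalid tuple: need 0 <= t3 <= t1 and 0 <= t4 <= t2, "
                         f"got ({t1}, {t2}, {t3}, {t4})")
    if t1 == 0 and t2 == 0:
        return DEGENERATE
    if t1 == t3 and t2 == t4:
        return "W1"
    if t2 == t4 and t1 > t3 and (t3 > 0 or t4 > 0):
        return "W1+W2"
    if t1 == t3 and t2 > t4 and (t3 > 0 or t4 > 0):
        return "W1+W3"
    if t3 == 0 and t4 == 0 and t1 > 0 and t2 > 0:
        return "W2+W3"
    if t1 > 0 and t2 > 0 and t1 > t3 and t2 > t4 and (t3 > 0 or t4 > 0):
        return "W1+W2+W3"
    if t1 > 0 and t2 == 0 and t3 == 0:
        return "W2"
    if t2 > 0 and t1 == 0 and t4 == 0:
        return "W3"
    raise ValueError(f"unclassifiable tuple ({t1}, {t2}, {t3}, {t4})")


@dataclass(frozen=True)
class WindowConfig:
    """One (t1, t2, t3, t4) timing tuple with its window class."""

    t1: float
    t2: float
    t3: float
    t4: float
    window_class: str

    @classmethod
    def from_times(cls, t1: float, t2: float, t3: float, t4: float) -> "WindowConfig":
        return cls(t1, t2, t3, t4, classify_config(t1, t2, t3, t4))

    @property
    def windows(self) -> tuple[str, ...]:
        """Non-empty windows of this configuration, in time order."""
        return _CLASS_WINDOWS[self.window_class]

    def spans(self) -> dict[str, tuple[float, float]]:
        """Signed time offsets (start, end) of each non-empty window."""
        all_spans = {
            "W2": (-self.t1, -self.t3),
            "W1": (-self.t3, self.t4),
            "W3": (self.t4, self.t2),
        }
        return {w: all_spans[w] for w in self.windows}


def enumerate_configs(
    t_max: float = 4.0, outer_step: float = 0.5, inner_step: float = 0.25
) -> list[WindowConfig]:
    """All grid tuples except the all-zero one, tagged with their class.

    t1 and t2 run from 0 to ``t_max`` in ``outer_step`` increments; t3 runs
    from 0 to t1 and t4 from 0 to t2 in ``inner_step`` increments.  With the
    defaults this yields exactly 6560 configurations.
    """
    def _units(value: float, unit: float) -> int:
        k = value / unit
        if abs(k - round(k)) > 1e-9:
            raise ValueError(
                f"grid steps must divide t_max: {value} not a multiple of {unit}"
            )
        return int(round(k))

    if t_max <= 0 or outer_step <= 0 or inner_step <= 0:
        raise ValueError("t_max and steps must be positive")
    n_outer = _units(t_max, outer_step)
    outer_units = _units(outer_step, inner_step)

    def _grid_outer() -> list[float]:
        return [i * outer_step for i in range(n_outer + 1)]

    configs = []
    for t1 in _grid_outer():
        n3 = _units(t1, inner_step)
        for t2 in _grid_outer():
            n4 = _units(t2, inner_step)
            for i3 in range(n3 + 1):
                t3 = i3 * inner_step
                for i4 in range(n4 + 1):
                    t4 = i4 * inner_step
                    if t1 == 0 and t2 == 0 and t3 == 0 and t4 == 0:
                        continue
                    configs.append(WindowConfig.from_times(t1, t2, t3, t4))
    return configs


def configs_to_frame(configs: Sequence[WindowConfig]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t1": c.t1,
                "t2": c.t2,
                "t3": c.t3,
                "t4": c.t4,
                "window_class": c.window_class,
            }
            for c in configs
        ]
    )


@dataclass
class Segment:
    """A tri-axial excerpt of one window cut from an event-centered record."""

    window_id: str
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs_hz: float
    parent_id: str

    @property
    def n(self) -> int:
        return len(self.ax)


def window_bounds(
    cfg: WindowConfig, fs_hz: float
) -> dict[str, tuple[int, int]]:
    """Sample offsets (start, end) relative to the event index, half-open."""
    return {
        w: (_samples(a, fs_hz), _samples(b, fs_hz)) for w, (a, b) in cfg.spans().items()
    }


def extract_segments(
    ecr: EventCenteredRecord, cfg: WindowConfig
) -> list[Segment]:
    """Cut the configuration's windows out of an event-centered record.

    Raises if t1 or t2 exceeds the record's margin or if a window of the
    configuration's class would be empty at this sampling rate.
    """
    if cfg.window_class == DEGENERATE:
        raise ValueError("cannot extract segments for the degenerate configuration")
    mid = ecr.center_index
    n = ecr.n
    segments = []
    for window_id, (a, b) in window_bounds(cfg, ecr.fs_hz).items():
        lo, hi = mid + a, mid + b
        if lo < 0 or hi > n:
            raise ValueError(
                f"window {window_id} [{a}, {b}) exceeds the +/-{mid}-sample margin "
                f"of event {ecr.event_id}"
            )
        if hi <= lo:
            raise ValueError(
                f"window {window_id} of class {cfg.window_class} is empty at "
                f"fs={ecr.fs_hz} Hz (t=({cfg.t1}, {cfg.t2}, {cfg.t3}, {cfg.t4}))"
            )
        segments.append(
            Segment(
                window_id=window_id,
                ax=ecr.ax[lo:hi],
                ay=ecr.ay[lo:hi],
                az=ecr.az[lo:hi],
                fs_hz=ecr.fs_hz,
                parent_id=ecr.event_id,
            )
        )
    return segments
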