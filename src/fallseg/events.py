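"""Potential-fall-event detection, labeling, threshold calibration and
event-centered record extraction.

A *potential fall event* is a sample whose AVM exceeds a threshold and that is
followed by a quiet period (default 2.5 s) in which no sample reaches the
threshold again: falling is a one-off event, so repetitive activities such as
walking keep re-crossing the threshold and never qualify.  Each qualifying
event becomes the anchor ``t0`` of an *event-centered record*, the +/- margin
(default 4 s) excerpt on which segmentation windows are later placed.

In fall records only the events at or after the global AVM maximum are true
falls; earlier events are triggered by activity preceding the fall and are
labeled ADL.  The per-dataset detection threshold is calibrated as the largest
grid value (0-5 g, 0.005 g steps) for which every fall record still yields at
least one fall-labeled event; the largest such threshold minimizes false
alarms on ADL data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .records import ADL, FALL, AccelRecord
from .signal import AVMSeries, compute_avm


@dataclass(frozen=True)
class DetectorConfig:
    """Detector parameters.

    ``allow_truncated_quiet`` controls the boundary case of events close to
    the record end: when True (default) a quiet window cut short by the end of
    the record still counts as quiet (fall records typically end in rest), so
    the trailing above-threshold sample of a record always qualifies; when
    False the full quiet window must fit inside the record.
    """

    threshold: float
    quiet_period_s: float = 2.5
    margin_s: float = 4.0
    allow_truncated_quiet: bool = True

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.quiet_period_s <= 0:
            raise ValueError("quiet_period_s must be > 0")
        if self.margin_s < 0:
            raise ValueError("margin_s must be >= 0")


@dataclass(frozen=True)
class PotentialEvent:
    """A detected impact-like instant in one record."""

    record_id: str
    t0_index: int
    t0_time_s: float
    truth_label: str | None = None


@dataclass
class EventCenteredRecord:
    """The +/- margin excerpt around one potential event.

    The event sample sits at ``center_index`` (the excerpt midpoint); the
    excerpt holds ``2 * margin_s * fs + 1`` samples.
    """

    event: PotentialEvent
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs_hz: float
    label: str
    activity_type: str

    @property
    def record_id(self) -> str:
        return self.event.record_id

    @property
    def event_id(self) -> str:
        return f"{self.event.record_id}:{self.event.t0_index}"

    @property
    def n(self) -> int:
        return len(self.ax)

    @property
    def center_index(self) -> int:
        return self.n // 2


def _samples(t_s: float, fs_hz: float) -> int:
    """Symmetric time-to-sample conversion used throughout the pipeline."""
    return int(round(t_s * fs_hz))


def _forward_window_max(x: np.ndarray, w: int) -> np.ndarray:
    """max over the quiet window (i, i+w], truncated at the record end.

    Positions whose window is entirely past the end get -inf (vacuously
    quiet).
    """
    n = len(x)
    padded = np.concatenate([x[1:], np.full(w, -np.inf)])
    return sliding_window_view(padded, w)[:n].max(axis=1)


def detect_events(avm: AVMSeries, cfg: DetectorConfig) -> list[PotentialEvent]:
    """Return every sample that crosses the threshold and is followed by quiet.

    A sample ``i`` qualifies iff ``AVM[i] > threshold`` (strict) and every
    sample in the quiet window ``(i, i + quiet_period_s * fs]`` is strictly
    below the threshold.  Within a run of consecutive above-threshold samples
    only the last can therefore qualify.  Events are returned in increasing
    index order.
    """
    x = np.asarray(avm.values, dtype=float)
    n = len(x)
    if n == 0:
        return []
    w = _samples(cfg.quiet_period_s, avm.fs_hz)
    if w < 1:
        raise ValueError(
            "quiet window shorter than one sample "
            f"(quiet_period_s={cfg.quiet_period_s}, fs={avm.fs_hz})"
        )
    ok = (x > cfg.threshold) & (_forward_window_max(x, w) < cfg.threshold)
    if not cfg.allow_truncated_quiet:
        ok &= np.arange(n) + w <= n - 1
    return [
        PotentialEvent(avm.record_id, int(i), i / avm.fs_hz)
        for i in np.nonzero(ok)[0]
    ]


def label_events(
    record: AccelRecord,
    events: Sequence[PotentialEvent],
    avm: AVMSeries | None = None,
) -> list[PotentialEvent]:
    """Attach truth labels: fall-record events at/after the global AVM maximum
    are falls, everything else (including all events in ADL records) is ADL.

    Ties at the maximum break to the first maximal sample.
    """
    if record.class_label == ADL:
        return [replace(e, truth_label=ADL) for e in events]
    if avm is None:
        avm = compute_avm(record)
    peak = int(np.argmax(avm.values))
    return [
        replace(e, truth_label=FALL if e.t0_index >= peak else ADL) for e in events
    ]


class NoFeasibleThreshold(RuntimeError):
    """Raised when even the lowest grid threshold misses some fall record."""


def calibrate_threshold(
    fall_records: Sequence[AccelRecord],
    grid_lo: float = 0.0,
    grid_hi: float = 5.0,
    grid_step: float = 0.005,
    cfg: DetectorConfig | None = None,
) -> float:
    """Largest grid threshold detecting >= 1 true fall event in every record.

    The grid runs from ``grid_lo`` to ``grid_hi`` in ``grid_step`` increments.
    For each fall record the set of feasible thresholds is assembled from the
    candidate samples at or after the AVM maximum: sample ``i`` yields a fall
    event at threshold ``th`` iff ``quiet_max(i) < th < AVM[i]``.  Raises
    :class:`NoFeasibleThreshold` if even ``grid_lo`` fails on some record.
    """
    if len(fall_records) == 0:
        raise ValueError("calibrate_threshold: empty fall record collection")
    if not grid_lo < grid_hi:
        raise ValueError("grid_lo must be < grid_hi")
    if not grid_step > 0:
        raise ValueError("grid_step must be > 0")
    quiet_s = cfg.quiet_period_s if cfg is not None else 2.5
    allow_trunc = cfg.allow_truncated_quiet if cfg is not None else True

    n_steps = int(round((grid_hi - grid_lo) / grid_step))
    grid = grid_lo + grid_step * np.arange(n_steps + 1)
    all_pass = np.ones(len(grid), dtype=bool)
    for rec in fall_records:
        if rec.class_label != FALL:
            raise ValueError(f"record {rec.record_id!r} is not a fall record")
        avm = compute_avm(rec)
        x = avm.values
        w = _samples(quiet_s, rec.fs_hz)
        w = max(w, 1)
        fmax = _forward_window_max(x, w)
        peak = int(np.argmax(x))
        cand = np.arange(peak, len(x))
        if not allow_trunc:
            cand = cand[cand + w <= len(x) - 1]
        # threshold th yields a fall event at candidate i iff fmax[i] < th < x[i]
        lo = fmax[cand]
        hi = x[cand]
        passes = ((grid[None, :] > lo[:, None]) & (grid[None, :] < hi[:, None])).any(
            axis=0
        )
        all_pass &= passes
        if not all_pass.any():
            raise NoFeasibleThreshold(
                f"no grid threshold detects a fall in record {rec.record_id!r}"
            )
    return float(grid[np.nonzero(all_pass)[0][-1]])


def build_event_centered(
    records: Sequence[AccelRecord], cfg: DetectorConfig
) -> tuple[list[EventCenteredRecord], pd.DataFrame]:
    """Detect, label and excerpt every event with enough data on both sides.

    Events with fewer than ``margin_s`` seconds of data before or after t0 are
    dropped.  Returns the retained event-centered records plus a one-row
    retention table (columns ``margin_s, n_fall, n_adl`` -- counts of retained
    records per truth label).
    """
    ecrs: list[EventCenteredRecord] = []
    retained = {FALL: 0, ADL: 0}
    for rec in records:
        avm = compute_avm(rec)
        events = label_events(rec, detect_events(avm, cfg), avm)
        m = _samples(cfg.margin_s, rec.fs_hz)
        for ev in events:
            if ev.t0_index - m < 0 or ev.t0_index + m > rec.n - 1:
                continue
            sl = slice(ev.t0_index - m, ev.t0_index + m + 1)
            ecrs.append(
                EventCenteredRecord(
                    event=ev,
                    ax=rec.ax[sl].copy(),
                    ay=rec.ay[sl].copy(),
                    az=rec.az[sl].copy(),
                    fs_hz=rec.fs_hz,
                    label=ev.truth_label,
                    activity_type=rec.activity_type,
                )
            )
            retained[ev.truth_label] += 1
    table = pd.DataFrame(
        [
            {
                "margin_s": cfg.margin_s,
                "n_fall": retained[FALL],
                "n_adl": retained[ADL],
            }
        ]
    )
    return ecrs, table


def retention_table(
    records: Sequence[AccelRecord],
    cfg: DetectorConfig,
    margins_s: Sequence[float] = (0.0, 4.0, 5.0),
) -> pd.DataFrame:
    """Retained event counts per class for several margin requirements.

    With margin 0 every detected event is retained; raising the margin can
    only drop events, so counts are non-increasing down the table.
    """
    rows = []
    for m in margins_s:
        _, row = build_event_centered(records, replace(cfg, margin_s=m))
        rows.append(row)
    return pd.concat(rows, ignore_index=True)


def events_to_frame(events: Sequence[PotentialEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "record_id": e.record_id,
                "t0_index": e.t0_index,
                "t0_time_s": e.t0_time_s,
                "label": e.truth_label,
            }
            for e in events
        ],
        columns=["record_id", "t0_index", "t0_time_s", "label"],
    )
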