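"""Acceleration vector magnitude (AVM) and record-level quality control.

The AVM combines the three accelerometer axes into a single orientation-free
sample stream, ``AVM[i] = sqrt(ax[i]^2 + ay[i]^2 + az[i]^2)`` in g units.
A sensor at rest reads 1 g regardless of orientation, which anchors the
quality-control rules: a record of either class whose AVM ever exceeds 30 g
is physically implausible for +/-8 g or +/-16 g accelerometers, and a *fall*
record whose AVM never reaches 1.1 g cannot contain an impact (real-world
falls show peaks of at least ~1.6 g).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import FALL, AccelRecord

#: QC bound: any record with max AVM strictly above this is excluded.
QC_AVM_MAX_G = 30.0
#: QC bound: fall records with max AVM strictly below this are excluded.
QC_FALL_PEAK_MIN_G = 1.1

REASON_OVER = "avm_over_30g"
REASON_UNDER = "fall_peak_under_1p1g"


@dataclass
class AVMSeries:
    """Per-sample acceleration vector magnitude of one record (g units)."""

    values: np.ndarray
    fs_hz: float
    record_id: str

    def __len__(self) -> int:
        return len(self.values)


def compute_avm(record: AccelRecord) -> AVMSeries:
    """Root-of-sum-of-squares of the three axes, sample by sample.

    Raises
    ------
    ValueError
        If any axis sample is non-finite; the error names the record and
        the first offending sample index.
    """
    stacked = np.stack([record.ax, record.ay, record.az])
    finite = np.isfinite(stacked)
    if not finite.all():
        idx = int(np.nonzero(~finite.all(axis=0))[0][0])
        raise ValueError(
            f"record {record.record_id!r}: non-finite sample at index {idx}"
        )
    values = np.sqrt(record.ax**2 + record.ay**2 + record.az**2)
    return AVMSeries(values=values, fs_hz=record.fs_hz, record_id=record.record_id)


@dataclass
class QCReport:
    """Partition of a record set into kept ids and (id, reason) exclusions."""

    kept: list[str]
    excluded: list[tuple[str, str]]

    @property
    def excluded_ids(self) -> set[str]:
        return {rid for rid, _ in self.excluded}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"record_id": r, "status": "kept", "reason": ""} for r in self.kept]
        rows += [
            {"record_id": r, "status": "excluded", "reason": why}
            for r, why in self.excluded
        ]
        return pd.DataFrame(rows, columns=["record_id", "status", "reason"])


def apply_qc_filters(records: Sequence[AccelRecord]) -> QCReport:
    """Exclude physically non-interpretable records.

    A record of either class is excluded when its maximal AVM is strictly
    larger than 30 g; a fall record is additionally excluded when its maximal
    AVM is strictly lower than 1.1 g.  ADL records are never excluded by the
    1.1 g rule.  Equality with either bound keeps the record.  The order of
    kept records is preserved.
    """
    if len(records) == 0:
        raise ValueError("apply_qc_filters: empty record collection")
    kept: list[str] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        peak = float(compute_avm(rec).values.max())
        if peak > QC_AVM_MAX_G:
            excluded.append((rec.record_id, REASON_OVER))
        elif rec.class_label == FALL and peak < QC_FALL_PEAK_MIN_G:
            excluded.append((rec.record_id, REASON_UNDER))
        else:
            kept.append(rec.record_id)
    return QCReport(kept=kept, excluded=excluded)


def filter_records(
    records: Sequence[AccelRecord], report: QCReport
) -> list[AccelRecord]:
    """Return the records kept by a QC report, in their original order."""
    bad = report.excluded_ids
    return [r for r in records if r.record_id not in bad]
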