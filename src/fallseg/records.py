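"""Containers and CSV input/output for labeled tri-axial accelerometer records.

A record holds one activity (a single fall or a single activity of daily
living, ADL) sampled at a fixed rate, with the three acceleration channels
expressed in g units (1 g = 9.81 m/s^2).  Datasets are a collection of
per-record CSV files plus a manifest CSV describing them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FALL = "fall"
ADL = "adl"
CLASS_LABELS = (FALL, ADL)

#: column layout of a per-record CSV file
RECORD_COLUMNS = ("time_s", "ax_g", "ay_g", "az_g")

#: column layout of a dataset manifest CSV
MANIFEST_COLUMNS = (
    "record_id",
    "subject_id",
    "activity_type",
    "class",
    "fs_hz",
    "path",
    "qc_error",
)


@dataclass
class AccelRecord:
    """One labeled tri-axial acceleration recording of a single activity.

    Parameters
    ----------
    record_id, subject_id, activity_type
        Identifiers carried through the whole pipeline; ``activity_type``
        feeds the per-type misclassification rates.
    class_label
        Ground-truth class, ``"fall"`` or ``"adl"``.
    fs_hz
        Sampling frequency in Hz.
    ax, ay, az
        Equal-length acceleration sample sequences in g units.
    """

    record_id: str
    subject_id: str
    activity_type: str
    class_label: str
    fs_hz: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.class_label not in CLASS_LABELS:
            raise ValueError(
                f"record {self.record_id!r}: class_label must be one of "
                f"{CLASS_LABELS}, got {self.class_label!r}"
            )
        if not (self.ax.ndim == self.ay.ndim == self.az.ndim == 1):
            raise ValueError(f"record {self.record_id!r}: axis arrays must be 1-D")
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise ValueError(f"record {self.record_id!r}: axis arrays differ in length")
        if len(self.ax) < 2:
            raise ValueError(f"record {self.record_id!r}: needs at least 2 samples")
        if not self.fs_hz > 0:
            raise ValueError(f"record {self.record_id!r}: fs_hz must be positive")

    @property
    def n(self) -> int:
        """Number of samples."""
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.n) / self.fs_hz
        return pd.DataFrame(
            {"time_s": t, "ax_g": self.ax, "ay_g": self.ay, "az_g": self.az}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        *,
        record_id: str,
        subject_id: str,
        activity_type: str,
        class_label: str,
        fs_hz: float,
    ) -> "AccelRecord":
        df = pd.read_csv(path)
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return cls(
            record_id=record_id,
            subject_id=subject_id,
            activity_type=activity_type,
            class_label=class_label,
            fs_hz=float(fs_hz),
            ax=df["ax_g"].to_numpy(),
            ay=df["ay_g"].to_numpy(),
            az=df["az_g"].to_numpy(),
        )


def write_dataset(
    records: Sequence[AccelRecord], manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Write one CSV per record plus the manifest; returns the manifest path.

    The manifest's ``path`` column is interpreted relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {r.record_id: r for r in records}
    for row in manifest.itertuples(index=False):
        rec = by_id[row.record_id]
        target = out_dir / row.path
        target.parent.mkdir(parents=True, exist_ok=True)
        rec.to_csv(target)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_dataset(manifest_path: str | Path) -> tuple[list[AccelRecord], pd.DataFrame]:
    """Load every record listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    root = manifest_path.parent
    records = [
        AccelRecord.from_csv(
            root / row["path"],
            record_id=row["record_id"],
            subject_id=str(row["subject_id"]),
            activity_type=row["activity_type"],
            class_label=row["class"],
            fs_hz=float(row["fs_hz"]),
        )
        for row in manifest.to_dict("records")
    ]
    return records, manifest
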