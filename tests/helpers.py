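"""Independent reference implementations (oracles) used by the test suite.

These deliberately use naive algorithms — per-candidate window scans, plain
Python loops, exact rational arithmetic, window-emptiness truth tables — so
that agreement with the package is a meaningful check rather than a
tautology.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from fallseg import AccelRecord


def make_avm_record(
    values, fs_hz=100.0, record_id="r", class_label="adl", activity_type="synthetic"
) -> AccelRecord:
    """A record whose AVM equals ``values`` exactly (signal on the z axis)."""
    values = np.asarray(values, dtype=float)
    return AccelRecord(
        record_id=record_id,
        subject_id="S01",
        activity_type=activity_type,
        class_label=class_label,
        fs_hz=fs_hz,
        ax=np.zeros_like(values),
        ay=np.zeros_like(values),
        az=values,
    )


def brute_force_detect(values, fs_hz, threshold, quiet_s=2.5, allow_truncated=True):
    """O(N*W) per-candidate scan for threshold + quiet-period events."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    w = max(1, round(quiet_s * fs_hz))
    out = []
    for i in range(n):
        if values[i] > threshold:
            end = i + w
            if end > n - 1 and not allow_truncated:
                continue
            window = values[i + 1 : min(end, n - 1) + 1]
            if np.all(window < threshold):
                out.append(i)
    return out


def emptiness_window_class(t1, t2, t3, t4):
    """Window class derived from which windows have nonzero duration.

    Independent of the criteria table: W2 = [t0-t1, t0-t3) is non-empty iff
    t1 > t3, W1 = [t0-t3, t0+t4) iff t3 + t4 > 0, W3 = [t0+t4, t0+t2) iff
    t2 > t4.
    """
    present = []
    if t1 > t3:
        present.append("W2")
    if t3 + t4 > 0:
        present.append("W1")
    if t2 > t4:
        present.append("W3")
    if not present:
        return "degenerate"
    order = [w for w in ("W1", "W2", "W3") if w in present]
    return "+".join(order)


def naive_features(ax, ay, az, aamv_divisor="n-1"):
    """Plain-Python single-pass reference for the eight segment features."""
    n = len(ax)
    avm = [math.sqrt(ax[i] ** 2 + ay[i] ** 2 + az[i] ** 2) for i in range(n)]
    mean = sum(avm) / n
    mx, mn = max(avm), min(avm)
    var = sum((v - mean) ** 2 for v in avm) / n
    sma = sum(abs(ax[i]) + abs(ay[i]) + abs(az[i]) for i in range(n))
    denom = n - 1 if aamv_divisor == "n-1" else n
    aamv = sum(abs(avm[i + 1] - avm[i]) for i in range(n - 1)) / denom
    rms = math.sqrt(sum(v * v for v in avm))
    return [mean, mx, mn, mx - mn, math.sqrt(var), sma, aamv, rms]


def exact_metrics(tp, fp, fn, tn, fn_type=None, fp_type=None):
    """Eq-by-eq rational-arithmetic metrics; None where undefined."""
    fscore = (
        Fraction(2 * tp, 2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else None
    )
    amr = None
    if fn_type is not None:
        amr = Fraction(fn_type, fn + tp) if fn + tp > 0 else None
    afpr = None
    if fp_type is not None:
        afpr = Fraction(fp_type, fp + tn) if fp + tn > 0 else None
    return fscore, amr, afpr
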