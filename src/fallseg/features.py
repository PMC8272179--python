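"""Per-segment feature extraction.

Eight features are computed from each data segment, all expressed in g-derived
units and all computable without knowing the sensor orientation:

* ``avm_mean``, ``avm_max``, ``avm_min``, ``avm_range`` -- first-order summary
  of the AVM samples (range = max - min);
* ``avm_std`` -- population standard deviation of the AVM (divisor N);
* ``sma`` -- summed magnitude area, the plain sum over the segment of
  ``|ax| + |ay| + |az|``;
* ``aamv`` -- average absolute AVM variation, the mean absolute difference of
  consecutive AVM samples (N - 1 differences);
* ``avm_rms`` -- square root of the summed squared axis values, equivalently
  ``sqrt(sum(AVM^2))``.

SMA and avm_rms are unnormalized sums and therefore grow with the sampling
rate and window duration; features are standardized before classification, so
this is deliberate.  For a configuration, per-window feature blocks are
concatenated in time order (W2, W1, W3), 8 values per window.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .events import EventCenteredRecord
from .segmentation import Segment, WindowConfig, extract_segments

FEATURE_NAMES = (
    "avm_mean",
    "avm_max",
    "avm_min",
    "avm_range",
    "avm_std",
    "sma",
    "aamv",
    "avm_rms",
)


def features_from_axes(
    ax: np.ndarray,
    ay: np.ndarray,
    az: np.ndarray,
    *,
    aamv_divisor: str = "n-1",
    rms_take_root: bool = True,
) -> np.ndarray:
    """The eight features from raw axis arrays (N >= 2 samples).

    ``aamv_divisor`` may be ``"n-1"`` (mean of the valid consecutive
    differences, the default) or ``"n"``; ``rms_take_root=False`` leaves the
    final feature as the plain sum of squares.  Both switches exist because
    either reading is defensible; the defaults follow the prose definitions.
    """
    n = len(ax)
    if n < 2:
        raise ValueError("segment needs at least 2 samples (AAMV undefined)")
    if aamv_divisor not in ("n-1", "n"):
        raise ValueError("aamv_divisor must be 'n-1' or 'n'")
    avm = np.sqrt(ax**2 + ay**2 + az**2)
    sq_sum = float((ax**2 + ay**2 + az**2).sum())
    denom = n - 1 if aamv_divisor == "n-1" else n
    return np.array(
        [
            float(avm.mean()),
            float(avm.max()),
            float(avm.min()),
            float(avm.max() - avm.min()),
            float(avm.std(ddof=0)),
            float((np.abs(ax) + np.abs(ay) + np.abs(az)).sum()),
            float(np.abs(np.diff(avm)).sum() / denom),
            float(np.sqrt(sq_sum)) if rms_take_root else sq_sum,
        ]
    )


def segment_features(segment: Segment, **kwargs) -> np.ndarray:
    """Eight-feature vector of one segment (see :data:`FEATURE_NAMES`)."""
    return features_from_axes(segment.ax, segment.ay, segment.az, **kwargs)


def config_features(
    ecr: EventCenteredRecord, cfg: WindowConfig, **kwargs
) -> np.ndarray:
    """Feature vector of one event-centered record under one configuration.

    Length is ``8 * number of windows``, blocks concatenated in time order
    (W2, W1, W3) restricted to the windows the configuration uses.
    """
    segs = extract_segments(ecr, cfg)
    return np.concatenate([segment_features(s, **kwargs) for s in segs])


def feature_names(cfg: WindowConfig) -> list[str]:
    """Column names matching :func:`config_features` for this configuration."""
    return [f"{w}_{f}" for w in cfg.windows for f in FEATURE_NAMES]
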