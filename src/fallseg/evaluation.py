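"""SVM classification under k-fold cross-validation and the window sweep.

The classifier is deliberately fixed — an RBF-kernel support vector machine
with C = 1 on standardized features — so that differences in detection
accuracy can be attributed to the data-segmentation configuration alone.
Records are randomly partitioned into five folds; for each fold the
standardization parameters are fit on the four training folds only and the
confusion counts are accumulated over the five test folds.  The unit of
cross-validation is the event-centered record: one feature vector per record
per window configuration, and fold membership depends only on the seed and
the record identifiers.

Evaluation metrics::

    Fscore     = 2 TP / (2 TP + FP + FN)
    AMR_type   = FN_type / (FN + TP)   (falls of one type that are missed)
    AFPR_type  = FP_type / (FP + TN)   (ADL of one type flagged as falls)

The sweep trains and scores one classifier per window configuration and
reports the per-class maxima (which window count wins, and at which t1-t4)
and pairwise-maximum grids over the parameter pairs defining each window.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .events import EventCenteredRecord
from .features import FEATURE_NAMES, features_from_axes
from .records import ADL, FALL
from .segmentation import DEGENERATE, WindowConfig, window_bounds

#: parameter pairs that determine each window's extent (W1, W2, W3)
PAIRWISE_PAIRS = (("t3", "t4"), ("t2", "t4"), ("t1", "t3"))


@dataclass(frozen=True)
class SVMConfig:
    """Classifier setup: RBF kernel, C = 1, standardized features.

    ``gamma`` follows scikit-learn semantics; the default ``"scale"`` is the
    reciprocal of (number of features x variance of the training features),
    evaluated after standardization.
    """

    C: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("C must be > 0")


@dataclass
class ConfusionCounts:
    """Summed confusion counts with per-activity-type breakdowns."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    per_type_fn: dict[str, int] = field(default_factory=dict)
    per_type_fp: dict[str, int] = field(default_factory=dict)


@dataclass
class MetricsReport:
    """Fscore plus per-type miss / false-positive rates (fractions).

    A rate whose denominator is zero is reported as None, never silently 0.
    """

    fscore: float | None
    amr_by_type: dict[str, float | None]
    afpr_by_type: dict[str, float | None]


@dataclass
class FeatureTable:
    """Feature matrix with aligned labels, record ids and activity types."""

    X: np.ndarray
    labels: np.ndarray
    record_ids: np.ndarray
    activity_types: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.record_ids = np.asarray(self.record_ids)
        self.activity_types = np.asarray(self.activity_types)
        n = len(self.X)
        if not (len(self.labels) == len(self.record_ids) == len(self.activity_types) == n):
            raise ValueError("misaligned feature table columns")


def build_feature_table(
    ecrs: Sequence[EventCenteredRecord], cfg: WindowConfig, **feature_kwargs
) -> FeatureTable:
    """One feature vector per event-centered record for one configuration."""
    from .features import config_features

    X = np.vstack([config_features(e, cfg, **feature_kwargs) for e in ecrs])
    return FeatureTable(
        X=X,
        labels=np.array([e.label for e in ecrs]),
        record_ids=np.array([e.event_id for e in ecrs]),
        activity_types=np.array([e.activity_type for e in ecrs]),
    )


def fold_assignment(
    record_ids: Sequence[str],
    k: int,
    seed: int,
    labels: Sequence[str] | None = None,
    stratified: bool = False,
) -> np.ndarray:
    """Fold index per record; a pure function of (seed, record ids).

    Identifiers are sorted before the seeded shuffle, so the assignment is
    independent of input order (and of features).  With ``stratified=True``
    folds are balanced per class.
    """
    ids = list(record_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")
    order = np.argsort(np.asarray(ids))
    rng = np.random.default_rng(seed)
    shuffled = order[rng.permutation(len(ids))]
    folds = np.empty(len(ids), dtype=int)
    if stratified:
        if labels is None:
            raise ValueError("stratified assignment needs labels")
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            members = [i for i in shuffled if labels[i] == lab]
            for j, i in enumerate(members):
                folds[i] = j % k
    else:
        for f, chunk in enumerate(np.array_split(shuffled, k)):
            folds[chunk] = f
    return folds


@dataclass
class CVResult:
    """Per-record predictions of a cross-validation run."""

    predicted: np.ndarray
    folds: np.ndarray
    gammas: list[float]


def cross_validate(
    table: FeatureTable,
    svm: SVMConfig = SVMConfig(),
    k: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> CVResult:
    """Train/test the SVM over k seeded folds; returns per-record predictions.

    Standardization parameters are fit on the training folds only.  Raises on
    single-class input or k outside [2, n].
    """
    classes = set(table.labels.tolist())
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes present")
    n = len(table.X)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}]")
    folds = fold_assignment(table.record_ids, k, seed, table.labels, stratified)
    predicted = np.empty(n, dtype=table.labels.dtype)
    gammas: list[float] = []
    for f in range(k):
        test = folds == f
        train = ~test
        if len(set(table.labels[train].tolist())) < 2:
            raise ValueError(f"fold {f}: training data contains a single class")
        X_tr, X_te = table.X[train], table.X[test]
        if svm.standardize:
            scaler = StandardScaler().fit(X_tr)
            X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
        clf = SVC(C=svm.C, kernel="rbf", gamma=svm.gamma)
        clf.fit(X_tr, table.labels[train])
        if svm.gamma == "scale":
            var = float(X_tr.var())
            gammas.append(1.0 / (X_tr.shape[1] * var) if var > 0 else 1.0)
        elif svm.gamma == "auto":
            gammas.append(1.0 / X_tr.shape[1])
        else:
            gammas.append(float(svm.gamma))
        if test.any():
            predicted[test] = clf.predict(X_te)
    return CVResult(predicted=predicted, folds=folds, gammas=gammas)


def confusion_from_predictions(
    labels: np.ndarray, predicted: np.ndarray, activity_types: np.ndarray
) -> ConfusionCounts:
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    tp = int(((labels == FALL) & (predicted == FALL)).sum())
    fn_mask = (labels == FALL) & (predicted == ADL)
    fp_mask = (labels == ADL) & (predicted == FALL)
    tn = int(((labels == ADL) & (predicted == ADL)).sum())
    return ConfusionCounts(
        tp=tp,
        fp=int(fp_mask.sum()),
        fn=int(fn_mask.sum()),
        tn=tn,
        per_type_fn=dict(Counter(np.asarray(activity_types)[fn_mask].tolist())),
        per_type_fp=dict(Counter(np.asarray(activity_types)[fp_mask].tolist())),
    )


def five_fold_cv(
    table: FeatureTable,
    svm: SVMConfig = SVMConfig(),
    k: int = 5,
    seed: int = 0,
    stratified: bool = False,
) -> ConfusionCounts:
    """Confusion counts summed over the k test folds."""
    result = cross_validate(table, svm, k=k, seed=seed, stratified=stratified)
    return confusion_from_predictions(table.labels, result.predicted, table.activity_types)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Fscore and per-type rates from summed confusion counts."""
    denom_f = 2 * counts.tp + counts.fp + counts.fn
    fscore = 2 * counts.tp / denom_f if denom_f > 0 else None
    denom_amr = counts.fn + counts.tp
    denom_afpr = counts.fp + counts.tn
    amr = {
        t: (c / denom_amr if denom_amr > 0 else None)
        for t, c in counts.per_type_fn.items()
    }
    afpr = {
        t: (c / denom_afpr if denom_afpr > 0 else None)
        for t, c in counts.per_type_fp.items()
    }
    return MetricsReport(fscore=fscore, amr_by_type=amr, afpr_by_type=afpr)


@dataclass
class SweepResult:
    """Cross-validated metrics for every swept window configuration.

    ``table`` has one row per configuration with columns
    t1, t2, t3, t4, window_class, fscore, tp, fp, fn, tn.
    """

    table: pd.DataFrame
    provenance: dict


def run_sweep(
    ecrs: Sequence[EventCenteredRecord],
    configs: Sequence[WindowConfig],
    svm: SVMConfig = SVMConfig(),
    seed: int = 0,
    k: int = 5,
    stratified: bool = False,
) -> SweepResult:
    """Cross-validate one classifier per window configuration.

    Window feature blocks are cached by their sample offsets, so
    configurations sharing a window (for example the same W1 extent) reuse
    its features.  Deterministic given the seed.
    """
    if len(ecrs) == 0:
        raise ValueError("run_sweep: no event-centered records")
    fs = {e.fs_hz for e in ecrs}
    if len(fs) != 1:
        raise ValueError("run_sweep requires a uniform sampling rate")
    labels = np.array([e.label for e in ecrs])
    ids = np.array([e.event_id for e in ecrs])
    types = np.array([e.activity_type for e in ecrs])
    mid = {e.center_index for e in ecrs}
    if len(mid) != 1:
        raise ValueError("run_sweep requires a uniform event-centered margin")
    mid = mid.pop()

    cache: dict[tuple[int, int], np.ndarray] = {}

    def window_block(a: int, b: int) -> np.ndarray:
        key = (a, b)
        if key not in cache:
            if mid + a < 0 or mid + b > ecrs[0].n:
                raise ValueError(
                    f"window [{a}, {b}) samples exceeds the +/-{mid}-sample margin"
                )
            if b <= a:
                raise ValueError(f"empty window [{a}, {b}) in sweep")
            cache[key] = np.vstack(
                [
                    features_from_axes(
                        e.ax[mid + a : mid + b],
                        e.ay[mid + a : mid + b],
                        e.az[mid + a : mid + b],
                    )
                    for e in ecrs
                ]
            )
        return cache[key]

    rows = []
    for cfg in configs:
        if cfg.window_class == DEGENERATE:
            raise ValueError("degenerate configuration in sweep")
        blocks = [window_block(a, b) for a, b in window_bounds(cfg, ecrs[0].fs_hz).values()]
        table = FeatureTable(
            X=np.hstack(blocks), labels=labels, record_ids=ids, activity_types=types
        )
        counts = five_fold_cv(table, svm, k=k, seed=seed, stratified=stratified)
        metrics = compute_metrics(counts)
        rows.append(
            {
                "t1": cfg.t1,
                "t2": cfg.t2,
                "t3": cfg.t3,
                "t4": cfg.t4,
                "window_class": cfg.window_class,
                "fscore": metrics.fscore,
                "tp": counts.tp,
                "fp": counts.fp,
                "fn": counts.fn,
                "tn": counts.tn,
            }
        )
    return SweepResult(
        table=pd.DataFrame(rows),
        provenance={
            "seed": seed,
            "k": k,
            "svm": svm,
            "stratified": stratified,
            "n_records": len(ecrs),
            "fs_hz": ecrs[0].fs_hz,
        },
    )


def best_by_class(sweep: SweepResult) -> pd.DataFrame:
    """Maximal Fscore and the achieving (t1..t4) per window class.

    Ties break to the smaller t1+t2+t3+t4, then lexicographically.
    """
    if len(sweep.table) == 0:
        raise ValueError("empty sweep")
    df = sweep.table.copy()
    df["_sum"] = df[["t1", "t2", "t3", "t4"]].sum(axis=1)
    df = df.sort_values(
        by=["fscore", "_sum", "t1", "t2", "t3", "t4"],
        ascending=[False, True, True, True, True, True],
    )
    best = df.groupby("window_class", sort=False).head(1).drop(columns="_sum")
    order = [c for c in ("W1", "W1+W2", "W1+W3", "W2+W3", "W1+W2+W3", "W2", "W3")
             if c in set(best["window_class"])]
    best["window_class"] = pd.Categorical(best["window_class"], categories=order)
    return (
        best.sort_values("window_class")
        .reset_index(drop=True)[
            ["window_class", "fscore", "t1", "t2", "t3", "t4", "tp", "fp", "fn", "tn"]
        ]
    )


def pairwise_max_grid(
    sweeps: SweepResult | Sequence[SweepResult],
    pair: tuple[str, str] = ("t3", "t4"),
) -> pd.DataFrame:
    """Maximum Fscore over all configurations sharing each parameter pair.

    ``pair`` must be one of (t3, t4), (t2, t4), (t1, t3) — the pairs that
    determine the extents of W1, W2 and W3 respectively.  Passing several
    sweeps averages their per-pair maxima (multi-dataset emulation).
    """
    if tuple(pair) not in PAIRWISE_PAIRS:
        raise ValueError(f"pair must be one of {PAIRWISE_PAIRS}")
    if isinstance(sweeps, SweepResult):
        sweeps = [sweeps]
    grids = []
    for sweep in sweeps:
        grid = sweep.table.pivot_table(
            index=pair[0], columns=pair[1], values="fscore", aggfunc="max"
        )
        grids.append(grid)
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError("sweeps cover different parameter grids")
    return sum(grids) / len(grids)
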