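"""Model evaluation: ROC analysis and bin-and-average categorization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default silencing percentage above which a record counts as "efficient"
DEFAULT_EFFICIENCY_THRESHOLD = 75.0


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    efficiency_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def roc_auc(predictions, activities, efficiency_threshold: float = DEFAULT_EFFICIENCY_THRESHOLD) -> ROCResult:
    """ROC of continuous predictions against thresholded binary efficiency.

    AUC is computed by the trapezoidal rule over all distinct prediction
    thresholds, which equals the normalized Mann-Whitney U statistic (ties
    contributing 1/2).
    """
    preds = np.asarray(predictions, dtype=float)
    acts = np.asarray(activities, dtype=float)
    if preds.shape != acts.shape:
        raise ValueError("predictions and activities must align")
    labels = acts >= efficiency_threshold
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"both classes required after thresholding at {efficiency_threshold}%"
            f" (got {n_pos} positive, {n_neg} negative)")
    order = np.argsort(-preds, kind="stable")
    sorted_preds = preds[order]
    sorted_labels = labels[order]
    # collapse tied prediction values into single curve points
    distinct = np.r_[np.nonzero(np.diff(sorted_preds))[0], len(sorted_preds) - 1]
    tp = np.cumsum(sorted_labels)[distinct]
    fp = np.cumsum(~sorted_labels)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=np.r_[np.inf, sorted_preds[distinct]],
                     fpr=fpr, tpr=tpr, auc=auc,
                     efficiency_threshold=efficiency_threshold)


def bin_by_feature(values, activities, edges, *, right_closed: bool = True) -> pd.DataFrame:
    """Mean activity and count per feature interval.

    Intervals are ``(edges[k], edges[k+1]]`` — right margins included, left
    open — matching the binning convention used for the stability scatter
    plots. Values outside ``(edges[0], edges[-1]]`` are ignored. Empty bins
    are reported with count 0 and NaN mean.
    """
    values = np.asarray(values, dtype=float)
    activities = np.asarray(activities, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if not right_closed:
        raise NotImplementedError("only right-closed bins are provided")
    idx = np.searchsorted(edges, values, side="left") - 1
    rows = []
    for k in range(len(edges) - 1):
        mask = idx == k
        cnt = int(mask.sum())
        rows.append((edges[k], edges[k + 1], cnt,
                     float(activities[mask].mean()) if cnt else float("nan")))
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "count", "mean_activity"])
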