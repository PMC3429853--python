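"""Correlation screening of candidate features with split-stability analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def correlate_features(X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Pearson R (vs ln activity) and two-sided p per feature column.

    Constant columns are degenerate: reported with R = 0, p = 1.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 records for correlation analysis")
    if np.ptp(y) == 0:
        raise ValueError("activity is constant; correlations undefined")
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((col, 0.0, 1.0, True))
        else:
            r, p = stats.pearsonr(x, y)
            rows.append((col, float(r), float(p), False))
    return pd.DataFrame(rows, columns=["feature", "R", "p", "degenerate"]
                        ).set_index("feature")


def _part_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Columnwise Pearson R of X against y; NaN for constant columns."""
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, xc.T @ yc / denom, np.nan)


@dataclass(frozen=True)
class SelectionReport:
    """Screening outcome: full-set R/p, split stability S_n, and kept flags."""

    table: pd.DataFrame  # index=feature; columns R, p, S_n, kept
    r_min: float
    p_max: float
    s_max: float
    n_splits: int
    n_repeats: int

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["kept"]])


def select_parameters(X: pd.DataFrame, y: np.ndarray, *,
                      r_min: float = 0.014, p_max: float = 0.05,
                      n_splits: int = 5, n_repeats: int = 1000,
                      s_max: float = 0.065, seed: int = 0) -> SelectionReport:
    """Keep features with |R| >= r_min, p < p_max, and stable correlation.

    Stability S_n is the standard deviation of the per-part correlation
    over ``n_repeats`` random splits of the data into ``n_splits``
    near-equal disjoint parts.
    """
    y = np.asarray(y, dtype=float)
    m = len(y)
    if m // n_splits < 3:
        raise ValueError(
            f"dataset of {m} records too small for {n_splits}-way splits")
    full = correlate_features(X, y)
    Xa = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    part_rs = np.empty((n_repeats * n_splits, Xa.shape[1]))
    row = 0
    for _ in range(n_repeats):
        order = rng.permutation(m)
        for part in np.array_split(order, n_splits):
            part_rs[row] = _part_correlations(Xa[part], y[part])
            row += 1
    with np.errstate(invalid="ignore"):
        s_n = np.nanstd(part_rs, axis=0, ddof=1)
    table = full.copy()
    table["S_n"] = s_n
    table["kept"] = ((table["R"].abs() >= r_min)
                     & (table["p"] < p_max)
                     & (table["S_n"] <= s_max)
                     & ~table["degenerate"])
    return SelectionReport(table=table, r_min=r_min, p_max=p_max, s_max=s_max,
                           n_splits=n_splits, n_repeats=n_repeats)
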