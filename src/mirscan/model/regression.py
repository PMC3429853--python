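"""OLS fitting, iterative model reduction, and non-overlapping cross-validation.

The dependent variable throughout is the natural log of the silencing
score. ``R^2`` follows the (Actual Variation - Error) / Actual Variation
definition, which coincides with the squared Pearson correlation only for
non-cross-validated in-sample predictions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .coefficients import CoefficientTable

_INDICATOR_RE = re.compile(r"^[ACGU]_(\d+)$")


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; offending columns are reported."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design matrix rank deficient; collinear columns: {self.columns}")


@dataclass(frozen=True)
class ModelFit:
    """A fitted linear model with classical t-test statistics."""

    table: CoefficientTable
    pvalues: Mapping[str, float]  # includes "intercept"
    stderr: Mapping[str, float]
    train_r: float
    resid_std: float
    n_obs: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.table.score_frame(X)


def _design(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = list(X.columns)
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    return mat, cols


def fit_ols(X: pd.DataFrame, y: np.ndarray, *, model_name: str = "fitted") -> ModelFit:
    """Ordinary least squares of *y* on the columns of *X* plus an intercept.

    Raises :class:`RankDeficiencyError` naming the collinear columns when
    the design matrix is not full rank.
    """
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    mat, cols = _design(X)
    n, k = mat.shape
    if n <= k:
        raise ValueError(f"need more rows ({n}) than parameters ({k})")
    _, R, piv = linalg.qr(mat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(mat.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < k:
        names = ["intercept"] + cols
        raise RankDeficiencyError([names[i] for i in sorted(piv[rank:])])
    beta, _, _, _ = np.linalg.lstsq(mat, y, rcond=None)
    resid = y - mat @ beta
    dof = n - k
    s2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(mat.T @ mat)
    se = np.sqrt(np.diag(xtx_inv) * s2)
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    fitted = mat @ beta
    train_r = float(np.corrcoef(fitted, y)[0, 1]) if np.ptp(fitted) > 0 else 0.0
    table = CoefficientTable(intercept=float(beta[0]),
                             terms=dict(zip(cols, map(float, beta[1:]))),
                             name=model_name)
    return ModelFit(table=table,
                    pvalues={"intercept": float(pvals[0]),
                             **dict(zip(cols, map(float, pvals[1:])))},
                    stderr={"intercept": float(se[0]),
                            **dict(zip(cols, map(float, se[1:])))},
                    train_r=train_r, resid_std=float(np.sqrt(s2)), n_obs=n)


def reduce_model(X: pd.DataFrame, y: np.ndarray, *, p_max: float = 0.05,
                 max_rounds: int | None = None) -> ModelFit:
    """Iteratively drop insignificant terms, refitting each round.

    Per round: among insignificant nucleotide indicators, at most one per
    sequence position is removed (the largest p-value at that position);
    among insignificant non-indicator (thermodynamic) terms, at most one
    overall. Stops when every remaining term is significant or nothing can
    be removed.
    """
    cols = list(X.columns)
    rounds = 0
    while True:
        fit = fit_ols(X[cols], y)
        if max_rounds is not None and rounds >= max_rounds:
            return fit
        drop: list[str] = []
        by_position: dict[int, tuple[float, str]] = {}
        worst_thermo: tuple[float, str] | None = None
        for name in cols:
            p = fit.pvalues[name]
            if p < p_max:
                continue
            m = _INDICATOR_RE.match(name)
            if m:
                pos = int(m.group(1))
                if pos not in by_position or p > by_position[pos][0]:
                    by_position[pos] = (p, name)
            else:
                if worst_thermo is None or p > worst_thermo[0]:
                    worst_thermo = (p, name)
        drop = [name for _, name in by_position.values()]
        if worst_thermo is not None:
            drop.append(worst_thermo[1])
        if not drop:
            return fit
        cols = [c for c in cols if c not in drop]
        rounds += 1


def r2_methods(actual: np.ndarray, predicted: np.ndarray) -> float:
    """(Actual Variation - Error) / Actual Variation on the ln scale."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sst = float(((actual - actual.mean()) ** 2).sum())
    sse = float(((actual - predicted) ** 2).sum())
    if sst == 0:
        raise ValueError("actual values are constant; R^2 undefined")
    return (sst - sse) / sst


@dataclass(frozen=True)
class CVResult:
    """Out-of-fold predictions from non-overlapping cross-validation."""

    predictions: np.ndarray
    fold_assignment: np.ndarray
    r2: float
    pearson_r: float
    n_folds: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fold": self.fold_assignment,
                             "prediction": self.predictions})


def cross_validate(X: pd.DataFrame, y: np.ndarray, *, n: int = 5,
                   seed: int = 0,
                   pipeline: Callable[[pd.DataFrame, np.ndarray], ModelFit] | None = None,
                   ) -> CVResult:
    """Split into *n* disjoint near-equal folds, train on n-1, predict the
    held-out fold; every record is predicted exactly once."""
    y = np.asarray(y, dtype=float)
    m = len(y)
    if n < 2:
        raise ValueError("need at least 2 folds")
    if n > m:
        raise ValueError(f"more folds ({n}) than records ({m})")
    pipeline = pipeline or (lambda Xtr, ytr: fit_ols(Xtr, ytr))
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, n)
    preds = np.empty(m)
    assignment = np.empty(m, dtype=int)
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        fit = pipeline(X.iloc[train_idx], y[train_idx])
        preds[test_idx] = fit.predict(X.iloc[test_idx])
        assignment[test_idx] = fi
    r = float(np.corrcoef(preds, y)[0, 1]) if np.ptp(preds) > 0 else 0.0
    return CVResult(predictions=preds, fold_assignment=assignment,
                    r2=r2_methods(y, preds), pearson_r=r, n_folds=n)
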