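"""Coefficient tables: the built-in complete-database model and JSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from ..features import FeatureVector


class TermResolutionError(KeyError):
    """A model term has no matching feature-vector column."""


@dataclass(frozen=True)
class CoefficientTable:
    """Intercept plus named term weights for the linear scoring model."""

    intercept: float
    terms: Mapping[str, float]
    name: str = "custom"
    source: str = ""

    def score(self, fv: FeatureVector) -> float:
        """Predicted ln-silencing score: intercept + sum(weight * feature)."""
        total = self.intercept
        for term, weight in self.terms.items():
            if term not in fv:
                raise TermResolutionError(
                    f"model term {term!r} not present in feature vector "
                    f"(available: {sorted(fv.values)[:8]}...)")
            total += weight * fv[term]
        return total

    def score_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Vectorized scoring over a feature DataFrame (rows = candidates)."""
        missing = [t for t in self.terms if t not in frame.columns]
        if missing:
            raise TermResolutionError(f"model terms {missing} not in feature frame")
        w = np.array(list(self.terms.values()))
        return self.intercept + frame[list(self.terms)].to_numpy() @ w

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "source": self.source,
                       "intercept": self.intercept, "terms": dict(self.terms)},
                      fh, indent=2)


def load_coefficients(path) -> CoefficientTable:
    with open(path) as fh:
        raw = json.load(fh)
    try:
        return CoefficientTable(intercept=float(raw["intercept"]),
                                terms={k: float(v) for k, v in raw["terms"].items()},
                                name=raw.get("name", "custom"),
                                source=raw.get("source", ""))
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"invalid coefficient JSON {path}: {exc}") from exc


@lru_cache(maxsize=1)
def builtin_table2() -> CoefficientTable:
    """The shipped complete-database regression model."""
    raw = json.loads((resources.files(__package__) / "data" / "table2.json").read_text())
    return CoefficientTable(intercept=raw["intercept"], terms=raw["terms"],
                            name=raw["name"], source=raw["source"])


def score(fv: FeatureVector, coeffs: CoefficientTable) -> float:
    """Functional alias for :meth:`CoefficientTable.score`."""
    return coeffs.score(fv)
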