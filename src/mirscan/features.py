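"""Position-dependent sequence encoding and per-candidate feature assembly.

Guide positions are 1-based from the 5' end. Nucleotide indicators are
named ``A_1 ... U_22``; thermodynamic terms are ``dG`` (total duplex free
energy), its powers ``dG2``/``dG3``, the first-dinucleotide stack ``dG1``,
the optional per-position profile ``dGp_1 ... dGp_21``, and the optional
competing-structure energies ``dG_self``, ``dG_dimer``, ``dG_target``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityRecord, ln_activity
from .alphabet import RNA_BASES, validate_rna
from . import thermo

GUIDE_LENGTH = thermo.GUIDE_LENGTH

#: canonical indicator column order: position-major, base alphabetical
INDICATOR_COLUMNS = tuple(f"{b}_{p}" for p in range(1, GUIDE_LENGTH + 1)
                          for b in RNA_BASES)
THERMO_COLUMNS = ("dG", "dG2", "dG3", "dG1")


def _check_guide(guide: str, length: int = GUIDE_LENGTH) -> str:
    validate_rna(guide, name="guide")
    if len(guide) != length:
        raise ValueError(f"guide length {len(guide)} != {length}")
    return guide


def one_hot(guide: str) -> dict[tuple[str, int], int]:
    """0/1 indicator map ``nuc[(base, position)]`` over all 88 cells."""
    _check_guide(guide)
    ind = {(b, p): 0 for p in range(1, GUIDE_LENGTH + 1) for b in RNA_BASES}
    for p, base in enumerate(guide, start=1):
        ind[(base, p)] = 1
    return ind


@dataclass(frozen=True)
class FeatureVector:
    """Named model inputs for one guide; missing terms read as absent."""

    guide: str | None
    values: Mapping[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.values), dtype=float)


def build_feature_vector(guide: str, *,
                         include_thermo: bool = True,
                         poly_degree: int = 3,
                         include_dG1: bool = True,
                         include_profile: bool = False,
                         include_self: bool = False,
                         include_dimer: bool = False,
                         dG_target: float | None = None,
                         params: thermo.NNParameterSet | None = None,
                         corrections: bool = True) -> FeatureVector:
    """Assemble the full feature vector for one 22-nt guide strand."""
    _check_guide(guide)
    params = params or thermo.default_parameters()
    vals: dict[str, float] = {}
    for p, base in enumerate(guide, start=1):
        for b in RNA_BASES:
            vals[f"{b}_{p}"] = 1.0 if b == base else 0.0
    if include_thermo:
        profile = thermo.duplex_dG_profile(guide, params)
        dG = sum(profile)
        if corrections:
            dG += (params.init_dG + params.terminal_penalty(guide[0])
                   + params.terminal_penalty(guide[-1]))
        vals["dG"] = dG
        if poly_degree >= 2:
            vals["dG2"] = dG * dG
        if poly_degree >= 3:
            vals["dG3"] = dG * dG * dG
        if include_dG1:
            vals["dG1"] = profile[0]
        if include_profile:
            for i, e in enumerate(profile, start=1):
                vals[f"dGp_{i}"] = e
        if include_self:
            vals["dG_self"] = thermo.fold_self_dG(guide, params).mfe_dG
        if include_dimer:
            vals["dG_dimer"] = thermo.dimer_dG(guide, guide, params)
    if dG_target is not None:
        vals["dG_target"] = dG_target
    return FeatureVector(guide=guide, values=vals)


def feature_frame(guides: Sequence[str], *,
                  columns: Iterable[str] | None = None,
                  params: thermo.NNParameterSet | None = None,
                  corrections: bool = True,
                  include_self: bool = False) -> pd.DataFrame:
    """Vectorized feature table for many guides (rows) x named terms.

    Only indicator, ``dG``-family and optional ``dG_self`` columns are
    produced; pass ``columns`` to subset/reorder.
    """
    params = params or thermo.default_parameters()
    n = len(guides)
    if n == 0:
        raise ValueError("no guides")
    arr = np.frombuffer("".join(guides).encode(), dtype="S1").reshape(n, -1)
    if arr.shape[1] != GUIDE_LENGTH:
        raise ValueError("all guides must be 22 nt")
    data: dict[str, np.ndarray] = {}
    for p in range(1, GUIDE_LENGTH + 1):
        col = arr[:, p - 1]
        for b in RNA_BASES:
            data[f"{b}_{p}"] = (col == b.encode()).astype(float)
    stack = params.stack_dG
    prof = np.empty((n, GUIDE_LENGTH - 1))
    for k, g in enumerate(guides):
        prof[k] = [stack[g[i:i + 2]] for i in range(GUIDE_LENGTH - 1)]
    dG = prof.sum(axis=1)
    if corrections:
        term = np.array([params.terminal_penalty(g[0])
                         + params.terminal_penalty(g[-1]) for g in guides])
        dG = dG + params.init_dG + term
    data["dG"] = dG
    data["dG2"] = dG ** 2
    data["dG3"] = dG ** 3
    data["dG1"] = prof[:, 0]
    if include_self:
        data["dG_self"] = np.array(
            [thermo.fold_self_dG(g, params).mfe_dG for g in guides])
    df = pd.DataFrame(data)
    if columns is not None:
        df = df[list(columns)]
    return df


@dataclass(frozen=True)
class ReducedMatrixSpec:
    """Per-position choice of the one nucleotide excluded from the design
    matrix, leaving 22 x 3 = 66 indicator variables."""

    dropped: Mapping[int, str]
    degenerate: bool = False  # constant activity: drop decided by tie-break only

    @property
    def retained_columns(self) -> tuple[str, ...]:
        return tuple(f"{b}_{p}" for p in range(1, GUIDE_LENGTH + 1)
                     for b in RNA_BASES if b != self.dropped[p])


def reduce_matrix(dataset: Sequence[ActivityRecord]) -> ReducedMatrixSpec:
    """Drop, per position, the indicator least correlated with ln activity.

    Ties go to the larger p-value, then alphabetically; a constant-activity
    dataset yields all-zero correlations and is flagged ``degenerate``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    y = np.array([ln_activity(r.score) for r in dataset])
    degenerate = bool(np.ptp(y) == 0) or len(dataset) < 2
    dropped: dict[int, str] = {}
    for p in range(1, GUIDE_LENGTH + 1):
        stats_by_base = []
        for b in RNA_BASES:
            x = np.array([1.0 if r.guide[p - 1] == b else 0.0 for r in dataset])
            if degenerate or np.ptp(x) == 0:
                r_val, p_val = 0.0, 1.0
            else:
                r_val, p_val = stats.pearsonr(x, y)
            stats_by_base.append((abs(r_val), -p_val, b))
        dropped[p] = min(stats_by_base)[2]
    return ReducedMatrixSpec(dropped=dropped, degenerate=degenerate)
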