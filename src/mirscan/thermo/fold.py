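"""Intramolecular minimum-free-energy folding for oligo-scale RNAs.

A deliberately compact Zuker-style dynamic program over nested structures:
Watson-Crick pairs only (no wobble), stack energies from the
nearest-neighbor table, tabulated hairpin/bulge/internal-loop penalties,
an affine multibranch-loop term, no coaxial stacking, no dangles, and a
minimum hairpin loop of 3 nt. The unfolded state scores 0, so the MFE is
never positive. Interior loops are capped at ``MAX_INTERIOR`` unpaired
nucleotides, the usual Zuker restriction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..alphabet import can_pair, validate_rna
from .params import MIN_HAIRPIN, NNParameterSet, default_parameters

MAX_INTERIOR = 30
_INF = float("inf")


@dataclass(frozen=True)
class FoldResult:
    """MFE (kcal/mol, <= 0) and the dot-bracket structure achieving it."""

    mfe_dG: float
    structure: str

    def pairs(self) -> list[tuple[int, int]]:
        """Base pairs as 0-based (i, j) tuples parsed from the structure."""
        stack: list[int] = []
        out: list[tuple[int, int]] = []
        for k, c in enumerate(self.structure):
            if c == "(":
                stack.append(k)
            elif c == ")":
                out.append((stack.pop(), k))
        return sorted(out)


class _Folder:
    def __init__(self, seq: str, params: NNParameterSet):
        self.s = seq
        self.p = params
        n = self.n = len(seq)
        self.pairable = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + MIN_HAIRPIN + 1, n):
                self.pairable[i, j] = can_pair(seq[i], seq[j])
        self.V = np.full((n, n), _INF)
        self.WM1 = np.full((n, n), _INF)
        self.WM = np.full((n, n), _INF)
        self.WM2 = np.full((n, n), _INF)

    def _interior(self, i: int, j: int) -> float:
        """Best stack / bulge / internal-loop continuation from pair (i, j)."""
        s, p, V = self.s, self.p, self.V
        best = _INF
        if self.pairable[i + 1, j - 1]:
            best = p.stack_dG[s[i:i + 2]] + V[i + 1, j - 1]
        for l1 in range(0, MAX_INTERIOR + 1):
            pi = i + 1 + l1
            if pi > j - 2:
                break
            for l2 in range(1 if l1 == 0 else 0, MAX_INTERIOR + 1 - l1):
                qi = j - 1 - l2
                if qi <= pi:
                    break
                if not self.pairable[pi, qi]:
                    continue
                size = l1 + l2
                pen = p.bulge(size) if min(l1, l2) == 0 else p.internal(size)
                e = pen + V[pi, qi]
                if e < best:
                    best = e
        return best

    def fill(self) -> float:
        n, s, p = self.n, self.s, self.p
        V, WM1, WM, WM2 = self.V, self.WM1, self.WM, self.WM2
        for d in range(MIN_HAIRPIN + 1, n):
            for i in range(0, n - d):
                j = i + d
                if self.pairable[i, j]:
                    e = p.hairpin(j - i - 1)
                    e = min(e, self._interior(i, j))
                    if WM2[i + 1, j - 1] < _INF:
                        e = min(e, p.multiloop_a + p.multiloop_b + WM2[i + 1, j - 1])
                    V[i, j] = e
                # multiloop component tables over [i, j]
                w1 = V[i, j] + p.multiloop_b if V[i, j] < _INF else _INF
                if j - 1 >= i and WM1[i, j - 1] < _INF:
                    w1 = min(w1, WM1[i, j - 1] + p.multiloop_c)
                WM1[i, j] = w1
                bifurc = _INF
                if j > i:
                    vec = WM[i, i:j] + WM1[i + 1:j + 1, j]
                    m = vec.min() if len(vec) else _INF
                    bifurc = m
                WM2[i, j] = bifurc
                w = min(w1, bifurc)
                if j > i and WM[i + 1, j] < _INF:
                    w = min(w, WM[i + 1, j] + p.multiloop_c)
                WM[i, j] = w
        # external loop
        W = np.zeros(n + 1)  # W[k] = best energy of prefix s[0:k]
        for j in range(1, n + 1):
            best = W[j - 1]
            for i in range(0, j - MIN_HAIRPIN - 1):
                if V[i, j - 1] < _INF:
                    best = min(best, W[i] + V[i, j - 1])
            W[j] = best
        self.W = W
        return min(0.0, W[n])

    # -- traceback ---------------------------------------------------------

    def traceback(self) -> list[tuple[int, int]]:
        pairs: list[tuple[int, int]] = []
        n = self.n
        j = n
        while j > 0:
            if self.W[j] == self.W[j - 1]:
                j -= 1
                continue
            for i in range(0, j - MIN_HAIRPIN - 1):
                if self.V[i, j - 1] < _INF and np.isclose(
                        self.W[j], self.W[i] + self.V[i, j - 1]):
                    self._trace_V(i, j - 1, pairs)
                    j = i
                    break
            else:  # pragma: no cover - numeric safety net
                j -= 1
        return pairs

    def _trace_V(self, i: int, j: int, pairs: list) -> None:
        s, p, V = self.s, self.p, self.V
        pairs.append((i, j))
        e = V[i, j]
        if np.isclose(e, p.hairpin(j - i - 1)):
            return
        if self.pairable[i + 1, j - 1] and np.isclose(
                e, p.stack_dG[s[i:i + 2]] + V[i + 1, j - 1]):
            self._trace_V(i + 1, j - 1, pairs)
            return
        for l1 in range(0, MAX_INTERIOR + 1):
            pi = i + 1 + l1
            if pi > j - 2:
                break
            for l2 in range(1 if l1 == 0 else 0, MAX_INTERIOR + 1 - l1):
                qi = j - 1 - l2
                if qi <= pi:
                    break
                if not self.pairable[pi, qi]:
                    continue
                size = l1 + l2
                pen = p.bulge(size) if min(l1, l2) == 0 else p.internal(size)
                if np.isclose(e, pen + V[pi, qi]):
                    self._trace_V(pi, qi, pairs)
                    return
        self._trace_WM(i + 1, j - 1, pairs, two=True)

    def _trace_WM(self, i: int, j: int, pairs: list, *, two: bool = False) -> None:
        p, WM, WM1, WM2, V = self.p, self.WM, self.WM1, self.WM2, self.V
        if two:
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < _INF and WM1[k, j] < _INF and np.isclose(
                        WM2[i, j], WM[i, k - 1] + WM1[k, j]):
                    self._trace_WM(i, k - 1, pairs)
                    self._trace_WM1(k, j, pairs)
                    return
            raise AssertionError("multiloop traceback failed")
        e = WM[i, j]
        if j > i and WM[i + 1, j] < _INF and np.isclose(e, WM[i + 1, j] + p.multiloop_c):
            self._trace_WM(i + 1, j, pairs)
            return
        if np.isclose(e, WM1[i, j]):
            self._trace_WM1(i, j, pairs)
            return
        for k in range(i + 1, j + 1):
            if WM[i, k - 1] < _INF and WM1[k, j] < _INF and np.isclose(
                    e, WM[i, k - 1] + WM1[k, j]):
                self._trace_WM(i, k - 1, pairs)
                self._trace_WM1(k, j, pairs)
                return
        raise AssertionError("WM traceback failed")

    def _trace_WM1(self, i: int, j: int, pairs: list) -> None:
        p, V, WM1 = self.p, self.V, self.WM1
        e = WM1[i, j]
        if V[i, j] < _INF and np.isclose(e, V[i, j] + p.multiloop_b):
            self._trace_V(i, j, pairs)
            return
        self._trace_WM1(i, j - 1, pairs)


def fold_self_dG(seq: str, params: NNParameterSet | None = None) -> FoldResult:
    """Minimum free energy and structure of the intramolecular fold of *seq*.

    Sequences unable to form any Watson-Crick pair (or any stabilizing
    structure) score exactly 0 with an all-dot structure.
    """
    params = params or default_parameters()
    validate_rna(seq)
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if len(seq) <= MIN_HAIRPIN + 1:
        return FoldResult(0.0, "." * len(seq))
    f = _Folder(seq, params)
    mfe = f.fill()
    if mfe >= 0.0:
        return FoldResult(0.0, "." * len(seq))
    pairs = f.traceback()
    db = ["."] * len(seq)
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult(float(mfe), "".join(db))
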