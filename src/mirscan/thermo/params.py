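"""Nearest-neighbor parameter sets for RNA-RNA duplex thermodynamics at 37 C.

The bundled default is the Xia et al. (1998) Watson-Crick stack table with
helix initiation and terminal A-U penalties, plus monotone loop penalty
tables (hairpin / bulge / internal) anchored at small sizes and extrapolated
with the Jacobson-Stockmayer entropy term. Alternative tables can be loaded
from plain-text files in the same format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping

from ..alphabet import RNA_BASES, validate_rna

# 1.75 * R * T at 310.15 K, for loop-size extrapolation beyond the tables
_JS_COEF = 1.75 * 0.0019872 * 310.15

MIN_HAIRPIN = 3  # minimum unpaired nucleotides in a hairpin loop


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor free-energy parameters (kcal/mol, 37 C).

    Attributes
    ----------
    stack_dG:
        Maps each of the 16 Watson-Crick dinucleotide stacks (keyed by the
        5'->3' dinucleotide on the guide strand; partner implied as the
        exact complement) to its stack free energy.
    init_dG:
        Helix initiation penalty.
    terminal_AU_dG:
        Penalty applied once per helix terminus closed by an A-U pair.
    hairpin_dG, bulge_dG, internal_dG:
        Loop penalties by loop size (number of unpaired nucleotides);
        sizes beyond the table are extrapolated logarithmically.
    multiloop_a, multiloop_b, multiloop_c:
        Affine multibranch-loop model: a + b per branch (closing helix
        included) + c per unpaired nucleotide.
    """

    stack_dG: Mapping[str, float]
    init_dG: float
    terminal_AU_dG: float
    hairpin_dG: Mapping[int, float]
    bulge_dG: Mapping[int, float]
    internal_dG: Mapping[int, float]
    multiloop_a: float = 3.4
    multiloop_b: float = 0.4
    multiloop_c: float = 0.0
    name: str = "xia1998"
    version: str = "1"
    _loop_max: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        expected = {a + b for a in RNA_BASES for b in RNA_BASES}
        missing = expected - set(self.stack_dG)
        if missing:
            raise ValueError(f"stack table incomplete, missing {sorted(missing)}")
        for k, v in self.stack_dG.items():
            if v >= 0:
                raise ValueError(f"stack {k} has non-negative energy {v}")
        for tab, minsize in ((self.hairpin_dG, MIN_HAIRPIN),
                             (self.bulge_dG, 1), (self.internal_dG, 2)):
            sizes = sorted(tab)
            if sizes[0] > minsize:
                raise ValueError("loop table does not cover minimal size")
            prev = None
            for s in sizes:
                if tab[s] <= 0:
                    raise ValueError(f"loop penalty for size {s} not positive")
                if prev is not None and tab[s] < prev:
                    raise ValueError("loop penalties must be non-decreasing")
                prev = tab[s]

    def _loop(self, table: Mapping[int, float], size: int) -> float:
        if size in table:
            return table[size]
        mx = max(table)
        return table[mx] + _JS_COEF * math.log(size / mx)

    def hairpin(self, size: int) -> float:
        if size < MIN_HAIRPIN:
            raise ValueError(f"hairpin loop of size {size} < {MIN_HAIRPIN}")
        return self._loop(self.hairpin_dG, size)

    def bulge(self, size: int) -> float:
        return self._loop(self.bulge_dG, size)

    def internal(self, size: int) -> float:
        return self._loop(self.internal_dG, size)

    def terminal_penalty(self, base: str) -> float:
        """Terminal correction for a helix end closed by `base` paired WC."""
        return self.terminal_AU_dG if base in ("A", "U") else 0.0


def _parse_stacks(text: str) -> tuple[dict[str, float], float, float]:
    stacks: dict[str, float] = {}
    init = terminal_au = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, val = line.split("\t")
        if key == "init":
            init = float(val)
        elif key == "terminal_AU":
            terminal_au = float(val)
        else:
            stacks[validate_rna(key, name="stack key")] = float(val)
    if init is None or terminal_au is None:
        raise ValueError("stack table missing init/terminal_AU corrections")
    return stacks, init, terminal_au


def _parse_loops(text: str) -> dict[str, dict[int, float]]:
    tables: dict[str, dict[int, float]] = {"hairpin": {}, "bulge": {}, "internal": {}}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        kind, size, val = line.split("\t")
        tables[kind][int(size)] = float(val)
    return tables


def load_parameter_set(stack_path=None, loop_path=None, name: str = "custom") -> NNParameterSet:
    """Load an NNParameterSet from plain-text tables (bundled format)."""
    if stack_path is None and loop_path is None:
        return default_parameters()
    stacks, init, term = _parse_stacks(open(stack_path).read())
    loops = _parse_loops(open(loop_path).read())
    return NNParameterSet(stacks, init, term,
                          loops["hairpin"], loops["bulge"], loops["internal"],
                          name=name)


@lru_cache(maxsize=1)
def default_parameters() -> NNParameterSet:
    """The bundled Xia et al. 1998 parameter set."""
    pkg = resources.files(__package__) / "data"
    stacks, init, term = _parse_stacks((pkg / "xia1998_stacks.tsv").read_text())
    loops = _parse_loops((pkg / "loops.tsv").read_text())
    return NNParameterSet(stacks, init, term,
                          loops["hairpin"], loops["bulge"], loops["internal"])
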