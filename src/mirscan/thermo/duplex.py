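"""Fully paired guide-target duplex energies and per-position profiles."""

from __future__ import annotations

from dataclasses import dataclass

from ..alphabet import validate_rna
from .params import NNParameterSet, default_parameters

GUIDE_LENGTH = 22


@dataclass(frozen=True)
class DuplexProfile:
    """Stack free energies of a fully paired duplex, one per dinucleotide.

    ``dG_i[k]`` (0-based list) is the energy of the stack whose 5' pair sits
    at guide position k+1 (1-based, 5'->3' along the guide).
    """

    dG_i: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.dG_i)

    def __getitem__(self, i: int) -> float:
        return self.dG_i[i]

    def __iter__(self):
        return iter(self.dG_i)


def nn_stack_dG(top: str, params: NNParameterSet | None = None) -> float:
    """Stack free energy of the 5'->3' dinucleotide *top* paired with its
    exact Watson-Crick complement (kcal/mol)."""
    params = params or default_parameters()
    validate_rna(top, name="dinucleotide")
    if len(top) != 2:
        raise ValueError(f"expected a dinucleotide, got {top!r}")
    return params.stack_dG[top]


def duplex_dG_profile(guide: str, params: NNParameterSet | None = None) -> DuplexProfile:
    """Per-position stack profile for the fully complementary duplex."""
    params = params or default_parameters()
    validate_rna(guide, name="guide")
    if len(guide) < 2:
        raise ValueError("guide must be at least 2 nt for a stack profile")
    return DuplexProfile(tuple(params.stack_dG[guide[i:i + 2]]
                               for i in range(len(guide) - 1)))


def duplex_dG_total(guide: str, params: NNParameterSet | None = None, *,
                    corrections: bool = True,
                    expected_length: int | None = GUIDE_LENGTH) -> float:
    """Total free energy of the fully paired guide:target duplex.

    With ``corrections`` on (default) the helix initiation penalty and one
    terminal A-U penalty per A-U/U-A-closed end are added to the stack sum;
    with corrections off the bare stack sum is returned.
    """
    params = params or default_parameters()
    validate_rna(guide, name="guide")
    if expected_length is not None and len(guide) != expected_length:
        raise ValueError(
            f"guide length {len(guide)} != {expected_length} "
            "(pass expected_length=None to override)")
    total = sum(duplex_dG_profile(guide, params))
    if corrections:
        total += params.init_dG
        total += params.terminal_penalty(guide[0])
        total += params.terminal_penalty(guide[-1])
    return total
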