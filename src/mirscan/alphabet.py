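"""RNA alphabet handling: validation, DNA->RNA transcription, complements.

The internal alphabet is strictly ``ACGU``. DNA input (``T``) is converted
once, at the I/O boundary; computational routines reject anything else.
"""

from __future__ import annotations

RNA_BASES = ("A", "C", "G", "U")
_RNA_SET = frozenset(RNA_BASES)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})


class AlphabetError(ValueError):
    """Sequence contains characters outside the strict RNA alphabet."""


def to_rna(seq: str) -> str:
    """Uppercase a sequence and transcribe T->U (I/O boundary only)."""
    return seq.upper().replace("T", "U")


def validate_rna(seq: str, *, name: str = "sequence") -> str:
    """Return *seq* if it is strict uppercase ACGU, else raise AlphabetError."""
    bad = set(seq) - _RNA_SET
    if bad:
        raise AlphabetError(
            f"{name} contains non-RNA characters {sorted(bad)!r}; "
            "expected only A, C, G, U (transcribe DNA at the I/O boundary)"
        )
    return seq


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str) -> bool:
    """True iff *a* and *b* form a Watson-Crick pair (no wobble)."""
    return (a, b) in WATSON_CRICK
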