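"""Intermolecular hybridization energy between two RNA strands.

Dynamic program over antiparallel pairings of two strands: Watson-Crick
stacks, bulge/internal loops between consecutive pairs (capped at
``MAX_INTERIOR`` unpaired nucleotides), helix initiation, and terminal A-U
penalties. No intramolecular pairs are allowed. Returns 0 when no
hybridization is stabilizing.
"""

from __future__ import annotations

from ..alphabet import can_pair, validate_rna
from .fold import MAX_INTERIOR
from .params import NNParameterSet, default_parameters

_INF = float("inf")


def dimer_dG(seqA: str, seqB: str, params: NNParameterSet | None = None) -> float:
    """Minimum free energy of the best inter-molecular duplex (kcal/mol).

    Typically called with ``seqA == seqB == guide`` to assess guide-strand
    self-dimerization. Symmetric in its two arguments.
    """
    params = params or default_parameters()
    validate_rna(seqA, name="seqA")
    validate_rna(seqB, name="seqB")
    a, b = seqA, seqB
    n, m = len(a), len(b)
    # C[i][j]: best energy of a duplex whose 3'-most pair on A is (a[i], b[j]),
    # including initiation and the start-terminal penalty.
    C = [[_INF] * m for _ in range(n)]
    best = 0.0
    for i in range(n):
        ai = a[i]
        for j in range(m - 1, -1, -1):
            if not can_pair(ai, b[j]):
                continue
            e = params.init_dG + params.terminal_penalty(ai)
            for pi in range(max(0, i - MAX_INTERIOR - 1), i):
                row = C[pi]
                g1 = i - pi - 1
                for pj in range(j + 1, min(m, j + MAX_INTERIOR - g1 + 2)):
                    prev = row[pj]
                    if prev == _INF:
                        continue
                    g2 = pj - j - 1
                    if g1 == 0 and g2 == 0:
                        step = params.stack_dG[a[pi:pi + 2]]
                    elif min(g1, g2) == 0:
                        step = params.bulge(g1 + g2)
                    else:
                        step = params.internal(g1 + g2)
                    if prev + step < e:
                        e = prev + step
            C[i][j] = e
            closed = e + params.terminal_penalty(ai)
            if closed < best:
                best = closed
    return best


def target_local_dG(transcript: str, site_start: int, window_flank: int = 100,
                    params: NNParameterSet | None = None, *,
                    site_length: int = 22) -> float:
    """Local secondary-structure stability around a target site.

    Folds the window ``[site_start - flank, site_start + site_length - 1
    + flank]`` (1-based, clipped to the transcript) and returns its MFE —
    a proxy for how structured, and hence how occluded, the target region
    is. More negative means more structured.
    """
    from .fold import fold_self_dG

    params = params or default_parameters()
    validate_rna(transcript, name="transcript")
    if site_start < 1 or site_start + site_length - 1 > len(transcript):
        raise IndexError(
            f"site [{site_start}, {site_start + site_length - 1}] outside "
            f"transcript of length {len(transcript)}")
    lo = max(0, site_start - 1 - window_flank)
    hi = min(len(transcript), site_start - 1 + site_length + window_flank)
    return fold_self_dG(transcript[lo:hi], params).mfe_dG
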