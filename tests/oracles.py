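"""Independent brute-force oracles used to cross-check the fast paths.

Everything here deliberately avoids the package's dynamic programs: folding
is exhaustive enumeration over nested structures, dimers enumerate every
antiparallel pairing chain, AUC counts concordant pairs, DUST recounts
triplets. Oracles share only the parameter *tables* with the implementation,
never its algorithms.
"""

from __future__ import annotations

from mirscan.alphabet import can_pair
from mirscan.thermo import MAX_INTERIOR, MIN_HAIRPIN


def enumerate_structures(seq: str) -> list[tuple[tuple[int, int], ...]]:
    """All nested Watson-Crick structures with hairpin loops >= 3 nt."""

    memo: dict[tuple[int, int], list] = {}

    def rec(i: int, j: int):  # structures over region [i, j)
        if j - i < MIN_HAIRPIN + 2:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + MIN_HAIRPIN + 1, j):
            if can_pair(seq[i], seq[k]):
                for inner in rec(i + 1, k):
                    for outer in rec(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        memo[key] = out
        return out

    return rec(0, len(seq))


def structure_energy(seq: str, pairs, params) -> float:
    """Loop-decomposition energy of a nested structure (same model as the
    DP, evaluated by explicit loop classification)."""
    pairs = sorted(pairs)
    if not pairs:
        return 0.0
    # direct children of each pair (and of the exterior)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        stack.append(p)
        children.setdefault(p, [])
    total = 0.0
    for (i, j) in pairs:
        ch = children[(i, j)]
        if not ch:
            total += params.hairpin(j - i - 1)
        elif len(ch) == 1:
            (p, q) = ch[0]
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                total += params.stack_dG[seq[i:i + 2]]
            elif min(l1, l2) == 0:
                total += params.bulge(l1 + l2)
            else:
                total += params.internal(l1 + l2)
        else:
            unpaired = (j - i - 1) - sum(q - p + 1 for (p, q) in ch)
            total += (params.multiloop_a
                      + params.multiloop_b * (len(ch) + 1)
                      + params.multiloop_c * unpaired)
    return total


def brute_force_mfe(seq: str, params) -> float:
    best = 0.0
    for s in enumerate_structures(seq):
        # skip structures whose interior loops exceed the DP cap
        e = structure_energy(seq, s, params)
        if e < best:
            best = e
    return best


def enumerate_dimer_chains(a: str, b: str):
    """Every antiparallel pairing chain between two strands: positions on A
    strictly increasing, on B strictly decreasing, gaps <= MAX_INTERIOR."""
    singles = [(i, j) for i in range(len(a)) for j in range(len(b))
               if can_pair(a[i], b[j])]

    def rec(chain):
        yield chain
        last_i, last_j = chain[-1]
        for (i, j) in singles:
            if (i > last_i and j < last_j
                    and (i - last_i - 1) + (last_j - j - 1) <= MAX_INTERIOR):
                yield from rec(chain + [(i, j)])

    for start in singles:
        yield from rec([start])


def dimer_chain_energy(a: str, b: str, chain, params) -> float:
    e = params.init_dG
    e += params.terminal_penalty(a[chain[0][0]])
    e += params.terminal_penalty(a[chain[-1][0]])
    for (i1, j1), (i2, j2) in zip(chain, chain[1:]):
        g1, g2 = i2 - i1 - 1, j1 - j2 - 1
        if g1 == 0 and g2 == 0:
            e += params.stack_dG[a[i1:i1 + 2]]
        elif min(g1, g2) == 0:
            e += params.bulge(g1 + g2)
        else:
            e += params.internal(g1 + g2)
    return e


def brute_force_dimer(a: str, b: str, params) -> float:
    best = 0.0
    for chain in enumerate_dimer_chains(a, b):
        e = dimer_chain_energy(a, b, chain, params)
        if e < best:
            best = e
    return best


def pair_counting_auc(predictions, labels) -> float:
    """AUC as the Mann-Whitney U normalization: P(pred+ > pred-) + ties/2."""
    pos = [p for p, l in zip(predictions, labels) if l]
    neg = [p for p, l in zip(predictions, labels) if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_dust(seq: str) -> float:
    """Whole-sequence DUST score by direct triplet counting."""
    triplets = [seq[i:i + 3] for i in range(len(seq) - 2)]
    return sum(c * (c - 1) / 2
               for c in (triplets.count(t) for t in set(triplets))) / (len(seq) - 3)


def ungapped_best_duplex(a: str, b: str, params) -> float:
    """Best fully stacked (no-loop) duplex over all offsets and run lengths."""
    best = 0.0
    n, m = len(a), len(b)
    for i0 in range(n):
        for j0 in range(m - 1, -1, -1):
            # extend an ungapped run starting at (i0, j0)
            for length in range(1, min(n - i0, j0 + 1) + 1):
                ii = [i0 + k for k in range(length)]
                jj = [j0 - k for k in range(length)]
                if not all(can_pair(a[i], b[j]) for i, j in zip(ii, jj)):
                    break
                chain = list(zip(ii, jj))
                e = dimer_chain_energy(a, b, chain, params)
                best = min(best, e)
    return best
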