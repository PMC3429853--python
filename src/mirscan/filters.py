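"""Artifact and off-target filters applied to guide candidates before ranking.

Four independent filters: forbidden sequence motifs, DUST-style low
complexity, stable guide self-structure, and matches to known miRNA seed
regions. A candidate survives iff every enabled filter passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .alphabet import to_rna, validate_rna
from . import thermo

#: motifs whose removal improved prediction (CCCC deliberately absent:
#: filtering it did not help); UUUU additionally terminates pol III.
DEFAULT_MOTIFS = ("UGGC", "GCCA", "GGGG", "UUUU", "AAAA")
DEFAULT_SELF_STRUCTURE_DG = -2.0
DEFAULT_DUST_THRESHOLD = 2.0
DEFAULT_SEED_REGION = (2, 7)  # 1-based inclusive positions on the guide


@dataclass(frozen=True)
class FilterConfig:
    motif_list: tuple[str, ...] = DEFAULT_MOTIFS
    self_structure_threshold: float = DEFAULT_SELF_STRUCTURE_DG
    complexity_threshold: float = DEFAULT_DUST_THRESHOLD
    seed_region: tuple[int, int] = DEFAULT_SEED_REGION
    seed_set: frozenset[str] = frozenset()
    motifs_enabled: bool = False
    complexity_enabled: bool = False
    self_structure_enabled: bool = False
    seed_enabled: bool = False
    params: thermo.NNParameterSet | None = field(default=None, compare=False)


@dataclass(frozen=True)
class CandidateFlags:
    motif: bool = False
    complexity: bool = False
    self_structure: bool = False
    seed_match: bool = False
    matched_motifs: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not (self.motif or self.complexity or self.self_structure
                    or self.seed_match)

    def labels(self) -> str:
        names = [n for n, v in (("motif", self.motif),
                                ("complexity", self.complexity),
                                ("self_structure", self.self_structure),
                                ("seed", self.seed_match)) if v]
        return ",".join(names) if names else "-"


@dataclass(frozen=True)
class FilterReport:
    flags: tuple[CandidateFlags, ...]
    removed_motif: int
    removed_complexity: int
    removed_self_structure: int
    removed_seed: int

    @property
    def n_survivors(self) -> int:
        return sum(f.passed for f in self.flags)


def motif_flags(guide: str, motif_list: Iterable[str] = DEFAULT_MOTIFS) -> tuple[bool, tuple[str, ...]]:
    """True plus the matched motifs iff any forbidden motif is a substring."""
    validate_rna(guide, name="guide")
    hits = tuple(m for m in motif_list if m in guide)
    return bool(hits), hits


def dust_score(guide: str, window: int | None = None,
               threshold: float = DEFAULT_DUST_THRESHOLD) -> tuple[float, bool]:
    """DUST-style low-complexity score and flag.

    Per window of length w: sum c_t(c_t - 1)/2 over triplet counts c_t,
    normalized by (w - 3); the score is the maximum over windows (default:
    the whole guide as a single window).
    """
    validate_rna(guide, name="guide")
    w = window or len(guide)
    if w < 4:
        raise ValueError("window must cover at least 4 nt (2 triplets)")
    best = 0.0
    for start in range(0, max(1, len(guide) - w + 1)):
        chunk = guide[start:start + w]
        counts: dict[str, int] = {}
        for i in range(len(chunk) - 2):
            t = chunk[i:i + 3]
            counts[t] = counts.get(t, 0) + 1
        score = sum(c * (c - 1) / 2 for c in counts.values()) / (len(chunk) - 3)
        best = max(best, score)
    return best, best > threshold


def seed_match(guide: str, seed_set: frozenset[str] | set[str],
               seed_region: tuple[int, int] = DEFAULT_SEED_REGION) -> bool:
    """True iff the guide's seed substring is one of the known seeds."""
    validate_rna(guide, name="guide")
    if not seed_set:
        warnings.warn("empty seed set: seed filter is disabled", stacklevel=2)
        return False
    lo, hi = seed_region
    return guide[lo - 1:hi] in seed_set


def self_structure_flag(guide: str, threshold: float = DEFAULT_SELF_STRUCTURE_DG,
                        params: thermo.NNParameterSet | None = None) -> bool:
    """True iff the guide folds into a self-structure below *threshold*."""
    return thermo.fold_self_dG(guide, params).mfe_dG < threshold


def extract_seed_set(mature_fasta, seed_region: tuple[int, int] = DEFAULT_SEED_REGION) -> frozenset[str]:
    """Seed substrings (same region rule as the guide) from a mature-miRNA
    FASTA (miRBase dialect; DNA or RNA alphabet accepted)."""
    lo, hi = seed_region
    seeds = set()
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        seq = to_rna(str(rec.seq))
        if len(seq) >= hi:
            seeds.add(validate_rna(seq[lo - 1:hi], name=rec.id))
    return frozenset(seeds)


def evaluate_candidate(guide: str, config: FilterConfig) -> CandidateFlags:
    motif = False
    matched: tuple[str, ...] = ()
    if config.motifs_enabled:
        motif, matched = motif_flags(guide, config.motif_list)
    complexity = False
    if config.complexity_enabled:
        _, complexity = dust_score(guide, threshold=config.complexity_threshold)
    self_struct = False
    if config.self_structure_enabled:
        self_struct = self_structure_flag(guide, config.self_structure_threshold,
                                          config.params)
    seed = False
    if config.seed_enabled and config.seed_set:
        seed = seed_match(guide, config.seed_set, config.seed_region)
    return CandidateFlags(motif=motif, complexity=complexity,
                          self_structure=self_struct, seed_match=seed,
                          matched_motifs=matched)


def apply_filters(candidates: Sequence[str], config: FilterConfig) -> tuple[FilterReport, list[str]]:
    """Flag every candidate; survivors keep their input order."""
    flags = tuple(evaluate_candidate(g, config) for g in candidates)
    survivors = [g for g, f in zip(candidates, flags) if f.passed]
    return FilterReport(
        flags=flags,
        removed_motif=sum(f.motif for f in flags),
        removed_complexity=sum(f.complexity for f in flags),
        removed_self_structure=sum(f.self_structure for f in flags),
        removed_seed=sum(f.seed_match for f in flags),
    ), survivors
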