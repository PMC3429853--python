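"""Synthetic transcripts and activity datasets for testing the pipeline.

The activity generator draws random 22-mer guides, evaluates the generating
coefficient table on their features, adds Gaussian noise on the ln scale,
and exponentiates back to a percent silencing score. Records whose percent
score had to be clipped into [0.5, 100] carry a ``clipped`` flag; the
unclipped latent ln value is available from :func:`synth_activity_frame`
for parameter-recovery work, since the built-in generating model places
most of its ln-scores far outside the representable percent range.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityRecord
from .alphabet import RNA_BASES
from .features import GUIDE_LENGTH, feature_frame
from .filters import DEFAULT_MOTIFS
from .model import CoefficientTable, builtin_table2
from . import thermo

CLIP_LO, CLIP_HI = 0.5, 100.0


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic activity dataset."""

    n: int
    table: CoefficientTable = field(default_factory=builtin_table2)
    noise_sd: float = 1.0
    gc: float = 0.5
    seed: int = 0
    planted_motif_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")


def synth_transcript(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random i.i.d. RNA sequence with P(G) + P(C) = gc."""
    if length < GUIDE_LENGTH:
        raise ValueError(f"transcript length must be >= {GUIDE_LENGTH}")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G U
    return "".join(rng.choice(list(RNA_BASES), size=length, p=probs))


def synth_guides(n: int, gc: float = 0.5, seed: int = 0,
                 planted_motif_fraction: float = 0.0) -> list[str]:
    """Random 22-mer guides, optionally with a forbidden motif planted into
    a given fraction of them (uniformly chosen motif and offset)."""
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    base = rng.choice(list(RNA_BASES), size=(n, GUIDE_LENGTH), p=probs)
    guides = ["".join(row) for row in base]
    if planted_motif_fraction > 0:
        py_rng = random.Random(seed + 1)
        k = int(round(planted_motif_fraction * n))
        for idx in py_rng.sample(range(n), k):
            motif = py_rng.choice(DEFAULT_MOTIFS)
            off = py_rng.randrange(GUIDE_LENGTH - len(motif) + 1)
            g = guides[idx]
            guides[idx] = g[:off] + motif + g[off + len(motif):]
    return guides


def synth_activity_frame(spec: SynthSpec,
                         params: thermo.NNParameterSet | None = None) -> pd.DataFrame:
    """Full synthetic table: guide, latent ln score, clipped percent score."""
    guides = synth_guides(spec.n, spec.gc, spec.seed, spec.planted_motif_fraction)
    frame = feature_frame(guides, params=params)
    latent = spec.table.score_frame(frame)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed + 7)
        latent = latent + rng.normal(0.0, spec.noise_sd, size=spec.n)
    percent = np.exp(latent)
    clipped = (percent < CLIP_LO) | (percent > CLIP_HI)
    percent = np.clip(percent, CLIP_LO, CLIP_HI)
    return pd.DataFrame({
        "guide_seq": guides,
        "latent_ln": latent,
        "silencing_percent": percent,
        "clipped": clipped,
    })


def synth_activity_dataset(spec: SynthSpec,
                           params: thermo.NNParameterSet | None = None) -> list[ActivityRecord]:
    """Synthetic activity records in the percent dialect the trainer reads."""
    df = synth_activity_frame(spec, params)
    return [ActivityRecord(guide=row.guide_seq, score=float(row.silencing_percent),
                           source="synthetic", clipped=bool(row.clipped))
            for row in df.itertuples(index=False)]
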