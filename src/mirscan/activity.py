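"""Activity records: 22-nt guides with experimental silencing scores.

The on-disk dialect is a tab-separated table with columns ``guide_seq``,
``silencing_percent`` and optional ``source`` / ``clipped``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .alphabet import to_rna, validate_rna

#: floor (in percent) applied to silencing scores before taking the log,
#: guarding ln(0); configurable in :func:`ln_activity`.
LN_FLOOR = 0.5


@dataclass(frozen=True)
class ActivityRecord:
    """A guide strand with its measured silencing efficiency in [0, 100]%."""

    guide: str
    score: float
    source: str | None = None
    clipped: bool = False  # synthetic-data bookkeeping: score hit a clip bound

    def __post_init__(self) -> None:
        validate_rna(self.guide, name="guide")
        if not 0.0 <= self.score <= 100.0:
            raise ValueError(f"silencing score {self.score} outside [0, 100]")


def ln_activity(score: float, floor: float = LN_FLOOR) -> float:
    """Natural log of a silencing score, flooring at *floor* percent."""
    return math.log(max(score, floor))


def read_activity_table(path) -> list[ActivityRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"guide_seq", "silencing_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"activity table {path} missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(ActivityRecord(
            guide=validate_rna(to_rna(row.guide_seq), name="guide_seq"),
            score=float(row.silencing_percent),
            source=str(row.source) if "source" in df.columns else None,
            clipped=bool(row.clipped) if "clipped" in df.columns else False,
        ))
    if not records:
        raise ValueError(f"activity table {path} is empty")
    return records


def write_activity_table(records, path) -> None:
    pd.DataFrame({
        "guide_seq": [r.guide for r in records],
        "silencing_percent": [r.score for r in records],
        "source": [r.source or "" for r in records],
        "clipped": [r.clipped for r in records],
    }).to_csv(path, sep="\t", index=False)
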