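"""Transcript scanning: enumerate target sites, score guides, filter, rank.

Coordinates are 1-based and inclusive on the sense transcript. The guide
strand is the reverse complement of the 22-nt sense target site. The
default reported score is on the ln scale; ``exp(score)`` clipped to
[0, 100] is available as a percent-scale convenience column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import reverse_complement, to_rna, _RNA_SET
from .features import GUIDE_LENGTH, feature_frame
from .filters import FilterConfig, FilterReport, apply_filters
from .model import CoefficientTable
from . import thermo

OUTPUT_COLUMNS = ("transcript_id", "start", "sense_seq", "guide_seq",
                  "dG", "dG1", "dG_self", "score", "flags", "rank")


@dataclass(frozen=True)
class TargetSite:
    """A 22-nt sense target site and its derived guide strand."""

    transcript_id: str
    start: int  # 1-based inclusive
    sense_seq: str
    guide: str


@dataclass(frozen=True)
class ScanReport:
    n_sites: int
    n_skipped: int  # sites containing non-ACGU characters
    filter_report: FilterReport | None
    n_outside_dg_range: int


def enumerate_candidates(transcript: str, transcript_id: str = "transcript",
                         *, site_length: int = GUIDE_LENGTH) -> list[TargetSite]:
    """Every possible target site; sites with degenerate characters skipped."""
    if len(transcript) < site_length:
        raise ValueError(
            f"transcript {transcript_id!r} shorter than {site_length} nt")
    sites = []
    for start in range(1, len(transcript) - site_length + 2):
        sense = transcript[start - 1:start - 1 + site_length]
        if set(sense) <= _RNA_SET:
            sites.append(TargetSite(transcript_id=transcript_id, start=start,
                                    sense_seq=sense,
                                    guide=reverse_complement(sense)))
    return sites


def scan_sequence(transcript: str, transcript_id: str,
                  coeffs: CoefficientTable,
                  filter_config: FilterConfig | None = None, *,
                  dg_range: tuple[float, float] | None = None,
                  top: int | None = None,
                  params: thermo.NNParameterSet | None = None,
                  percent_column: bool = False) -> tuple[pd.DataFrame, ScanReport]:
    """Scan one transcript; returns the ranked table and a scan report.

    Survivors are sorted by descending predicted score with a stable
    tie-break on start position; filtered-out candidates are omitted from
    the table but counted in the report.
    """
    params = params or thermo.default_parameters()
    n_possible = len(transcript) - GUIDE_LENGTH + 1
    sites = enumerate_candidates(transcript, transcript_id)
    n_skipped = n_possible - len(sites)
    if not sites:
        empty = pd.DataFrame(columns=list(OUTPUT_COLUMNS))
        return empty, ScanReport(0, n_skipped, None, 0)
    guides = [s.guide for s in sites]
    frame = feature_frame(guides, params=params, include_self=True)
    scores = coeffs.score_frame(frame)
    config = filter_config or FilterConfig()
    freport, _ = apply_filters(guides, config)
    dG = frame["dG"].to_numpy()
    in_range = np.ones(len(sites), dtype=bool)
    if dg_range is not None:
        lo, hi = dg_range
        in_range = (dG >= lo) & (dG <= hi)
    keep = np.array([f.passed for f in freport.flags]) & in_range
    df = pd.DataFrame({
        "transcript_id": [s.transcript_id for s in sites],
        "start": [s.start for s in sites],
        "sense_seq": [s.sense_seq for s in sites],
        "guide_seq": guides,
        "dG": dG,
        "dG1": frame["dG1"].to_numpy(),
        "dG_self": frame["dG_self"].to_numpy(),
        "score": scores,
        "flags": [f.labels() for f in freport.flags],
    })
    df = df[keep]
    df = df.sort_values(["score", "start"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if top is not None:
        df = df.head(top)
    report = ScanReport(n_sites=len(sites), n_skipped=n_skipped,
                        filter_report=freport,
                        n_outside_dg_range=int((~in_range).sum()))
    if percent_column:
        df = df.assign(percent_score=np.clip(np.exp(df["score"]), 0.0, 100.0))
    return df, report


def read_fasta_transcripts(path) -> list[tuple[str, str]]:
    """(id, RNA sequence) per FASTA record; DNA transcribed, lowercase
    uppercased with a warning."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if any(c.islower() for c in raw):
            warnings.warn(f"{rec.id}: lowercase (masked) bases uppercased",
                          stacklevel=2)
        out.append((rec.id, to_rna(raw)))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def scan_transcripts(fasta_path, coeffs: CoefficientTable,
                     filter_config: FilterConfig | None = None, *,
                     dg_range: tuple[float, float] | None = None,
                     top: int | None = None,
                     params: thermo.NNParameterSet | None = None,
                     percent_column: bool = False) -> tuple[pd.DataFrame, dict[str, ScanReport]]:
    """Scan every transcript in a FASTA file; tables are concatenated."""
    frames, reports = [], {}
    for tid, seq in read_fasta_transcripts(fasta_path):
        df, rep = scan_sequence(seq, tid, coeffs, filter_config,
                                dg_range=dg_range, top=top, params=params,
                                percent_column=percent_column)
        frames.append(df)
        reports[tid] = rep
    return pd.concat(frames, ignore_index=True), reports
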