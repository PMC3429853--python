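# mirscan

Design and scoring of efficient miR30-based shRNA guide strands.

`mirscan` scans transcripts for all possible 22-nt guide strands, computes
thermodynamic and position-dependent sequence features for each candidate,
scores them with a built-in multiple-regression model (or any user-supplied
coefficient table), and filters out artifact-prone candidates (forbidden
motifs, low-complexity sequences, stable guide self-structures, and matches
to known miRNA seed regions). It also ships the full training pipeline —
correlation screening with split-stability analysis, OLS with iterative
term reduction, non-overlapping cross-validation, and ROC analysis — so
the model can be refit on any (guide sequence, silencing score) table.

## Layout

| module | what it does |
| --- | --- |
| `mirscan.thermo` | nearest-neighbor RNA–RNA thermodynamics: duplex ΔG and per-position stack profiles, intramolecular MFE folding (Zuker-style DP), inter-molecular dimer ΔG, local target-structure ΔG |
| `mirscan.features` | one-hot position encoding (`A_1 … U_22`), feature-vector assembly (`dG`, `dG2`, `dG3`, `dG1`, …), per-position matrix reduction to 66 indicators |
| `mirscan.filters` | motif, DUST low-complexity, self-structure and miRNA-seed filters |
| `mirscan.model` | scoring with the built-in coefficient table, OLS + t-tests, iterative model reduction, feature selection with S_n stability, n-fold cross-validation, ROC/AUC, binning |
| `mirscan.scan` | transcript scanner and ranked TSV reports |
| `mirscan.synth` | seeded synthetic transcripts and activity datasets |

Thermodynamic parameters (Xia et al. 1998 stacks plus loop tables) are
bundled as plain-text data files under `src/mirscan/thermo/data/` and can
be swapped via `thermo.load_parameter_set`. The built-in scoring model
lives in `src/mirscan/model/data/table2.json`.

## CLI

```bash
# rank all candidate guides across transcripts in a FASTA (DNA or RNA)
mirscan scan --fasta transcripts.fa --model table2 --out hits.tsv \
    --dg-range -35:-25 --filter-motifs --filter-complexity \
    --filter-self -2.0 --seed-filter mature.fa --seed-region 2:7 --top 20

# refit the model on an activity table (TSV: guide_seq, silencing_percent)
mirscan train --activities activities.tsv --out model.json --cv 5

# score an activity table with a model and report R / R^2 / AUC
mirscan evaluate --activities activities.tsv --model model.json --roc-threshold 75
```

Scan output columns: `transcript_id, start, sense_seq, guide_seq, dG, dG1,
dG_self, score, flags, rank`. Coordinates are 1-based inclusive on the
sense transcript; the score is on the natural-log scale (`--percent` adds
`exp(score)` clipped to [0, 100]).

## Notes

- Guide positions are numbered 1–22 from the 5' end; the guide is the
  reverse complement of the sense target site.
- `duplex_dG_total` defaults to corrections on (helix initiation +
  terminal A·U penalties); pass `corrections=False` for the bare stack sum.
- Folding uses Watson–Crick pairs only, a minimum hairpin loop of 3 nt,
  and monotone loop penalty tables; it is verified against exhaustive
  structure enumeration in the test suite.
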