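#!/usr/bin/env python
"""Collate the analysis outputs into a single plain-text summary.

Reads the tables written by the earlier steps (variance partition,
genetic correlations, CV accuracies) from the results directory and
prints them together, mirroring the variance-partition figure, the
correlation heatmap and the accuracy-by-scheme panels as text tables.
"""

import argparse
from pathlib import Path

import pandas as pd

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

sections = [
    ("variance partition (PVE per model)", "pve.csv"),
    ("cross-environment genetic correlations (rA)", "genetic_correlations.csv"),
    ("per-environment genomic heritability", "heritability.csv"),
    ("pooled R2 (model x scheme)", "accuracy_pooled.csv"),
    ("mean within-environment R2", "accuracy_within_env.csv"),
    ("per-environment R2, New Environment scheme", "accuracy_new_environment_per_env.csv"),
]
lines = []
for title, fname in sections:
    path = args.results / fname
    if not path.exists():
        print(f"[missing] {fname} — run the earlier analysis steps first")
        continue
    table = pd.read_csv(path, index_col=0)
    lines += [title, "-" * len(title), table.to_string(), ""]
summary = "\n".join(lines)
(args.results / "summary.txt").write_text(summary + "\n")
print(summary)
print(f"wrote {args.results / 'summary.txt'}")
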