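#!/usr/bin/env python
"""Cluster Shared and Differential SAGs into patterns and major groups.

k = 30 correlation k-means per track, up/down split by the dominant
excursion of each cluster's mean fold-change profile, complete-linkage
merging into shared patterns (4 up + 3 down) and differential patterns
(10 up + 6 down), then major groups (>10% of differential genes) from the
pattern-level FL-SL difference profiles.
"""

import argparse
from pathlib import Path

import pandas as pd

from leafsen import io
from leafsen.pipeline import run_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results"))
args = ap.parse_args()

data = args.outdir / "data"
cm = io.read_count_matrix(data / "counts.tsv", data / "samples.tsv")
res = run_pipeline(cm, {"seed": args.seed})
patterns = res["patterns"]
io.write_table(patterns, args.outdir / "patterns.tsv")

truth = pd.read_csv(data / "truth.tsv", sep="\t").set_index("gene_id")
for track, sub in patterns.groupby("track"):
    n_pat = sub["pattern_id"].nunique()
    print(f"{track} track: {len(sub)} genes in {sub['cluster_id'].nunique()} "
          f"clusters -> {n_pat} patterns")
diff = patterns[patterns["track"] == "diff"]
if len(diff):
    groups = diff.groupby("group").agg(n=("gene_id", "size"),
                                       major=("major", "first"))
    print("major groups (>10% of differential genes):")
    print(groups.to_string())
    joined = diff.join(truth["archetype"], on="gene_id")
    purity = (joined.groupby("group")["archetype"]
              .agg(lambda s: s.value_counts(normalize=True).iloc[0]))
    print("dominant planted archetype fraction per group:")
    print(purity.round(3).to_string())
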