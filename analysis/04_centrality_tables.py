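#!/usr/bin/env python
"""Weighted centrality (strength, closeness, betweenness) of each disease in
the estimated per-sex networks; the table layout mirrors the published
centrality table (missing closeness for isolated nodes printed as '-').
Writes results/centrality/centrality_<sex>.tsv and prints the strongest hubs.
"""

from pathlib import Path

import pandas as pd

import comorbnet as cn
from comorbnet.centrality import centrality_table_to_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "centrality"
OUT.mkdir(parents=True, exist_ok=True)


def load_network(sex: str) -> cn.IsingNetwork:
    import numpy as np
    edges = pd.read_csv(ROOT / "networks" / f"network_{sex}.tsv", sep="\t")
    thr = pd.read_csv(ROOT / "networks" / f"thresholds_{sex}.tsv", sep="\t")
    labels = list(thr["node"])
    idx = {c: i for i, c in enumerate(labels)}
    w = np.zeros((len(labels), len(labels)))
    for _, r in edges.iterrows():
        i, j = idx[r["code_i"]], idx[r["code_j"]]
        w[i, j] = w[j, i] = r["weight"]
    return cn.IsingNetwork(w, thr["threshold"].to_numpy(), labels)


for sex in ("male", "female"):
    net = load_network(sex)
    table = cn.centrality_table(net)
    centrality_table_to_tsv(table, OUT / f"centrality_{sex}.tsv")
    top = table.sort_values("strength", ascending=False).head(5)
    print(f"{sex}: top-5 hubs by strength")
    for _, r in top.iterrows():
        c = "-" if pd.isna(r["closeness"]) else f"{r['closeness']:.4f}"
        print(f"  {r['node']:<8} s={r['strength']:.3f}  c={c}  "
              f"b={int(r['betweenness_int'])}")
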