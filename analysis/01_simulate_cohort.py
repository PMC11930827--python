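#!/usr/bin/env python
"""Simulate the study cohort: a planted comorbidity network over the 38-code
chronic-disease panel, Gibbs-sampled patient disease profiles, and a raw
visit-record file with injected mess (duplicate visits, garbled codes,
non-chronic diagnoses, out-of-window ages, single-disease patients).

Writes under results/data/: the raw record file, the ground-truth network
(edge list + thresholds) and the generator ledger.
"""

import json
from pathlib import Path

import comorbnet as cn

SEED = 20230601
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

panel, rules = cn.default_panel()
gt = cn.make_planted_network(len(panel.codes), 6, 0.5, w_out=0.0, b=-1.5,
                             seed=SEED)
gt.labels = list(panel.codes)

mess = cn.MessSpec(n_duplicates=100, n_invalid=50, n_nonchronic=60,
                   n_single_patients=40, n_out_of_age=20, n_merge_pairs=25)
frame, ledger = cn.make_record_file(
    cn.CohortSpec(n_patients=4000, ising=gt), mess, seed=SEED,
    path=OUT / "records.csv")

gt.to_tsv(OUT / "true_network.tsv", OUT / "true_thresholds.tsv")
(OUT / "ledger.json").write_text(json.dumps({
    "n_base_patients": ledger.n_base_patients,
    "n_records_emitted": ledger.n_records_emitted,
    "sex_counts": ledger.sex_counts,
    "injected": {
        "duplicates": ledger.n_duplicates,
        "invalid_codes": ledger.n_invalid,
        "non_chronic": ledger.n_nonchronic,
        "single_disease_patients": ledger.n_single_patients,
        "out_of_age_records": ledger.n_out_of_age_records,
        "merge_pairs": ledger.n_merge_pairs,
    },
    "expected_stage_drops": ledger.expected_stage_drops(0.01),
}, indent=2))

print(f"cohort: {ledger.n_base_patients} patients, "
      f"{ledger.n_records_emitted} raw records -> {OUT/'records.csv'}")
print(f"planted network: {len(gt.edge_set())} edges in 6 blocks, "
      f"w_in=0.5, b=-1.5")
print(f"injected mess: {mess}")
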