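#!/usr/bin/env python
"""Descriptive statistics: (a) the published cohort aggregates re-derived
from their printed counts (visit percentages, age-band shares, pooled mean
age), and (b) the same table schemas computed on the synthetic cohort.
Writes results/descriptives/*.tsv.
"""

from pathlib import Path

import comorbnet as cn
from comorbnet import reference as ref
from comorbnet.report import pooled_mean

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "descriptives"
OUT.mkdir(parents=True, exist_ok=True)

top10 = cn.prevalence_table_from_counts(ref.TOP10_VISITS, ref.TOTAL_RECORDS)
top10.to_csv(OUT / "published_top10.tsv", sep="\t", index=False)
print("published top-10 visit shares (recomputed from counts):")
print(top10.head(5).to_string(index=False))

bands = cn.age_distribution_from_counts(ref.AGE_BAND_VISITS)
bands.to_csv(OUT / "published_age_bands.tsv", sep="\t", index=False)
print("\npublished age-band shares (recomputed):")
print(bands.to_string(index=False))
pooled = pooled_mean({
    "male": (ref.MEAN_AGE["male"][0], ref.TOTAL_RECORDS_MALE),
    "female": (ref.MEAN_AGE["female"][0], ref.TOTAL_RECORDS_FEMALE)})
print(f"\npooled mean age from per-sex means: {pooled:.2f}")

records = cn.read_records(ROOT / "data" / "records.csv")
panel_cfg, rules = cn.default_panel()
cleaned = cn.deduplicate(cn.etl.filter_age(records))
cleaned = cn.apply_recoding(cleaned, rules)
prev = cn.prevalence_table(cleaned[cleaned["code"].isin(panel_cfg.codes)],
                           top_k=10, names=panel_cfg.names)
prev.to_csv(OUT / "synthetic_top10.tsv", sep="\t", index=False)
dist = cn.age_distribution(cleaned)
dist.bands.to_csv(OUT / "synthetic_age_bands.tsv", sep="\t", index=False)
dist.means.to_csv(OUT / "synthetic_age_means.tsv", sep="\t", index=False)
print("\nsynthetic cohort, top-5 panel diseases:")
print(prev.head(5).to_string(index=False))
m, sd = dist.mean_of("total")
print(f"synthetic mean age: {m:.2f} (SD {sd:.3f})")
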