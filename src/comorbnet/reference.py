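"""Published aggregate counts for a municipal outpatient claims cohort of
adults aged 60-99 (one study year), used as worked inputs for the
descriptive-statistics routines.  Patient-level data is not redistributable;
these are the printed table-level counts only.
"""

from __future__ import annotations

#: total processed records after cleaning (denominator for visit percentages)
TOTAL_RECORDS = 3_779_756
TOTAL_RECORDS_MALE = 1_734_188
TOTAL_RECORDS_FEMALE = 2_045_568

#: visits by 10-year age band: (lo, hi) -> (total, male, female)
AGE_BAND_VISITS: dict[tuple[int, int], tuple[int, int, int]] = {
    (60, 69): (1_787_022, 841_369, 945_653),
    (70, 79): (1_284_756, 606_310, 678_446),
    (80, 89): (543_220, 231_466, 311_754),
    (90, 99): (164_758, 55_043, 109_715),
}

#: mean age (SD) by stratum
MEAN_AGE = {"total": (72.87, 8.578), "male": (72.52, 8.320), "female": (73.13, 8.758)}

#: top 10 single-diagnosed diseases: name -> (total, male, female) visit counts
TOP10_VISITS: dict[str, tuple[int, int, int]] = {
    "Hypertension": (2_448_548, 1_142_288, 1_306_260),
    "IHD": (1_476_396, 637_315, 839_081),
    "T2DM": (943_812, 465_184, 478_628),
    "LMD": (823_572, 329_847, 493_725),
    "Gastritis": (744_880, 311_084, 433_796),
    "Sleep disorders": (667_676, 272_915, 394_761),
    "Conjunctivitis": (518_629, 195_735, 322_894),
    "Intestinal disorders": (513_921, 218_230, 295_691),
    "Bronchitis": (458_076, 199_803, 258_273),
    "Respiratory disorders": (430_433, 200_616, 229_817),
}
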