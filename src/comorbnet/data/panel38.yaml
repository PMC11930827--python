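# Default 38-disease chronic panel for the elderly comorbidity-network pipeline.
#
# Each entry maps a recoded disease label to the raw ICD-10 codes (exact codes or
# prefixes) it aggregates.  Merged labels combine conditions of the same body
# system with shared pathogenesis (e.g. EE03 pools the E03.8/E03.9 hypothyroidism
# subcodes; II2520 pools chronic ischaemic heart disease I25 with angina I20,
# since angina is a common presentation of chronic IHD).  Only the EE03 and
# II2520 source sets are published; the remaining source lists are reconstructed
# from ICD-10 semantics of the disease names and should be treated as a
# synthetic, editable default rather than an authoritative mapping.
#
# `top5: true` marks the five most prevalent index diseases used to seed panel
# construction (hypertension, chronic IHD, type 2 diabetes, gastritis, lipid
# metabolism disorders).
panel:
  - {code: I10,    name: "Hypertension",                              top5: true,  sources: [I10]}
  - {code: II2520, name: "Chronic ischaemic heart disease",           top5: true,  sources: [I25, I20]}
  - {code: EE1114, name: "Type 2 diabetes mellitus",                  top5: true,  sources: [E11, E14]}
  - {code: KK29,   name: "Gastritis",                                 top5: true,  sources: [K29]}
  - {code: E78,    name: "Lipoprotein metabolism disorders",          top5: true,  sources: [E78]}
  - {code: EE03,   name: "Hypothyroidism",                            top5: false, sources: [E03.8, E03.9]}
  - {code: EE04,   name: "Non-toxic diffuse goiter",                  top5: false, sources: [E04]}
  - {code: G47_0,  name: "Sleep disorders",                           top5: false, sources: [G47.0]}
  - {code: G47_3,  name: "Sleep apnea",                               top5: false, sources: [G47.3]}
  - {code: I21,    name: "Acute myocardial infarction",               top5: false, sources: [I21]}
  - {code: I49,    name: "Cardiac arrhythmia",                        top5: false, sources: [I49]}
  - {code: I63,    name: "Cerebral infarction",                       top5: false, sources: [I63]}
  - {code: II67,   name: "Cerebrovascular disease",                   top5: false, sources: [I65, I66, I67]}
  - {code: J31_0,  name: "Chronic rhinitis",                          top5: false, sources: [J31.0]}
  - {code: J31_2,  name: "Chronic pharyngitis",                       top5: false, sources: [J31.2]}
  - {code: JJ4042, name: "Bronchitis",                                top5: false, sources: [J40, J41, J42]}
  - {code: K21,    name: "GERD with esophagitis",                     top5: false, sources: [K21]}
  - {code: K52_9,  name: "Non-infective gastroenteritis and colitis", top5: false, sources: [K52.9]}
  - {code: K59_0,  name: "Constipation",                              top5: false, sources: [K59.0]}
  - {code: K59_1,  name: "Functional diarrhea",                       top5: false, sources: [K59.1]}
  - {code: K63_5,  name: "Polyps of the colon",                       top5: false, sources: [K63.5]}
  - {code: K76_0,  name: "Non-alcoholic fatty liver disease",         top5: false, sources: [K76.0]}
  - {code: L30_9,  name: "Dermatitis",                                top5: false, sources: [L30.9]}
  - {code: M13,    name: "Arthritis",                                 top5: false, sources: [M13]}
  - {code: M81,    name: "Osteoporosis",                              top5: false, sources: [M81]}
  - {code: NN18,   name: "Chronic kidney disease",                    top5: false, sources: [N18, N19]}
  - {code: R42,    name: "Dizziness and giddiness",                   top5: false, sources: [R42]}
  - {code: F41,    name: "Anxiety disorders",                         top5: false, sources: [F41]}
  - {code: F48,    name: "Neurotic disorders",                        top5: false, sources: [F48]}
  - {code: I48,    name: "Atrial fibrillation and flutter",           top5: false, sources: [I48]}
  - {code: I50,    name: "Heart failure",                             top5: false, sources: [I50]}
  - {code: I70,    name: "Atherosclerosis",                           top5: false, sources: [I70]}
  - {code: J44,    name: "Chronic obstructive pulmonary disease",     top5: false, sources: [J44]}
  - {code: K25,    name: "Gastric ulcer",                             top5: false, sources: [K25]}
  - {code: ME1079, name: "Hyperuricemia",                             top5: false, sources: [M10, E79]}
  - {code: M17,    name: "Gonarthrosis",                              top5: false, sources: [M17]}
  - {code: M47,    name: "Spondylosis",                               top5: false, sources: [M47]}
  - {code: N95,    name: "(Peri-)menopausal disorders",               top5: false, sources: [N95]}
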