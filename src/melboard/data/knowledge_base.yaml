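# First-line treatment knowledge base for cutaneous malignant melanoma,
# keyed by AJCC-8 pathological stage group plus qualifiers.
#
# Entry semantics: an entry applies when the case's stage group is listed in
# `stage`, every `when` qualifier matches (list values mean set membership),
# and the entry's `era` (pre2018 / post2018, absent = both) matches the active
# guideline era. The loader verifies that exactly one entry matches every
# stage/qualifier combination reachable from the staging engine, per era.
#
# Qualifier keys:
#   margin   - excision safety margin band from Breslow thickness
#              ("1cm" for <=2.0 mm, "2cm" for >2.0 mm)
#   route    - regional-disease route: occult_nodal (sentinel-biopsy detected),
#              clinical_nodal (clinically detected nodes),
#              satellite_in_transit (satellite / in-transit metastases)
#   mutation - driver-mutation class: braf (BRAF V600) / non_braf
version: "melboard-kb-1.0"
default_era: post2018
age_flag_threshold: 80

entries:
  - stage: [IA]
    code: EXC_1CM
    text: "Wide local excision with 1 cm safety margin"

  - stage: [IB, IIA]
    when: {margin: "1cm"}
    code: EXC_1CM_SLNB
    text: "Wide local excision with 1 cm safety margin; offer sentinel lymph node biopsy"

  - stage: [IIA, IIB, IIC]
    when: {margin: "2cm"}
    code: EXC_2CM_SLNB
    text: "Wide local excision with 2 cm safety margin; offer sentinel lymph node biopsy"

  - stage: [IIIA, IIIB, IIIC, IIID]
    when: {route: [occult_nodal, clinical_nodal], mutation: braf}
    era: post2018
    code: ADJ_TARGETED_OR_PD1
    text: "Complete resection of regional disease; adjuvant BRAF/MEK-targeted therapy or anti-PD-1 antibody (BRAF V600 mutated)"

  - stage: [IIIA, IIIB, IIIC, IIID]
    when: {route: [occult_nodal, clinical_nodal], mutation: non_braf}
    era: post2018
    code: ADJ_PD1
    text: "Complete resection of regional disease; adjuvant anti-PD-1 antibody"

  - stage: [IIIA, IIIB, IIIC, IIID]
    when: {route: [occult_nodal, clinical_nodal]}
    era: pre2018
    code: ADJ_IFN
    text: "Complete resection of regional disease; adjuvant interferon-alpha"

  - stage: [IIIB, IIIC, IIID]
    when: {route: satellite_in_transit, mutation: braf}
    code: RESECT_SAT_ADJ_TARGETED_OR_PD1
    text: "Complete surgical resection of satellite/in-transit metastases; adjuvant BRAF/MEK-targeted therapy or anti-PD-1 antibody"

  - stage: [IIIB, IIIC, IIID]
    when: {route: satellite_in_transit, mutation: non_braf}
    code: RESECT_SAT_ADJ_PD1
    text: "Complete surgical resection of satellite/in-transit metastases; adjuvant anti-PD-1 antibody"

  - stage: [IV]
    when: {mutation: braf}
    code: SYS_TARGETED_OR_PD1
    text: "Mutation-directed systemic therapy: BRAF/MEK-targeted therapy or checkpoint-inhibitor immunotherapy"

  - stage: [IV]
    when: {mutation: non_braf}
    code: SYS_IMMUNO
    text: "Systemic checkpoint-inhibitor immunotherapy (anti-PD-1 based)"

# Recommendation codes that appear only as board (MDT) decisions, never as
# engine output; they must still resolve for concordance analysis.
extra_codes:
  TVEC: "Intralesional oncolytic viral immunotherapy with talimogene laherparepvec (T-VEC)"

# Non-identical recommendation pairs accepted as correct clinical
# alternatives, with the guideline era in which the equivalence holds.
equivalences:
  - {a: ADJ_PD1, b: ADJ_IFN, era: pre2018}
  - {a: ADJ_TARGETED_OR_PD1, b: ADJ_IFN, era: pre2018}
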