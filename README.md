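# melboard

Decision support and concordance analysis for melanoma tumor boards.

Certified skin-cancer centers must present essentially every melanoma case in
a multidisciplinary tumor board (MDT), which floods the conference with
registrations whose first-line treatment is fixed by the guideline anyway.
`melboard` implements the workflow that lets such **standard cases** be
flagged at registration time: a deterministic AJCC 8th-edition TNM staging
engine, a stepwise minimal-question therapy query over a versioned guideline
knowledge base, a standard-case triage filter, and a blinded concordance
analysis that scores the decision-support output against the board's real
recommendations. A seeded synthetic cohort generator stands in for patient
data, which cannot be deposited.

It is written for clinical-informatics and dermato-oncology researchers who
want to evaluate rule-based decision support against tumor-board decisions,
and for methodologists who need a fully reproducible replica of such an
evaluation.

## The method

**Staging.** A case's clinicopathologic findings map deterministically to
AJCC-8 categories: T from Breslow thickness and ulceration (T1 ≤ 1.0 mm with
T1a < 0.8 mm non-ulcerated, T2 > 1.0–2.0 mm, T3 > 2.0–4.0 mm, T4 > 4.0 mm;
suffix b = ulcerated), N from occult vs clinically detected node counts and
in-transit/satellite disease, M from the highest-ranking distant site
(CNS > non-CNS visceral > lung > distant skin/soft tissue/nodes) with an
optional LDH suffix. The pathological stage grouping is a shipped 400-cell
flat table over T × N × M, validated for totality at load.

**Therapy query.** A decision tree requests only decision-relevant variables
in canonical order (pT category → Breslow → sentinel-node result → staging
radiology → mutation status; regional and distant presentations enter
shorter branches). Simple cases resolve after two questions, the deepest
path needs five. Outcomes are in-band: a coded treatment recommendation, a
board referral (`REFER_MDT`, e.g. for unresolved radiology), or
`MISSING_INFO` naming the variable that blocked the decision.

**Triage.** Registrations with complicating attributes (non-cutaneous origin,
relapse, secondary cancer, severe comorbidity, trial enrolment, declined
procedures, brain metastases, complex constellations) are excluded in a
fixed priority cascade; cases whose query ends in `MISSING_INFO` are excluded
last. What remains are the standard-case candidates.

**Concordance.** For each candidate the decision-support recommendation and
the board's recommendation form a response pair, adjudicated into three
categories: *concordant* (identical codes), *correct alternative*
(era-dependent equivalences such as pre-2018 adjuvant interferon vs
mutation-directed adjuvant therapy, or a documented manual review), or
*incorrect* (including pairs where one side issued no treatment at all).
The overall concordance rate is

    (concordant + correct alternative) / all pairs

kept in exact rational arithmetic, with integer-percent rendering rounding
half up. Group comparisons between concordant and non-concordant cases use
the chi-squared test (categorical) and the two-sided Mann–Whitney U test
(ordinal/numeric).

## Worked example

```python
from melboard import load_knowledge_base, recommend, query_trace, assign_stage
from melboard.records import CaseRecord

kb = load_knowledge_base()
case = CaseRecord(case_id="demo", age=61, breslow_mm=0.5,
                  ulceration="absent", slnb="not_done")

print(assign_stage(case).stage_group.value)
print(query_trace(case, kb))
rec = recommend(case, kb)
print(rec.code, "-", rec.text)
```

prints

```
IA
['pT_category', 'breslow_mm']
EXC_1CM - Wide local excision with 1 cm safety margin
```

— a thin non-ulcerated primary is stage IA, resolved after the two-question
path, with wide local excision (1 cm margin) as the guideline first-line
recommendation.

Replaying the full study-replica cohort:

```python
from melboard import replay_preset
cohort, outcome = replay_preset(seed=1)
print(outcome.triage.n_eligible, outcome.n_missing_info, outcome.n_refer_mdt)
print(outcome.report.counts, outcome.report.overall_percent)
print(outcome.report.per_stage_percent())
```

prints

```
111 72 2
{'concordant': 87, 'correct_alternative': 21, 'incorrect': 3} 97
{'I': 100, 'II': 95, 'III': 98, 'IV': 100}
```

i.e. of 705 melanoma registrations, 111 qualify as standard-case candidates
(72 are blocked by missing information); 2 candidates are referred back to
the board; the adjudicated pairs split 87 / 21 / 3 across the three
categories for an overall concordance of 108/111 = 97%, uniform across
stages.

The same pipeline is available from a shell:

```bash
melboard simulate --preset cologne_2017_2020 --seed 1 --out-cases cohort.csv
melboard triage cohort.csv --out-summary triage.json
melboard concordance cohort.csv --out report.json
```

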