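# Methods notes

## Scope and model

`melboard` models the registration-time decision pathway of a melanoma tumor
board as three deterministic layers — staging, guideline lookup, and a
stepwise query planner — plus an evaluation layer that scores the system
against the board's real decisions. Nothing is fitted: the package is a
rule engine with a statistical evaluation harness, and every number it
reports is a count or an exact rational rate derived from counts.

## Staging engine

T, N and M classification follow the AJCC 8th-edition definitions. Interval
edges are half-open at the lower bound (> 1.0 mm means strictly greater), so
a Breslow thickness of exactly 1.0 mm is T1 and exactly 2.0 mm is T2. Two
in-band missing-data conventions matter:

* **Unknown ulceration** never silently assumes the favorable suffix. The
  T category resolves only where the suffix is determined regardless
  (0.8–1.0 mm is T1b either way); otherwise `classify_pt` returns `None`
  and the therapy layer reports missing information.
* **Unresolved radiology** (a suspicious but diagnostically unresolved
  finding) is not a confirmed metastasis: staging proceeds on confirmed
  sites and the therapy layer converts the unresolved finding into a board
  referral instead.

The stage grouping ships as a 400-row CSV (one row per T × N × M cell)
rather than code, so it is diffable and auditable; the loader refuses any
file that is not total over the grid. The test suite carries an independent
rule-based re-encoding of the grouping prose and compares all 400 cells.
The flat N order (N1a … N3c) is *not* globally monotone in stage — in-transit
disease without nodal involvement (N1c) outranks two occult nodes (N2a) at
low T — so the tested ordering invariant is monotonicity along each nodal
suffix series plus "any nodal disease outranks N0", which is the strongest
true statement.

## Knowledge base

The guideline mapping is data (`data/knowledge_base.yaml`) with a version
stamp and an era switch, because the underlying national guideline changed
repeatedly across the study window. Entries are keyed by stage group plus
three qualifiers: excision-margin band (1 cm for ≤ 2.0 mm Breslow, 2 cm
above), regional-disease route (occult nodal / clinical nodal /
satellite–in-transit), and driver-mutation class (BRAF vs non-BRAF). The
loader enumerates every stage/qualifier combination the staging engine can
emit and requires exactly one matching entry per era — coverage gaps and
duplicates are load-time errors, not lookup-time surprises.

Era handling: the engine always recommends at the active (default: modern)
era; historic board decisions are assumed correct, so the adjudication uses
the era of the board's decision date. The equivalence table currently
contains one family: mutation-directed adjuvant therapy ↔ adjuvant
interferon, valid only before 2018.

Advanced patient age (threshold 80 years, configurable) attaches an advisory
qualifier to the recommendation without changing the emitted code: the one
age-driven deviation in the evaluated workflow was an adjudication matter,
and silently altering codes by age would change concordance accounting.

## Query planner

The planner asks, in canonical order, only variables that can still change
the outcome. Design choices that were genuinely open:

* The initial-diagnosis selection (localized / regional / distant) opens the
  questionnaire and is not counted as a clinicopathologic variable; the
  two-variable minimum (pT category, Breslow thickness) and five-variable
  maximum (pT, Breslow, sentinel-node result, radiology, mutation) are
  counted over the remaining questions. The regional branch asks a
  `regional_pattern` sub-question (nodal vs satellite/in-transit) that is
  counted.
* Ulceration is folded into the pT-category question; Breslow thickness is
  asked separately. When the pT answer already withholds the suffix outside
  T1, no Breslow value can resolve the category, so the Breslow question is
  skipped and missing information is reported immediately.
* `slnb = not_done` and `slnb = declined` are answers, not missing data: the
  workup legitimately may not include the procedure, and the excision
  recommendation then includes the sentinel-node offer. Only explicit
  `unknown` blocks the recommendation.
* Radiologic staging is requested for node-positive disease and for thicker
  primaries (T2b and up); R1/R2 residual status after regional resection is
  referred to the board rather than given a first-line code.
* Mutation status is asked only where an entry depends on it (adjuvant
  stage III, satellite resection, stage IV systemic therapy).
* Contradictions (a presentation inconsistent with the recorded findings, or
  a pT answer inconsistent with the Breslow value) raise a validation error
  rather than applying silent precedence — registration-time data entry is
  the quality-assurance use case.

Minimality is checked by exhaustively walking the decision tree over
discretized answer domains: for every asked variable there exist answer
values that change the final outcome. For the Breslow question under a
fully specified pT category this discrimination runs through the
missing-information outcome (its clinical role there is verification and
margin documentation); all other questions also separate treatment outcomes.

## Triage cascade

Exclusion reasons are evaluated in a fixed priority order (non-melanoma,
non-cutaneous, relapse, secondary cancer, severe comorbidity, trial,
declined procedure, brain metastases, complex constellation, missing data).
The order among attribute reasons is a convention — the source workflow does
not define one — with missing data deliberately last because it is decided
by the recommendation engine, not by an input attribute. A board referral
does **not** exclude a case: flagging a constellation for discussion is a
legitimate output and is adjudicated like any other pair.

## Concordance analysis

Matching is by recommendation code, never by text. Category order of
evidence: identical codes → era equivalence table → documented manual
override → incorrect. Pairs where the system referred to the board while
the board issued a treatment count as incorrect (with an advisory
annotation preserving that the referral was clinically appropriate).
Rates are `fractions.Fraction`s; the identity "overall rate equals the
pair-count-weighted mean of per-stage rates" therefore holds exactly, and
percent rendering rounds half up (18/19 → 95).

Group comparisons use `scipy.stats.chi2_contingency` without continuity
correction for categorical variables and the asymptotic two-sided
Mann–Whitney U test with tie correction for ordinal/numeric ones, with
0.05 as the significance threshold. The exact test variants behind the
published descriptive table are not specified, so these defaults are
documented rather than calibrated, and no p-value is treated as a
reproduction target.

## Synthetic cohort generator

The generator emulates a four-year conference registry at desk scale.
Categorical structure is placed as exact counts: the exclusion-attribute
allocation, the eligible stage mix, and the deviation injections
(era-driven alternatives on node-positive stage III cases, one
patient-factor deviation on a satellite-disease case with advanced age,
unresolved-radiology constellations on thick ulcerated primaries). Board
codes are produced by running the engine itself and then applying the
injections, so category counts recover the injections exactly. Only
incidental attributes are sampled: ages from a log-normal fitted to median
62 and interquartile range 52–72 (the simplest two-parameter fit to those
summaries), truncated to 18–95; thicknesses uniformly within the required
T band; dates uniformly within the era.

The shipped `cologne_2017_2020` preset encodes 2399 skin-cancer
registrations with 705 melanomas; exclusions 377 relapsed, 78 non-cutaneous,
43 complex constellations and 72 with insufficient information are printed
in the source counts, and the 24 remaining exclusions are split evenly
across secondary cancer, trial enrolment, declined procedures and brain
metastases — an assumption, as their attribution is not printed. The
insufficient-information block is modeled as disjoint from the attribute
exclusions. Missing-information cases cycle three variants: sentinel-node
result undocumented, ulceration pending (unresolvable pT suffix), and
mutation analysis pending on a node-positive case.

Two deliberate deviations from the published descriptive marginals:
mutation status is known for every eligible node-positive case (the query
requires it, whereas the descriptive table records chart availability), and
the presentation marginals shift by one or two cases for the same reason.
These marginals are descriptive only and carry no evaluation weight.

What passing tests show — and do not show. The replica demonstrates that
the pipeline arithmetic (cascade counts, outcome counts, three-category
adjudication, exact rates) reproduces the study-scale quantities, and that
the structural properties hold on the full reachable grid. It does not
validate the clinical content against real patients: free-text pathology,
comorbidity scoring, longitudinal course and inter-rater variability are
all outside the generator's scope.

## Numerical and degenerate-input conventions

* Concordance of zero pairs is an error, not 0/0.
* Degenerate group comparisons (an empty group, a constant variable) are
  flagged and no statistic is computed.
* All randomness flows through one `numpy` generator seeded from the spec;
  identical seeds give byte-identical cohorts.
* Thickness is millimeters with a decimal point; dates are ISO-8601; blank
  CSV cells map to explicit unknown enum members, never to zero.

## Known limitations

* The knowledge base reconstructs recommendation codes and texts from the
  evaluated workflow's documented cases; the exact wording of the original
  app per stage is not public. Whether the study-era system issued adjuvant
  recommendations for stage IIB/IIC is unknown and the shipped default
  omits them (override via a custom knowledge-base file).
* Only the single pathological stage-grouping table is implemented; no
  clinical (cTNM) grouping, no 7th-edition tables.
* Single first-line recommendation only: no therapy sequencing, dosing,
  neoadjuvant protocols or T-VEC eligibility logic (T-VEC exists only as a
  board-side adjudication outcome).
* Exclusion-cascade priority affects per-reason counts when a record
  carries several exclusion attributes; the partition of eligible vs
  excluded is unaffected.
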