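"""DSS-vs-MDT decision pairs, three-category adjudication and cohort statistics.

Each eligible case contributes one response pair: the decision-support output
and the recommendation the multidisciplinary tumor board actually issued.
Pairs are adjudicated blind to origin into three categories:

* ``concordant`` — identical recommendation codes;
* ``correct_alternative`` — different codes, but listed in the knowledge
  base's equivalence table for the era of the board decision (historic board
  decisions are assumed correct, so era-driven deviations such as pre-2018
  adjuvant interferon fall here), or upheld as valid by a documented manual
  review;
* ``incorrect`` — everything else, including pairs where one side issued no
  treatment at all (a board referral or missing-information outcome against
  a board treatment). A referral adjudicated incorrect keeps an ``advisory``
  annotation: recommending discussion can be clinically appropriate even
  though it counts as non-concordant.

The overall concordance rate is
(concordant + correct alternative) / all pairs, kept as an exact rational
number; percent rendering rounds half up to an integer.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats as _stats

from .knowledge_base import (
    EraLike,
    KnowledgeBase,
    Recommendation,
    RecommendationKind,
    are_correct_alternatives,
)
from .records import CaseRecord
from .staging import StageAssignment, assign_stage
from .therapy_finder import recommend


class PairCategory(str, enum.Enum):
    concordant = "concordant"
    correct_alternative = "correct_alternative"
    incorrect = "incorrect"
    unadjudicated = "unadjudicated"


class AdjudicationSource(str, enum.Enum):
    automatic_equal = "automatic_equal"
    equivalence_table = "equivalence_table"
    manual = "manual"


@dataclass
class DecisionPair:
    case_id: str
    dss: Recommendation
    mdt: Recommendation
    stage: Optional[StageAssignment]
    era: EraLike = None
    category: PairCategory = PairCategory.unadjudicated
    adjudication_source: Optional[AdjudicationSource] = None
    advisory: Optional[str] = None

    @property
    def stage_major(self) -> Optional[str]:
        return self.stage.stage_group.major if self.stage else None


#: Manual override: case id -> (category, note). Mirrors the study's second
#: independent review of non-concordant pairs by a dermato-oncologist.
ManualOverrides = Mapping[str, tuple[PairCategory, str]]


def classify_pair(
    pair: DecisionPair,
    kb: KnowledgeBase,
    manual_overrides: Optional[ManualOverrides] = None,
) -> PairCategory:
    """Adjudicate one response pair; updates and returns its category.

    Order of evidence: identical codes, then the era-aware equivalence table,
    then a documented manual override, else incorrect. Matching is by code
    only — never by recommendation text — and is symmetric in which member
    is labeled DSS or MDT when both are treatments (blinded comparison).
    """
    if pair.dss.code == pair.mdt.code:
        pair.category = PairCategory.concordant
        pair.adjudication_source = AdjudicationSource.automatic_equal
    elif are_correct_alternatives(pair.dss, pair.mdt, pair.era, kb):
        pair.category = PairCategory.correct_alternative
        pair.adjudication_source = AdjudicationSource.equivalence_table
    elif manual_overrides and pair.case_id in manual_overrides:
        category, note = manual_overrides[pair.case_id]
        pair.category = PairCategory(category)
        pair.adjudication_source = AdjudicationSource.manual
        pair.advisory = note
    else:
        pair.category = PairCategory.incorrect
        pair.adjudication_source = AdjudicationSource.manual
        if pair.dss.kind is RecommendationKind.refer_to_MDT:
            # counted non-concordant, but recommending board discussion of an
            # unresolved constellation is clinically appropriate
            pair.advisory = "DSS referral to the board; counted as incorrect"
    return pair.category


def build_pairs(
    records: Sequence[CaseRecord],
    kb: KnowledgeBase,
    manual_overrides: Optional[ManualOverrides] = None,
) -> list[DecisionPair]:
    """Response pairs for records carrying a board recommendation code.

    The DSS member is recomputed by the stepwise query engine at the current
    knowledge-base era; the pair is adjudicated with the era of the board's
    decision date (historic board decisions are assumed correct).
    """
    pairs = []
    for case in records:
        if case.mdt_code is None:
            continue
        dss = recommend(case, kb)
        mdt = kb.treatment_from_code(case.mdt_code)
        pair = DecisionPair(
            case_id=case.case_id,
            dss=dss,
            mdt=mdt,
            stage=assign_stage(case),
            era=case.decision_date,
        )
        classify_pair(pair, kb, manual_overrides)
        pairs.append(pair)
    return pairs


def overall_concordance(counts: Mapping[PairCategory | str, int]) -> Fraction:
    """(concordant + correct alternative) / all pairs, as an exact fraction."""
    c = {PairCategory(k): v for k, v in counts.items()}
    n = sum(c.values())
    if n == 0:
        raise ValueError("concordance undefined for zero pairs")
    hits = c.get(PairCategory.concordant, 0) + c.get(PairCategory.correct_alternative, 0)
    return Fraction(hits, n)


def percent(fraction: Fraction) -> int:
    """Integer percent, rounding half up (18/19 -> 95)."""
    return int((100 * Fraction(fraction) + Fraction(1, 2)).__floor__())


def per_stage_concordance(pairs: Sequence[DecisionPair]) -> dict[str, Fraction]:
    """Concordance rate per major stage (I-IV), exact fractions."""
    hits: Counter[str] = Counter()
    totals: Counter[str] = Counter()
    for p in pairs:
        if p.stage_major is None:
            raise ValueError(f"pair {p.case_id} is not staged")
        totals[p.stage_major] += 1
        if p.category in (PairCategory.concordant, PairCategory.correct_alternative):
            hits[p.stage_major] += 1
    return {s: Fraction(hits[s], totals[s]) for s in sorted(totals)}


@dataclass
class GroupTest:
    variable: str
    test: str  # "chi2" or "mannwhitney"
    statistic: Optional[float]
    p_value: Optional[float]
    degenerate: bool = False


def compare_groups(
    table: pd.DataFrame,
    variable: str,
    kind: str,
    group_col: str = "concordant_group",
) -> GroupTest:
    """Compare a variable between concordant and non-concordant cases.

    ``kind='categorical'`` uses a chi-squared test on the contingency table
    (no continuity correction); ``kind='numeric'`` (or ordinal) uses the
    two-sided Mann-Whitney U test with tie correction. An empty group or a
    constant variable is flagged degenerate and no test is computed.
    """
    sub = table[[group_col, variable]].dropna()
    groups = sub[group_col].unique()
    if len(groups) < 2:
        return GroupTest(variable, "none", None, None, degenerate=True)
    if kind == "categorical":
        crosstab = pd.crosstab(sub[variable], sub[group_col])
        if crosstab.shape[0] < 2:
            return GroupTest(variable, "chi2", None, None, degenerate=True)
        stat, p, _, _ = _stats.chi2_contingency(crosstab.to_numpy(), correction=False)
        return GroupTest(variable, "chi2", float(stat), float(p))
    if kind in ("numeric", "ordinal"):
        a = sub.loc[sub[group_col], variable].astype(float)
        b = sub.loc[~sub[group_col].astype(bool), variable].astype(float)
        if a.empty or b.empty:
            return GroupTest(variable, "mannwhitney", None, None, degenerate=True)
        res = _stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupTest(variable, "mannwhitney", float(res.statistic), float(res.pvalue))
    raise ValueError(f"unknown variable kind {kind!r}")


@dataclass
class CohortReport:
    """Concordance summary: counts, exact rates and group-comparison tests."""

    n_pairs: int
    counts: dict[str, int]
    overall: Fraction
    per_stage: dict[str, Fraction]
    group_tests: list[GroupTest] = field(default_factory=list)

    @property
    def overall_percent(self) -> int:
        return percent(self.overall)

    def per_stage_percent(self) -> dict[str, int]:
        return {s: percent(f) for s, f in self.per_stage.items()}

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "counts": dict(self.counts),
            "overall_concordance": float(self.overall),
            "overall_concordance_percent": self.overall_percent,
            "per_stage_concordance": {s: float(f) for s, f in sorted(self.per_stage.items())},
            "per_stage_concordance_percent": {
                s: p for s, p in sorted(self.per_stage_percent().items())
            },
            "group_tests": [
                {
                    "variable": t.variable,
                    "test": t.test,
                    "statistic": t.statistic,
                    "p_value": t.p_value,
                    "degenerate": t.degenerate,
                }
                for t in self.group_tests
            ],
        }


def pair_table(pairs: Sequence[DecisionPair], records: Sequence[CaseRecord]) -> pd.DataFrame:
    """Case-level table for group comparisons (Table-1-style)."""
    by_id = {c.case_id: c for c in records}
    rows = []
    for p in pairs:
        c = by_id[p.case_id]
        rows.append(
            {
                "case_id": p.case_id,
                "category": p.category.value,
                "concordant_group": p.category
                in (PairCategory.concordant, PairCategory.correct_alternative),
                "stage": p.stage_major,
                "age": c.age,
                "ecog": c.ecog,
                "presentation": c.presentation.value,
                "slnb": c.slnb.value,
                "mutation": c.mutation.value,
            }
        )
    return pd.DataFrame(rows)


def build_report(
    pairs: Sequence[DecisionPair],
    records: Optional[Sequence[CaseRecord]] = None,
    test_variables: Iterable[tuple[str, str]] = (
        ("age", "numeric"),
        ("ecog", "ordinal"),
        ("stage", "categorical"),
        ("presentation", "categorical"),
    ),
) -> CohortReport:
    counts = Counter(p.category.value for p in pairs)
    tests: list[GroupTest] = []
    if records is not None and pairs:
        table = pair_table(pairs, records)
        for variable, kind in test_variables:
            tests.append(compare_groups(table, variable, kind))
    return CohortReport(
        n_pairs=len(pairs),
        counts=dict(counts),
        overall=overall_concordance(counts) if pairs else Fraction(0, 1),
        per_stage=per_stage_concordance(pairs) if pairs else {},
        group_tests=tests,
    )
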