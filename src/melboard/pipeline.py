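"""End-to-end replay: cohort generation -> triage -> recommendations -> concordance.

Convenience layer used by the command line and the reproduction script: runs
the full registration pipeline on a (typically synthetic) cohort and collects
the quantities the study design reports — the exclusion cascade counts, the
missing-information and board-referral outcome counts, and the adjudicated
concordance report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .concordance import CohortReport, DecisionPair, build_pairs, build_report
from .knowledge_base import KnowledgeBase, RecommendationKind, load_knowledge_base
from .synthetic import CohortResult, generate_cohort
from .therapy_finder import recommend
from .triage import TriageCounts, triage_cohort


@dataclass
class StudyOutcome:
    triage: TriageCounts
    n_melanoma: int
    n_missing_info: int  # over all melanoma registrations
    n_refer_mdt: int  # over the triage-eligible candidates
    pairs: list[DecisionPair]
    report: CohortReport

    def summary_dict(self) -> dict:
        return {
            "triage": self.triage.as_dict(),
            "n_melanoma": self.n_melanoma,
            "n_missing_info": self.n_missing_info,
            "n_refer_mdt": self.n_refer_mdt,
            "concordance": self.report.as_dict(),
        }


def run_study_pipeline(
    cohort: CohortResult,
    kb: Optional[KnowledgeBase] = None,
) -> StudyOutcome:
    """Replay the registration pipeline on a generated cohort.

    Non-melanoma registrations are dropped by the cascade's first rule;
    missing-information outcomes are counted over every melanoma
    registration, board referrals over the eligible candidates only (the
    excluded strata are never run through the final recommendation step in
    the study design). Pairs are adjudicated with the generator's manifest
    supplying the documented manual review of patient-factor deviations.
    """
    if kb is None:
        kb = load_knowledge_base()
    melanoma = cohort.melanoma
    tri = triage_cohort(melanoma, kb)
    n_missing = sum(
        1
        for case in melanoma
        if recommend(case, kb).kind is RecommendationKind.missing_info
    )
    eligible = tri.eligible
    n_refer = sum(
        1
        for case in eligible
        if recommend(case, kb).kind is RecommendationKind.refer_to_MDT
    )
    pairs = build_pairs(eligible, kb, cohort.manual_overrides())
    report = build_report(pairs, eligible)
    return StudyOutcome(
        triage=tri,
        n_melanoma=len(melanoma),
        n_missing_info=n_missing,
        n_refer_mdt=n_refer,
        pairs=pairs,
        report=report,
    )


def replay_preset(seed: int, kb: Optional[KnowledgeBase] = None) -> tuple[CohortResult, StudyOutcome]:
    """Generate the study-replica preset at the given seed and replay it."""
    from .synthetic import cologne_2017_2020

    cohort = generate_cohort(cologne_2017_2020(seed), kb)
    return cohort, run_study_pipeline(cohort, kb)
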