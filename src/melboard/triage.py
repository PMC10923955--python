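"""Standard-case eligibility filter applied at conference registration.

Only uncomplicated, fully documented first-line cutaneous melanoma cases can
be flagged as standard-case candidates whose board discussion is optional.
Every other registration is excluded with exactly one reason, assigned by the
first matching rule in a fixed priority cascade; the final missing-data rule
is decided by the recommendation engine itself (a case whose stepwise query
ends in a missing-information outcome cannot be pre-answered).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .knowledge_base import KnowledgeBase, RecommendationKind, load_knowledge_base
from .records import CaseRecord, MetastaticSite, Origin, SlnbResult
from .therapy_finder import recommend


class ExclusionReason(str, enum.Enum):
    non_melanoma_skin_cancer = "non_melanoma_skin_cancer"
    non_cutaneous_melanoma = "non_cutaneous_melanoma"
    relapsed_disease = "relapsed_disease"
    secondary_cancer = "secondary_cancer"
    severe_comorbidity = "severe_comorbidity"
    clinical_trial = "clinical_trial"
    declined_procedure = "declined_procedure"
    brain_metastases = "brain_metastases"
    complex_constellation = "complex_constellation"
    missing_data = "missing_data"
    none = "none"


class TriageStatus(str, enum.Enum):
    eligible_standard_candidate = "eligible_standard_candidate"
    excluded = "excluded"


@dataclass(frozen=True)
class TriageResult:
    status: TriageStatus
    reason: ExclusionReason

    def __post_init__(self) -> None:
        eligible = self.status is TriageStatus.eligible_standard_candidate
        if eligible != (self.reason is ExclusionReason.none):
            raise ValueError("eligible iff reason is 'none'")


#: Attribute-based rules in priority order (missing-data comes last and is
#: decided by the recommendation engine, not an input attribute).
_ATTRIBUTE_RULES: tuple[tuple[ExclusionReason, object], ...] = (
    (
        ExclusionReason.non_melanoma_skin_cancer,
        lambda c: c.origin is Origin.non_melanoma,
    ),
    (
        ExclusionReason.non_cutaneous_melanoma,
        lambda c: c.origin in (Origin.mucosal, Origin.uveal, Origin.unknown_primary),
    ),
    (ExclusionReason.relapsed_disease, lambda c: c.relapse),
    (ExclusionReason.secondary_cancer, lambda c: c.secondary_cancer),
    (ExclusionReason.severe_comorbidity, lambda c: c.severe_comorbidity),
    (ExclusionReason.clinical_trial, lambda c: c.clinical_trial),
    (ExclusionReason.declined_procedure, lambda c: c.slnb is SlnbResult.declined),
    (
        ExclusionReason.brain_metastases,
        lambda c: MetastaticSite.cns in c.metastatic_sites,
    ),
    (ExclusionReason.complex_constellation, lambda c: c.complex_constellation),
)


def triage(case: CaseRecord, kb: Optional[KnowledgeBase] = None) -> TriageResult:
    """Classify one registration as standard-case candidate or excluded.

    A case that passes every attribute rule but whose stepwise query ends in
    a missing-information outcome is excluded as ``missing_data``. A query
    that ends in a board referral does *not* exclude the case — flagging such
    constellations for discussion is the intended behavior, and the referral
    is adjudicated downstream like any other decision.
    """
    for reason, rule in _ATTRIBUTE_RULES:
        if rule(case):
            return TriageResult(TriageStatus.excluded, reason)
    if kb is None:
        kb = load_knowledge_base()
    if recommend(case, kb).kind is RecommendationKind.missing_info:
        return TriageResult(TriageStatus.excluded, ExclusionReason.missing_data)
    return TriageResult(TriageStatus.eligible_standard_candidate, ExclusionReason.none)


@dataclass
class TriageCounts:
    """Exclusion-cascade summary: per-reason counts plus the eligible cases."""

    n_input: int
    counts: dict[str, int] = field(default_factory=dict)
    eligible: list[CaseRecord] = field(default_factory=list)

    @property
    def n_eligible(self) -> int:
        return len(self.eligible)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "excluded": dict(self.counts),
        }


def triage_cohort(
    records: Sequence[CaseRecord] | Iterable[CaseRecord],
    kb: Optional[KnowledgeBase] = None,
) -> TriageCounts:
    """Apply the exclusion cascade to a cohort; counts partition the input."""
    if kb is None:
        kb = load_knowledge_base()
    records = list(records)
    counter: Counter[str] = Counter()
    eligible: list[CaseRecord] = []
    for case in records:
        result = triage(case, kb)
        if result.status is TriageStatus.eligible_standard_candidate:
            eligible.append(case)
        else:
            counter[result.reason.value] += 1
    return TriageCounts(n_input=len(records), counts=dict(counter), eligible=eligible)
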