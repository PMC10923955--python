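"""Stepwise minimal-question query engine for first-line melanoma therapy.

The engine replays the registration-time questionnaire of an expert-curated
decision support system: starting from the initial-diagnosis selection it
requests only the clinicopathologic variables that can still influence the
final recommendation, in a fixed canonical order, and terminates in one of
three in-band outcomes — a coded treatment recommendation, a referral to the
multidisciplinary tumor board, or a missing-information notice naming the
variable that blocked the decision.

Question depth on the shipped decision tree ranges from two variables
(thin localized primary: pT category, then Breslow thickness) to five
(node-positive primary: pT, Breslow, sentinel-node result, staging
radiology, mutation status). The initial-diagnosis selection opens the
questionnaire and is not counted as a clinicopathologic variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .knowledge_base import (
    KnowledgeBase,
    Recommendation,
    RecommendationKind,
    EraLike,
    margin_band,
    match_recommendation,
    missing_info,
    refer_to_mdt,
)
from .records import (
    CaseRecord,
    MetastaticSite,
    Mutation,
    Origin,
    Presentation,
    SlnbResult,
    RStatus,
    Ulceration,
)
from .staging import (
    MCategory,
    NCategory,
    StageGroup,
    TCategory,
    TumorFindings,
    classify_pt,
    stage_group,
)

UNKNOWN = "unknown"

#: Canonical question order. ``presentation`` is the uncounted entry point;
#: ``regional_pattern`` distinguishes nodal from satellite/in-transit disease
#: within the regional branch.
VARIABLE_REGISTRY: dict[str, tuple[str, ...]] = {
    "presentation": tuple(p.value for p in Presentation),
    "pT_category": tuple(t.value for t in TCategory) + ("T1", "T2", "T3", "T4", UNKNOWN),
    "breslow_mm": ("<numeric mm>", UNKNOWN),
    "regional_pattern": ("nodal", "in_transit_satellite"),
    "slnb_result": tuple(s.value for s in SlnbResult),
    "staging_radiology": ("no_evidence", "distant_non_cns", "cns", "unclear", UNKNOWN),
    "cnd_or_r_status": ("R0", "R1", "R2", "not_applicable", UNKNOWN),
    "mutation_status": ("BRAF", "NRAS", "cKIT", "wild_type", UNKNOWN),
}

_PROMPTS = {
    "presentation": "Initial diagnosis: localized primary, regional disease, or distant metastases?",
    "pT_category": "pT category of the primary tumor (incl. ulceration status)?",
    "breslow_mm": "Breslow thickness of the primary tumor (mm)?",
    "regional_pattern": "Regional disease pattern: lymph-node or satellite/in-transit metastases?",
    "slnb_result": "Histopathologic result of the sentinel lymph node biopsy?",
    "staging_radiology": "Result of radiologic staging?",
    "cnd_or_r_status": "Residual status after resection of regional disease (R status)?",
    "mutation_status": "Driver gene mutation status (BRAF / NRAS / cKIT / wild type)?",
}


class ContradictionError(ValueError):
    """Raised when the answered variables contradict each other."""


@dataclass(frozen=True)
class QueryStep:
    variable: str
    prompt: str
    allowed_values: tuple[str, ...]


@dataclass
class CaseState:
    """Mutable questionnaire state: the variables answered so far."""

    answered: dict[str, object] = field(default_factory=dict)

    @property
    def presentation(self) -> Optional[Presentation]:
        v = self.answered.get("presentation")
        return Presentation(v) if v is not None else None

    def answer(self, variable: str, value: object) -> None:
        if variable not in VARIABLE_REGISTRY:
            raise KeyError(f"{variable!r} is not a registry variable")
        if variable in self.answered:
            raise ContradictionError(f"{variable!r} already answered")
        self.answered[variable] = value


def _ask(variable: str) -> QueryStep:
    return QueryStep(variable, _PROMPTS[variable], VARIABLE_REGISTRY[variable])


def _numeric_class(breslow: float) -> int:
    if breslow <= 1.0:
        return 1
    if breslow <= 2.0:
        return 2
    if breslow <= 4.0:
        return 3
    return 4


def _pt_from_answers(pt_answer: str, breslow: float) -> Optional[TCategory]:
    """Resolve the T category from the two answers; None if suffix unresolved."""
    if pt_answer not in VARIABLE_REGISTRY["pT_category"]:
        raise ContradictionError(f"invalid pT answer {pt_answer!r}")
    cls = _numeric_class(breslow)
    if int(pt_answer[1]) != cls:
        raise ContradictionError(
            f"pT answer {pt_answer} inconsistent with Breslow {breslow} mm (T{cls})"
        )
    if len(pt_answer) == 2:  # suffix withheld: ulceration unknown
        ulc = Ulceration.unknown
    else:
        ulc = Ulceration.present if pt_answer.endswith("b") else Ulceration.absent
    return classify_pt(TumorFindings(breslow, ulc))


def next_query(state: CaseState, kb: KnowledgeBase, era: EraLike = None) -> Union[QueryStep, Recommendation]:
    """The next decision-relevant question, or the final recommendation.

    Deterministic in the answered variables; questions whose answer cannot
    change the outcome given the current answers are never asked.
    """
    a = state.answered
    if "presentation" not in a:
        return _ask("presentation")
    pres = Presentation(a["presentation"])

    if pres is Presentation.primary_localized:
        return _localized(a, kb, era)
    if pres is Presentation.regional_nodal_or_in_transit:
        return _regional(a, kb, era)
    return _distant(a, kb, era)


def _final(group: StageGroup, quals: dict[str, str], kb: KnowledgeBase, era: EraLike) -> Recommendation:
    rec = match_recommendation(group, quals, kb, era)
    if rec is None:  # unreachable constellation: never fail silently
        return refer_to_mdt(kb.version, "no_matching_entry")
    return rec


def _mutation(a: dict, kb: KnowledgeBase) -> Union[QueryStep, str, Recommendation]:
    if "mutation_status" not in a:
        return _ask("mutation_status")
    v = a["mutation_status"]
    if v == UNKNOWN or v == Mutation.unknown:
        return missing_info(["mutation_status"], kb.version)
    return "braf" if Mutation(v) is Mutation.BRAF else "non_braf"


def _localized(a: dict, kb: KnowledgeBase, era: EraLike) -> Union[QueryStep, Recommendation]:
    if "pT_category" not in a:
        return _ask("pT_category")
    if a["pT_category"] == UNKNOWN:
        return missing_info(["pT_category"], kb.version)
    if len(a["pT_category"]) == 2 and a["pT_category"] != "T1":
        # suffix withheld (ulceration unresolved) outside T1: no Breslow value
        # can resolve the category, so the question is skipped
        return missing_info(["pT_category"], kb.version)
    if "breslow_mm" not in a:
        return _ask("breslow_mm")
    breslow = a["breslow_mm"]
    if breslow == UNKNOWN or breslow is None:
        return missing_info(["breslow_mm"], kb.version)
    t = _pt_from_answers(a["pT_category"], float(breslow))
    if t is None:  # ulceration unresolved where the suffix matters
        return missing_info(["pT_category"], kb.version)

    if t is TCategory.T1a:
        return _final(StageGroup.IA, {"margin": "1cm"}, kb, era)

    if "slnb_result" not in a:
        return _ask("slnb_result")
    slnb = SlnbResult(a["slnb_result"]) if a["slnb_result"] != UNKNOWN else SlnbResult.unknown
    if slnb is SlnbResult.unknown:
        return missing_info(["slnb_result"], kb.version)
    positive = slnb is SlnbResult.positive

    # Radiologic staging is decision-relevant for node-positive disease and
    # for thicker primaries (>= T2b) where imaging is part of the workup.
    if positive or t.order >= TCategory.T2b.order:
        rad = a.get("staging_radiology")
        if rad is None:
            return _ask("staging_radiology")
        if rad == UNKNOWN:
            return missing_info(["staging_radiology"], kb.version)
        if rad == "unclear":
            return refer_to_mdt(kb.version, "unclear_radiology")
        if rad == "cns":
            return refer_to_mdt(kb.version, "brain_metastases")
        if rad == "distant_non_cns":
            mut = _mutation(a, kb)
            if not isinstance(mut, str):
                return mut
            return _final(StageGroup.IV, {"mutation": mut}, kb, era)

    if positive:
        mut = _mutation(a, kb)
        if not isinstance(mut, str):
            return mut
        grp = stage_group(t, NCategory.N1a, MCategory.M0)
        return _final(grp, {"route": "occult_nodal", "mutation": mut}, kb, era)

    grp = stage_group(t, NCategory.N0, MCategory.M0)
    return _final(grp, {"margin": margin_band(float(breslow))}, kb, era)


def _regional(a: dict, kb: KnowledgeBase, era: EraLike) -> Union[QueryStep, Recommendation]:
    if "regional_pattern" not in a:
        return _ask("regional_pattern")
    satellite = a["regional_pattern"] == "in_transit_satellite"

    rad = a.get("staging_radiology")
    if rad is None:
        return _ask("staging_radiology")
    if rad == UNKNOWN:
        return missing_info(["staging_radiology"], kb.version)
    if rad == "unclear":
        return refer_to_mdt(kb.version, "unclear_radiology")
    if rad == "cns":
        return refer_to_mdt(kb.version, "brain_metastases")
    if rad == "distant_non_cns":
        mut = _mutation(a, kb)
        if not isinstance(mut, str):
            return mut
        return _final(StageGroup.IV, {"mutation": mut}, kb, era)

    # Stage III; the recommendation is uniform across the III subgroups, so a
    # representative subgroup consistent with the route suffices for lookup.
    if satellite:
        mut = _mutation(a, kb)
        if not isinstance(mut, str):
            return mut
        return _final(
            StageGroup.IIIB, {"route": "satellite_in_transit", "mutation": mut}, kb, era
        )

    r = a.get("cnd_or_r_status")
    if r is None:
        return _ask("cnd_or_r_status")
    if r == UNKNOWN:
        return missing_info(["cnd_or_r_status"], kb.version)
    if r in ("R1", "R2"):  # incompletely resected regional disease
        return refer_to_mdt(kb.version, "incomplete_resection")
    mut = _mutation(a, kb)
    if not isinstance(mut, str):
        return mut
    return _final(StageGroup.IIIB, {"route": "clinical_nodal", "mutation": mut}, kb, era)


def _distant(a: dict, kb: KnowledgeBase, era: EraLike) -> Union[QueryStep, Recommendation]:
    rad = a.get("staging_radiology")
    if rad is None:
        return _ask("staging_radiology")
    if rad == UNKNOWN:
        return missing_info(["staging_radiology"], kb.version)
    if rad == "unclear":
        return refer_to_mdt(kb.version, "unclear_radiology")
    if rad == "cns":
        return refer_to_mdt(kb.version, "brain_metastases")
    if rad == "no_evidence":
        raise ContradictionError(
            "distant_metastatic presentation with no radiologic evidence of metastases"
        )
    mut = _mutation(a, kb)
    if not isinstance(mut, str):
        return mut
    return _final(StageGroup.IV, {"mutation": mut}, kb, era)


# --------------------------------------------------------------------------
# Driving the questionnaire from a case record


def _expected_presentation(case: CaseRecord) -> Presentation:
    if case.metastatic_sites != frozenset({MetastaticSite.none}):
        return Presentation.distant_metastatic
    if case.clinically_detected_nodes > 0 or case.in_transit_or_satellite:
        return Presentation.regional_nodal_or_in_transit
    return Presentation.primary_localized


def validate_presentation(case: CaseRecord) -> None:
    """Reject records whose presentation contradicts their findings."""
    expected = _expected_presentation(case)
    if case.presentation is not expected:
        raise ContradictionError(
            f"case {case.case_id}: presentation {case.presentation.value} "
            f"contradicts findings (expected {expected.value})"
        )


def _radiology_answer(case: CaseRecord) -> str:
    if case.unclear_radiology:
        return "unclear"
    sites = case.metastatic_sites - {MetastaticSite.none}
    if MetastaticSite.cns in sites:
        return "cns"
    if sites:
        return "distant_non_cns"
    return "no_evidence"


def _answer_from_record(case: CaseRecord, variable: str) -> object:
    """The record acting as answer oracle for one query step."""
    if variable == "presentation":
        return case.presentation.value
    if variable == "pT_category":
        if case.breslow_mm is None:
            return UNKNOWN
        t = classify_pt(TumorFindings(case.breslow_mm, case.ulceration))
        if t is not None:
            return t.value
        return f"T{_numeric_class(case.breslow_mm)}"  # suffix withheld
    if variable == "breslow_mm":
        return case.breslow_mm if case.breslow_mm is not None else UNKNOWN
    if variable == "regional_pattern":
        return "in_transit_satellite" if case.in_transit_or_satellite else "nodal"
    if variable == "slnb_result":
        return case.slnb.value
    if variable == "staging_radiology":
        return _radiology_answer(case)
    if variable == "cnd_or_r_status":
        if case.r_status is RStatus.unknown:
            return UNKNOWN
        return case.r_status.value
    if variable == "mutation_status":
        return case.mutation.value
    raise KeyError(variable)  # pragma: no cover


def _drive(case: CaseRecord, kb: KnowledgeBase, era: EraLike) -> tuple[Recommendation, list[str]]:
    if case.origin is not Origin.cutaneous:
        return refer_to_mdt(kb.version, "non_cutaneous_origin"), []
    validate_presentation(case)
    state = CaseState()
    trace: list[str] = []
    while True:
        step = next_query(state, kb, era)
        if isinstance(step, Recommendation):
            return step, trace
        state.answer(step.variable, _answer_from_record(case, step.variable))
        if step.variable != "presentation":  # entry selection is not counted
            trace.append(step.variable)


def recommend(case: CaseRecord, kb: KnowledgeBase, era: EraLike = None) -> Recommendation:
    """Run the stepwise query to completion with the record as answer oracle.

    Missing data never raises: a required-but-absent variable yields a
    ``missing_info`` outcome naming it; unresolved radiology or other
    non-standard constellations yield a board referral. Advanced patient age
    attaches an advisory qualifier without changing the emitted code.
    """
    rec, _ = _drive(case, kb, era)
    if case.age >= kb.age_flag_threshold:
        rec = rec.with_qualifiers("advanced_age_flag")
    return rec


def query_trace(case: CaseRecord, kb: KnowledgeBase, era: EraLike = None) -> list[str]:
    """Ordered clinicopathologic variables the questionnaire requested.

    For any record that reaches a treatment recommendation the length lies in
    [2, 5]; a referral or missing-information outcome truncates the trace at
    the triggering variable.
    """
    _, trace = _drive(case, kb, era)
    return trace
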