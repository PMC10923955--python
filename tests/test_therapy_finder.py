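"""Stepwise query engine: traces, outcomes, depth bounds and minimality.

The exhaustive checks walk the whole decision tree over discretized answer
domains (every reachable question sequence), so the depth-bound and
minimality properties are established by enumeration, not sampling.
"""

from __future__ import annotations

import pytest

from conftest import make_case
from melboard.knowledge_base import RecommendationKind, Recommendation
from melboard.records import Presentation
from melboard.therapy_finder import (
    UNKNOWN,
    CaseState,
    ContradictionError,
    QueryStep,
    next_query,
    query_trace,
    recommend,
)

# ----------------------------------------------------------------------
# worked paths


def test_thin_primary_reaches_recommendation_after_two_questions(kb):
    case = make_case(breslow_mm=0.5, ulceration="absent", slnb="not_done")
    rec = recommend(case, kb)
    assert rec.kind is RecommendationKind.treatment
    assert rec.code == "EXC_1CM"
    assert query_trace(case, kb) == ["pT_category", "breslow_mm"]


def test_node_positive_path_needs_five_variables(kb):
    case = make_case(
        breslow_mm=2.5,
        slnb="positive",
        occult_positive_nodes=2,
        mutation="BRAF",
    )
    rec = recommend(case, kb)
    assert rec.code == "ADJ_TARGETED_OR_PD1"
    assert query_trace(case, kb) == [
        "pT_category",
        "breslow_mm",
        "slnb_result",
        "staging_radiology",
        "mutation_status",
    ]


def test_distant_presentation_is_two_questions(kb):
    case = make_case(
        presentation="distant_metastatic",
        metastatic_sites=frozenset({"lung"}),
        slnb="not_done",
        mutation="NRAS",
    )
    rec = recommend(case, kb)
    assert rec.code == "SYS_IMMUNO"
    assert query_trace(case, kb) == ["staging_radiology", "mutation_status"]


def test_missing_sentinel_biopsy_yields_missing_info(kb):
    case = make_case(breslow_mm=2.5, slnb="unknown")
    rec = recommend(case, kb)
    assert rec.kind is RecommendationKind.missing_info
    assert "missing:slnb_result" in rec.qualifiers


def test_unclear_radiology_yields_board_referral(kb):
    case = make_case(
        breslow_mm=4.5, ulceration="present", slnb="not_done", unclear_radiology=True
    )
    rec = recommend(case, kb)
    assert rec.kind is RecommendationKind.refer_to_MDT
    trace = query_trace(case, kb)
    assert trace[-1] == "staging_radiology"  # trace ends at the trigger


def test_prefilled_state_returns_recommendation_without_questions(kb):
    state = CaseState(
        {
            "presentation": Presentation.distant_metastatic.value,
            "staging_radiology": "distant_non_cns",
            "mutation_status": "BRAF",
        }
    )
    out = next_query(state, kb)
    assert isinstance(out, Recommendation)
    assert out.code == "SYS_TARGETED_OR_PD1"


def test_determinism(kb):
    case = make_case(breslow_mm=2.5, slnb="positive", occult_positive_nodes=1, mutation="NRAS")
    assert recommend(case, kb) == recommend(case, kb)
    assert query_trace(case, kb) == query_trace(case, kb)


def test_presentation_contradicting_findings_raises(kb):
    case = make_case(
        presentation="primary_localized",
        metastatic_sites=frozenset({"lung"}),
        slnb="not_done",
    )
    with pytest.raises(ContradictionError):
        recommend(case, kb)


def test_inconsistent_pt_and_breslow_raise(kb):
    state = CaseState({"presentation": "primary_localized", "pT_category": "T1a"})
    step = next_query(state, kb)
    assert step.variable == "breslow_mm"
    state.answer("breslow_mm", 3.0)
    with pytest.raises(ContradictionError):
        next_query(state, kb)


def test_treatment_never_emitted_with_required_variable_unknown(kb):
    """Blanking any single queried variable turns a treatment outcome into a
    missing-information outcome, never a treatment."""
    blankings = [
        {"breslow_mm": None},
        {"slnb": "unknown"},
        {"mutation": "unknown"},
    ]
    base = dict(breslow_mm=2.5, slnb="positive", occult_positive_nodes=1, mutation="BRAF")
    assert recommend(make_case(**base), kb).kind is RecommendationKind.treatment
    for blank in blankings:
        case = make_case(**{**base, **blank})
        assert recommend(case, kb).kind is RecommendationKind.missing_info


# ----------------------------------------------------------------------
# exhaustive walk of the decision tree

_BRESLOW_BY_CLASS = {1: [0.5, 0.9], 2: [1.5, 2.0], 3: [3.0], 4: [4.5]}


def _answer_domain(variable: str, answered: dict) -> list:
    if variable == "presentation":
        return [p.value for p in Presentation]
    if variable == "pT_category":
        return ["T1a", "T1b", "T2a", "T2b", "T3", "T4b", UNKNOWN]
    if variable == "breslow_mm":
        cls = int(answered["pT_category"][1])
        return _BRESLOW_BY_CLASS[cls] + [UNKNOWN]
    if variable == "regional_pattern":
        return ["nodal", "in_transit_satellite"]
    if variable == "slnb_result":
        return ["positive", "negative", "not_done", "unknown"]
    if variable == "staging_radiology":
        return ["no_evidence", "distant_non_cns", "cns", "unclear", UNKNOWN]
    if variable == "cnd_or_r_status":
        return ["R0", "R1", "not_applicable", UNKNOWN]
    if variable == "mutation_status":
        return ["BRAF", "wild_type", UNKNOWN]
    raise KeyError(variable)


def _walk(kb):
    """DFS over every reachable question sequence; yields (trace, outcome)."""
    stack = [({}, [])]
    while stack:
        answered, trace = stack.pop()
        try:
            step = next_query(CaseState(dict(answered)), kb)
        except ContradictionError:
            continue  # pruned: inconsistent answer combination
        if isinstance(step, Recommendation):
            yield trace, step, answered
            continue
        for value in _answer_domain(step.variable, answered):
            nxt = dict(answered)
            nxt[step.variable] = value
            counted = trace + ([step.variable] if step.variable != "presentation" else [])
            stack.append((nxt, counted))


def test_depth_bounds_by_exhaustive_enumeration(kb):
    """Every treatment recommendation is reached after 2-5 counted variables."""
    lengths = set()
    n_paths = 0
    for trace, outcome, _ in _walk(kb):
        n_paths += 1
        if outcome.kind is RecommendationKind.treatment:
            assert 2 <= len(trace) <= 5, (trace, outcome.code)
            lengths.add(len(trace))
    assert n_paths > 50  # the walk actually explored the tree
    assert min(lengths) == 2
    assert max(lengths) == 5


def test_minimality_every_question_can_change_the_outcome(kb):
    """For each asked variable, at least two answer values lead to different
    final outcomes (checked over the exhaustively enumerated tree)."""
    # group paths by the prefix at which each variable was asked
    from collections import defaultdict

    outcomes_by_branch = defaultdict(lambda: defaultdict(set))
    for trace, outcome, answered in _walk(kb):
        ordered = [v for v in trace]
        for var in ordered:
            # prefix = all answers that precede var in this path
            idx = ordered.index(var)
            prefix = tuple(
                sorted((k, str(v)) for k, v in answered.items() if k in ordered[:idx] or k == "presentation")
            )
            outcomes_by_branch[(var, prefix)][str(answered[var])].add(
                (outcome.kind.value, outcome.code)
            )
    assert outcomes_by_branch
    for (var, prefix), by_value in outcomes_by_branch.items():
        all_outcomes = set().union(*by_value.values())
        assert len(by_value) > 1, (var, prefix)
        assert len(all_outcomes) > 1, (var, prefix, all_outcomes)
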