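"""Versioned guideline knowledge base: stage group -> first-line recommendation.

The knowledge base is data, not code: a YAML file mapping AJCC-8 stage groups
plus qualifiers (excision-margin band, regional-disease route, driver-mutation
class) to recommendation codes, with a guideline-era switch because national
melanoma guidelines were revised repeatedly during the study window
(pre-2018 adjuvant interferon vs modern mutation-directed adjuvant therapy).
An equivalence table lists non-identical recommendation pairs accepted as
correct clinical alternatives in a given era; it drives the concordance
adjudication.

Loading validates the file eagerly: schema, stage coverage (exactly one entry
matches every stage/qualifier combination reachable from the staging engine,
checked exhaustively per era), duplicate detection, and that every referenced
recommendation code resolves.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .records import CaseRecord, Mutation
from .staging import (
    MCategory,
    NCategory,
    StageAssignment,
    StageGroup,
    TCategory,
    stage_group,
)

REFER_MDT = "REFER_MDT"
MISSING_INFO = "MISSING_INFO"

PRE_2018 = "pre2018"
POST_2018 = "post2018"
ERAS = (PRE_2018, POST_2018)


class KnowledgeBaseError(ValueError):
    """Base class for knowledge-base loading/validation failures."""


class SchemaError(KnowledgeBaseError):
    pass


class CoverageGapError(KnowledgeBaseError):
    pass


class DuplicateEntryError(KnowledgeBaseError):
    pass


class RecommendationKind(str, enum.Enum):
    treatment = "treatment"
    refer_to_MDT = "refer_to_MDT"
    missing_info = "missing_info"


@dataclass(frozen=True)
class Recommendation:
    """A coded decision-support output.

    Non-treatment kinds use the reserved codes ``REFER_MDT`` and
    ``MISSING_INFO``; treatment codes resolve in the loaded knowledge base.
    Qualifiers carry metadata such as the missing variable names
    (``missing:<variable>``) or the advanced-age advisory flag, and never
    participate in concordance matching, which is by code only.
    """

    kind: RecommendationKind
    code: str
    text: str
    guideline_version: str = ""
    qualifiers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind is RecommendationKind.refer_to_MDT and self.code != REFER_MDT:
            raise ValueError("refer_to_MDT must use the reserved REFER_MDT code")
        if self.kind is RecommendationKind.missing_info and self.code != MISSING_INFO:
            raise ValueError("missing_info must use the reserved MISSING_INFO code")

    def with_qualifiers(self, *extra: str) -> "Recommendation":
        return Recommendation(
            self.kind,
            self.code,
            self.text,
            self.guideline_version,
            self.qualifiers | frozenset(extra),
        )


def refer_to_mdt(version: str = "", *qualifiers: str) -> Recommendation:
    return Recommendation(
        RecommendationKind.refer_to_MDT,
        REFER_MDT,
        "Case needs to be discussed in the multidisciplinary tumor board",
        version,
        frozenset(qualifiers),
    )


def missing_info(missing: Iterable[str], version: str = "") -> Recommendation:
    names = sorted(missing)
    return Recommendation(
        RecommendationKind.missing_info,
        MISSING_INFO,
        "No automatic recommendation: insufficient information (" + ", ".join(names) + ")",
        version,
        frozenset(f"missing:{n}" for n in names),
    )


class _EntryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    stage: list[StageGroup]
    code: str
    text: str
    when: dict[str, Union[str, list[str]]] = {}
    era: Optional[str] = None


class _EquivalenceModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    a: str
    b: str
    era: str


class _KbFileModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    version: str
    default_era: str = POST_2018
    age_flag_threshold: float = 80
    entries: list[_EntryModel]
    extra_codes: dict[str, str] = {}
    equivalences: list[_EquivalenceModel] = []


@dataclass(frozen=True)
class KbEntry:
    stages: frozenset[StageGroup]
    code: str
    text: str
    when: tuple[tuple[str, tuple[str, ...]], ...]  # key -> allowed values
    era: Optional[str]

    def matches(self, stage: StageGroup, qualifiers: dict[str, str], era: str) -> bool:
        if self.era is not None and self.era != era:
            return False
        if stage not in self.stages:
            return False
        return all(qualifiers.get(k) in allowed for k, allowed in self.when)


@dataclass
class KnowledgeBase:
    version: str
    default_era: str
    age_flag_threshold: float
    entries: list[KbEntry]
    extra_codes: dict[str, str]
    equivalences: frozenset[tuple[str, str, str]] = field(default_factory=frozenset)

    def resolve_code(self, code: str) -> str:
        """Human-readable text for a recommendation code; raises if unknown."""
        for entry in self.entries:
            if entry.code == code:
                return entry.text
        if code in self.extra_codes:
            return self.extra_codes[code]
        raise KeyError(f"recommendation code {code!r} not in knowledge base")

    def treatment_from_code(self, code: str, era: Optional[str] = None) -> Recommendation:
        return Recommendation(
            RecommendationKind.treatment,
            code,
            self.resolve_code(code),
            self.version,
        )


EraLike = Union[str, int, _dt.date, _dt.datetime, None]


def era_label(era: EraLike) -> str:
    """Normalise a date, year or label to a guideline-era label."""
    if era is None:
        return POST_2018
    if isinstance(era, str):
        if era not in ERAS:
            raise ValueError(f"unknown era label {era!r}")
        return era
    year = era if isinstance(era, int) else era.year
    return PRE_2018 if year < 2018 else POST_2018


def margin_band(breslow_mm: float) -> str:
    """Excision safety-margin band: 1 cm for Breslow <= 2.0 mm, else 2 cm."""
    return "1cm" if breslow_mm <= 2.0 else "2cm"


def _route(case: CaseRecord) -> str:
    if case.in_transit_or_satellite:
        return "satellite_in_transit"
    if case.clinically_detected_nodes > 0:
        return "clinical_nodal"
    return "occult_nodal"


def case_qualifiers(stage: StageAssignment, case: CaseRecord) -> dict[str, str]:
    """Derive the knowledge-base qualifier values for a staged case.

    A mutation-dependent qualifier with unknown mutation status is emitted as
    ``"unknown"``, which matches no entry — callers surface that as a
    missing-information outcome before the lookup.
    """
    quals: dict[str, str] = {}
    major = stage.stage_group.major
    if major in ("I", "II"):
        quals["margin"] = margin_band(case.breslow_mm)
    elif major == "III":
        quals["route"] = _route(case)
        quals["mutation"] = _mutation_class(case.mutation)
    else:  # IV
        quals["mutation"] = _mutation_class(case.mutation)
    return quals


def _mutation_class(mutation: Mutation) -> str:
    if mutation is Mutation.unknown:
        return "unknown"
    return "braf" if mutation is Mutation.BRAF else "non_braf"


def reachable_combinations() -> list[tuple[StageGroup, dict[str, str]]]:
    """Every (stage group, qualifier) combination the staging engine can emit.

    Enumerated from the full T x N x M grid: the margin band follows from the
    T numeric class (T1/T2 imply Breslow <= 2.0 mm, T3/T4 > 2.0 mm), the
    regional route from the N suffix (a = occult, b = clinical, c =
    satellite/in-transit), and mutation-dependent stages fan out over both
    mutation classes.
    """
    combos: set[tuple[StageGroup, tuple[tuple[str, str], ...]]] = set()
    for t in TCategory:
        band = "1cm" if t.value[1] in "12" else "2cm"
        for n in NCategory:
            for m in MCategory:
                grp = stage_group(t, n, m)
                major = grp.major
                if major in ("I", "II"):
                    quals_list = [{"margin": band}]
                elif major == "III":
                    route = {
                        "a": "occult_nodal",
                        "b": "clinical_nodal",
                        "c": "satellite_in_transit",
                    }[n.value[-1]]
                    quals_list = [
                        {"route": route, "mutation": mc} for mc in ("braf", "non_braf")
                    ]
                else:
                    quals_list = [{"mutation": mc} for mc in ("braf", "non_braf")]
                for q in quals_list:
                    combos.add((grp, tuple(sorted(q.items()))))
    return [(grp, dict(items)) for grp, items in sorted(combos, key=lambda c: (c[0].order, c[1]))]


def _validate_coverage(kb: KnowledgeBase) -> None:
    for grp, quals in reachable_combinations():
        for era in ERAS:
            hits = [e for e in kb.entries if e.matches(grp, quals, era)]
            if len(hits) > 1:
                raise DuplicateEntryError(
                    f"{len(hits)} entries match stage {grp.value} {quals} in era {era}: "
                    + ", ".join(e.code for e in hits)
                )
            if not hits:
                raise CoverageGapError(
                    f"no entry for reachable stage {grp.value} {quals} in era {era}"
                )


def load_knowledge_base(path: Union[str, Path, None] = None) -> KnowledgeBase:
    """Load and fully validate a knowledge-base file (default: shipped file).

    Fails loudly on schema violations, duplicate or missing entries for any
    reachable stage/qualifier combination, unknown era labels, and
    equivalence codes that do not resolve.
    """
    if path is None:
        raw = resources.files("melboard.data").joinpath("knowledge_base.yaml").read_text()
    else:
        raw = Path(path).read_text()
    try:
        model = _KbFileModel.model_validate(yaml.safe_load(raw))
    except (yaml.YAMLError, ValidationError) as exc:
        raise SchemaError(f"knowledge base file invalid: {exc}") from exc

    entries = []
    for e in model.entries:
        if e.era is not None and e.era not in ERAS:
            raise SchemaError(f"unknown era {e.era!r} in entry {e.code}")
        when = tuple(
            (k, tuple(v) if isinstance(v, list) else (v,)) for k, v in sorted(e.when.items())
        )
        entries.append(KbEntry(frozenset(e.stage), e.code, e.text, when, e.era))

    equivalences = set()
    for eq in model.equivalences:
        if eq.era not in ERAS:
            raise SchemaError(f"unknown era {eq.era!r} in equivalence {eq.a}~{eq.b}")
        equivalences.add((eq.a, eq.b, eq.era))
        equivalences.add((eq.b, eq.a, eq.era))  # equivalence is symmetric

    kb = KnowledgeBase(
        version=model.version,
        default_era=era_label(model.default_era),
        age_flag_threshold=model.age_flag_threshold,
        entries=entries,
        extra_codes=dict(model.extra_codes),
        equivalences=frozenset(equivalences),
    )
    _validate_coverage(kb)
    for a, b, _ in kb.equivalences:
        kb.resolve_code(a), kb.resolve_code(b)
    return kb


def match_recommendation(
    group: StageGroup,
    qualifiers: dict[str, str],
    kb: KnowledgeBase,
    era: EraLike = None,
) -> Optional[Recommendation]:
    """Resolve a stage group + qualifiers against the entries, or ``None``.

    The load-time coverage check guarantees at most one entry can match any
    reachable combination; more than one match is an internal error.
    """
    active_era = era_label(era) if era is not None else kb.default_era
    hits = [e for e in kb.entries if e.matches(group, qualifiers, active_era)]
    if len(hits) > 1:  # pragma: no cover - excluded by load-time check
        raise DuplicateEntryError(f"ambiguous entries for {group.value} {qualifiers}")
    if not hits:
        return None
    e = hits[0]
    return Recommendation(
        RecommendationKind.treatment,
        e.code,
        e.text,
        f"{kb.version}/{active_era}",
        frozenset(f"{k}={v}" for k, v in qualifiers.items()),
    )


def lookup_recommendation(
    stage: StageAssignment,
    case: CaseRecord,
    kb: KnowledgeBase,
    era: EraLike = None,
) -> Recommendation:
    """Deterministic recommendation for a fully staged case.

    Unresolved radiologic findings short-circuit to a board referral; a
    mutation-dependent entry with unknown mutation status yields a
    missing-information outcome; a constellation no entry covers is referred
    to the board, never silently dropped. Advanced patient age never changes
    the emitted code — it only attaches an advisory qualifier (the study's
    one age-driven deviation is an adjudication matter, not an engine rule).
    """
    if case.unclear_radiology:
        rec = refer_to_mdt(kb.version, "unclear_radiology")
    else:
        quals = case_qualifiers(stage, case)
        if quals.get("mutation") == "unknown":
            rec = missing_info(["mutation_status"], kb.version)
        else:
            rec = match_recommendation(stage.stage_group, quals, kb, era)
            if rec is None:
                rec = refer_to_mdt(kb.version, "no_matching_entry")
    if case.age >= kb.age_flag_threshold:
        rec = rec.with_qualifiers("advanced_age_flag")
    return rec


def are_correct_alternatives(
    a: Recommendation, b: Recommendation, era: EraLike, kb: KnowledgeBase
) -> bool:
    """True iff two treatment recommendations are accepted clinical alternatives.

    Identical codes are trivially equivalent; otherwise the (symmetric)
    equivalence table must contain the pair for the era of the board decision.
    """
    if a.kind is not RecommendationKind.treatment or b.kind is not RecommendationKind.treatment:
        return False
    if a.code == b.code:
        return True
    return (a.code, b.code, era_label(era)) in kb.equivalences
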