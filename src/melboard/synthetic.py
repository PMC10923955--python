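"""Seeded synthetic tumor-board cohorts with paired board recommendations.

No deposited patient data exists for this problem, so every downstream module
is exercised on generated cohorts. A :class:`CohortSpec` fixes the cohort
composition as *counts, not expectations*: the exclusion-attribute allocation,
the eligible stage mix, and the deviation injections (era-driven alternative
recommendations, patient-factor deviations, unresolved radiology) are placed
exactly; only incidental attributes (ages, thicknesses, dates, histotypes)
are sampled from the seeded generator. Paired board (MDT) recommendation
codes equal the decision-support output except for the injected deviations.

The shipped ``cologne_2017_2020`` preset replays a four-year skin-cancer
conference registry: 2399 registrations, of which 705 are melanoma; 594 of
those carry an exclusion attribute or lack required query variables (377
relapsed, 78 non-cutaneous, 43 complex constellations, 24 further
attribute-based exclusions, 72 with insufficient information), leaving 111
standard-case candidates with stage mix 3 / 19 / 85 / 4 (I-IV) and
deviation injections 21 / 1 / 2.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .knowledge_base import KnowledgeBase, RecommendationKind, load_knowledge_base
from .records import (
    CaseRecord,
    Ldh,
    MetastaticSite,
    Mutation,
    Origin,
    Presentation,
    SlnbResult,
    RStatus,
    Ulceration,
)
from .therapy_finder import recommend

_NORM_QUARTILE = 0.6744897501960817  # standard-normal 75th percentile


class CohortSpec(BaseModel):
    """Composition of a synthetic conference cohort.

    ``stage_mix`` with integer values fixes exact eligible counts per major
    stage; float values are sampled as multinomial probabilities. The
    exclusion allocation (including the ``missing_data`` block, whose records
    have required query fields blanked) is always exact.
    """

    model_config = ConfigDict(extra="forbid")

    name: str = "custom"
    n_total: int
    n_non_melanoma: int = 0
    exclusion_allocation: dict[str, int] = {}
    stage_mix: dict[str, Union[int, float]]
    deviation_injection: dict[str, int] = {
        "era_alternative": 0,
        "patient_factor_alternative": 0,
        "unclear_radiology": 0,
    }
    histotype_mix: dict[str, float] = {
        "superficial_spreading": 0.234,
        "nodular": 0.423,
        "lentigo_maligna": 0.009,
        "acral_lentiginous": 0.045,
        "amelanotic": 0.045,
        "other": 0.244,
    }
    ecog_mix: dict[int, float] = {0: 0.838, 1: 0.081, 2: 0.054, 3: 0.027}
    mutation_mix: dict[str, float] = {
        "BRAF": 0.41,
        "NRAS": 0.27,
        "cKIT": 0.05,
        "wild_type": 0.27,
    }
    age_median: float = 62.0
    age_iqr: tuple[float, float] = (52.0, 72.0)
    seed: int = 0

    @property
    def n_eligible(self) -> int:
        return self.n_total - sum(self.exclusion_allocation.values())

    @property
    def exact_stages(self) -> bool:
        return all(isinstance(v, int) for v in self.stage_mix.values())

    @model_validator(mode="after")
    def _feasible(self) -> "CohortSpec":
        if self.n_eligible < 0:
            raise ValueError("exclusion allocation exceeds n_total")
        for mix_name in ("histotype_mix", "ecog_mix", "mutation_mix"):
            mix = getattr(self, mix_name)
            if not math.isclose(sum(mix.values()), 1.0, abs_tol=1e-6):
                raise ValueError(f"{mix_name} must sum to 1")
        if self.exact_stages and sum(self.stage_mix.values()) != self.n_eligible:
            raise ValueError(
                f"exact stage counts sum to {sum(self.stage_mix.values())}, "
                f"expected {self.n_eligible} eligible cases"
            )
        if not self.exact_stages and not math.isclose(
            sum(self.stage_mix.values()), 1.0, abs_tol=1e-6
        ):
            raise ValueError("stage_mix probabilities must sum to 1")
        if any(v < 0 for v in self.deviation_injection.values()):
            raise ValueError("deviation injections must be non-negative")
        return self


def cologne_2017_2020(seed: int = 20172020) -> CohortSpec:
    """Study-replica preset: the 2017-2020 skin-cancer conference registry."""
    return CohortSpec(
        name="cologne_2017_2020",
        n_total=705,
        n_non_melanoma=1694,
        exclusion_allocation={
            "relapsed_disease": 377,
            "non_cutaneous_melanoma": 78,
            "complex_constellation": 43,
            # 24 exclusions are not attributed in the source counts; split
            # evenly across the remaining named attribute categories.
            "secondary_cancer": 6,
            "clinical_trial": 6,
            "declined_procedure": 6,
            "brain_metastases": 6,
            "missing_data": 72,
        },
        stage_mix={"I": 3, "II": 19, "III": 85, "IV": 4},
        deviation_injection={
            "era_alternative": 21,
            "patient_factor_alternative": 1,
            "unclear_radiology": 2,
        },
        seed=seed,
    )


PRESETS = {"cologne_2017_2020": cologne_2017_2020}


@dataclass
class CohortResult:
    """Generated records plus the injection manifest.

    ``manifest`` maps each injection type to the affected case ids and lists
    eligible-by-construction ids; ``manual_overrides`` carries the documented
    manual adjudication for patient-factor deviations (reviewer upholds the
    board's choice, so the pair counts as incorrect)."""

    spec: CohortSpec
    records: list[CaseRecord]
    manifest: dict[str, list[str]] = field(default_factory=dict)

    @property
    def melanoma(self) -> list[CaseRecord]:
        return [r for r in self.records if r.origin is not Origin.non_melanoma]

    def manual_overrides(self) -> dict[str, tuple[str, str]]:
        from .concordance import PairCategory

        return {
            cid: (
                PairCategory.incorrect,
                "board recommendation upheld on review: patient-specific factors "
                "(advanced age, resection site) favor the board's choice",
            )
            for cid in self.manifest.get("patient_factor_alternative", [])
        }


class _Gen:
    def __init__(self, spec: CohortSpec, kb: KnowledgeBase):
        self.spec = spec
        self.kb = kb
        self.rng = np.random.default_rng(spec.seed)
        self._serial = 0
        mu = math.log(spec.age_median)
        q1, q3 = spec.age_iqr
        self.age_sigma = (math.log(q3) - math.log(q1)) / (2 * _NORM_QUARTILE)
        self.age_mu = mu

    def next_id(self) -> str:
        self._serial += 1
        return f"MB-{self._serial:04d}"

    def age(self) -> float:
        # log-normal fitted to the configured median/IQR, truncated to [18, 95]
        for _ in range(100):
            v = float(np.exp(self.rng.normal(self.age_mu, self.age_sigma)))
            if 18 <= v <= 95:
                return round(v, 1)
        return float(self.spec.age_median)

    def ecog(self) -> int:
        keys = sorted(self.spec.ecog_mix)
        p = np.array([self.spec.ecog_mix[k] for k in keys], dtype=float)
        return int(self.rng.choice(keys, p=p / p.sum()))

    def histotype(self) -> str:
        keys = sorted(self.spec.histotype_mix)
        p = np.array([self.spec.histotype_mix[k] for k in keys], dtype=float)
        return str(self.rng.choice(keys, p=p / p.sum()))

    def mutation(self) -> Mutation:
        keys = sorted(self.spec.mutation_mix)
        p = np.array([self.spec.mutation_mix[k] for k in keys], dtype=float)
        return Mutation(str(self.rng.choice(keys, p=p / p.sum())))

    def date(self, era: str = "post2018") -> _dt.date:
        if era == "pre2018":
            start, days = _dt.date(2017, 1, 1), 364
        else:
            start, days = _dt.date(2018, 1, 1), 1094
        return start + _dt.timedelta(days=int(self.rng.integers(0, days + 1)))

    def breslow(self, lo: float, hi: float) -> float:
        return round(float(self.rng.uniform(lo, hi)), 1)

    # ----- record archetypes -------------------------------------------

    def base(self, **over) -> CaseRecord:
        fields = dict(
            case_id=self.next_id(),
            age=self.age(),
            histotype=self.histotype(),
            ecog=self.ecog(),
            decision_date=self.date(),
            origin=Origin.cutaneous,
            presentation=Presentation.primary_localized,
            breslow_mm=self.breslow(2.1, 3.9),
            ulceration=Ulceration.absent,
            slnb=SlnbResult.negative,
            r_status=RStatus.not_applicable,
            mutation=Mutation.unknown,
        )
        fields.update(over)
        return CaseRecord(**fields)

    def stage_i(self, idx: int) -> CaseRecord:
        if idx == 0:  # thin non-ulcerated primary: IA, two-question path
            return self.base(
                breslow_mm=self.breslow(0.3, 0.7),
                ulceration=Ulceration.absent,
                slnb=SlnbResult.not_done,
            )
        return self.base(  # T1b, sentinel biopsy negative: IB
            breslow_mm=self.breslow(0.8, 1.0),
            ulceration=Ulceration.absent,
            slnb=SlnbResult.negative,
        )

    def stage_ii(self) -> CaseRecord:
        band = self.rng.integers(0, 4)  # T2b / T3a / T3b / T4a-b mixtures
        if band == 0:
            bres, ulc = self.breslow(1.2, 2.0), Ulceration.present  # IIA
        elif band == 1:
            bres, ulc = self.breslow(2.2, 3.9), Ulceration.present  # IIB (T3b)
        elif band == 2:
            bres, ulc = self.breslow(4.1, 6.0), Ulceration.absent  # IIB (T4a)
        else:
            bres, ulc = self.breslow(4.1, 6.0), Ulceration.present  # IIC (T4b)
        slnb = SlnbResult.negative if self.rng.random() < 0.8 else SlnbResult.not_done
        return self.base(breslow_mm=bres, ulceration=ulc, slnb=slnb)

    def stage_iii_occult(self, era: str = "post2018") -> CaseRecord:
        return self.base(
            decision_date=self.date(era),
            breslow_mm=self.breslow(1.2, 3.9),
            ulceration=Ulceration.present if self.rng.random() < 0.5 else Ulceration.absent,
            slnb=SlnbResult.positive,
            occult_positive_nodes=int(self.rng.integers(1, 4)),
            mutation=self.mutation(),
        )

    def stage_iii_clinical(self) -> CaseRecord:
        return self.base(
            presentation=Presentation.regional_nodal_or_in_transit,
            breslow_mm=self.breslow(1.5, 3.9),
            ulceration=Ulceration.present,
            slnb=SlnbResult.not_done,
            clinically_detected_nodes=int(self.rng.integers(1, 4)),
            r_status=RStatus.R0,
            mutation=self.mutation(),
        )

    def stage_iii_satellite(self, advanced_age: bool) -> CaseRecord:
        return self.base(
            age=82.0 if advanced_age else self.age(),
            presentation=Presentation.regional_nodal_or_in_transit,
            breslow_mm=self.breslow(2.1, 3.9),
            ulceration=Ulceration.absent,
            slnb=SlnbResult.not_done,
            in_transit_or_satellite=True,
            mutation=Mutation.wild_type,
        )

    def stage_iv(self) -> CaseRecord:
        site = [
            MetastaticSite.lung,
            MetastaticSite.skin_soft_tissue_distant_nodes,
            MetastaticSite.other_visceral_non_cns,
        ][int(self.rng.integers(0, 3))]
        return self.base(
            presentation=Presentation.distant_metastatic,
            breslow_mm=self.breslow(1.5, 5.0),
            ulceration=Ulceration.present,
            slnb=SlnbResult.not_done,
            metastatic_sites=frozenset({site}),
            ldh=Ldh.normal if self.rng.random() < 0.6 else Ldh.elevated,
            mutation=self.mutation(),
        )

    def unclear_radiology_case(self, localized: bool) -> CaseRecord:
        """High-risk thick ulcerated primary with an unresolved CT finding.

        The localized variant mirrors a solitary pulmonary nodule after
        primary resection (stage IIC by confirmed findings); the regional
        variant mirrors suspicious cervical lymph nodes (stage IIIC)."""
        if localized:
            return self.base(
                breslow_mm=self.breslow(4.2, 5.5),
                ulceration=Ulceration.present,
                slnb=SlnbResult.not_done,
                unclear_radiology=True,
            )
        return self.base(
            presentation=Presentation.regional_nodal_or_in_transit,
            breslow_mm=self.breslow(4.2, 5.5),
            ulceration=Ulceration.present,
            slnb=SlnbResult.not_done,
            clinically_detected_nodes=1,
            r_status=RStatus.R0,
            unclear_radiology=True,
        )

    def missing_data_case(self, variant: int) -> CaseRecord:
        variant %= 3
        if variant == 0:  # sentinel-node result not documented on a >=T1b primary
            return self.base(breslow_mm=self.breslow(1.2, 3.9), slnb=SlnbResult.unknown)
        if variant == 1:  # ulceration status pending: pT suffix unresolved
            return self.base(
                breslow_mm=self.breslow(2.1, 3.9),
                ulceration=Ulceration.unknown,
                slnb=SlnbResult.negative,
            )
        # node-positive case with mutation analysis still pending
        return self.base(
            breslow_mm=self.breslow(1.2, 3.9),
            slnb=SlnbResult.positive,
            occult_positive_nodes=1,
            mutation=Mutation.unknown,
        )

    def excluded_case(self, reason: str, idx: int) -> CaseRecord:
        if reason == "relapsed_disease":
            return self.base(relapse=True)
        if reason == "non_cutaneous_melanoma":
            origin = [Origin.mucosal, Origin.uveal, Origin.unknown_primary][idx % 3]
            return self.base(origin=origin)
        if reason == "secondary_cancer":
            return self.base(secondary_cancer=True)
        if reason == "severe_comorbidity":
            return self.base(severe_comorbidity=True, ecog=3)
        if reason == "clinical_trial":
            return self.base(clinical_trial=True)
        if reason == "declined_procedure":
            return self.base(breslow_mm=self.breslow(1.2, 3.9), slnb=SlnbResult.declined)
        if reason == "brain_metastases":
            return self.base(
                presentation=Presentation.distant_metastatic,
                slnb=SlnbResult.not_done,
                metastatic_sites=frozenset(
                    {MetastaticSite.cns, MetastaticSite.lung}
                ),
                ldh=Ldh.elevated,
                mutation=self.mutation(),
            )
        if reason == "complex_constellation":
            return self.base(complex_constellation=True)
        raise ValueError(f"unknown exclusion reason {reason!r}")

    def non_melanoma_case(self) -> CaseRecord:
        return self.base(
            origin=Origin.non_melanoma,
            breslow_mm=None,
            ulceration=Ulceration.unknown,
            slnb=SlnbResult.not_done,
        )


def _stage_counts(spec: CohortSpec, rng: np.random.Generator) -> dict[str, int]:
    if spec.exact_stages:
        return {s: int(n) for s, n in spec.stage_mix.items()}
    stages = sorted(spec.stage_mix)
    p = np.array([spec.stage_mix[s] for s in stages], dtype=float)
    draws = rng.multinomial(spec.n_eligible, p / p.sum())
    return dict(zip(stages, (int(d) for d in draws)))


def generate_cohort(spec: CohortSpec, kb: Optional[KnowledgeBase] = None) -> CohortResult:
    """Generate the cohort deterministically from the spec's seed.

    Raises ``ValueError`` when the allocation is infeasible (injections
    exceeding the capacity of the stages that can carry them). Board codes
    are derived by running the recommendation engine and then applying the
    injected deviations, so concordance category counts equal the injection
    counts exactly.
    """
    if kb is None:
        kb = load_knowledge_base()
    gen = _Gen(spec, kb)
    rng = gen.rng
    manifest: dict[str, list[str]] = {
        "era_alternative": [],
        "patient_factor_alternative": [],
        "unclear_radiology": [],
        "eligible": [],
    }

    stage_counts = _stage_counts(spec, rng)
    n1 = stage_counts.get("I", 0)
    n2 = stage_counts.get("II", 0)
    n3 = stage_counts.get("III", 0)
    n4 = stage_counts.get("IV", 0)

    inj = dict(spec.deviation_injection)
    n_era = inj.get("era_alternative", 0)
    n_pf = inj.get("patient_factor_alternative", 0)
    n_unclear = inj.get("unclear_radiology", 0)

    # unresolved-radiology injections alternate localized (stage II) /
    # regional (stage III) high-risk constellations, localized first
    u2 = u3 = 0
    for i in range(n_unclear):
        if (i % 2 == 0 and u2 < n2) or u3 + 1 > max(n3 - n_pf, 0):
            u2 += 1
        else:
            u3 += 1
    if u2 > n2 or u3 > n3 - n_pf:
        raise ValueError("unclear-radiology injections exceed stage capacity")

    n_clinical = min(max(round(0.08 * n3), 0), n3 - n_pf - u3)
    n_occult = n3 - n_pf - u3 - n_clinical
    if n_occult < n_era:
        raise ValueError("era-alternative injections exceed node-positive capacity")
    if n_pf > n3:
        raise ValueError("patient-factor injections exceed stage III capacity")

    eligible: list[CaseRecord] = []
    for i in range(n1):
        eligible.append(gen.stage_i(i))
    for _ in range(n2 - u2):
        eligible.append(gen.stage_ii())
    for i in range(u2):
        case = gen.unclear_radiology_case(localized=True)
        manifest["unclear_radiology"].append(case.case_id)
        eligible.append(case)
    for i in range(n_occult):
        era = "pre2018" if i < n_era else "post2018"
        case = gen.stage_iii_occult(era)
        if i < n_era:
            manifest["era_alternative"].append(case.case_id)
        eligible.append(case)
    for _ in range(n_clinical):
        eligible.append(gen.stage_iii_clinical())
    for _ in range(n_pf):
        case = gen.stage_iii_satellite(advanced_age=True)
        manifest["patient_factor_alternative"].append(case.case_id)
        eligible.append(case)
    for _ in range(u3):
        case = gen.unclear_radiology_case(localized=False)
        manifest["unclear_radiology"].append(case.case_id)
        eligible.append(case)
    for _ in range(n4):
        eligible.append(gen.stage_iv())

    # paired board codes: engine output, then injected deviations
    era_ids = set(manifest["era_alternative"])
    pf_ids = set(manifest["patient_factor_alternative"])
    unclear_ids = set(manifest["unclear_radiology"])
    for idx, case in enumerate(eligible):
        rec = recommend(case, kb)
        if case.case_id in era_ids:
            mdt = "ADJ_IFN"
        elif case.case_id in pf_ids:
            mdt = "TVEC"
        elif case.case_id in unclear_ids:
            # the board did issue a treatment for these cases
            mdt = "EXC_2CM_SLNB" if case.clinically_detected_nodes == 0 else "ADJ_PD1"
        else:
            if rec.kind is not RecommendationKind.treatment:  # pragma: no cover
                raise RuntimeError(
                    f"eligible archetype {case.case_id} produced {rec.kind}"
                )
            mdt = rec.code
        eligible[idx] = case.model_copy(update={"mdt_code": mdt})
    manifest["eligible"] = [c.case_id for c in eligible]

    excluded: list[CaseRecord] = []
    for reason, count in spec.exclusion_allocation.items():
        if reason == "missing_data":
            excluded.extend(gen.missing_data_case(i) for i in range(count))
        else:
            excluded.extend(gen.excluded_case(reason, i) for i in range(count))

    melanoma = eligible + excluded
    order = rng.permutation(len(melanoma))
    melanoma = [melanoma[i] for i in order]
    wrapper = [gen.non_melanoma_case() for _ in range(spec.n_non_melanoma)]
    return CohortResult(spec=spec, records=melanoma + wrapper, manifest=manifest)
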