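"""Case-record model and closed vocabularies for tumor-board registrations.

A :class:`CaseRecord` holds everything a melanoma tumor-board registration
carries: the clinicopathologic findings the staging engine consumes, the
administrative exclusion flags the triage filter reads, and (optionally) the
recommendation code the multidisciplinary tumor board (MDT) actually issued,
for concordance analysis.

Unknown values are always explicit enum members or ``None`` — an empty string
is never silently coerced to a value.
"""

from __future__ import annotations

import datetime as _dt
import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Origin(str, enum.Enum):
    """Primary-tumor origin; only cutaneous melanoma is in the tool's scope."""

    cutaneous = "cutaneous"
    mucosal = "mucosal"
    uveal = "uveal"
    unknown_primary = "unknown_primary"
    non_melanoma = "non_melanoma"


class Presentation(str, enum.Enum):
    """Initial-diagnosis selection that opens the stepwise query."""

    primary_localized = "primary_localized"
    regional_nodal_or_in_transit = "regional_nodal_or_in_transit"
    distant_metastatic = "distant_metastatic"


class Ulceration(str, enum.Enum):
    present = "present"
    absent = "absent"
    unknown = "unknown"


class SlnbResult(str, enum.Enum):
    """Sentinel lymph node biopsy outcome.

    ``not_done`` and ``declined`` are real answers (the workup simply does not
    include the procedure); ``unknown`` means the information is missing and
    blocks an automatic recommendation.
    """

    positive = "positive"
    negative = "negative"
    not_done = "not_done"
    declined = "declined"
    unknown = "unknown"


class RStatus(str, enum.Enum):
    R0 = "R0"
    R1 = "R1"
    R2 = "R2"
    unknown = "unknown"
    not_applicable = "not_applicable"


class Mutation(str, enum.Enum):
    BRAF = "BRAF"
    NRAS = "NRAS"
    cKIT = "cKIT"
    wild_type = "wild_type"
    unknown = "unknown"


class Ldh(str, enum.Enum):
    normal = "normal"
    elevated = "elevated"
    unknown = "unknown"


class MetastaticSite(str, enum.Enum):
    """Distant-metastasis site classes, ranked for M categorisation."""

    none = "none"
    skin_soft_tissue_distant_nodes = "skin_soft_tissue_distant_nodes"
    lung = "lung"
    other_visceral_non_cns = "other_visceral_non_cns"
    cns = "cns"


class CaseRecord(BaseModel):
    """One tumor-board registration.

    Houses every variable the stepwise query can request (Breslow thickness,
    ulceration, SLNB result, radiology, CLND / residual status, in-transit and
    satellite disease, driver mutation) plus the administrative attributes the
    standard-case triage filter inspects, and the paired MDT recommendation
    code when the record is used for concordance analysis.
    """

    model_config = ConfigDict(validate_assignment=True)

    case_id: str
    age: float
    histotype: Optional[str] = None
    ecog: Optional[int] = None
    decision_date: Optional[_dt.date] = None
    origin: Origin = Origin.cutaneous
    presentation: Presentation = Presentation.primary_localized

    # tumor findings
    breslow_mm: Optional[float] = None
    ulceration: Ulceration = Ulceration.unknown

    # nodal findings
    occult_positive_nodes: int = 0
    clinically_detected_nodes: int = 0
    matted_nodes: bool = False
    in_transit_or_satellite: bool = False

    # metastasis findings
    metastatic_sites: frozenset[MetastaticSite] = frozenset({MetastaticSite.none})
    ldh: Ldh = Ldh.unknown
    unclear_radiology: bool = False

    # workup / therapy variables
    slnb: SlnbResult = SlnbResult.unknown
    cnd_performed: Optional[bool] = None
    r_status: RStatus = RStatus.not_applicable
    mutation: Mutation = Mutation.unknown

    # exclusion attributes
    relapse: bool = False
    secondary_cancer: bool = False
    severe_comorbidity: bool = False
    clinical_trial: bool = False
    complex_constellation: bool = False

    # paired board decision (optional)
    mdt_code: Optional[str] = None

    @field_validator("age")
    @classmethod
    def _age_plausible(cls, v: float) -> float:
        if not 0 <= v <= 120:
            raise ValueError(f"age {v} outside [0, 120]")
        return v

    @field_validator("ecog")
    @classmethod
    def _ecog_range(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and not 0 <= v <= 4:
            raise ValueError(f"ECOG {v} outside 0-4")
        return v

    @field_validator("breslow_mm")
    @classmethod
    def _breslow_nonneg(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and v < 0:
            raise ValueError(f"Breslow thickness {v} mm is negative")
        return v

    @field_validator("occult_positive_nodes", "clinically_detected_nodes")
    @classmethod
    def _counts_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("node counts must be non-negative")
        return v

    @model_validator(mode="after")
    def _cross_field(self) -> "CaseRecord":
        if self.matted_nodes and self.clinically_detected_nodes < 1:
            raise ValueError("matted nodes require >=1 clinically detected node")
        sites = self.metastatic_sites
        if MetastaticSite.none in sites and len(sites) > 1:
            raise ValueError("'none' is exclusive of other metastatic sites")
        return self
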