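"""AJCC 8th-edition melanoma TNM classification and stage grouping.

The T, N and M classifiers are deterministic table rules on the
clinicopathologic findings; the pathological stage grouping is a shipped
400-cell flat lookup table (``data/stage_groups.csv``, one row per
T x N x M cell) so the grouping is diffable and independently auditable.
The loader verifies totality — every cell of the 8 x 10 x 5 grid present
exactly once — before the first lookup.

Encoded category rules
----------------------
T: T1 <=1.0 mm (T1a <0.8 mm non-ulcerated; T1b <0.8 mm ulcerated or
0.8-1.0 mm), T2 >1.0-2.0 mm, T3 >2.0-4.0 mm, T4 >4.0 mm; suffix a =
non-ulcerated, b = ulcerated; intervals half-open at the lower edge.

N: N1a/N2a/N3a = 1 / 2-3 / >=4 occult (sentinel-biopsy detected) nodes;
N1b/N2b/N3b = 1 / 2-3 / >=4-or-matted with at least one clinically detected
node; N1c/N2c/N3c = in-transit/satellite/microsatellite disease with
0 / 1 / >=2-or-matted involved nodes.

M: highest-ranking distant site wins (CNS > non-CNS visceral > lung >
distant skin/soft tissue/nodes); the LDH suffix (0)/(1) is appended only
when LDH is known and never blocks classification.

Missing data is signalled in-band: ``classify_pt`` returns ``None`` when the
T category cannot be determined (thickness unknown, or ulceration unknown
where the a/b suffix matters), so the therapy layer can convert it into a
missing-information outcome instead of crashing.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .records import CaseRecord, Ldh, MetastaticSite, Ulceration


class TCategory(str, enum.Enum):
    T1a = "T1a"
    T1b = "T1b"
    T2a = "T2a"
    T2b = "T2b"
    T3a = "T3a"
    T3b = "T3b"
    T4a = "T4a"
    T4b = "T4b"

    @property
    def order(self) -> int:
        return list(TCategory).index(self)


class NCategory(str, enum.Enum):
    N0 = "N0"
    N1a = "N1a"
    N1b = "N1b"
    N1c = "N1c"
    N2a = "N2a"
    N2b = "N2b"
    N2c = "N2c"
    N3a = "N3a"
    N3b = "N3b"
    N3c = "N3c"

    @property
    def order(self) -> int:
        return list(NCategory).index(self)


class MCategory(str, enum.Enum):
    M0 = "M0"
    M1a = "M1a"
    M1b = "M1b"
    M1c = "M1c"
    M1d = "M1d"


class StageGroup(str, enum.Enum):
    IA = "IA"
    IB = "IB"
    IIA = "IIA"
    IIB = "IIB"
    IIC = "IIC"
    IIIA = "IIIA"
    IIIB = "IIIB"
    IIIC = "IIIC"
    IIID = "IIID"
    IV = "IV"

    @property
    def order(self) -> int:
        return list(StageGroup).index(self)

    @property
    def major(self) -> str:
        """Roman-numeral major stage (IA -> 'I', IIIC -> 'III')."""
        return self.value.rstrip("ABCD")


@dataclass(frozen=True)
class TumorFindings:
    breslow_mm: Optional[float]
    ulceration: Ulceration = Ulceration.unknown

    def __post_init__(self) -> None:
        if self.breslow_mm is not None and self.breslow_mm < 0:
            raise ValueError("Breslow thickness must be non-negative")


@dataclass(frozen=True)
class NodalFindings:
    occult_positive_nodes: int = 0
    clinically_detected_nodes: int = 0
    matted_nodes: bool = False
    in_transit_or_satellite: bool = False

    def __post_init__(self) -> None:
        if self.occult_positive_nodes < 0 or self.clinically_detected_nodes < 0:
            raise ValueError("node counts must be non-negative")
        if self.matted_nodes and self.clinically_detected_nodes < 1:
            raise ValueError("matted nodes require >=1 clinically detected node")


@dataclass(frozen=True)
class MetastasisFindings:
    sites: frozenset[MetastaticSite] = frozenset({MetastaticSite.none})
    ldh: Ldh = Ldh.unknown
    unclear_radiology: bool = False

    def __post_init__(self) -> None:
        if MetastaticSite.none in self.sites and len(self.sites) > 1:
            raise ValueError("'none' is exclusive of other metastatic sites")


@dataclass(frozen=True)
class StageAssignment:
    t_category: TCategory
    n_category: NCategory
    m_category: MCategory
    stage_group: StageGroup
    ldh_suffix: Optional[int] = None  # 0/1 when LDH known and M != M0

    @property
    def m_label(self) -> str:
        if self.m_category is MCategory.M0 or self.ldh_suffix is None:
            return self.m_category.value
        return f"{self.m_category.value}({self.ldh_suffix})"


def classify_pt(tf: TumorFindings) -> Optional[TCategory]:
    """T category from Breslow thickness and ulceration.

    Returns ``None`` when the category cannot be resolved: unknown thickness,
    or unknown ulceration where the a/b suffix is ambiguous. The favorable
    suffix is never assumed silently. A thickness of 0.8-1.0 mm is T1b
    regardless of ulceration, so unknown ulceration is no obstacle there.
    """
    d = tf.breslow_mm
    if d is None:
        return None
    if d <= 1.0:
        if d < 0.8:
            if tf.ulceration is Ulceration.absent:
                return TCategory.T1a
            if tf.ulceration is Ulceration.present:
                return TCategory.T1b
            return None
        return TCategory.T1b
    if tf.ulceration is Ulceration.unknown:
        return None
    ulcerated = tf.ulceration is Ulceration.present
    if d <= 2.0:
        return TCategory.T2b if ulcerated else TCategory.T2a
    if d <= 4.0:
        return TCategory.T3b if ulcerated else TCategory.T3a
    return TCategory.T4b if ulcerated else TCategory.T4a


def classify_n(nf: NodalFindings) -> NCategory:
    """N category from node counts and in-transit/satellite status."""
    total = nf.occult_positive_nodes + nf.clinically_detected_nodes
    clinical = nf.clinically_detected_nodes > 0
    if nf.in_transit_or_satellite:
        if total >= 2 or nf.matted_nodes:
            return NCategory.N3c
        if total == 1:
            return NCategory.N2c
        return NCategory.N1c
    if total == 0:
        return NCategory.N0
    if total >= 4 or nf.matted_nodes:
        return NCategory.N3b if (clinical or nf.matted_nodes) else NCategory.N3a
    if total >= 2:
        return NCategory.N2b if clinical else NCategory.N2a
    return NCategory.N1b if clinical else NCategory.N1a


_M_PRECEDENCE = (
    (MetastaticSite.cns, MCategory.M1d),
    (MetastaticSite.other_visceral_non_cns, MCategory.M1c),
    (MetastaticSite.lung, MCategory.M1b),
    (MetastaticSite.skin_soft_tissue_distant_nodes, MCategory.M1a),
)


def classify_m(mf: MetastasisFindings) -> tuple[MCategory, Optional[int]]:
    """M category plus optional LDH suffix (0 normal / 1 elevated).

    The highest-ranking involved site determines the category; unknown LDH
    yields no suffix but never blocks classification.
    """
    sites = mf.sites - {MetastaticSite.none}
    if not sites:
        return MCategory.M0, None
    for site, cat in _M_PRECEDENCE:
        if site in sites:
            break
    else:  # pragma: no cover - precedence table spans the enum
        raise ValueError(f"unrecognised metastatic sites: {sites}")
    suffix = {Ldh.normal: 0, Ldh.elevated: 1}.get(mf.ldh)
    return cat, suffix


_STAGE_TABLE: Optional[dict[tuple[TCategory, NCategory, MCategory], StageGroup]] = None


def load_stage_table() -> dict[tuple[TCategory, NCategory, MCategory], StageGroup]:
    """Load and validate the shipped pathological stage-grouping table.

    Raises ``ValueError`` if any T x N x M cell is missing, duplicated or
    carries an unknown label — the table must be total over the 400-cell grid.
    """
    global _STAGE_TABLE
    if _STAGE_TABLE is not None:
        return _STAGE_TABLE
    table: dict[tuple[TCategory, NCategory, MCategory], StageGroup] = {}
    text = resources.files("melboard.data").joinpath("stage_groups.csv").read_text()
    for row in csv.DictReader(text.splitlines()):
        key = (TCategory(row["t"]), NCategory(row["n"]), MCategory(row["m"]))
        if key in table:
            raise ValueError(f"duplicate stage-table cell {key}")
        table[key] = StageGroup(row["stage_group"])
    expected = len(TCategory) * len(NCategory) * len(MCategory)
    if len(table) != expected:
        raise ValueError(
            f"stage table not total: {len(table)} cells, expected {expected}"
        )
    _STAGE_TABLE = table
    return table


def stage_group(t: TCategory, n: NCategory, m: MCategory) -> StageGroup:
    """Pathological stage group for a (T, N, M) triple via the shipped table."""
    return load_stage_table()[(TCategory(t), NCategory(n), MCategory(m))]


def tumor_findings(case: CaseRecord) -> TumorFindings:
    return TumorFindings(case.breslow_mm, case.ulceration)


def nodal_findings(case: CaseRecord) -> NodalFindings:
    return NodalFindings(
        case.occult_positive_nodes,
        case.clinically_detected_nodes,
        case.matted_nodes,
        case.in_transit_or_satellite,
    )


def metastasis_findings(case: CaseRecord) -> MetastasisFindings:
    return MetastasisFindings(case.metastatic_sites, case.ldh, case.unclear_radiology)


def assign_stage(case: CaseRecord) -> Optional[StageAssignment]:
    """Full TNM assignment for a case, or ``None`` if T is indeterminate.

    Unresolved radiologic findings do not enter the M classification: a
    suspicious-but-unresolved lesion is not a confirmed metastasis, so staging
    proceeds on the confirmed sites (the therapy layer separately converts the
    unresolved finding into a board referral).
    """
    t = classify_pt(tumor_findings(case))
    if t is None:
        return None
    n = classify_n(nodal_findings(case))
    m, suffix = classify_m(metastasis_findings(case))
    return StageAssignment(t, n, m, stage_group(t, n, m), suffix)
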