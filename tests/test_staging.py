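"""Staging engine: T/N/M classifiers and the pathological stage-group table.

The grouping table shipped with the package is checked cell-for-cell against
an independent oracle that re-encodes the stage-III subgrouping prose rules
here in the test, so a transcription error in either representation surfaces
as a cell mismatch.
"""

from __future__ import annotations

from itertools import chain, combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melboard.records import Ldh, MetastaticSite, Ulceration
from melboard.staging import (
    MCategory,
    MetastasisFindings,
    NCategory,
    NodalFindings,
    StageGroup,
    TCategory,
    TumorFindings,
    classify_m,
    classify_n,
    classify_pt,
    load_stage_table,
    stage_group,
)

# ----------------------------------------------------------------------
# T classification


@pytest.mark.parametrize(
    "breslow, ulceration, expected",
    [
        (0.5, Ulceration.absent, TCategory.T1a),
        (4.5, Ulceration.present, TCategory.T4b),
        (1.0, Ulceration.absent, TCategory.T1b),  # 0.8-1.0 band
        (0.79, Ulceration.absent, TCategory.T1a),
        (0.8, Ulceration.absent, TCategory.T1b),
        (0.5, Ulceration.present, TCategory.T1b),
        (1.01, Ulceration.absent, TCategory.T2a),  # strictly >1.0 leaves T1
        (2.0, Ulceration.present, TCategory.T2b),
        (2.01, Ulceration.absent, TCategory.T3a),
        (4.0, Ulceration.present, TCategory.T3b),
        (4.01, Ulceration.absent, TCategory.T4a),
        (0.9, Ulceration.unknown, TCategory.T1b),  # suffix independent of ulceration
    ],
)
def test_pt_banding(breslow, ulceration, expected):
    assert classify_pt(TumorFindings(breslow, ulceration)) is expected


@pytest.mark.parametrize(
    "breslow, ulceration",
    [
        (None, Ulceration.absent),  # thickness unknown
        (2.5, Ulceration.unknown),  # suffix ambiguous
        (0.5, Ulceration.unknown),  # T1a vs T1b undecidable
    ],
)
def test_pt_indeterminate_is_signalled_not_raised(breslow, ulceration):
    assert classify_pt(TumorFindings(breslow, ulceration)) is None


def test_negative_thickness_rejected():
    with pytest.raises(ValueError):
        TumorFindings(-1.0, Ulceration.absent)


@settings(max_examples=200, derandomize=True)
@given(
    d1=st.floats(0.05, 12.0, allow_nan=False),
    d2=st.floats(0.05, 12.0, allow_nan=False),
    ulcerated=st.booleans(),
)
def test_pt_monotone_in_thickness(d1, d2, ulcerated):
    """With ulceration fixed, thicker primaries never get a lower T category."""
    ulc = Ulceration.present if ulcerated else Ulceration.absent
    lo, hi = sorted((d1, d2))
    t_lo = classify_pt(TumorFindings(lo, ulc))
    t_hi = classify_pt(TumorFindings(hi, ulc))
    assert t_lo.order <= t_hi.order


@settings(max_examples=100, derandomize=True)
@given(d=st.floats(0.05, 12.0, allow_nan=False))
def test_ulceration_never_downgrades(d):
    t_abs = classify_pt(TumorFindings(d, Ulceration.absent))
    t_ulc = classify_pt(TumorFindings(d, Ulceration.present))
    assert t_ulc.order >= t_abs.order
    assert int(t_ulc.value[1]) == int(t_abs.value[1])  # numeric class unchanged


# ----------------------------------------------------------------------
# N classification


def _n_oracle(occult: int, clinical: int, matted: bool, transit: bool) -> NCategory:
    # independent re-encoding of the nodal table
    total = occult + clinical
    if transit:
        return (
            NCategory.N3c
            if (total >= 2 or matted)
            else (NCategory.N2c if total == 1 else NCategory.N1c)
        )
    if total == 0:
        return NCategory.N0
    if matted or total >= 4:
        return NCategory.N3b if (clinical or matted) else NCategory.N3a
    if total >= 2:
        return NCategory.N2b if clinical else NCategory.N2a
    return NCategory.N1b if clinical else NCategory.N1a


@pytest.mark.parametrize(
    "occult, clinical, matted, transit, expected",
    [
        (1, 0, False, False, NCategory.N1a),
        (0, 0, False, True, NCategory.N1c),
        (0, 0, False, False, NCategory.N0),
        (0, 1, False, True, NCategory.N2c),
        (1, 1, False, True, NCategory.N3c),
        (2, 0, False, False, NCategory.N2a),
        (1, 1, False, False, NCategory.N2b),
        (4, 0, False, False, NCategory.N3a),
        (0, 2, True, False, NCategory.N3b),
        (0, 1, False, False, NCategory.N1b),
    ],
)
def test_n_examples(occult, clinical, matted, transit, expected):
    nf = NodalFindings(occult, clinical, matted, transit)
    assert classify_n(nf) is expected


def test_n_exhaustive_against_oracle():
    for occult in range(0, 7):
        for clinical in range(0, 7):
            for matted in (False, True):
                if matted and clinical < 1:
                    continue
                for transit in (False, True):
                    nf = NodalFindings(occult, clinical, matted, transit)
                    assert classify_n(nf) is _n_oracle(occult, clinical, matted, transit)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        NodalFindings(occult_positive_nodes=-1)
    with pytest.raises(ValueError):
        NodalFindings(matted_nodes=True, clinically_detected_nodes=0)


# ----------------------------------------------------------------------
# M classification

_SITES = [
    MetastaticSite.skin_soft_tissue_distant_nodes,
    MetastaticSite.lung,
    MetastaticSite.other_visceral_non_cns,
    MetastaticSite.cns,
]
_RANK = {
    MetastaticSite.skin_soft_tissue_distant_nodes: MCategory.M1a,
    MetastaticSite.lung: MCategory.M1b,
    MetastaticSite.other_visceral_non_cns: MCategory.M1c,
    MetastaticSite.cns: MCategory.M1d,
}


def test_m_site_precedence_over_all_subsets():
    """The highest-ranking site determines M, for every subset of sites."""
    subsets = chain.from_iterable(combinations(_SITES, k) for k in range(1, 5))
    for subset in subsets:
        expected = max((_RANK[s] for s in subset), key=lambda m: list(MCategory).index(m))
        m, _ = classify_m(MetastasisFindings(frozenset(subset), Ldh.unknown))
        assert m is expected


@pytest.mark.parametrize(
    "sites, ldh, expected_m, expected_suffix",
    [
        (frozenset({MetastaticSite.none}), Ldh.normal, MCategory.M0, None),
        (frozenset({MetastaticSite.lung}), Ldh.unknown, MCategory.M1b, None),
        (
            frozenset({MetastaticSite.lung, MetastaticSite.cns}),
            Ldh.elevated,
            MCategory.M1d,
            1,
        ),
        (
            frozenset({MetastaticSite.skin_soft_tissue_distant_nodes}),
            Ldh.normal,
            MCategory.M1a,
            0,
        ),
    ],
)
def test_m_examples(sites, ldh, expected_m, expected_suffix):
    m, suffix = classify_m(MetastasisFindings(sites, ldh))
    assert m is expected_m
    assert suffix == expected_suffix


def test_none_site_exclusive():
    with pytest.raises(ValueError):
        MetastasisFindings(frozenset({MetastaticSite.none, MetastaticSite.lung}))


# ----------------------------------------------------------------------
# Stage grouping: totality and independent-oracle agreement

_LOW_T = {TCategory.T1a, TCategory.T1b, TCategory.T2a}
_MID_T = {TCategory.T2b, TCategory.T3a}
_HIGH_T = {TCategory.T3b, TCategory.T4a}
_N0_GROUPS = {
    TCategory.T1a: StageGroup.IA,
    TCategory.T1b: StageGroup.IB,
    TCategory.T2a: StageGroup.IB,
    TCategory.T2b: StageGroup.IIA,
    TCategory.T3a: StageGroup.IIA,
    TCategory.T3b: StageGroup.IIB,
    TCategory.T4a: StageGroup.IIB,
    TCategory.T4b: StageGroup.IIC,
}


def _group_oracle(t: TCategory, n: NCategory, m: MCategory) -> StageGroup:
    """Independent rule-based re-encoding of the pathological grouping."""
    if m is not MCategory.M0:
        return StageGroup.IV
    if n is NCategory.N0:
        return _N0_GROUPS[t]
    n3 = n in (NCategory.N3a, NCategory.N3b, NCategory.N3c)
    if t is TCategory.T4b:
        return StageGroup.IIID if n3 else StageGroup.IIIC
    if t in _HIGH_T:
        return StageGroup.IIIC
    if n is NCategory.N2c or n3:
        return StageGroup.IIIC
    if t in _MID_T:
        return StageGroup.IIIB
    if n in (NCategory.N1a, NCategory.N2a):
        return StageGroup.IIIA
    return StageGroup.IIIB


def test_stage_table_total_and_matches_oracle():
    table = load_stage_table()
    assert len(table) == len(TCategory) * len(NCategory) * len(MCategory)
    for t in TCategory:
        for n in NCategory:
            for m in MCategory:
                assert stage_group(t, n, m) is _group_oracle(t, n, m), (t, n, m)


@pytest.mark.parametrize(
    "t, n, m, expected",
    [
        (TCategory.T4b, NCategory.N0, MCategory.M0, StageGroup.IIC),
        (TCategory.T2a, NCategory.N1a, MCategory.M0, StageGroup.IIIA),
        (TCategory.T4b, NCategory.N3c, MCategory.M0, StageGroup.IIID),
        (TCategory.T1a, NCategory.N1c, MCategory.M0, StageGroup.IIIB),
    ],
)
def test_stage_group_examples(t, n, m, expected):
    assert stage_group(t, n, m) is expected


def test_distant_metastasis_forces_stage_iv():
    for t in TCategory:
        for n in NCategory:
            for m in (MCategory.M1a, MCategory.M1b, MCategory.M1c, MCategory.M1d):
                assert stage_group(t, n, m) is StageGroup.IV


def test_nodal_progression_never_downstages():
    """With T and M0 fixed, nodal burden never lowers the stage group.

    Monotonicity holds along each suffix series (N1a<N2a<N3a, N1b<N2b<N3b,
    N1c<N2c<N3c) and any nodal disease outranks N0; across suffix series the
    table is genuinely non-monotone (e.g. in-transit disease without nodes,
    N1c, can outrank two occult nodes, N2a), so the series-wise statement is
    the strongest true ordering."""
    for t in TCategory:
        n0 = stage_group(t, NCategory.N0, MCategory.M0)
        for series in ("a", "b", "c"):
            groups = [
                stage_group(t, NCategory(f"N{k}{series}"), MCategory.M0)
                for k in (1, 2, 3)
            ]
            assert all(g.order > n0.order for g in groups)
            assert groups[0].order <= groups[1].order <= groups[2].order
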