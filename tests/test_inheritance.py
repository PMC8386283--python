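"""Transmission classification (exhaustive truth tables) and gene-level
monogenic-candidate enumeration."""

from __future__ import annotations

import itertools

import pytest

from trioburden.filters import filter_candidates
from trioburden.inheritance import (
    InheritanceCall as IC,
    Mode,
    annotate_transmission,
    classify_transmission,
    find_compound_het,
    monogenic_candidates,
)
from trioburden.types import Genotype as G

from conftest import make_record

X_NONPAR = 99_000_000  # outside both GRCh37 pseudoautosomal intervals
_DOSAGE = {0: G.HOM_REF, 1: G.HET, 2: G.HOM_ALT}


def autosomal_truth(child: int, mother: int, father: int) -> IC:
    """Hand-built expectation for each of the 27 autosomal dosage triples.

    Written as an explicit decision list, independently of the
    implementation's boolean algebra.
    """
    if child == 0:
        return IC.UNRESOLVED  # non-carrier: outside the classifier's domain
    if child == 1:
        if mother == 0 and father == 0:
            return IC.DE_NOVO
        if mother == 2 and father == 2:
            return IC.INCONSISTENT  # both parents can only donate alt
        # origin is certain when only one parent can have donated the alt
        # allele while the other donated the ref allele
        maternal_ok = mother >= 1 and father <= 1
        paternal_ok = father >= 1 and mother <= 1
        if maternal_ok and paternal_ok:
            return IC.UNRESOLVED  # both parents het: phase-ambiguous
        return IC.MATERNAL if maternal_ok else IC.PATERNAL
    # child == 2: one alt allele needed from each parent
    if mother >= 1 and father >= 1:
        return IC.BIPARENTAL_HOMOZYGOUS
    return IC.INCONSISTENT


@pytest.mark.parametrize(
    "child,mother,father", list(itertools.product(range(3), repeat=3))
)
def test_autosomal_27_case_truth_table(child, mother, father, female_trio):
    rec = make_record(
        "7", 5000, _DOSAGE[child], _DOSAGE[mother], _DOSAGE[father]
    )
    assert classify_transmission(rec, female_trio) is autosomal_truth(
        child, mother, father
    )


MALE_X_TABLE = [
    # (child, mother, father) -> expected
    (G.HEMI_ALT, G.HET, G.HEMI_REF, IC.HEMIZYGOUS_MATERNAL),
    (G.HEMI_ALT, G.HET, G.HEMI_ALT, IC.MATERNAL),  # carrier father muddies XLR
    (G.HEMI_ALT, G.HOM_ALT, G.HEMI_REF, IC.MATERNAL),
    (G.HEMI_ALT, G.HOM_ALT, G.HEMI_ALT, IC.MATERNAL),
    (G.HEMI_ALT, G.HOM_REF, G.HEMI_REF, IC.DE_NOVO),
    (G.HEMI_ALT, G.HOM_REF, G.HEMI_ALT, IC.DE_NOVO),  # father's X not transmitted
    (G.HEMI_REF, G.HET, G.HEMI_REF, IC.UNRESOLVED),  # non-carrier proband
]


@pytest.mark.parametrize("child,mother,father,expected", MALE_X_TABLE)
def test_male_x_truth_table(child, mother, father, expected, male_trio):
    rec = make_record("X", X_NONPAR, child, mother, father)
    assert classify_transmission(rec, male_trio) is expected


FEMALE_X_TABLE = [
    (G.HET, G.HOM_REF, G.HEMI_ALT, IC.PATERNAL),
    (G.HET, G.HET, G.HEMI_REF, IC.MATERNAL),
    # hemizygous-alt father must donate the alt, so origin is certain
    (G.HET, G.HET, G.HEMI_ALT, IC.PATERNAL),
    (G.HET, G.HOM_ALT, G.HEMI_ALT, IC.INCONSISTENT),
    (G.HET, G.HOM_REF, G.HEMI_REF, IC.DE_NOVO),
    (G.HOM_ALT, G.HET, G.HEMI_ALT, IC.BIPARENTAL_HOMOZYGOUS),
    (G.HOM_ALT, G.HET, G.HEMI_REF, IC.INCONSISTENT),
]


@pytest.mark.parametrize("child,mother,father,expected", FEMALE_X_TABLE)
def test_female_x_truth_table(child, mother, father, expected, female_trio):
    rec = make_record("X", X_NONPAR, child, mother, father)
    assert classify_transmission(rec, female_trio) is expected


def test_par_region_on_x_is_treated_as_autosomal(male_trio):
    rec = make_record("X", 61_000, G.HET, G.HOM_REF, G.HOM_REF)  # inside PAR1
    assert classify_transmission(rec, male_trio) is IC.DE_NOVO


def test_parental_quality_failure_yields_unresolved_not_de_novo(male_trio):
    rec = make_record("1", 100, G.HET, G.HOM_REF, G.HOM_REF, father_depth=5)
    assert classify_transmission(rec, male_trio) is IC.UNRESOLVED
    rec2 = make_record("1", 100, G.HET, G.HOM_REF, G.MISSING)
    assert classify_transmission(rec2, male_trio) is IC.UNRESOLVED


def test_de_novo_calls_never_have_carrier_parents(female_trio):
    """Partition sanity over all autosomal triples: no de novo with a carrier
    parent, no maternal call with a non-carrier mother."""
    for child, mother, father in itertools.product(range(3), repeat=3):
        rec = make_record("3", 42, _DOSAGE[child], _DOSAGE[mother], _DOSAGE[father])
        call = classify_transmission(rec, female_trio)
        if call is IC.DE_NOVO:
            assert mother == 0 and father == 0
        if call is IC.MATERNAL:
            assert mother >= 1


# ---------------------------------------------------------------------------
# Compound het and gene-level enumeration


def _annotated(records, trio):
    cands = filter_candidates(records)
    assert len(cands) == len(records), "test records must all pass the filter"
    return annotate_transmission(cands, trio)


def test_compound_het_requires_opposite_origins(female_trio):
    trans = [
        make_record("1", 1, G.HET, G.HET, G.HOM_REF, gene="GG"),  # maternal
        make_record("1", 2, G.HET, G.HOM_REF, G.HET, gene="GG"),  # paternal
    ]
    (mc,) = find_compound_het(_annotated(trans, female_trio), female_trio)
    assert mc.mode is Mode.AR_COMPOUND_HET and mc.gene == "GG"
    assert len(mc.variants) == 2

    cis = [
        make_record("1", 1, G.HET, G.HET, G.HOM_REF, gene="GG"),
        make_record("1", 2, G.HET, G.HET, G.HOM_REF, gene="GG"),
    ]
    assert find_compound_het(_annotated(cis, female_trio), female_trio) == []


def test_compound_het_emits_one_candidate_per_gene(female_trio):
    records = [
        make_record("1", 1, G.HET, G.HET, G.HOM_REF, gene="GG"),
        make_record("1", 2, G.HET, G.HOM_REF, G.HET, gene="GG"),
        make_record("1", 3, G.HET, G.HOM_REF, G.HET, gene="GG"),
    ]
    (mc,) = find_compound_het(_annotated(records, female_trio), female_trio)
    assert len(mc.variants) == 3


def test_phase_ambiguous_hets_do_not_support_compound_het(female_trio):
    records = [
        make_record("1", 1, G.HET, G.HET, G.HOM_REF, gene="GG"),
        make_record("1", 2, G.HET, G.HET, G.HET, gene="GG"),  # both parents het
    ]
    assert find_compound_het(_annotated(records, female_trio), female_trio) == []


def test_monogenic_union_of_modes(female_trio):
    """A de novo in one gene plus a biparental compound het in another gives
    exactly two gene-level candidates (the pattern of the first case trio)."""
    records = [
        make_record("2", 1, G.HET, G.HOM_REF, G.HOM_REF, gene="TTLL4"),
        make_record("6", 2, G.HET, G.HET, G.HOM_REF, gene="TNXB"),
        make_record("6", 3, G.HET, G.HOM_REF, G.HET, gene="TNXB"),
    ]
    mcs = monogenic_candidates(_annotated(records, female_trio), female_trio)
    assert [(m.gene, m.mode) for m in mcs] == [
        ("TNXB", Mode.AR_COMPOUND_HET),
        ("TTLL4", Mode.DE_NOVO),
    ]


def test_monogenic_empty_input(female_trio):
    assert monogenic_candidates([], female_trio) == []


def test_xlr_counted_only_for_male_probands(male_trio, female_trio):
    rec_m = make_record("X", X_NONPAR, G.HEMI_ALT, G.HET, G.HEMI_REF, gene="GPC3")
    mcs = monogenic_candidates(_annotated([rec_m], male_trio), male_trio)
    assert [(m.gene, m.mode) for m in mcs] == [("GPC3", Mode.XLR)]

    # female homozygous X variant counts as AR-homozygous, never XLR
    rec_f = make_record("X", X_NONPAR, G.HOM_ALT, G.HET, G.HEMI_ALT, gene="GPC3")
    mcs_f = monogenic_candidates(_annotated([rec_f], female_trio), female_trio)
    assert [(m.gene, m.mode) for m in mcs_f] == [("GPC3", Mode.AR_HOMOZYGOUS)]


def test_male_x_de_novo_is_de_novo_not_xlr(male_trio):
    rec = make_record("X", X_NONPAR, G.HEMI_ALT, G.HOM_REF, G.HEMI_REF, gene="XG")
    mcs = monogenic_candidates(_annotated([rec], male_trio), male_trio)
    assert [(m.gene, m.mode) for m in mcs] == [("XG", Mode.DE_NOVO)]


def test_ar_homozygous_singleton(female_trio):
    rec = make_record("4", 9, G.HOM_ALT, G.HET, G.HET, gene="MET")
    mcs = monogenic_candidates(_annotated([rec], female_trio), female_trio)
    assert [(m.gene, m.mode) for m in mcs] == [("MET", Mode.AR_HOMOZYGOUS)]


def test_gene_mode_deduplication(female_trio):
    records = [
        make_record("4", 9, G.HOM_ALT, G.HET, G.HET, gene="MET"),
        make_record("4", 20, G.HOM_ALT, G.HET, G.HET, gene="MET"),
    ]
    mcs = monogenic_candidates(_annotated(records, female_trio), female_trio)
    assert len(mcs) == 1 and len(mcs[0].variants) == 2
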