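"""Pedigree parsing, VCF reading/writing, multiallelic splitting, Mendelian QC."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from trioburden.simulate import SimConfig, TrioEventRates, simulate_cohort
from trioburden.trio_io import (
    MalformedGenotypeError,
    RawVariant,
    mendelian_consistent,
    mendelian_error_rate,
    read_pedigree,
    read_trio_vcf,
    split_multiallelic,
    write_trio_vcf,
)
from trioburden.types import Genotype, PedigreeTrio, Sex, VariantAnnotation

from conftest import make_record


# ---------------------------------------------------------------------------
# Pedigree


def write_ped(tmp_path, text):
    p = tmp_path / "fam.ped"
    p.write_text(text)
    return p


def test_read_pedigree_maps_fields(tmp_path):
    ped = write_ped(
        tmp_path,
        "F1 D1 0 0 1 1\n"
        "F1 M1 0 0 2 1\n"
        "F1 P1 D1 M1 1 2\n",
    )
    trios = read_pedigree(ped)
    assert len(trios) == 1
    t = trios[0]
    assert (t.proband_id, t.mother_id, t.father_id) == ("P1", "M1", "D1")
    assert t.proband_sex is Sex.MALE and t.affected


def test_read_pedigree_skips_incomplete_trio(tmp_path, caplog):
    ped = write_ped(
        tmp_path,
        "F1 M1 0 0 2 1\n"
        "F1 P1 0 M1 1 2\n",  # father unknown
    )
    with caplog.at_level("WARNING"):
        trios = read_pedigree(ped)
    assert trios == []
    assert any("skipped" in r.message for r in caplog.records)


def test_read_pedigree_rejects_unknown_proband_sex(tmp_path):
    ped = write_ped(
        tmp_path,
        "F1 D1 0 0 1 1\nF1 M1 0 0 2 1\nF1 P1 D1 M1 0 2\n",
    )
    with pytest.raises(ValueError, match="sex"):
        read_pedigree(ped)


def test_read_pedigree_rejects_duplicate_ids(tmp_path):
    ped = write_ped(
        tmp_path,
        "F1 D1 0 0 1 1\nF1 M1 0 0 2 1\nF1 P1 D1 M1 1 2\nF2 P1 D1 M1 1 2\n",
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_pedigree(ped)


# ---------------------------------------------------------------------------
# Multiallelic splitting


def raw(pairs, alts=("A", "G")):
    return RawVariant(
        chrom="1",
        pos=100,
        ref="C",
        alts=list(alts),
        allele_pairs=pairs,
        depths=[30, 30, 30],
        quality_scores=[24.0, 24.0, 24.0],
        annotations=[VariantAnnotation(gene=f"G{k}") for k in range(len(alts))],
    )


def test_split_recodes_het_for_each_alt():
    # GT=1/2: carries one copy of each alt
    r = raw([(1, 2), (0, 0), (0, 0)])
    parts = split_multiallelic(r)
    assert [p.alts for p in parts] == [["A"], ["G"]]
    assert parts[0].allele_pairs[0] == (1, 0)
    assert parts[1].allele_pairs[0] == (0, 1)


def test_split_collapses_other_alts_to_reference():
    # GT=2/2: non-carrier for alt A, homozygous for alt G
    r = raw([(2, 2), (0, 0), (0, 0)])
    parts = split_multiallelic(r)
    assert parts[0].allele_pairs[0] == (0, 0)
    assert parts[1].allele_pairs[0] == (1, 1)


def test_split_single_alt_is_identity():
    r = raw([(0, 1), (0, 0), (0, 0)], alts=("A",))
    assert split_multiallelic(r) == [r]


def test_split_rejects_out_of_range_allele():
    with pytest.raises(MalformedGenotypeError):
        split_multiallelic(raw([(0, 3), (0, 0), (0, 0)]))


@settings(derandomize=True, deadline=None, max_examples=100)
@given(
    pairs=st.lists(
        st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=3, max_size=3
    )
)
def test_split_conserves_alt_carriers(pairs):
    """Total carrier count over split records equals the raw row's."""
    r = raw(pairs, alts=("A", "G", "T"))
    parts = split_multiallelic(r)
    raw_carriers = sum(any(a > 0 for a in p) for p in pairs)
    split_carriers = sum(
        any(a == 1 for a in p) for part in parts for p in part.allele_pairs
    )
    # a sample carrying two different alts is counted once in raw but appears
    # as a carrier in two split records; compare per-allele dosage instead
    raw_dosage = sum(sum(1 for a in p if a > 0) for p in pairs)
    split_dosage = sum(
        sum(a for a in p if a) for part in parts for p in part.allele_pairs
    )
    assert split_dosage == raw_dosage
    assert split_carriers >= raw_carriers


# ---------------------------------------------------------------------------
# VCF reading and round-trip


VCF_TEXT = """##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=X>
##INFO=<ID=GENE,Number=A,Type=String,Description="g">
##INFO=<ID=CSQ_CLASS,Number=A,Type=String,Description="c">
##INFO=<ID=GNOMAD_AF,Number=A,Type=Float,Description="af">
##INFO=<ID=SIFT,Number=A,Type=String,Description="s">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
##FORMAT=<ID=MPG,Number=1,Type=Float,Description="mpg">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tM1\tD1
1\t1000\t.\tA\tG\t.\tPASS\tGENE=AAA;CSQ_CLASS=missense;GNOMAD_AF=0.001;SIFT=damaging\tGT:DP:MPG\t0/1:25:20\t0/0:30:25\t0/0:28:22
1\t2000\t.\tC\tA,T\t.\tPASS\tGENE=BBB,CCC;CSQ_CLASS=missense,synonymous;GNOMAD_AF=0.1,0.002\tGT:DP:MPG\t1/2:40:30\t0/1:35:30\t0/2:33:28
1\t3000\t.\tG\tC\t.\tPASS\tGENE=DDD;CSQ_CLASS=nonsense\tGT:DP:MPG\t0/1:20:15\t./.:0:0\t0/0:21:18
X\t99999000\t.\tT\tC\t.\tPASS\tGENE=XG1;CSQ_CLASS=missense\tGT:DP:MPG\t1/1:22:18\t0/1:30:25\t0/0:29:24
X\t99999500\t.\tT\tG\t.\tPASS\tGENE=XG2;CSQ_CLASS=missense\tGT:DP:MPG\t1:22:18\t0/1:30:25\t0:29:24
X\t61000\t.\tA\tC\t.\tPASS\tGENE=PAR1G;CSQ_CLASS=missense\tGT:DP:MPG\t0/1:22:18\t0/1:30:25\t0/0:29:24
"""


@pytest.fixture
def vcf_path(tmp_path):
    p = tmp_path / "trio.vcf"
    p.write_text(VCF_TEXT)
    return p


def test_read_trio_vcf_field_mapping(vcf_path, male_trio):
    records = list(read_trio_vcf(vcf_path, male_trio))
    first = records[0]
    assert first.proband.genotype is Genotype.HET
    assert first.proband.depth == 25
    assert first.proband.quality_score == 20
    assert first.proband.quality_ratio == pytest.approx(0.8)
    assert first.annotation.gene == "AAA"
    assert first.annotation.population_af == pytest.approx(0.001)
    # no AF key on row 3: treated as not-found (None)
    third = [r for r in records if r.pos == 3000][0]
    assert third.annotation.population_af is None
    assert third.mother.genotype is Genotype.MISSING


def test_read_trio_vcf_expands_multiallelics(vcf_path, male_trio):
    records = [r for r in read_trio_vcf(vcf_path, male_trio) if r.pos == 2000]
    assert len(records) == 2
    by_alt = {r.alt: r for r in records}
    # proband GT=1/2 is het for each alt; father 0/2 carries only alt T
    assert by_alt["A"].proband.genotype is Genotype.HET
    assert by_alt["T"].proband.genotype is Genotype.HET
    assert by_alt["A"].father.genotype is Genotype.HOM_REF
    assert by_alt["T"].father.genotype is Genotype.HET
    assert by_alt["A"].annotation.gene == "BBB"
    assert by_alt["T"].annotation.gene == "CCC"
    assert by_alt["T"].annotation.population_af == pytest.approx(0.002)


def test_male_x_genotypes_become_hemizygous(vcf_path, male_trio):
    records = {r.pos: r for r in read_trio_vcf(vcf_path, male_trio)}
    # diploid-coded 1/1 and haploid-coded 1 both map to hemi_alt outside PAR
    assert records[99999000].proband.genotype is Genotype.HEMI_ALT
    assert records[99999500].proband.genotype is Genotype.HEMI_ALT
    assert records[99999500].father.genotype is Genotype.HEMI_REF
    # PAR position stays diploid
    assert records[61000].proband.genotype is Genotype.HET


def test_female_x_genotypes_stay_diploid(vcf_path, female_trio, tmp_path):
    # same VCF but sample names adjusted for the female trio
    text = VCF_TEXT.replace("P1\tM1\tD1", "P2\tM2\tD2")
    p = tmp_path / "trio2.vcf"
    p.write_text(text)
    records = {r.pos: r for r in read_trio_vcf(p, female_trio)}
    assert records[99999000].proband.genotype is Genotype.HOM_ALT
    assert records[99999000].father.genotype is Genotype.HEMI_REF


def test_unknown_sample_is_hard_error(vcf_path):
    stranger = PedigreeTrio(
        family_id="F9", proband_id="NOPE", proband_sex=Sex.MALE,
        mother_id="M1", father_id="D1",
    )
    with pytest.raises(KeyError, match="NOPE"):
        list(read_trio_vcf(vcf_path, stranger))


def test_round_trip_preserves_all_fields(tmp_path, male_trio):
    records = [
        make_record("1", 500, Genotype.HET, af=0.004, nhomalt=1, votes=2),
        make_record("2", 700, Genotype.HOM_ALT, Genotype.HET, Genotype.HET,
                    gene="ZZZ", af=None),
        make_record("X", 99_000_000, Genotype.HEMI_ALT, Genotype.HET,
                    Genotype.HEMI_REF, gene="XG"),
    ]
    path = tmp_path / "rt.vcf"
    write_trio_vcf(path, male_trio, records)
    back = list(read_trio_vcf(path, male_trio))
    assert len(back) == len(records)
    for a, b in zip(records, back):
        assert (a.chrom, a.pos, a.ref, a.alt) == (b.chrom, b.pos, b.ref, b.alt)
        for side in ("proband", "mother", "father"):
            ca, cb = getattr(a, side), getattr(b, side)
            assert ca.genotype is cb.genotype
            assert ca.depth == cb.depth
            assert ca.quality_score == pytest.approx(cb.quality_score)
        assert a.annotation == b.annotation


# ---------------------------------------------------------------------------
# Mendelian QC


def test_all_het_triples_are_consistent(male_trio):
    records = [make_record(pos=i, child=Genotype.HET, mother=Genotype.HET,
                           father=Genotype.HET) for i in range(1, 50)]
    assert mendelian_error_rate(records, male_trio) == 0.0


def test_impossible_triple_is_an_error(male_trio):
    rec = make_record(child=Genotype.HOM_ALT, mother=Genotype.HOM_REF,
                      father=Genotype.HOM_REF)
    assert mendelian_error_rate([rec], male_trio) == 1.0
    assert not mendelian_consistent(rec, male_trio)


def test_de_novo_het_is_a_mendelian_error_for_qc(male_trio):
    rec = make_record(child=Genotype.HET, mother=Genotype.HOM_REF,
                      father=Genotype.HOM_REF)
    assert not mendelian_consistent(rec, male_trio)


def test_male_x_consistency_uses_mother_only(male_trio):
    rec = make_record("X", 99_000_000, Genotype.HEMI_ALT, Genotype.HET,
                      Genotype.HEMI_REF)
    assert mendelian_consistent(rec, male_trio)
    rec2 = make_record("X", 99_000_000, Genotype.HEMI_ALT, Genotype.HOM_REF,
                       Genotype.HEMI_ALT)
    assert not mendelian_consistent(rec2, male_trio)


def test_error_rate_requires_usable_records(male_trio):
    rec = make_record(mother=Genotype.MISSING)
    with pytest.raises(ValueError):
        mendelian_error_rate([rec], male_trio)


def test_clean_synthetic_cohort_has_zero_error_rate():
    """With no planted events and no genotype errors, background transmission
    is exactly Mendelian in every trio."""
    cfg = SimConfig(
        n_case_trios=3, n_control_trios=3, n_male_case=2, n_male_control=1,
        n_background_sites=300, seed=11,
    )
    cohort = simulate_cohort(cfg)
    for trio in cohort.trios:
        rate = mendelian_error_rate(cohort.records[trio.proband_id], trio)
        assert rate == 0.0


def test_genotype_errors_raise_the_error_rate():
    cfg = SimConfig(
        n_case_trios=2, n_control_trios=2, n_background_sites=400,
        genotype_error_rate=0.02, seed=11,
    )
    cohort = simulate_cohort(cfg)
    rates = [
        mendelian_error_rate(cohort.records[t.proband_id], t) for t in cohort.trios
    ]
    assert all(r > 0 for r in rates)
    assert all(r < 0.1 for r in rates)
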