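"""Shared builders for trio-record tests.

All fixture data is constructed programmatically; no binary files.
"""

from __future__ import annotations

import pytest

from trioburden.types import (
    Consequence,
    Genotype,
    PedigreeTrio,
    PredictorCall,
    SampleCall,
    Sex,
    TrioVariantRecord,
    VariantAnnotation,
)


def make_call(genotype: Genotype, depth: int = 30, ratio: float = 0.8) -> SampleCall:
    return SampleCall(genotype=genotype, depth=depth, quality_score=ratio * depth)


def make_annotation(
    gene: str = "GENE1",
    consequence: Consequence = Consequence.MISSENSE,
    af=None,
    nhomalt=None,
    votes: int = 3,
) -> VariantAnnotation:
    calls = [PredictorCall.DAMAGING] * votes + [PredictorCall.BENIGN] * (3 - votes)
    return VariantAnnotation(
        gene=gene,
        consequence=consequence,
        population_af=af,
        population_nhomalt=nhomalt,
        sift=calls[0],
        polyphen=calls[1],
        mutation_taster=calls[2],
    )


def make_record(
    chrom: str = "1",
    pos: int = 1000,
    child: Genotype = Genotype.HET,
    mother: Genotype = Genotype.HOM_REF,
    father: Genotype = Genotype.HOM_REF,
    *,
    gene: str = "GENE1",
    consequence: Consequence = Consequence.MISSENSE,
    af=None,
    nhomalt=None,
    votes: int = 3,
    depth: int = 30,
    ratio: float = 0.8,
    mother_depth: int | None = None,
    father_depth: int | None = None,
) -> TrioVariantRecord:
    return TrioVariantRecord(
        chrom=chrom,
        pos=pos,
        ref="A",
        alt="G",
        annotation=make_annotation(gene, consequence, af, nhomalt, votes),
        proband=make_call(child, depth, ratio),
        mother=make_call(mother, mother_depth if mother_depth is not None else depth, ratio),
        father=make_call(father, father_depth if father_depth is not None else depth, ratio),
    )


@pytest.fixture
def male_trio() -> PedigreeTrio:
    return PedigreeTrio(
        family_id="F1",
        proband_id="P1",
        proband_sex=Sex.MALE,
        mother_id="M1",
        father_id="D1",
    )


@pytest.fixture
def female_trio() -> PedigreeTrio:
    return PedigreeTrio(
        family_id="F2",
        proband_id="P2",
        proband_sex=Sex.FEMALE,
        mother_id="M2",
        father_id="D2",
    )
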