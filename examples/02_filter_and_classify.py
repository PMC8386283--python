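"""Filter candidate variants and classify their transmission in one trio.

Constructs a handful of records for a male proband and shows which survive
the five-criterion filter and how each is inherited.
"""

from trioburden import (
    Consequence,
    Genotype,
    PedigreeTrio,
    PredictorCall,
    SampleCall,
    Sex,
    TrioVariantRecord,
    VariantAnnotation,
    annotate_transmission,
    filter_candidates,
    monogenic_candidates,
)

trio = PedigreeTrio("FAM1", "CHILD", Sex.MALE, "MOTHER", "FATHER")


def call(gt, depth=35, ratio=0.8):
    return SampleCall(gt, depth, ratio * depth)


def record(chrom, pos, child, mother, father, gene, csq, af, votes=3):
    preds = [PredictorCall.DAMAGING] * votes + [PredictorCall.BENIGN] * (3 - votes)
    ann = VariantAnnotation(
        gene=gene, consequence=csq, population_af=af,
        sift=preds[0], polyphen=preds[1], mutation_taster=preds[2],
    )
    return TrioVariantRecord(
        chrom, pos, "A", "G", ann,
        proband=call(child), mother=call(mother), father=call(father),
    )


records = [
    # de novo missense, 3/3 damaging, absent from the population database
    record("2", 1000, Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF,
           "TTLL4", Consequence.MISSENSE, None),
    # compound het in one gene: one allele from each parent
    record("6", 2000, Genotype.HET, Genotype.HET, Genotype.HOM_REF,
           "TNXB", Consequence.MISSENSE, 0.002),
    record("6", 3000, Genotype.HET, Genotype.HOM_REF, Genotype.HET,
           "TNXB", Consequence.FRAMESHIFT, None),
    # too common: 2% allele frequency fails the < 1% rarity criterion
    record("1", 4000, Genotype.HET, Genotype.HET, Genotype.HOM_REF,
           "COMMON1", Consequence.MISSENSE, 0.02),
    # only 1 of 3 predictors damaging: fails the 2-of-3 consensus
    record("3", 5000, Genotype.HET, Genotype.HOM_REF, Genotype.HET,
           "WEAK1", Consequence.MISSENSE, 0.001, votes=1),
]

candidates = filter_candidates(records)
annotate_transmission(candidates, trio)
print(f"{len(candidates)} of {len(records)} records pass the candidate filter:")
for c in candidates:
    print(f"  {c.record.key:<16} {c.gene:<6} {c.record.annotation.consequence.value:<11}"
          f" transmission={c.transmission.value}")

print("\ngene-level monogenic candidates (fully penetrant models):")
for mc in monogenic_candidates(candidates, trio):
    print(f"  {mc.gene:<6} {mc.mode.value} ({len(mc.variants)} variant(s))")
# Expect: TTLL4 de novo and TNXB compound het - the two rejected records
# fail rarity and predictor consensus respectively.
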