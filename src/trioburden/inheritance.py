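"""Trio transmission classification and monogenic-candidate enumeration.

Each candidate variant carried by the proband is assigned one transmission
category; gene-level *monogenic candidates* are then enumerated under the
three fully penetrant models that can explain an affected child of two
unaffected parents:

* autosomal recessive — homozygous (one allele from each carrier parent) or
  compound heterozygous (two variants in one gene, one inherited from each
  parent);
* X-linked recessive — hemizygous variant in a male proband inherited from a
  heterozygous-carrier mother;
* de novo — heterozygous (or male-X hemizygous) in the proband, absent from
  both parents.

Parental calls must pass the quality thresholds before any definitive
category is assigned; otherwise the variant is ``UNRESOLVED`` (never a false
de novo).  Phasing is by parental transmission only: a variant heterozygous
in the child and in both parents has uncertain origin and is excluded from
compound-het support.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

from .filters import CandidateVariant, FilterThresholds, DEFAULT_THRESHOLDS, passes_quality
from .trio_io import PAR_GRCH37, in_par
from .types import Genotype, PedigreeTrio, Sex, TrioVariantRecord


class InheritanceCall(enum.Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BIPARENTAL_HOMOZYGOUS = "biparental_homozygous"
    HEMIZYGOUS_MATERNAL = "hemizygous_maternal"
    INCONSISTENT = "inconsistent"
    UNRESOLVED = "unresolved"


class Mode(enum.Enum):
    """Monogenic model supported by a gene-level candidate."""

    AR_HOMOZYGOUS = "AR_homozygous"
    AR_COMPOUND_HET = "AR_compound_het"
    XLR = "XLR"
    DE_NOVO = "de_novo"


@dataclass
class MonogenicCandidate:
    """One gene-level candidate per (gene, mode, trio) — the unit counted in
    the genome-wide monogenic burden analysis."""

    gene: str
    mode: Mode
    variants: List[CandidateVariant]
    trio_id: str

    def __post_init__(self) -> None:
        if self.mode is Mode.AR_COMPOUND_HET and len(self.variants) < 2:
            raise ValueError("compound het requires >= 2 supporting variants")


def classify_transmission(
    record: TrioVariantRecord,
    trio: PedigreeTrio,
    t: FilterThresholds = DEFAULT_THRESHOLDS,
    par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37,
) -> InheritanceCall:
    """Assign the transmission category of one carried variant.

    Order of evaluation: missing/low-quality parental calls short-circuit to
    UNRESOLVED; then the genotype triple is matched against the transmission
    patterns; triples impossible under Mendelian transmission (other than
    the explicit de novo pattern) are INCONSISTENT.
    """
    child = record.proband.genotype
    mother = record.mother.genotype
    father = record.father.genotype
    if not child.carries_alt:
        return InheritanceCall.UNRESOLVED
    if mother.is_missing or father.is_missing:
        return InheritanceCall.UNRESOLVED
    if not (passes_quality(record.mother, t) and passes_quality(record.father, t)):
        return InheritanceCall.UNRESOLVED

    on_x_nonpar = record.is_x and not in_par(record.pos, par_intervals)

    if on_x_nonpar and trio.proband_sex is Sex.MALE:
        # son's single X allele comes from the mother; father contributes Y
        if child is not Genotype.HEMI_ALT:
            return InheritanceCall.UNRESOLVED  # het male X call: unusable
        if mother is Genotype.HET:
            if not father.carries_alt:
                return InheritanceCall.HEMIZYGOUS_MATERNAL
            return InheritanceCall.MATERNAL  # carrier father muddies XLR reading
        if mother in (Genotype.HOM_ALT,):
            return InheritanceCall.MATERNAL
        return InheritanceCall.DE_NOVO  # mother confidently non-carrier

    # diploid child (autosome, PAR, or female X; father may be hemizygous on X)
    m_can_alt, m_can_ref = mother.has_alt_allele, mother.has_ref_allele
    f_can_alt, f_can_ref = father.has_alt_allele, father.has_ref_allele

    if child is Genotype.HET:
        maternal_possible = m_can_alt and f_can_ref
        paternal_possible = f_can_alt and m_can_ref
        if maternal_possible and paternal_possible:
            return InheritanceCall.UNRESOLVED  # phase-ambiguous
        if maternal_possible:
            return InheritanceCall.MATERNAL
        if paternal_possible:
            return InheritanceCall.PATERNAL
        if not m_can_alt and not f_can_alt:
            return InheritanceCall.DE_NOVO
        return InheritanceCall.INCONSISTENT  # e.g. both parents hom_alt

    if child in (Genotype.HOM_ALT, Genotype.HEMI_ALT):
        # HEMI_ALT here can only be a residual odd call; treat as hom-like
        if m_can_alt and f_can_alt:
            return InheritanceCall.BIPARENTAL_HOMOZYGOUS
        return InheritanceCall.INCONSISTENT

    return InheritanceCall.UNRESOLVED


def annotate_transmission(
    candidates: Iterable[CandidateVariant],
    trio: PedigreeTrio,
    t: FilterThresholds = DEFAULT_THRESHOLDS,
    par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37,
) -> List[CandidateVariant]:
    """Fill the ``transmission`` field of each candidate in place."""
    out = []
    for cand in candidates:
        cand.transmission = classify_transmission(cand.record, trio, t, par_intervals)
        out.append(cand)
    return out


def find_compound_het(
    candidates: Sequence[CandidateVariant], trio: PedigreeTrio
) -> List[MonogenicCandidate]:
    """Genes with at least one maternal and one paternal heterozygous candidate.

    Emits exactly one gene-level candidate listing *all* maternal/paternal
    het variants in that gene; genes whose candidates all come from one
    parent (cis configuration) emit nothing.  Only autosomal/diploid het
    calls with a definite single-parent origin contribute.
    """
    by_gene: Dict[str, List[CandidateVariant]] = {}
    for cand in candidates:
        if cand.record.proband.genotype is not Genotype.HET:
            continue
        if cand.transmission in (InheritanceCall.MATERNAL, InheritanceCall.PATERNAL):
            by_gene.setdefault(cand.gene, []).append(cand)
    out = []
    for gene in sorted(by_gene):
        members = by_gene[gene]
        origins = {c.transmission for c in members}
        if InheritanceCall.MATERNAL in origins and InheritanceCall.PATERNAL in origins:
            out.append(
                MonogenicCandidate(
                    gene=gene,
                    mode=Mode.AR_COMPOUND_HET,
                    variants=members,
                    trio_id=trio.proband_id,
                )
            )
    return out


def monogenic_candidates(
    candidates: Sequence[CandidateVariant], trio: PedigreeTrio
) -> List[MonogenicCandidate]:
    """Enumerate gene-level candidates under the fully penetrant models.

    Union of de novo singletons, autosomal-recessive homozygotes,
    compound hets, and (male probands only) X-linked recessive hemizygotes;
    deduplicated to one entry per (gene, mode) and sorted by gene symbol.
    Candidates must already carry a transmission call.
    """
    singles: Dict[Tuple[str, Mode], List[CandidateVariant]] = {}

    def add(gene: str, mode: Mode, cand: CandidateVariant) -> None:
        singles.setdefault((gene, mode), []).append(cand)

    for cand in candidates:
        if cand.transmission is None:
            raise ValueError("candidates must be transmission-annotated first")
        tr = cand.transmission
        rec = cand.record
        if tr is InheritanceCall.DE_NOVO:
            add(cand.gene, Mode.DE_NOVO, cand)
        elif tr is InheritanceCall.BIPARENTAL_HOMOZYGOUS:
            # autosomes and female X homozygotes both count as AR-homozygous
            add(cand.gene, Mode.AR_HOMOZYGOUS, cand)
        elif tr is InheritanceCall.HEMIZYGOUS_MATERNAL and trio.proband_sex is Sex.MALE:
            add(cand.gene, Mode.XLR, cand)

    out = [
        MonogenicCandidate(gene=gene, mode=mode, variants=members, trio_id=trio.proband_id)
        for (gene, mode), members in singles.items()
    ]
    out.extend(find_compound_het(candidates, trio))
    out.sort(key=lambda mc: (mc.gene, mc.mode.value))
    return out
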