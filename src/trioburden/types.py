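"""Core domain types for trio variant analysis.

A *trio* is an affected child (the proband) plus both biological parents.
Every downstream operation — quality filtering, rarity filtering, inheritance
classification, burden statistics — works on normalized, biallelic
:class:`TrioVariantRecord` objects carrying one genotype call per family
member and one set of annotations per alternate allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Genotype(enum.Enum):
    """Diploid or haploid genotype of one sample at one biallelic site.

    ``HEMI_REF``/``HEMI_ALT`` are single-copy calls, used for the male X
    outside the pseudoautosomal regions (and would apply to Y).  A male X
    genotype written diploid-homozygous in a VCF (``1/1``) is mapped to the
    hemizygous code on read.
    """

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_REF = "hemi_ref"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)

    @property
    def alt_dosage(self) -> int:
        """Number of alternate alleles carried (missing counts as 0)."""
        return {
            Genotype.HOM_REF: 0,
            Genotype.HET: 1,
            Genotype.HOM_ALT: 2,
            Genotype.HEMI_REF: 0,
            Genotype.HEMI_ALT: 1,
            Genotype.MISSING: 0,
        }[self]

    @property
    def has_ref_allele(self) -> bool:
        return self in (Genotype.HOM_REF, Genotype.HET, Genotype.HEMI_REF)

    @property
    def has_alt_allele(self) -> bool:
        return self.carries_alt

    @property
    def is_missing(self) -> bool:
        return self is Genotype.MISSING


class Consequence(enum.Enum):
    """Coarse functional consequence class of a coding variant."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_CANONICAL = "splice_canonical"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequence classes for which in-silico missense predictors generally
#: cannot produce a score (truncations and indels).
TRUNCATING_CLASSES = frozenset(
    {
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE_CANONICAL,
        Consequence.INFRAME_INDEL,
    }
)


class PredictorCall(enum.Enum):
    """One pathogenicity predictor's verdict (SIFT / PolyPhen-2 / MutationTaster)."""

    DAMAGING = "damaging"
    BENIGN = "benign"
    ABSENT = "absent"


@dataclass(frozen=True)
class PedigreeTrio:
    """One affected-child trio from a pedigree file.

    Sex of the proband is required because X-linked recessive logic depends
    on it; pedigrees with unknown proband sex are rejected at parse time.
    """

    family_id: str
    proband_id: str
    proband_sex: Sex
    mother_id: str
    father_id: str
    affected: bool = True

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError(
                f"trio {self.family_id}: proband/mother/father IDs must be distinct"
            )


@dataclass(frozen=True)
class SampleCall:
    """Genotype call of one family member at one site.

    ``quality_score`` is a genotype-confidence score (an MPG-style most
    probable genotype score, or GQ as a fallback); its ratio to read depth is
    the quality statistic gating every analysis.
    """

    genotype: Genotype
    depth: int = 0
    quality_score: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.quality_score < 0:
            raise ValueError("quality_score must be >= 0")

    @property
    def quality_ratio(self) -> Optional[float]:
        """quality_score / depth; undefined (None) at zero depth."""
        if self.depth > 0:
            return self.quality_score / self.depth
        return None


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-alternate-allele annotations consumed (never computed) by the pipeline.

    ``population_af`` of ``None`` means the allele was not found in the
    population reference database and is treated as frequency 0 everywhere.
    """

    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    population_af: Optional[float] = None
    population_nhomalt: Optional[int] = None
    sift: PredictorCall = PredictorCall.ABSENT
    polyphen: PredictorCall = PredictorCall.ABSENT
    mutation_taster: PredictorCall = PredictorCall.ABSENT

    @property
    def af_or_zero(self) -> float:
        return 0.0 if self.population_af is None else self.population_af

    @property
    def damaging_votes(self) -> int:
        """Number of predictors calling the variant damaging (absent is not a vote)."""
        return sum(
            p is PredictorCall.DAMAGING
            for p in (self.sift, self.polyphen, self.mutation_taster)
        )


def normalize_chrom(chrom: str) -> str:
    """Canonical contig name: strip a leading 'chr' prefix, keep case of the rest."""
    if chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


@dataclass(frozen=True)
class TrioVariantRecord:
    """One normalized biallelic site with the three family members' calls.

    Multiallelic VCF rows are split upstream so every record has exactly one
    alternate allele; ``chrom`` is stored without a ``chr`` prefix.
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    annotation: VariantAnnotation = field(default_factory=VariantAnnotation)
    proband: SampleCall = field(default_factory=lambda: SampleCall(Genotype.MISSING))
    mother: SampleCall = field(default_factory=lambda: SampleCall(Genotype.MISSING))
    father: SampleCall = field(default_factory=lambda: SampleCall(Genotype.MISSING))

    def __post_init__(self) -> None:
        if "," in self.alt:
            raise ValueError("TrioVariantRecord must be biallelic (single alt)")
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_x(self) -> bool:
        return self.chrom.upper() == "X"
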