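"""The rare, predicted-pathogenic candidate-variant filter.

A variant in a proband is a *candidate* when it satisfies all of:

1. call quality — read depth > 10 and genotype-score/depth ratio > 0.5
   (strict inequalities, evaluated on the proband call);
2. rarity — population allele frequency < 1% (absent from the reference
   database counts as 0), and, when the proband is homozygous or hemizygous,
   fewer than 2 homozygotes in the database;
3. protein-altering consequence — missense, nonsense, frameshift, in-frame
   indel, or canonical splice;
4. predicted pathogenic — at least 2 of 3 predictor calls damaging for
   missense; truncating/indel classes satisfy this structurally (predictors
   cannot score them) and are flagged ``truncating_bypass``.

The original manual read-alignment review step is replaced here by the
quality thresholds; candidates whose quality ratio falls below
``review_ratio`` are additionally flagged ``review_recommended``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple, TYPE_CHECKING

from .types import (
    Consequence,
    Genotype,
    SampleCall,
    TRUNCATING_CLASSES,
    TrioVariantRecord,
    VariantAnnotation,
)

if TYPE_CHECKING:  # avoid circular import at runtime
    from .inheritance import InheritanceCall


@dataclass(frozen=True)
class FilterThresholds:
    """Every numeric cutoff of the candidate definition.

    All comparisons are strict, matching the definitions above:
    depth > ``min_depth_exclusive``, ratio > ``min_quality_ratio_exclusive``,
    AF < ``max_af_exclusive``, nhomalt < ``max_nhomalt_exclusive``.
    """

    min_depth_exclusive: int = 10
    min_quality_ratio_exclusive: float = 0.5
    max_af_exclusive: float = 0.01
    max_nhomalt_exclusive: int = 2
    min_pathogenic_votes: int = 2
    review_ratio: float = 0.6

    def __post_init__(self) -> None:
        if min(
            self.min_depth_exclusive,
            self.min_quality_ratio_exclusive,
            self.max_af_exclusive,
            self.max_nhomalt_exclusive,
            self.min_pathogenic_votes,
        ) <= 0:
            raise ValueError("all thresholds must be strictly positive")


DEFAULT_THRESHOLDS = FilterThresholds()

CRITERIA = ("carrier", "quality", "rarity", "protein_altering", "predicted_pathogenic")


@dataclass
class CandidateVariant:
    """A record together with its per-criterion verdicts.

    ``transmission`` is filled in later by the inheritance module; it is
    carried here so gene-level enumeration can work from one object.
    """

    record: TrioVariantRecord
    criteria_passed: Dict[str, bool]
    truncating_bypass: bool = False
    review_recommended: bool = False
    transmission: Optional["InheritanceCall"] = None

    @property
    def is_candidate(self) -> bool:
        return all(self.criteria_passed.values())

    @property
    def gene(self) -> str:
        return self.record.annotation.gene


def passes_quality(call: SampleCall, t: FilterThresholds = DEFAULT_THRESHOLDS) -> bool:
    """Depth and score/depth ratio both strictly above threshold; missing fails."""
    if call.genotype.is_missing:
        return False
    if call.depth <= t.min_depth_exclusive:
        return False
    ratio = call.quality_ratio
    return ratio is not None and ratio > t.min_quality_ratio_exclusive


def passes_rarity(
    ann: VariantAnnotation,
    proband_gt: Genotype,
    t: FilterThresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """AF strictly below 1% (absent = 0); homozygote-count bound applies only
    when the proband carries two (or a hemizygous single) alt dose."""
    if ann.population_af is not None and ann.population_af >= t.max_af_exclusive:
        return False
    if proband_gt in (Genotype.HOM_ALT, Genotype.HEMI_ALT):
        nh = ann.population_nhomalt
        if nh is not None and nh >= t.max_nhomalt_exclusive:
            return False
    return True


def is_protein_altering(consequence: Consequence) -> bool:
    return consequence is Consequence.MISSENSE or consequence in TRUNCATING_CLASSES


def is_predicted_pathogenic(
    ann: VariantAnnotation, t: FilterThresholds = DEFAULT_THRESHOLDS
) -> Tuple[bool, bool]:
    """(passes, truncating_bypass).

    Missense requires >= ``min_pathogenic_votes`` damaging calls, with an
    absent predictor counting as a non-damaging vote.  Truncating and indel
    classes pass structurally (bypass flag set) because the missense
    predictors largely cannot score them.
    """
    if ann.consequence in TRUNCATING_CLASSES:
        return True, True
    if ann.consequence is Consequence.MISSENSE:
        return ann.damaging_votes >= t.min_pathogenic_votes, False
    return False, False


def evaluate_record(
    record: TrioVariantRecord, t: FilterThresholds = DEFAULT_THRESHOLDS
) -> CandidateVariant:
    """Apply all criteria to one record (proband call only)."""
    ann = record.annotation
    carrier = record.proband.genotype.carries_alt
    quality = passes_quality(record.proband, t)
    rarity = passes_rarity(ann, record.proband.genotype, t)
    altering = is_protein_altering(ann.consequence)
    pathogenic, bypass = is_predicted_pathogenic(ann, t)
    ratio = record.proband.quality_ratio
    return CandidateVariant(
        record=record,
        criteria_passed={
            "carrier": carrier,
            "quality": quality,
            "rarity": rarity,
            "protein_altering": altering,
            "predicted_pathogenic": pathogenic,
        },
        truncating_bypass=bypass and pathogenic,
        review_recommended=ratio is not None and ratio < t.review_ratio,
    )


def filter_candidates(
    records: Iterable[TrioVariantRecord],
    t: FilterThresholds = DEFAULT_THRESHOLDS,
    counts: Optional[Dict[str, int]] = None,
) -> List[CandidateVariant]:
    """Return the records passing all criteria, in input order.

    ``counts``, if supplied, accumulates per-criterion pass tallies over all
    evaluated records (for QC logging).  Output is deterministic and
    independent of record order up to that order itself.
    """
    out: List[CandidateVariant] = []
    for rec in records:
        cand = evaluate_record(rec, t)
        if counts is not None:
            for name, ok in cand.criteria_passed.items():
                counts[name] = counts.get(name, 0) + int(ok)
        if cand.is_candidate:
            out.append(cand)
    return out
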