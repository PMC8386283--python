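"""Pedigree and trio-VCF input/output.

Reads 6-column PED pedigrees and per-trio annotated VCFs (via cyvcf2) into
normalized :class:`~trioburden.types.TrioVariantRecord` streams, splitting
multiallelic rows, unifying contig naming, and mapping male X genotypes to
hemizygous calls outside the pseudoautosomal regions (PARs).  Also provides a
plain-text VCF writer for the normalized records (round-trip safe) and a
Mendelian-error QC statistic.

Annotation dialect
------------------
Annotations are read from simple INFO keys by default::

    GENE, CSQ_CLASS, GNOMAD_AF, GNOMAD_NHOMALT, SIFT, POLYPHEN, MTASTER

with per-allele (Number=A) values honoured at multiallelic sites.  The
genotype-quality FORMAT key defaults to ``MPG`` with ``GQ`` fallback.  A
``record_hook`` on the dialect lets callers map any other annotation scheme
(e.g. VEP CSQ strings) into :class:`VariantAnnotation` objects themselves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, List, Optional, Sequence, Tuple

from .types import (
    Consequence,
    Genotype,
    PedigreeTrio,
    PredictorCall,
    SampleCall,
    Sex,
    TrioVariantRecord,
    VariantAnnotation,
    normalize_chrom,
)

log = logging.getLogger(__name__)

#: GRCh37 X-chromosome pseudoautosomal intervals (1-based, inclusive).
PAR_GRCH37: Tuple[Tuple[int, int], ...] = ((60001, 2699520), (154931044, 155260560))


def in_par(pos: int, par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37) -> bool:
    return any(lo <= pos <= hi for lo, hi in par_intervals)


_CONSEQUENCE_ALIASES = {
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "nonsense": Consequence.NONSENSE,
    "stop_gained": Consequence.NONSENSE,
    "frameshift": Consequence.FRAMESHIFT,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "splice_canonical": Consequence.SPLICE_CANONICAL,
    "splice_acceptor_variant": Consequence.SPLICE_CANONICAL,
    "splice_donor_variant": Consequence.SPLICE_CANONICAL,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
}

_PREDICTOR_ALIASES = {
    "damaging": PredictorCall.DAMAGING,
    "deleterious": PredictorCall.DAMAGING,
    "disease_causing": PredictorCall.DAMAGING,
    "benign": PredictorCall.BENIGN,
    "tolerated": PredictorCall.BENIGN,
    "polymorphism": PredictorCall.BENIGN,
}


def parse_consequence(value: Optional[str]) -> Consequence:
    if not value:
        return Consequence.OTHER
    return _CONSEQUENCE_ALIASES.get(str(value).strip().lower(), Consequence.OTHER)


def parse_predictor(value: Optional[str]) -> PredictorCall:
    if not value or str(value) in (".", ""):
        return PredictorCall.ABSENT
    return _PREDICTOR_ALIASES.get(str(value).strip().lower(), PredictorCall.ABSENT)


@dataclass
class AnnotationDialect:
    """Mapping from VCF INFO/FORMAT keys to the normalized annotation fields."""

    gene_key: str = "GENE"
    consequence_key: str = "CSQ_CLASS"
    af_key: str = "GNOMAD_AF"
    nhomalt_key: str = "GNOMAD_NHOMALT"
    sift_key: str = "SIFT"
    polyphen_key: str = "POLYPHEN"
    mutation_taster_key: str = "MTASTER"
    quality_key: str = "MPG"
    quality_fallback_key: str = "GQ"
    #: optional override: (cyvcf2 variant, alt_index) -> VariantAnnotation
    record_hook: Optional[Callable[[object, int], VariantAnnotation]] = None


DEFAULT_DIALECT = AnnotationDialect()


# ---------------------------------------------------------------------------
# Pedigree


def read_pedigree(path: str | Path) -> List[PedigreeTrio]:
    """Parse a 6-column PED file into complete affected-child trios.

    Column order: family, individual, father, mother, sex (1=male, 2=female),
    phenotype (2=affected).  One trio is returned per affected individual
    whose two parent IDs are non-missing and present as rows; incomplete
    trios are skipped with a warning.  Duplicate proband IDs and unknown sex
    codes for a proband are hard errors.
    """
    rows = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
            fam, iid, pat, mat, sex, pheno = fields[:6]
            if iid in rows:
                raise ValueError(f"{path}:{lineno}: duplicate individual ID {iid!r}")
            rows[iid] = (fam, iid, pat, mat, sex, pheno)
            order.append(iid)

    trios: List[PedigreeTrio] = []
    seen_probands = set()
    for iid in order:
        fam, _, pat, mat, sex, pheno = rows[iid]
        if pheno != "2":
            continue
        if iid in seen_probands:
            raise ValueError(f"duplicate proband ID {iid!r}")
        seen_probands.add(iid)
        if pat == "0" or mat == "0" or pat not in rows or mat not in rows:
            log.warning("pedigree %s: trio for %s skipped (missing parent)", fam, iid)
            continue
        if sex == "1":
            proband_sex = Sex.MALE
        elif sex == "2":
            proband_sex = Sex.FEMALE
        else:
            raise ValueError(
                f"proband {iid!r} has unknown sex code {sex!r}; sex is required"
            )
        trios.append(
            PedigreeTrio(
                family_id=fam,
                proband_id=iid,
                proband_sex=proband_sex,
                mother_id=mat,
                father_id=pat,
                affected=True,
            )
        )
    return trios


# ---------------------------------------------------------------------------
# Raw variant representation and multiallelic splitting


@dataclass
class RawVariant:
    """A VCF row before normalization: possibly multiallelic, genotypes as
    allele-index tuples (``None`` entries are missing alleles)."""

    chrom: str
    pos: int
    ref: str
    alts: List[str]
    # per sample (proband, mother, father): tuple of allele indices; haploid
    # calls have length 1; missing calls contain None
    allele_pairs: List[Tuple[Optional[int], ...]]
    depths: List[int]
    quality_scores: List[float]
    # per-alt annotations, parallel to alts
    annotations: List[VariantAnnotation] = field(default_factory=list)


class MalformedGenotypeError(ValueError):
    """Genotype references an allele index outside the ALT list."""


def split_multiallelic(raw: RawVariant) -> List[RawVariant]:
    """Expand a raw row into one biallelic row per alternate allele.

    Genotypes are recoded against each alt in turn: other alternate alleles
    collapse to the non-carrier (reference) state.  Per-allele annotations
    follow their allele.  The total number of alt-carrying samples summed
    over the split rows equals that of the original row.
    """
    n_alts = len(raw.alts)
    if n_alts == 0:
        raise ValueError("raw variant has no alternate allele")
    for pair in raw.allele_pairs:
        for a in pair:
            if a is not None and a > n_alts:
                raise MalformedGenotypeError(
                    f"{raw.chrom}:{raw.pos}: allele index {a} exceeds {n_alts} alts"
                )
    if n_alts == 1:
        return [raw]
    out = []
    for k in range(1, n_alts + 1):
        pairs = []
        for pair in raw.allele_pairs:
            pairs.append(
                tuple(None if a is None else (1 if a == k else 0) for a in pair)
            )
        out.append(
            RawVariant(
                chrom=raw.chrom,
                pos=raw.pos,
                ref=raw.ref,
                alts=[raw.alts[k - 1]],
                allele_pairs=pairs,
                depths=list(raw.depths),
                quality_scores=list(raw.quality_scores),
                annotations=[raw.annotations[k - 1]] if raw.annotations else [],
            )
        )
    return out


def genotype_from_alleles(
    alleles: Tuple[Optional[int], ...],
    *,
    male_x_nonpar: bool = False,
) -> Genotype:
    """Map a biallelic allele-index tuple to a Genotype enum.

    ``male_x_nonpar`` converts diploid-coded homozygous calls on the male X
    (outside the PARs) to hemizygous codes; a residual heterozygous call
    there is kept as ``HET`` (it is biologically implausible and will be
    treated as unresolvable downstream).
    """
    if any(a is None for a in alleles) or len(alleles) == 0:
        return Genotype.MISSING
    dosage = sum(alleles)
    if len(alleles) == 1:  # haploid call
        return Genotype.HEMI_ALT if dosage else Genotype.HEMI_REF
    if male_x_nonpar:
        if dosage == 0:
            return Genotype.HEMI_REF
        if dosage == len(alleles):
            return Genotype.HEMI_ALT
        return Genotype.HET
    if dosage == 0:
        return Genotype.HOM_REF
    if dosage == len(alleles):
        return Genotype.HOM_ALT
    return Genotype.HET


# ---------------------------------------------------------------------------
# VCF reading


def _info_for_alt(value, alt_index: int):
    """Select the per-allele element of an INFO value (Number=A), else pass through.

    cyvcf2 hands per-allele String fields back as the raw comma-joined text,
    numeric ones as tuples; both are handled.
    """
    if isinstance(value, str):
        parts = value.split(",")
        if len(parts) > 1:
            return parts[alt_index] if alt_index < len(parts) else None
        return value
    if isinstance(value, (tuple, list)) or (hasattr(value, "__len__")):
        if alt_index < len(value):
            return value[alt_index]
        return None
    return value


def _annotation_from_info(variant, alt_index: int, dialect: AnnotationDialect) -> VariantAnnotation:
    def get(key):
        try:
            v = variant.INFO.get(key)
        except Exception:
            v = None
        return _info_for_alt(v, alt_index)

    af = get(dialect.af_key)
    if af is None or (isinstance(af, float) and math.isnan(af)):
        af = None
    else:
        # normalize float32 storage noise back to the written precision
        af = float(f"{float(af):.6g}")
    nh = get(dialect.nhomalt_key)
    nh = None if nh is None else int(nh)
    gene = get(dialect.gene_key)
    return VariantAnnotation(
        gene="" if gene is None else str(gene),
        consequence=parse_consequence(get(dialect.consequence_key)),
        population_af=af,
        population_nhomalt=nh,
        sift=parse_predictor(get(dialect.sift_key)),
        polyphen=parse_predictor(get(dialect.polyphen_key)),
        mutation_taster=parse_predictor(get(dialect.mutation_taster_key)),
    )


@dataclass
class ReadStats:
    n_rows: int = 0
    n_records: int = 0
    n_malformed: int = 0


def read_trio_vcf(
    path: str | Path,
    trio: PedigreeTrio,
    dialect: AnnotationDialect = DEFAULT_DIALECT,
    par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37,
    stats: Optional[ReadStats] = None,
) -> Iterator[TrioVariantRecord]:
    """Stream normalized biallelic records for one trio from an annotated VCF.

    The three sample columns named in the trio must be present in the VCF
    header (hard error otherwise).  Multiallelic rows are expanded; rows with
    genotypes referencing out-of-range allele indices are counted as
    malformed and skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_index = {s: i for i, s in enumerate(vcf.samples)}
    for sid in (trio.proband_id, trio.mother_id, trio.father_id):
        if sid not in sample_index:
            raise KeyError(f"sample {sid!r} not found in VCF {path}")
    idx = [sample_index[trio.proband_id], sample_index[trio.mother_id], sample_index[trio.father_id]]

    for variant in vcf:
        if stats:
            stats.n_rows += 1
        pairs = []
        for i in idx:
            g = variant.genotypes[i]
            # cyvcf2 genotype entry: [a1, a2, phased] or [a1, phased] (haploid)
            alleles = tuple(None if a < 0 else int(a) for a in g[:-1])
            pairs.append(alleles)
        depths = _format_ints(variant, "DP", idx)
        scores = _format_floats(variant, dialect.quality_key, idx)
        if scores is None:
            scores = _format_floats(variant, dialect.quality_fallback_key, idx)
        if scores is None:
            scores = [0.0, 0.0, 0.0]

        n_alts = len(variant.ALT)
        if dialect.record_hook is not None:
            annotations = [dialect.record_hook(variant, k) for k in range(n_alts)]
        else:
            annotations = [_annotation_from_info(variant, k, dialect) for k in range(n_alts)]

        raw = RawVariant(
            chrom=variant.CHROM,
            pos=variant.POS,
            ref=variant.REF,
            alts=list(variant.ALT),
            allele_pairs=pairs,
            depths=depths,
            quality_scores=scores,
            annotations=annotations,
        )
        try:
            splits = split_multiallelic(raw)
        except MalformedGenotypeError as exc:
            if stats:
                stats.n_malformed += 1
            log.warning("skipping malformed record: %s", exc)
            continue
        for sub in splits:
            rec = raw_to_record(sub, trio, par_intervals)
            if stats:
                stats.n_records += 1
            yield rec


def _format_ints(variant, key: str, idx: List[int]) -> List[int]:
    try:
        arr = variant.format(key)
    except KeyError:
        arr = None
    if arr is None:
        return [0, 0, 0]
    out = []
    for i in idx:
        v = arr[i]
        v = v[0] if hasattr(v, "__len__") else v
        out.append(0 if v is None or (isinstance(v, float) and math.isnan(v)) or int(v) < 0 else int(v))
    return out


def _format_floats(variant, key: str, idx: List[int]) -> Optional[List[float]]:
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    out = []
    for i in idx:
        v = arr[i]
        v = v[0] if hasattr(v, "__len__") else v
        out.append(0.0 if v is None or (isinstance(v, float) and math.isnan(v)) or float(v) < 0 else float(v))
    return out


def raw_to_record(
    raw: RawVariant,
    trio: PedigreeTrio,
    par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37,
) -> TrioVariantRecord:
    """Convert a biallelic RawVariant into a normalized TrioVariantRecord."""
    if len(raw.alts) != 1:
        raise ValueError("raw_to_record requires a biallelic raw variant")
    chrom = normalize_chrom(raw.chrom)
    on_x_nonpar = chrom.upper() == "X" and not in_par(raw.pos, par_intervals)
    male_hemi = [
        trio.proband_sex is Sex.MALE and on_x_nonpar,  # proband
        False,  # mother
        on_x_nonpar,  # father is male by definition
    ]
    calls = []
    for alleles, depth, score, hemi in zip(
        raw.allele_pairs, raw.depths, raw.quality_scores, male_hemi
    ):
        gt = genotype_from_alleles(alleles, male_x_nonpar=hemi)
        calls.append(SampleCall(genotype=gt, depth=depth, quality_score=score))
    ann = raw.annotations[0] if raw.annotations else VariantAnnotation()
    return TrioVariantRecord(
        chrom=chrom,
        pos=raw.pos,
        ref=raw.ref,
        alt=raw.alts[0],
        annotation=ann,
        proband=calls[0],
        mother=calls[1],
        father=calls[2],
    )


# ---------------------------------------------------------------------------
# VCF writing (round-trip of normalized records)

_GT_STRINGS = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.HEMI_REF: "0",
    Genotype.HEMI_ALT: "1",
    Genotype.MISSING: "./.",
}

_VCF_HEADER_LINES = [
    '##INFO=<ID=GENE,Number=A,Type=String,Description="Gene symbol">',
    '##INFO=<ID=CSQ_CLASS,Number=A,Type=String,Description="Consequence class">',
    '##INFO=<ID=GNOMAD_AF,Number=A,Type=Float,Description="Population allele frequency">',
    '##INFO=<ID=GNOMAD_NHOMALT,Number=A,Type=Integer,Description="Population homozygote count">',
    '##INFO=<ID=SIFT,Number=A,Type=String,Description="SIFT call">',
    '##INFO=<ID=POLYPHEN,Number=A,Type=String,Description="PolyPhen-2 call">',
    '##INFO=<ID=MTASTER,Number=A,Type=String,Description="MutationTaster call">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=MPG,Number=1,Type=Float,Description="Most probable genotype score">',
]


def write_trio_vcf(
    path: str | Path,
    trio: PedigreeTrio,
    records: Iterable[TrioVariantRecord],
    contigs: Optional[Sequence[str]] = None,
) -> None:
    """Write normalized records as a plain-text VCF 4.2 file.

    Sample column order is proband, mother, father.  Reading the file back
    with :func:`read_trio_vcf` reproduces genotype, depth, quality-score and
    annotation fields exactly (the round-trip contract used by the tests).
    """
    records = list(records)
    if contigs is None:
        seen = []
        for r in records:
            if r.chrom not in seen:
                seen.append(r.chrom)
        contigs = seen
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=trioburden\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{trio.proband_id}\t{trio.mother_id}\t{trio.father_id}\n"
        )
        for r in records:
            ann = r.annotation
            info = [
                f"GENE={ann.gene or '.'}",
                f"CSQ_CLASS={ann.consequence.value}",
            ]
            if ann.population_af is not None:
                info.append(f"GNOMAD_AF={ann.population_af:.6g}")
            if ann.population_nhomalt is not None:
                info.append(f"GNOMAD_NHOMALT={ann.population_nhomalt}")
            for key, call in (
                ("SIFT", ann.sift),
                ("POLYPHEN", ann.polyphen),
                ("MTASTER", ann.mutation_taster),
            ):
                if call is not PredictorCall.ABSENT:
                    info.append(f"{key}={call.value}")
            samples = []
            for call in (r.proband, r.mother, r.father):
                samples.append(
                    f"{_GT_STRINGS[call.genotype]}:{call.depth}:{call.quality_score:g}"
                )
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                + ";".join(info)
                + "\tGT:DP:MPG\t"
                + "\t".join(samples)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Mendelian-consistency QC


def _allele_set(gt: Genotype) -> Optional[set]:
    """Alleles a parent can transmit (None if missing)."""
    return {
        Genotype.HOM_REF: {0},
        Genotype.HET: {0, 1},
        Genotype.HOM_ALT: {1},
        Genotype.HEMI_REF: {0},
        Genotype.HEMI_ALT: {1},
        Genotype.MISSING: None,
    }[gt]


def mendelian_consistent(record: TrioVariantRecord, trio: PedigreeTrio,
                         par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37) -> bool:
    """True if the genotype triple is possible under Mendelian transmission.

    De novo events are, by definition, Mendelian *errors* for the purpose of
    this QC statistic.  Male X (non-PAR) children receive their single allele
    from the mother; female X children receive the paternal X allele.
    """
    child, mother, father = record.proband.genotype, record.mother.genotype, record.father.genotype
    m, f = _allele_set(mother), _allele_set(father)
    if m is None or f is None or child.is_missing:
        raise ValueError("all three genotypes must be non-missing")
    on_x_nonpar = record.is_x and not in_par(record.pos, par_intervals)
    if on_x_nonpar and trio.proband_sex is Sex.MALE:
        allele = 1 if child.carries_alt else 0
        return allele in m
    # diploid child: one allele from each parent
    if child is Genotype.HET:
        return (0 in m and 1 in f) or (1 in m and 0 in f)
    target = 1 if child in (Genotype.HOM_ALT, Genotype.HEMI_ALT) else 0
    return target in m and target in f


def mendelian_error_rate(
    records: Iterable[TrioVariantRecord],
    trio: PedigreeTrio,
    par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37,
) -> float:
    """Fraction of fully genotyped records inconsistent with Mendelian transmission.

    A surrogate pedigree-integrity check: high rates indicate sample swaps or
    non-paternity.  Raises if no record has all three genotypes called.
    """
    n = 0
    errors = 0
    for rec in records:
        if (
            rec.proband.genotype.is_missing
            or rec.mother.genotype.is_missing
            or rec.father.genotype.is_missing
        ):
            continue
        n += 1
        if not mendelian_consistent(rec, trio, par_intervals):
            errors += 1
    if n == 0:
        raise ValueError("no records with all three genotypes non-missing")
    return errors / n
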