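"""Synthetic trio-cohort generator with ground truth.

Generates case/control trio cohorts whose structure matches the data the
analysis consumes: per-trio annotated VCFs (or in-memory record streams), a
pedigree, a gene panel, and a truth table of planted events.  Background
sites draw parental genotypes at Hardy-Weinberg equilibrium from a
rare/common allele-frequency spectrum and transmit to the child Mendelianly
(X sites respect sex); disease-model events — de novo, compound
heterozygous, autosomal-recessive homozygous, X-linked recessive, and
heterozygous panel-gene variants — are planted at configurable per-trio
Poisson rates with annotations constructed to pass the candidate filter.
Decoy plants that violate exactly one filter criterion are injected
alongside (a configurable fraction of all plants) so filter rejection is
testable; the violated criterion is recorded in the truth table.

Design notes
------------
* Sites are abstract: synthetic contig names 1..22 plus one X contig with
  GRCh37 pseudoautosomal intervals; planted X sites sit well inside the
  non-PAR region.
* Every background site gets a unique synthetic gene (``BG#####``) so
  compound heterozygotes can never arise from background; background X
  sites draw only common allele frequencies so they can never pass the
  rarity criterion.  Planted monogenic events use a dedicated gene pool
  (``MG####``, sampled without replacement per trio) disjoint from the
  panel, and panel plants draw panel genes without replacement per trio.
  These choices make planted-event recall and precision exactly decidable
  against the truth table.
* The configured event rates are expected counts of *filter-passing* plants
  per trio; decoys are injected on top at ``rate * decoy_fraction /
  (1 - decoy_fraction)`` so that decoys make up ``decoy_fraction`` of all
  plants in expectation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .stats import GenePanel, default_panel
from .trio_io import PAR_GRCH37, write_trio_vcf
from .types import (
    Consequence,
    Genotype,
    PedigreeTrio,
    PredictorCall,
    SampleCall,
    Sex,
    TrioVariantRecord,
    VariantAnnotation,
)

_BASES = ("A", "C", "G", "T")

#: planted X sites are placed here: inside GRCh37 non-PAR X
_X_PLANT_POS0 = 100_000_000
_X_BACKGROUND_POS0 = 3_000_000


@dataclass(frozen=True)
class TrioEventRates:
    """Expected filter-passing planted events per trio, by class.

    ``xlr`` applies to male-proband trios only.  ``panel_het`` plants are
    inherited heterozygous candidates in panel genes (the quantity compared
    in the panel burden analysis); the other four classes are genome-wide
    monogenic events in a synthetic gene pool disjoint from the panel.
    """

    de_novo: float = 0.0
    comp_het: float = 0.0
    ar_hom: float = 0.0
    xlr: float = 0.0
    panel_het: float = 0.0

    def __post_init__(self) -> None:
        if min(self.de_novo, self.comp_het, self.ar_hom, self.xlr, self.panel_het) < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort; the seed determines everything."""

    n_case_trios: int = 13
    n_control_trios: int = 19
    n_male_case: int = 5
    n_male_control: int = 12
    n_background_sites: int = 400
    x_background_fraction: float = 0.05
    af_common_fraction: float = 0.7
    rates_case: TrioEventRates = field(default_factory=TrioEventRates)
    rates_control: TrioEventRates = field(default_factory=TrioEventRates)
    depth_mean: float = 40.0
    quality_ratio_range: Tuple[float, float] = (0.6, 0.95)
    genotype_error_rate: float = 0.0
    parental_dropout_rate: float = 0.0
    predictor_concordance: float = 1.0
    decoy_fraction: float = 0.2
    background_candidate_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case_trios < 1 or self.n_control_trios < 1:
            raise ValueError("need at least one trio per group")
        if self.n_background_sites < 1:
            raise ValueError("need at least one background site")
        for p in (
            self.genotype_error_rate,
            self.parental_dropout_rate,
            self.predictor_concordance,
            self.decoy_fraction,
            self.af_common_fraction,
            self.x_background_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def study_scale_config(seed: int = 1234) -> SimConfig:
    """Cohort configuration matching the reference study conditions.

    13 case vs. 19 control trios (5 and 12 male probands); panel-variant
    rates 1.1 vs. 0.21 per proband; gene-level monogenic candidate rates
    totalling 1.3 vs. 2.5 per trio, apportioned across de novo /
    compound-het / AR-homozygous / XLR in the proportions of the reference
    cohort's candidate table (5:6:5:1 among 17 case candidates; the XLR rate
    is per male trio).
    """
    rates_case = TrioEventRates(
        de_novo=5 / 13,
        comp_het=6 / 13,
        ar_hom=5 / 13,
        xlr=0.2,  # 1 event among 5 male case trios
        panel_het=1.1,
    )
    # control total 2.5 = 0.9 + 0.9 + 0.5737 + (12/19) * 0.2
    rates_control = TrioEventRates(
        de_novo=0.9,
        comp_het=0.9,
        ar_hom=2.5 - 0.9 - 0.9 - (12 / 19) * 0.2,
        xlr=0.2,
        panel_het=0.21,
    )
    return SimConfig(rates_case=rates_case, rates_control=rates_control, seed=seed)


@dataclass(frozen=True)
class TruthRecord:
    """One planted event member, with its expected filter outcome."""

    trio_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    planted_class: str  # de_novo | comp_het_member | ar_hom | xlr | panel_het
    should_pass_filter: bool
    violated: str = ""  # criterion violated by a decoy plant
    event_id: str = ""  # shared by the members of one compound-het event


@dataclass
class Cohort:
    """In-memory synthetic cohort: trios, per-trio records, truth, panel."""

    config: SimConfig
    trios: List[PedigreeTrio]
    group: Dict[str, str]  # proband_id -> "case" | "control"
    records: Dict[str, List[TrioVariantRecord]]
    truth: List[TruthRecord]
    panel: GenePanel

    def case_trios(self) -> List[PedigreeTrio]:
        return [t for t in self.trios if self.group[t.proband_id] == "case"]

    def control_trios(self) -> List[PedigreeTrio]:
        return [t for t in self.trios if self.group[t.proband_id] == "control"]


# ---------------------------------------------------------------------------
# Generation internals


def _make_trios(config: SimConfig) -> Tuple[List[PedigreeTrio], Dict[str, str]]:
    trios: List[PedigreeTrio] = []
    group: Dict[str, str] = {}
    for label, n, n_male in (
        ("case", config.n_case_trios, config.n_male_case),
        ("control", config.n_control_trios, config.n_male_control),
    ):
        prefix = "CASE" if label == "case" else "CTRL"
        for i in range(n):
            fam = f"{prefix}{i:02d}"
            trio = PedigreeTrio(
                family_id=fam,
                proband_id=f"{fam}P",
                proband_sex=Sex.MALE if i < n_male else Sex.FEMALE,
                mother_id=f"{fam}M",
                father_id=f"{fam}F",
            )
            trios.append(trio)
            group[trio.proband_id] = label
    return trios, group


@dataclass
class _SiteTable:
    """Cohort-wide background site definitions (shared across trios, as in a
    jointly called cohort)."""

    chrom: np.ndarray  # object array of contig names
    pos: np.ndarray
    ref: List[str]
    alt: List[str]
    af: np.ndarray
    is_x: np.ndarray
    annotations: List[VariantAnnotation]


def _build_background_sites(config: SimConfig, rng: np.random.Generator) -> _SiteTable:
    n = config.n_background_sites
    n_x = int(round(n * config.x_background_fraction))
    n_auto = n - n_x
    chroms = [str(1 + (i % 22)) for i in range(n_auto)] + ["X"] * n_x
    pos = np.concatenate(
        [
            10_000 + 1_000 * np.arange(n_auto, dtype=np.int64),
            _X_BACKGROUND_POS0 + 1_000 * np.arange(n_x, dtype=np.int64),
        ]
    )
    is_x = np.array([c == "X" for c in chroms])
    common = rng.random(n) < config.af_common_fraction
    common |= is_x  # X background sites are always common (never rarity-passing)
    af = np.where(
        common,
        rng.uniform(0.05, 0.5, size=n),
        rng.uniform(1e-5, 0.01, size=n),
    )
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    refs = [_BASES[i] for i in ref_idx]
    alts = [_BASES[i] for i in alt_idx]

    missense = rng.random(n) < 0.8
    incidental = rng.random(n) < config.background_candidate_rate
    annotations = []
    for i in range(n):
        rare_missense = missense[i] and not common[i]
        damaging = rare_missense and incidental[i]
        call = PredictorCall.DAMAGING if damaging else PredictorCall.BENIGN
        annotations.append(
            VariantAnnotation(
                gene=f"BG{i:05d}",
                consequence=Consequence.MISSENSE if missense[i] else Consequence.SYNONYMOUS,
                population_af=float(af[i]),
                population_nhomalt=int(min(af[i] ** 2 * 150_000, 10_000)),
                sift=call if missense[i] else PredictorCall.ABSENT,
                polyphen=call if missense[i] else PredictorCall.ABSENT,
                mutation_taster=PredictorCall.BENIGN if missense[i] else PredictorCall.ABSENT,
            )
        )
    return _SiteTable(
        chrom=np.array(chroms, dtype=object),
        pos=pos,
        ref=refs,
        alt=alts,
        af=af,
        is_x=is_x,
        annotations=annotations,
    )


_AUTO_DOSAGE_GT = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}
_HEMI_DOSAGE_GT = {0: Genotype.HEMI_REF, 1: Genotype.HEMI_ALT}


def _background_genotypes(
    sites: _SiteTable, male: bool, config: SimConfig, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dosage arrays (child, mother, father) under HW + Mendelian transmission."""
    n = len(sites.pos)
    p = sites.af
    mother = rng.binomial(2, p)
    father = np.where(
        sites.is_x, rng.binomial(1, p), rng.binomial(2, p)
    )
    from_mother = rng.random(n) < mother / 2.0
    father_ploidy = np.where(sites.is_x, 1, 2)
    from_father = rng.random(n) < father / father_ploidy
    child = from_mother.astype(np.int64) + from_father.astype(np.int64)
    if male:
        # male child: X allele comes from the mother only (hemizygous)
        child = np.where(sites.is_x, from_mother.astype(np.int64), child)
    if config.genotype_error_rate > 0:
        for arr, ploidy in ((child, None), (mother, 2), (father, None)):
            err = rng.random(n) < config.genotype_error_rate
            if not err.any():
                continue
            idx = np.nonzero(err)[0]
            for i in idx:
                if ploidy == 2 or not sites.is_x[i]:
                    top = 2
                elif arr is father or (arr is child and male):
                    top = 1
                else:
                    top = 2
                choices = [d for d in range(top + 1) if d != arr[i]]
                arr[i] = rng.choice(choices)
    return child, mother, father


def _dosage_to_genotype(dosage: int, hemi: bool) -> Genotype:
    return _HEMI_DOSAGE_GT[min(dosage, 1)] if hemi else _AUTO_DOSAGE_GT[dosage]


class _PlantFactory:
    """Builds planted-event records for one trio."""

    def __init__(self, config: SimConfig, rng: np.random.Generator, panel_genes: List[str]):
        self.config = config
        self.rng = rng
        self.panel_genes = sorted(panel_genes)
        self.counter = 0

    def _alleles(self, consequence: Consequence) -> Tuple[str, str]:
        b = _BASES[self.rng.integers(0, 4)]
        if consequence is Consequence.FRAMESHIFT:
            return b + "AC", b  # 2-bp deletion
        if consequence is Consequence.INFRAME_INDEL:
            return b + "CAG", b  # 3-bp deletion
        alt = _BASES[(_BASES.index(b) + int(self.rng.integers(1, 4))) % 4]
        return b, alt

    def _annotation(
        self, gene: str, proband_hom: bool, violated: str
    ) -> Tuple[VariantAnnotation, bool, str]:
        """(annotation, passes, violated).  A non-empty ``violated`` forces
        that criterion to fail; predictor-concordance draws can also demote a
        would-pass missense plant (the returned ``violated`` reflects it)."""
        rng = self.rng
        if violated == "protein_altering":
            consequence = Consequence.SYNONYMOUS
        elif rng.random() < 0.7:
            consequence = Consequence.MISSENSE
        else:
            consequence = rng.choice(
                [Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.SPLICE_CANONICAL]
            )
        if violated == "rarity":
            af: Optional[float] = float(rng.uniform(0.02, 0.2))
        else:
            af = None if rng.random() < 0.3 else float(rng.uniform(1e-5, 0.009))
        nhomalt = None if af is None else int(rng.integers(0, 2))
        if proband_hom and violated != "rarity" and nhomalt is not None:
            nhomalt = int(rng.integers(0, 2))  # keep < 2 for passing homozygotes

        passes = violated == ""
        if consequence is Consequence.MISSENSE:
            if violated == "predicted_pathogenic":
                n_damaging = 1
            elif violated == "" and rng.random() >= self.config.predictor_concordance:
                n_damaging = 1
                passes = False
                violated = "predicted_pathogenic"
            else:
                n_damaging = int(rng.integers(2, 4))
            calls = [PredictorCall.DAMAGING] * n_damaging + [PredictorCall.BENIGN] * (
                3 - n_damaging
            )
            rng.shuffle(calls)
        else:
            calls = [PredictorCall.ABSENT] * 3
            if violated == "predicted_pathogenic":
                # predictors cannot fail a truncating class; fall back to rarity
                violated = "rarity"
                af = float(rng.uniform(0.02, 0.2))
                passes = False
        ann = VariantAnnotation(
            gene=gene,
            consequence=consequence,
            population_af=af,
            population_nhomalt=nhomalt,
            sift=calls[0],
            polyphen=calls[1],
            mutation_taster=calls[2],
        )
        return ann, passes, violated

    def _call(self, genotype: Genotype, low_depth: bool = False) -> SampleCall:
        rng = self.rng
        if low_depth:
            depth = int(rng.integers(3, 10))
        else:
            depth = max(int(rng.poisson(self.config.depth_mean)), 12)
        lo, hi = self.config.quality_ratio_range
        ratio = float(rng.uniform(lo, hi))
        return SampleCall(genotype=genotype, depth=depth, quality_score=ratio * depth)

    def build(
        self,
        trio: PedigreeTrio,
        planted_class: str,
        gene: str,
        genotypes: Tuple[Genotype, Genotype, Genotype],
        on_x: bool,
        violated: str,
        event_id: str,
    ) -> Tuple[TrioVariantRecord, TruthRecord]:
        self.counter += 1
        if on_x:
            chrom, pos = "X", _X_PLANT_POS0 + 100 * self.counter
        else:
            chrom, pos = "2", 50_000_000 + 100 * self.counter
        proband_hom = genotypes[0] in (Genotype.HOM_ALT, Genotype.HEMI_ALT)
        ann, passes, violated = self._annotation(gene, proband_hom, violated)
        ref, alt = self._alleles(ann.consequence)
        proband = self._call(genotypes[0], low_depth=(violated == "quality"))
        record = TrioVariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            annotation=ann,
            proband=proband,
            mother=self._call(genotypes[1]),
            father=self._call(genotypes[2]),
        )
        if violated == "quality":
            passes = False
        truth = TruthRecord(
            trio_id=trio.proband_id,
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            gene=gene,
            planted_class=planted_class,
            should_pass_filter=passes,
            violated=violated,
            event_id=event_id,
        )
        return record, truth


_DECOY_CRITERIA = ("quality", "rarity", "protein_altering", "predicted_pathogenic")


def _plant_events(
    trio: PedigreeTrio,
    rates: TrioEventRates,
    config: SimConfig,
    rng: np.random.Generator,
    factory: _PlantFactory,
) -> Tuple[List[TrioVariantRecord], List[TruthRecord]]:
    records: List[TrioVariantRecord] = []
    truths: List[TruthRecord] = []
    male = trio.proband_sex is Sex.MALE

    decoy_ratio = (
        config.decoy_fraction / (1.0 - config.decoy_fraction)
        if config.decoy_fraction < 1.0
        else 0.0
    )

    # genome-wide monogenic plant genes: sampled without replacement per trio
    gene_pool = [f"MG{i:04d}" for i in rng.permutation(1000)]
    pool_iter = iter(gene_pool)

    def counts(rate: float) -> Tuple[int, int]:
        return int(rng.poisson(rate)), int(rng.poisson(rate * decoy_ratio))

    def plant(planted_class, gene, genotypes, on_x, violated, event_id=""):
        rec, tr = factory.build(trio, planted_class, gene, genotypes, on_x, violated, event_id)
        records.append(rec)
        truths.append(tr)

    def decoy_criterion() -> str:
        return str(rng.choice(_DECOY_CRITERIA))

    # --- de novo: child het, both parents hom-ref (autosomal)
    n_pass, n_decoy = counts(rates.de_novo)
    for i in range(n_pass + n_decoy):
        plant(
            "de_novo",
            next(pool_iter),
            (Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF),
            False,
            decoy_criterion() if i >= n_pass else "",
        )

    # --- compound het: two members in one gene, opposite parental origins
    n_pass, n_decoy = counts(rates.comp_het)
    for i in range(n_pass + n_decoy):
        gene = next(pool_iter)
        event_id = f"{trio.proband_id}:CH{i}"
        violated = decoy_criterion() if i >= n_pass else ""
        plant(
            "comp_het_member",
            gene,
            (Genotype.HET, Genotype.HET, Genotype.HOM_REF),
            False,
            violated,
            event_id,
        )
        plant(
            "comp_het_member",
            gene,
            (Genotype.HET, Genotype.HOM_REF, Genotype.HET),
            False,
            violated,
            event_id,
        )

    # --- AR homozygous: child hom-alt, both parents het (autosomal)
    n_pass, n_decoy = counts(rates.ar_hom)
    for i in range(n_pass + n_decoy):
        plant(
            "ar_hom",
            next(pool_iter),
            (Genotype.HOM_ALT, Genotype.HET, Genotype.HET),
            False,
            decoy_criterion() if i >= n_pass else "",
        )

    # --- XLR: male proband hemizygous, carrier mother, non-carrier father
    if male:
        n_pass, n_decoy = counts(rates.xlr)
        for i in range(n_pass + n_decoy):
            plant(
                "xlr",
                next(pool_iter),
                (Genotype.HEMI_ALT, Genotype.HET, Genotype.HEMI_REF),
                True,
                decoy_criterion() if i >= n_pass else "",
            )

    # --- panel heterozygous candidates, inherited from one parent
    n_pass, n_decoy = counts(rates.panel_het)
    n_total = min(n_pass + n_decoy, len(factory.panel_genes))
    genes = rng.choice(len(factory.panel_genes), size=n_total, replace=False)
    for i in range(n_total):
        gene = factory.panel_genes[genes[i]]
        maternal = rng.random() < 0.5
        genotypes = (
            Genotype.HET,
            Genotype.HET if maternal else Genotype.HOM_REF,
            Genotype.HOM_REF if maternal else Genotype.HET,
        )
        plant("panel_het", gene, genotypes, False, decoy_criterion() if i >= n_pass else "")

    return records, truths


def _apply_parental_dropout(
    records: List[TrioVariantRecord], rate: float, rng: np.random.Generator
) -> List[TrioVariantRecord]:
    if rate <= 0:
        return records
    out = []
    for rec in records:
        mother, father = rec.mother, rec.father
        if rng.random() < rate:
            mother = SampleCall(mother.genotype, int(rng.integers(0, 9)), 1.0)
        if rng.random() < rate:
            father = SampleCall(father.genotype, int(rng.integers(0, 9)), 1.0)
        if mother is not rec.mother or father is not rec.father:
            rec = dataclasses.replace(rec, mother=mother, father=father)
        out.append(rec)
    return out


def simulate_cohort(config: SimConfig, out_dir: Optional[str | Path] = None) -> Cohort:
    """Generate one cohort; optionally write VCFs/PED/panel/truth to ``out_dir``.

    The same configuration (including seed) always produces the same cohort,
    byte-identical on disk.
    """
    rng = np.random.default_rng(config.seed)
    trios, group = _make_trios(config)
    sites = _build_background_sites(config, rng)
    panel = default_panel()
    factory = _PlantFactory(config, rng, sorted(panel.genes))

    lo, hi = config.quality_ratio_range
    records: Dict[str, List[TrioVariantRecord]] = {}
    truth: List[TruthRecord] = []
    n_sites = len(sites.pos)

    for trio in trios:
        male = trio.proband_sex is Sex.MALE
        child_d, mother_d, father_d = _background_genotypes(sites, male, config, rng)
        depths = rng.poisson(config.depth_mean, size=(3, n_sites))
        ratios = rng.uniform(lo, hi, size=(3, n_sites))
        trio_records: List[TrioVariantRecord] = []
        for i in range(n_sites):
            on_x = bool(sites.is_x[i])
            child_gt = _dosage_to_genotype(int(child_d[i]), on_x and male)
            mother_gt = _dosage_to_genotype(int(mother_d[i]), False)
            father_gt = _dosage_to_genotype(int(father_d[i]), on_x)
            trio_records.append(
                TrioVariantRecord(
                    chrom=str(sites.chrom[i]),
                    pos=int(sites.pos[i]),
                    ref=sites.ref[i],
                    alt=sites.alt[i],
                    annotation=sites.annotations[i],
                    proband=SampleCall(child_gt, int(depths[0, i]), float(ratios[0, i] * depths[0, i])),
                    mother=SampleCall(mother_gt, int(depths[1, i]), float(ratios[1, i] * depths[1, i])),
                    father=SampleCall(father_gt, int(depths[2, i]), float(ratios[2, i] * depths[2, i])),
                )
            )
        rates = config.rates_case if group[trio.proband_id] == "case" else config.rates_control
        plant_records, plant_truth = _plant_events(trio, rates, config, rng, factory)
        trio_records.extend(plant_records)
        truth.extend(plant_truth)
        trio_records = _apply_parental_dropout(
            trio_records, config.parental_dropout_rate, rng
        )
        records[trio.proband_id] = trio_records

    cohort = Cohort(
        config=config, trios=trios, group=group, records=records, truth=truth, panel=panel
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


# ---------------------------------------------------------------------------
# On-disk output


def _chrom_sort_key(chrom: str) -> Tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (100, chrom)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write per-trio VCFs, 6-column PED, panel file, truth TSV and config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = sorted(
        {r.chrom for recs in cohort.records.values() for r in recs}, key=_chrom_sort_key
    )
    for trio in cohort.trios:
        recs = sorted(
            cohort.records[trio.proband_id], key=lambda r: (_chrom_sort_key(r.chrom), r.pos)
        )
        write_trio_vcf(out / f"{trio.family_id}.vcf", trio, recs, contigs=contigs)
    with open(out / "cohort.ped", "w") as fh:
        for trio in cohort.trios:
            sex = "1" if trio.proband_sex is Sex.MALE else "2"
            fh.write(f"{trio.family_id}\t{trio.father_id}\t0\t0\t1\t1\n")
            fh.write(f"{trio.family_id}\t{trio.mother_id}\t0\t0\t2\t1\n")
            fh.write(
                f"{trio.family_id}\t{trio.proband_id}\t{trio.father_id}\t{trio.mother_id}\t{sex}\t2\n"
            )
    with open(out / "panel.txt", "w") as fh:
        fh.write("# synthetic cohort panel\n")
        for g in sorted(cohort.panel.genes):
            fh.write(g + "\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write(
            "trio_id\tchrom\tpos\tref\talt\tgene\tplanted_class\t"
            "should_pass_filter\tviolated\tevent_id\n"
        )
        for t in cohort.truth:
            fh.write(
                f"{t.trio_id}\t{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{t.gene}\t"
                f"{t.planted_class}\t{int(t.should_pass_filter)}\t{t.violated}\t{t.event_id}\n"
            )
    with open(out / "manifest_cases.txt", "w") as fh:
        for trio in cohort.case_trios():
            fh.write(f"{trio.family_id}.vcf\n")
    with open(out / "manifest_controls.txt", "w") as fh:
        for trio in cohort.control_trios():
            fh.write(f"{trio.family_id}.vcf\n")
    cfg = dataclasses.asdict(cohort.config)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Truth-table scoring


def truth_events(cohort: Cohort, passing_only: bool = True) -> Dict[str, set]:
    """Planted gene-level events by mode: sets of (trio_id, gene).

    A compound-het event counts as expected only when *all* of its members
    pass the filter (with a single surviving member the pipeline rightly
    cannot call the gene).
    """
    single_modes = {"de_novo": "de_novo", "ar_hom": "AR_homozygous", "xlr": "XLR"}
    out: Dict[str, set] = {
        m: set() for m in ("de_novo", "AR_compound_het", "AR_homozygous", "XLR")
    }
    ch_members: Dict[Tuple[str, str], List[bool]] = {}
    for t in cohort.truth:
        if t.planted_class == "comp_het_member":
            ch_members.setdefault((t.trio_id, t.gene), []).append(t.should_pass_filter)
        elif t.planted_class in single_modes:
            if not passing_only or t.should_pass_filter:
                out[single_modes[t.planted_class]].add((t.trio_id, t.gene))
    for key, passes in ch_members.items():
        if not passing_only or all(passes):
            out["AR_compound_het"].add(key)
    return out


def score_recovery(
    cohort: Cohort,
    monogenic_by_proband: Dict[str, list],
) -> Dict[str, Dict[str, float]]:
    """Recall and precision per monogenic mode against the truth table.

    ``monogenic_by_proband`` maps proband_id to the pipeline's
    MonogenicCandidate lists.  Called events are restricted to the planted
    gene pool's modes; recall/precision are 1.0 on empty-truth classes with
    no calls.
    """
    truth = truth_events(cohort, passing_only=True)
    called: Dict[str, set] = {m: set() for m in truth}
    for pid, candidates in monogenic_by_proband.items():
        for mc in candidates:
            mode = mc.mode.value
            if mode in called:
                called[mode].add((pid, mc.gene))
    scores = {}
    for mode in truth:
        tp = len(called[mode] & truth[mode])
        recall = tp / len(truth[mode]) if truth[mode] else 1.0
        precision = tp / len(called[mode]) if called[mode] else 1.0
        scores[mode] = {
            "recall": recall,
            "precision": precision,
            "n_truth": len(truth[mode]),
            "n_called": len(called[mode]),
        }
    return scores
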