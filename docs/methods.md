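# Methods

## The analysis model

The package implements a two-stage case/control burden design for trio
exomes of sporadic congenital disease. The unit of observation is the trio
(affected proband, two unaffected parents); the unit of counting differs by
stage:

* **Stage 1 (panel burden)** counts *variants*: each rare,
  predicted-pathogenic candidate carried by the proband in a
  pituitary-development panel gene contributes 1, regardless of
  inheritance. This deliberately captures incompletely penetrant and
  potentially oligogenic contributions — a proband with three panel
  variants counts 3.
* **Stage 2 (monogenic burden)** counts *gene-level candidates* under
  fully penetrant models that can explain an affected child of two
  unaffected parents: de novo, autosomal-recessive homozygous,
  autosomal-recessive compound heterozygous, X-linked recessive (male
  probands only). A gene supporting a model counts once per (gene, mode,
  trio) however many variants support it; this makes the per-trio
  candidate arithmetic (17 candidates / 13 trios = 1.3) reproducible. The
  alternative convention — counting supporting variants — would inflate
  compound hets and is not used.

## Candidate definition

All five criteria are strict inequalities, applied to the proband call:
depth > 10; genotype-score/depth > 0.5; population allele frequency < 1%
(a variant absent from the reference database is treated as frequency 0
and kept); database homozygote count < 2 when the proband is homozygous
or hemizygous; protein-altering consequence; and ≥ 2 of 3 damaging
predictor calls for missense. Absent predictor calls count as
non-damaging votes (conservative). Truncating and indel classes
(nonsense, frameshift, canonical splice, in-frame indel) satisfy the
predictor criterion structurally, because the missense predictors largely
cannot score them; such candidates carry a `truncating_bypass` flag.

Manual read-alignment review is not automatable; it is replaced by the
quality thresholds above, and candidates with score/depth < 0.6 are
flagged `review_recommended` for downstream triage.

The genotype-quality dialect is configurable: the FORMAT key defaults to
`MPG` (most probable genotype score) with `GQ` fallback, and only the
score-to-depth ratio enters the criterion, so any caller producing a
genotype-confidence score can be used.

## Transmission classification

Classification operates on one biallelic record at a time. Parental calls
must pass the same quality thresholds before any definitive category is
assigned; otherwise the variant is `unresolved` — parental dropout can
therefore suppress a de novo call but can never fabricate one. For a
heterozygous child, the parental origin is assigned only when it is
*certain*: exactly one parent can have donated the alternate allele while
the other donated the reference (this includes a hom-alt parent with a
het/hom-ref co-parent, and a hemizygous-alt father of a het daughter).
Variants het in child and both parents are phase-ambiguous, classified
`unresolved`, and excluded from compound-het support; no read-backed
phasing is attempted. Genotype triples impossible under Mendelian
transmission (other than the explicit de novo pattern) are `inconsistent`.

On the X chromosome outside the pseudoautosomal regions (PARs; GRCh37
intervals by default, configurable), male probands and fathers are
hemizygous; diploid-coded homozygous calls are remapped on read. A male
X variant with a heterozygous carrier mother and non-carrier father is
`hemizygous_maternal` (the XLR pattern); with a carrier father it is
demoted to plain `maternal`, since the father contributes the Y and a
carrier father muddies the XLR interpretation. A male X variant absent
from the mother is de novo, counted under the de novo mode, not XLR.
Female probands never yield XLR candidates; homozygous female X variants
count as AR-homozygous. PAR variants are treated as autosomal.

## Exact statistics

*Fisher exact test* (proportion of probands with ≥ 1 qualifying variant):
two-sided by the point-probability ("min-like") rule — the sum of
hypergeometric probabilities of all margin-preserving tables no more
probable than the observed one. The computation is exact integer
arithmetic (binomial-coefficient numerators over a common denominator,
summed as a rational), so no tolerance is involved. This rule reproduces
the reference cohort's printed 0.03 and 0.01; the alternative doubling
rule does not.

*Mann-Whitney U* (mean qualifying variants per proband): U from midranks.
The default null is the exact permutation distribution, fully enumerated
when C(n₁+n₂, n₁) ≤ 2×10⁶ and otherwise approximated by a seeded
Monte-Carlo permutation sample (10⁵ draws, add-one corrected); the
p-value is the two-sided tail probability of |U − n₁n₂/2|. At the
reference sample sizes (13 vs 19, C(32,13) ≈ 3.5×10⁸) the Monte-Carlo
path is taken. A tie-corrected normal approximation with continuity
correction is available (`normal_tie_corrected`) and agrees with the
exact mode to ~0.01 at n = 30.

Both implementations are checked in the test suite against independent
brute-force oracles (full table enumeration from the factorial formula;
full label enumeration with library-computed ranks) and against
`scipy.stats` as an external cross-check.

## The synthetic cohort generator

The generator emulates the *structure* the analysis consumes, not
sequencing physics. Defaults are the study conditions: 13 case trios
(5 male probands) vs 19 control trios (12 male); panel-candidate rates
1.1 (case) and 0.21 (control) per proband; gene-level monogenic rates
totalling 1.3 and 2.5 per trio, apportioned 5:6:5:1 across de novo /
compound-het / AR-homozygous / XLR following the reference candidate
table (the XLR rate, 0.2, is per male trio). Event counts are Poisson.

Background sites (400 per cohort by default — enough to exercise every
code path while keeping replicate studies fast; real exomes carry
thousands more) draw each parent's genotype at Hardy-Weinberg equilibrium
from a mixed allele-frequency spectrum (70% common, AF ~ U(0.05, 0.5);
30% rare, AF ~ U(10⁻⁵, 0.01)) and transmit alleles Mendelianly, with X
sites respecting proband sex. Depths are Poisson (mean 40); score/depth
ratios are U(0.6, 0.95); planted-site depths are floored at 12 so a
passing plant cannot fail on a depth fluctuation. About 5% of rare
background missense variants receive ≥ 2 damaging predictor votes,
creating realistic incidental candidate burden.

Three generator choices make recovery exactly scoreable against the truth
table, at a cost in realism:

* every background site has a unique synthetic gene, so compound
  heterozygotes cannot arise from background;
* background X sites draw only common frequencies, so they can never pass
  the rarity criterion (rare background X variants would produce
  legitimate but unplanted XLR-pattern candidates);
* panel plants draw panel genes without replacement per trio, so two
  panel plants cannot accidentally form a compound het.

Planted events pass the filter by construction; *decoy* plants, injected
at `rate × decoy_fraction / (1 − decoy_fraction)` (decoys are 20% of all
plants by default), each violate exactly one recorded criterion. The
configured rates are therefore expected counts of *filter-passing* plants,
which is what the burden analyses recover. `predictor_concordance` < 1
demotes that fraction of would-pass missense plants to predictor-failing
decoys. `genotype_error_rate` perturbs background genotypes only (for
Mendelian-error QC testing); `parental_dropout_rate` drops parental call
quality at any site, converting affected de novo calls to `unresolved`.

What passing tests on synthetic data do **not** show: robustness to
alignment artefacts, multi-nucleotide variants, annotation disagreement
between transcripts, population stratification of allele frequencies, or
linkage disequilibrium — none of which the generator models.

## Numerical and interface choices

* Coordinates are 1-based VCF throughout; indel left-normalization is
  assumed, not enforced. Contig names are normalized by stripping a
  `chr` prefix.
* Multiallelic rows are split into biallelic records; genotypes are
  recoded per alternate allele (other alts collapse to non-carrier) and
  per-allele annotations follow their allele. Carrier dosage is conserved
  across the split.
* Missing population frequency means "not found" and is treated as 0;
  missing homozygote counts impose no constraint.
* Gene symbols are uppercased for panel membership; a user-suppliable
  alias map resolves synonyms (TPIT → TBX19 ships as the default). The
  shipped panel file contains only the individually documented panel
  genes and is marked incomplete; the full 42-gene panel is a runtime
  input.
* Reports: TSV tables plus a versioned JSON with full-precision
  statistics; the display summary rounds means to 2 significant figures
  and p-values to 2 decimals. CLI exit codes: 0 success, 2 configuration
  error, 3 data error.
* Determinism: a single integer seed fixes simulator output
  byte-for-byte and the Monte-Carlo permutation null; the pipeline is
  deterministic given inputs and seed and independent of record order.

## Known limitations

Quality is evaluated on the proband call only in stage 1 (stage 2 adds
the parental gate); whether parental quality should also gate stage-1
candidates is analytically open — the choice here reproduces the
inheritance annotations of the reference tables. Phasing is pedigree-only,
so cis/trans resolution fails exactly where both parents are het.
No imprinting, mosaicism, incomplete-penetrance or digenic scoring is
modelled. Per-gene burden testing is out of scope (the sample sizes this
design targets cannot power it), as is any comparison against public
database cohorts.
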