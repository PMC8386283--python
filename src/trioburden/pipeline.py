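"""End-to-end analysis orchestration.

Two cohort analyses are run over the same filtered candidate sets:

* **Analysis 1 (panel burden)** — per proband, the number of candidate
  variants in a pituitary-development gene panel, regardless of inheritance;
  compared case vs. control by Mann-Whitney (means) and Fisher exact
  (fraction of probands with >= 1 panel variant).
* **Analysis 2 (monogenic burden)** — per trio, the number of gene-level
  candidates consistent with a fully penetrant monogenic model (de novo,
  autosomal recessive, X-linked recessive); compared with the same tests.

The entry points work either from files (pedigree + per-trio VCF manifests,
:func:`run_analysis1` / :func:`run_analysis2` / :func:`run_full`) or from
in-memory record streams (:func:`analyze_cohort`), which the simulator and
the test-suite use directly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .filters import (
    CandidateVariant,
    DEFAULT_THRESHOLDS,
    FilterThresholds,
    filter_candidates,
)
from .inheritance import MonogenicCandidate, annotate_transmission, monogenic_candidates
from .stats import BurdenResult, GenePanel, compare_groups, default_panel, panel_counts
from .trio_io import PAR_GRCH37, read_pedigree, read_trio_vcf
from .types import PedigreeTrio, TrioVariantRecord

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"


class DataError(RuntimeError):
    """Input data is structurally unusable (missing VCF, unmatched trio...)."""


@dataclass
class RunConfig:
    """File-based pipeline configuration."""

    ped_path: Path
    case_manifest: Path
    control_manifest: Path
    panel_path: Optional[Path] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37
    mw_method: str = "exact_permutation"
    seed: int = 0
    out_dir: Optional[Path] = None


@dataclass
class AnalysisReport:
    """Everything the two analyses produce for one cohort run."""

    analysis1: BurdenResult
    analysis2: BurdenResult
    panel_table: pd.DataFrame
    monogenic_table: pd.DataFrame
    candidates_by_proband: Dict[str, List[CandidateVariant]]
    monogenic_by_proband: Dict[str, List[MonogenicCandidate]]
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)


# ---------------------------------------------------------------------------
# Core (in-memory) analysis


def analyze_cohort(
    records_by_proband: Mapping[str, Sequence[TrioVariantRecord]],
    trios: Sequence[PedigreeTrio],
    group: Mapping[str, str],
    panel: GenePanel,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    par_intervals: Sequence[Tuple[int, int]] = PAR_GRCH37,
    mw_method: str = "exact_permutation",
    seed: int = 0,
) -> AnalysisReport:
    """Run both burden analyses on normalized per-trio record streams.

    ``group`` maps proband_id to ``"case"`` or ``"control"``.  Candidate
    filtering and transmission classification are shared between the two
    analyses, so the Analysis-1 variant rows are always a superset of the
    Analysis-2 panel-gene rows for the same trios.
    """
    trio_by_id = {t.proband_id: t for t in trios}
    candidates_by_proband: Dict[str, List[CandidateVariant]] = {}
    monogenic_by_proband: Dict[str, List[MonogenicCandidate]] = {}

    for trio in trios:
        pid = trio.proband_id
        records = records_by_proband.get(pid)
        if records is None:
            raise DataError(f"no records supplied for trio {trio.family_id} ({pid})")
        cands = filter_candidates(records, thresholds)
        annotate_transmission(cands, trio, thresholds, par_intervals)
        candidates_by_proband[pid] = cands
        monogenic_by_proband[pid] = monogenic_candidates(cands, trio)

    case_ids = [t.proband_id for t in trios if group[t.proband_id] == "case"]
    control_ids = [t.proband_id for t in trios if group[t.proband_id] == "control"]
    if not case_ids or not control_ids:
        raise DataError("both a case and a control group are required")

    # Analysis 1: variant-level panel counts per proband
    case_panel = panel_counts({p: candidates_by_proband[p] for p in case_ids}, panel)
    control_panel = panel_counts({p: candidates_by_proband[p] for p in control_ids}, panel)
    analysis1 = compare_groups(case_panel, control_panel, mw_method=mw_method, seed=seed)

    # Analysis 2: gene-level monogenic candidates per trio
    case_mono = [len(monogenic_by_proband[p]) for p in case_ids]
    control_mono = [len(monogenic_by_proband[p]) for p in control_ids]
    analysis2 = compare_groups(case_mono, control_mono, mw_method=mw_method, seed=seed)

    panel_rows = []
    for pid, cands in candidates_by_proband.items():
        trio = trio_by_id[pid]
        for c in cands:
            if c.gene.upper() not in panel.genes:
                continue
            r = c.record
            panel_rows.append(
                {
                    "trio": trio.family_id,
                    "group": group[pid],
                    "gene": c.gene,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "consequence": r.annotation.consequence.value,
                    "inheritance_from": c.transmission.value if c.transmission else "",
                    "population_af": r.annotation.population_af,
                    "review_recommended": c.review_recommended,
                }
            )
    panel_table = pd.DataFrame(
        panel_rows,
        columns=[
            "trio", "group", "gene", "chrom", "pos", "ref", "alt",
            "consequence", "inheritance_from", "population_af", "review_recommended",
        ],
    )

    mono_rows = []
    for pid, mcs in monogenic_by_proband.items():
        trio = trio_by_id[pid]
        for mc in mcs:
            mono_rows.append(
                {
                    "trio": trio.family_id,
                    "group": group[pid],
                    "mode": mc.mode.value,
                    "gene": mc.gene,
                    "n_variants": len(mc.variants),
                    "variants": ";".join(v.record.key for v in mc.variants),
                }
            )
    monogenic_table = pd.DataFrame(
        mono_rows, columns=["trio", "group", "mode", "gene", "n_variants", "variants"]
    )

    return AnalysisReport(
        analysis1=analysis1,
        analysis2=analysis2,
        panel_table=panel_table,
        monogenic_table=monogenic_table,
        candidates_by_proband=candidates_by_proband,
        monogenic_by_proband=monogenic_by_proband,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# File-based entry points


def _load_manifest(path: Path) -> List[Path]:
    base = Path(path).parent
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            p = Path(line)
            out.append(p if p.is_absolute() else base / p)
    if not out:
        raise DataError(f"manifest {path} lists no VCFs")
    return out


def _match_vcfs_to_trios(
    vcf_paths: Sequence[Path], trios: Sequence[PedigreeTrio]
) -> Dict[str, Path]:
    """Match each trio to the VCF containing its three sample columns."""
    from cyvcf2 import VCF

    samples_by_path: Dict[Path, set] = {}
    for p in vcf_paths:
        if not p.exists():
            raise DataError(f"VCF not found: {p}")
        samples_by_path[p] = set(VCF(str(p)).samples)
    mapping: Dict[str, Path] = {}
    for trio in trios:
        needed = {trio.proband_id, trio.mother_id, trio.father_id}
        for p, samples in samples_by_path.items():
            if needed <= samples:
                mapping[trio.proband_id] = p
                break
        else:
            raise DataError(
                f"no VCF in the manifests contains all samples of trio "
                f"{trio.family_id} ({trio.proband_id})"
            )
    return mapping


def load_cohort(
    config: RunConfig,
) -> Tuple[List[PedigreeTrio], Dict[str, str], Dict[str, List[TrioVariantRecord]], GenePanel]:
    """Read pedigree, match VCFs from the two manifests, and stream records."""
    trios = read_pedigree(config.ped_path)
    if not trios:
        raise DataError(f"no complete trios in pedigree {config.ped_path}")
    case_paths = _load_manifest(config.case_manifest)
    control_paths = _load_manifest(config.control_manifest)
    if set(case_paths) & set(control_paths):
        raise DataError("case and control manifests overlap")

    # assign each trio to whichever manifest holds its VCF
    group: Dict[str, str] = {}
    all_map = _match_vcfs_to_trios(case_paths + control_paths, trios)
    case_set = set(case_paths)
    for trio in trios:
        group[trio.proband_id] = "case" if all_map[trio.proband_id] in case_set else "control"

    records: Dict[str, List[TrioVariantRecord]] = {}
    for trio in trios:
        records[trio.proband_id] = list(
            read_trio_vcf(all_map[trio.proband_id], trio, par_intervals=config.par_intervals)
        )
    panel = (
        GenePanel.from_file(config.panel_path) if config.panel_path else default_panel()
    )
    return trios, group, records, panel


def run_full(config: RunConfig) -> AnalysisReport:
    """Load the cohort from files, run both analyses, optionally write reports."""
    trios, group, records, panel = load_cohort(config)
    report = analyze_cohort(
        records,
        trios,
        group,
        panel,
        thresholds=config.thresholds,
        par_intervals=config.par_intervals,
        mw_method=config.mw_method,
        seed=config.seed,
    )
    log.info(
        "thresholds used: depth>%d ratio>%.3g AF<%.3g nhomalt<%d votes>=%d",
        config.thresholds.min_depth_exclusive,
        config.thresholds.min_quality_ratio_exclusive,
        config.thresholds.max_af_exclusive,
        config.thresholds.max_nhomalt_exclusive,
        config.thresholds.min_pathogenic_votes,
    )
    if config.out_dir is not None:
        write_report(report, config.out_dir)
    return report


def run_analysis1(config: RunConfig) -> Tuple[BurdenResult, pd.DataFrame]:
    """Panel-burden analysis: BurdenResult plus the per-variant table."""
    report = run_full(config)
    return report.analysis1, report.panel_table


def run_analysis2(config: RunConfig) -> Tuple[BurdenResult, pd.DataFrame]:
    """Monogenic-candidate analysis: BurdenResult plus the per-trio table."""
    report = run_full(config)
    return report.analysis2, report.monogenic_table


# ---------------------------------------------------------------------------
# Reports


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def summary_frame(report: AnalysisReport) -> pd.DataFrame:
    """Display summary: means to 2 significant figures, p values to 2 decimals."""
    rows = []
    for name, res in (("panel_burden", report.analysis1), ("monogenic_burden", report.analysis2)):
        rows.append(
            {
                "analysis": name,
                "case_mean": _round_sig(res.case_mean),
                "control_mean": _round_sig(res.control_mean),
                "case_pct_ge1": round(100 * res.case_prop_ge1),
                "control_pct_ge1": round(100 * res.control_prop_ge1),
                "p_mannwhitney": round(res.p_mannwhitney, 2),
                "p_fisher": round(res.p_fisher, 2),
            }
        )
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, out_dir: str | Path) -> None:
    """TSV tables + a versioned JSON with full-precision statistics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.panel_table.to_csv(out / "analysis1_panel_variants.tsv", sep="\t", index=False)
    report.monogenic_table.to_csv(
        out / "analysis2_monogenic_candidates.tsv", sep="\t", index=False
    )
    summary_frame(report).to_csv(out / "summary.tsv", sep="\t", index=False)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "thresholds": dataclasses.asdict(report.thresholds),
        "analysis1_panel_burden": report.analysis1.to_dict(),
        "analysis2_monogenic_burden": report.analysis2.to_dict(),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
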