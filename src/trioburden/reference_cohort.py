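"""Published summary data of the reference case-control trio cohort.

The pipeline was designed around a published trio-exome study of 13 sporadic
congenital hypopituitarism probands versus 19 probands with non-familial
short stature (NFSS) as controls.  The raw sequence data are controlled
access, but the study's result tables — which probands carried which
rare, predicted-pathogenic panel variants, and which gene-level monogenic
candidates each trio yielded — are public.  This module encodes those tables
so the counting and statistics operations can be exercised against known
published quantities.

Only summary-level content is encoded (gene symbols, per-proband groupings,
inheritance modes); no sequence-level data.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

# -- Panel screen (42 pituitary-development genes, counted per variant) -----

#: Panel-gene candidate variants per case proband (one inner list per
#: proband; empty list = no panel candidate).  Two probands carried more
#: than one variant (CDON+ARID1B; LHX4+CDON+SIX5 and GLI1+SOX3+CHD7 triples).
CASE_PANEL_VARIANTS: List[List[str]] = [
    ["CDON", "ARID1B"],
    ["SIX6"],
    ["SIX1"],
    ["LHX4", "CDON", "SIX5"],
    ["ARID1B"],
    ["GLI1", "SOX3", "CHD7"],
    ["GLI4"],
    ["LHX3"],
    [],
    [],
    [],
    [],
    [],
]

#: Panel-gene candidate variants per NFSS control proband.
CONTROL_PANEL_VARIANTS: List[List[str]] = [
    ["CHD7"],
    ["LHX4"],
    ["LHX4"],
    ["WNT5A"],
] + [[] for _ in range(15)]


# -- Genome-wide monogenic candidates (counted per gene-level candidate) ----

#: (mode, gene) gene-level monogenic candidates per case trio.
CASE_MONOGENIC: List[List[Tuple[str, str]]] = [
    [("de_novo", "TTLL4"), ("AR_compound_het", "TNXB")],
    [("de_novo", "KLHDC4")],
    [("de_novo", "MARCH3"), ("AR_compound_het", "PER2"), ("AR_compound_het", "FLG")],
    [("de_novo", "CRHR1"), ("XLR", "GPC3")],
    [("AR_homozygous", "TTLL6"), ("AR_homozygous", "DCAKD")],
    [],
    [],
    [("AR_compound_het", "PDE4DIP")],
    [("AR_compound_het", "CEP128")],
    [("AR_homozygous", "MET")],
    [("AR_homozygous", "PRRG2")],
    [("de_novo", "GJB5"), ("AR_homozygous", "ACADVL"), ("AR_compound_het", "RGPD3")],
    [],
]

#: Control probands carrying a candidate in a gene already established to
#: cause their phenotype (short stature): 8 of 19; no case proband carried a
#: candidate in an established hypopituitarism gene (0 of 13).
CONTROL_CAUSATIVE_GENES: List[str] = [
    "BRF1",
    "QRICH1",
    "FBN1",
    "HUWE1",
    "SRCAP",
    "ACAN",
    "ZEB2",
    "CUL7",
]

N_CASE_TRIOS = len(CASE_PANEL_VARIANTS)  # 13
N_CONTROL_TRIOS = len(CONTROL_PANEL_VARIANTS)  # 19


def panel_variant_counts() -> Tuple[List[int], List[int]]:
    """Per-proband panel-variant counts (case, control)."""
    return (
        [len(v) for v in CASE_PANEL_VARIANTS],
        [len(v) for v in CONTROL_PANEL_VARIANTS],
    )


def monogenic_counts_case() -> List[int]:
    """Gene-level monogenic candidate counts per case trio."""
    return [len(v) for v in CASE_MONOGENIC]


def unique_case_panel_genes() -> List[str]:
    """Distinct panel genes hit in the case group (11 genes)."""
    return sorted({g for v in CASE_PANEL_VARIANTS for g in v})


def causative_contingency() -> List[List[int]]:
    """2x2 table: probands with vs. without an established causative candidate."""
    n_ctrl = len(CONTROL_CAUSATIVE_GENES)
    return [[0, N_CASE_TRIOS], [n_ctrl, N_CONTROL_TRIOS - n_ctrl]]


def monogenic_mode_tally() -> Dict[str, int]:
    tally: Dict[str, int] = {}
    for trio in CASE_MONOGENIC:
        for mode, _ in trio:
            tally[mode] = tally.get(mode, 0) + 1
    return tally
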