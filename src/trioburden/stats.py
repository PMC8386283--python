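"""Burden comparisons and exact statistics.

Two cohort-level comparisons are supported, both case vs. control over
per-proband counts:

* mean qualifying variants per proband — Mann-Whitney U test (exact
  permutation null by default at these sample sizes);
* fraction of probands with >= 1 qualifying variant — Fisher exact test on
  the 2x2 table, two-sided by the point-probability rule.

Both tests are implemented here from first principles in exact integer /
rational arithmetic where feasible; the test suite cross-checks them against
brute-force enumeration and independent library implementations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .filters import CandidateVariant

#: default gene-symbol aliases applied when loading a panel
DEFAULT_ALIASES = {"TPIT": "TBX19"}


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols, uppercase-normalized."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel must be non-empty")
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.genes

    @classmethod
    def from_symbols(
        cls,
        symbols: Iterable[str],
        name: str = "panel",
        aliases: Optional[Mapping[str, str]] = None,
    ) -> "GenePanel":
        aliases = DEFAULT_ALIASES if aliases is None else aliases
        resolved = {aliases.get(s.upper(), s.upper()) for s in symbols}
        return cls(name=name, genes=frozenset(resolved))

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        name: Optional[str] = None,
        aliases: Optional[Mapping[str, str]] = None,
    ) -> "GenePanel":
        """One symbol per line; '#' starts a comment."""
        symbols = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if line:
                    symbols.append(line)
        return cls.from_symbols(symbols, name=name or Path(path).stem, aliases=aliases)


def default_panel() -> GenePanel:
    """The pituitary-development gene panel shipped with the package.

    Note: the shipped list covers the panel genes that are individually
    documented in this package's reference material and is marked INCOMPLETE
    in the data file; a full user-supplied panel file is the intended input
    for faithful cohort screening.
    """
    path = Path(__file__).parent / "data" / "panel_pituitary.txt"
    return GenePanel.from_file(path, name="pituitary_development")


# ---------------------------------------------------------------------------
# Counting


def panel_counts(
    candidates_by_proband: Mapping[str, Sequence[CandidateVariant]],
    panel: GenePanel,
) -> List[int]:
    """Variant-level count of panel-gene candidates per proband.

    A proband carrying candidates in three distinct panel genes counts 3;
    two candidate variants in the same panel gene also count 2 (counting is
    per variant, not per gene).  Order follows the mapping's iteration order.
    """
    return [
        sum(c.gene.upper() in panel.genes for c in cands)
        for cands in candidates_by_proband.values()
    ]


# ---------------------------------------------------------------------------
# Fisher exact test (2x2, two-sided, point-probability rule)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table
    (the point-probability or "min-like" two-sided rule).  Computed in exact
    integer arithmetic: for cell value k the probability numerator is
    C(r1, k) * C(r2, c1 - k) over the constant denominator C(n, c1), so the
    comparison and the sum are both exact.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0  # degenerate margin: only one table possible

    def numer(k: int) -> int:
        return math.comb(r1, k) * math.comb(r2, c1 - k)

    obs = numer(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(numer(k) for k in range(lo, hi + 1) if numer(k) <= obs)
    return float(Fraction(total, math.comb(n, c1)))


def fisher_point_probability(table: Sequence[Sequence[int]]) -> float:
    """Hypergeometric probability of the observed table itself."""
    (a, b), (c, d) = table
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    return float(
        Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), math.comb(n, c1))
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged) of a 1-D array."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1  # average of ranks i+1..j+1
        i = j + 1
    return ranks


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    method: str = "exact_permutation",
    seed: int = 0,
    max_enumeration: int = 2_000_000,
    n_resamples: int = 100_000,
) -> Tuple[float, float]:
    """Mann-Whitney U statistic (for sample ``a``) and two-sided p.

    U is computed from midranks.  ``exact_permutation`` enumerates every
    label assignment when C(n_a + n_b, n_a) <= ``max_enumeration`` and falls
    back to a seeded Monte-Carlo permutation null (>= ``n_resamples`` draws)
    otherwise; the p-value is the tail probability of ``|U - E[U]|`` under
    the permutation null.  ``normal_tie_corrected`` uses the tie-corrected
    Gaussian approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    mu = na * nb / 2.0
    dev = abs(u_a - mu)
    tol = 1e-9 * max(1.0, mu)

    if method == "normal_tie_corrected":
        n = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float((counts**3 - counts).sum())
        sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            return u_a, 1.0
        # continuity correction of 0.5 toward the mean
        z = max(dev - 0.5, 0.0) / math.sqrt(sigma2)
        return u_a, math.erfc(z / math.sqrt(2))

    if method != "exact_permutation":
        raise ValueError(f"unknown method {method!r}")

    n = na + nb
    offset = na * (na + 1) / 2
    if math.comb(n, na) <= max_enumeration:
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), na):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - tol:
                count += 1
        return u_a, count / total
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    chunk = 20_000
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, na - 1, axis=1)[:, :na]
        u = ranks[idx].sum(axis=1) - offset
        count += int((np.abs(u - mu) >= dev - tol).sum())
        done += m
    # add-one keeps the Monte-Carlo p strictly positive and conservative
    return u_a, (count + 1) / (n_resamples + 1)


# ---------------------------------------------------------------------------
# Group comparison


@dataclass
class BurdenResult:
    """Per-group per-proband counts with summary statistics and exact p values."""

    case_counts: List[int]
    control_counts: List[int]
    case_mean: float
    control_mean: float
    case_prop_ge1: float
    control_prop_ge1: float
    u_statistic: float
    p_mannwhitney: float
    p_fisher: float
    contingency: List[List[int]] = field(default_factory=list)

    def to_dict(self) -> Dict:
        return {
            "case_counts": list(map(int, self.case_counts)),
            "control_counts": list(map(int, self.control_counts)),
            "case_mean": self.case_mean,
            "control_mean": self.control_mean,
            "case_prop_ge1": self.case_prop_ge1,
            "control_prop_ge1": self.control_prop_ge1,
            "u_statistic": self.u_statistic,
            "p_mannwhitney": self.p_mannwhitney,
            "p_fisher": self.p_fisher,
            "contingency": self.contingency,
        }


def compare_groups(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    mw_method: str = "exact_permutation",
    seed: int = 0,
) -> BurdenResult:
    """Full burden comparison of two per-proband count vectors.

    The 2x2 table for the Fisher test is
    ``[[case >=1, case ==0], [control >=1, control ==0]]``.
    """
    case_counts = list(case_counts)
    control_counts = list(control_counts)
    if not case_counts or not control_counts:
        raise ValueError("both groups must be non-empty")
    case_ge1 = sum(c >= 1 for c in case_counts)
    ctrl_ge1 = sum(c >= 1 for c in control_counts)
    table = [
        [case_ge1, len(case_counts) - case_ge1],
        [ctrl_ge1, len(control_counts) - ctrl_ge1],
    ]
    u, p_mw = mann_whitney_u(case_counts, control_counts, method=mw_method, seed=seed)
    return BurdenResult(
        case_counts=case_counts,
        control_counts=control_counts,
        case_mean=sum(case_counts) / len(case_counts),
        control_mean=sum(control_counts) / len(control_counts),
        case_prop_ge1=case_ge1 / len(case_counts),
        control_prop_ge1=ctrl_ge1 / len(control_counts),
        u_statistic=u,
        p_mannwhitney=p_mw,
        p_fisher=fisher_exact_2x2(table),
        contingency=table,
    )
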