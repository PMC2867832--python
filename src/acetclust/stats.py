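"""Association tests, expression-tier subsetting, and per-cluster feature tables.

Contingency tables are represented as :class:`pandas.DataFrame` with labeled
rows (clusters) and columns (feature categories).  Every test returns a
:class:`TestResult`; Bonferroni correction is ``min(1, m·p)`` with ``m``
recorded alongside.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import PromoterTable

TIER_NAMES = ("low", "medium", "high")


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | None
    p: float
    p_bonferroni: float | None = None
    m: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p <= 1):
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    def corrected(self, m: int) -> "TestResult":
        return TestResult(self.name, self.statistic, self.df, self.p, bonferroni(self.p, m), m)

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_bonferroni": self.p_bonferroni,
            "m": self.m,
        }


# ---------------------------------------------------------------------------
# Rank-based tests (shared core for probe p-values and expression comparisons)


def mann_whitney_pvalue(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Rank-sum (Mann-Whitney U) p-value with the pipeline's method policy.

    Exact null enumeration when the pooled sample is small (≤ 25) and tie-free;
    otherwise the tie-corrected normal approximation (no continuity
    correction).  Returns ``(U of the first sample, p)``.  A fully tied pooled
    sample returns p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> TestResult:
    stat, p = mann_whitney_pvalue(a, b, alternative)
    return TestResult("wilcoxon_rank_sum", stat, None, p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis test with the chi-square approximation."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, float(len(groups) - 1), 1.0)
    stat, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(len(groups) - 1), float(p))


# ---------------------------------------------------------------------------
# Contingency-table tests


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(arr < 0):
        raise ValueError("negative cell count")
    return arr


def chi_square_test(table) -> TestResult:
    """Pearson chi-square of independence, Σ (O−E)²/E, df = (r−1)(c−1)."""
    observed = _as_table(table)
    row = observed.sum(axis=1)
    col = observed.sum(axis=0)
    total = observed.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(row, col) / total
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult("chi_square", stat, float(df), p)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test (point-probability rule) on a 2×2 table."""
    observed = _as_table(table)
    if observed.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2×2 table")
    odds, p = sps.fisher_exact(observed.astype(int), alternative="two-sided")
    return TestResult("fisher_exact", float(odds), None, float(p))


def bonferroni(p: float, m: int) -> float:
    if m < 1:
        raise ValueError("m must be ≥ 1")
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# Per-cluster feature tables

BINARY_FEATURES = ("architecture", "cpg", "gene", "lincrna", "tata", "repeat")
CLUSTER_ORDER = ("upstream", "centered", "downstream")


def feature_by_cluster_table(
    labels: Mapping[str, str], annotations: pd.DataFrame, feature: str
) -> pd.DataFrame:
    """Cross-tabulate cluster label against one feature column.

    ``annotations`` is indexed by promoter id.  ``architecture`` yields SP/BR
    columns; the boolean flags yield yes/no columns; ``repeat_class`` yields
    one column per planted repeat class (non-repeat promoters excluded).
    """
    if feature not in set(BINARY_FEATURES) | {"repeat_class"}:
        raise ValueError(f"unknown feature {feature!r}")
    ids = [i for i in annotations.index if i in labels]
    if len(ids) != len(labels):
        missing = sorted(set(labels) - set(annotations.index))
        raise ValueError(f"promoters missing from annotations: {missing[:5]}")
    sub = annotations.loc[ids]
    row = pd.Series({i: labels[i] for i in ids}, name="cluster")
    if feature == "architecture":
        col = sub["architecture"]
        col_order = ["SP", "BR"]
    elif feature == "repeat_class":
        mask = sub["repeat"].astype(bool)
        row, col = row[mask], sub.loc[mask, "repeat_class"]
        col_order = sorted(col.dropna().unique())
    else:
        col = sub[feature].map(lambda v: "yes" if bool(v) else "no")
        col_order = ["yes", "no"]
    table = pd.crosstab(row, col)
    row_order = [c for c in CLUSTER_ORDER if c in table.index] + [
        c for c in table.index if c not in CLUSTER_ORDER
    ]
    table = table.reindex(index=row_order, columns=col_order, fill_value=0)
    table.index.name, table.columns.name = "cluster", feature
    return table


# ---------------------------------------------------------------------------
# Expression tiers


@dataclass(frozen=True)
class ExpressionTiers:
    """Bottom/top ``fraction`` of promoters by tpm, middle as ``medium``."""

    tier_by_id: Mapping[str, str]
    timepoint: str
    n_low: int
    n_high: int
    low_max_tpm: float
    high_min_tpm: float

    def ids_in(self, tier: str) -> list[str]:
        return [i for i, t in self.tier_by_id.items() if t == tier]


def expression_tiers(
    promoters: PromoterTable,
    timepoint: str = "0h",
    fraction: float = 0.10,
    strict: bool = True,
) -> ExpressionTiers:
    """Tier promoters by expression with exact tier sizes regardless of ties.

    Stable sort by ``(tpm, id)``; the bottom ``floor(fraction·n)`` promoters
    are ``low``, the top ``floor(fraction·n)`` are ``high``.  With fewer than
    ``1/fraction`` promoters: error when ``strict``, else tier size 1.
    """
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    missing = [p.id for p in promoters if timepoint not in p.tpm]
    if missing:
        raise ValueError(f"no tpm at {timepoint} for {missing[:5]}")
    n = len(promoters)
    q = int(np.floor(fraction * n))
    if q == 0:
        if strict:
            raise ValueError(f"cannot form {fraction:.0%} tiers from {n} promoters")
        q = 1
    ranked = sorted(promoters, key=lambda p: (p.tpm[timepoint], p.id))
    tiers: dict[str, str] = {}
    for i, p in enumerate(ranked):
        if i < q:
            tiers[p.id] = "low"
        elif i >= n - q:
            tiers[p.id] = "high"
        else:
            tiers[p.id] = "medium"
    return ExpressionTiers(
        tier_by_id=tiers,
        timepoint=timepoint,
        n_low=q,
        n_high=q,
        low_max_tpm=float(ranked[q - 1].tpm[timepoint]),
        high_min_tpm=float(ranked[n - q].tpm[timepoint]),
    )


def repeat_fraction_by_tier(
    tiers: ExpressionTiers, annotations: pd.DataFrame
) -> dict[str, float | None]:
    """Fraction of promoters in each tier whose core promoter overlaps a repeat."""
    out: dict[str, float | None] = {}
    for tier in TIER_NAMES:
        ids = tiers.ids_in(tier)
        if not ids:
            out[tier] = None
            continue
        flags = annotations.loc[ids, "repeat"].astype(bool)
        out[tier] = float(flags.mean())
    return out
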