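"""Nonparametric battery for the longitudinal cohort analyses.

Repeated measures within a group are compared by the Friedman test with
Dunn's multiple-comparison test against a reference timepoint; paired two
groups by the Wilcoxon matched-pairs signed-rank test; unpaired two groups
(TdP >=3 vs TdP 0-1 animals) by the Mann-Whitney U test.  All tests are
two-sided, significance at p < 0.05.  Missing animals are removed listwise
within each test.  Mann-Whitney p-values are exact by enumeration at the
study's sample sizes (n_a + n_b <= 12, tie-safe) and tie-corrected normal
approximation above; Wilcoxon is exact for n <= 25 without ties.

Also here: the >=2-fold / <=0.5-fold expression flagging used for the
microarray summary table, and a boundary-inclusive physiological-range
check.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


# ---------------------------------------------------------------- Friedman


@dataclass
class FriedmanDunnResult:
    statistic: float
    pvalue: float
    n: int
    k: int
    rank_means: pd.Series
    comparisons: pd.DataFrame  # timepoint, z, p_raw, p_adj, significant


def friedman_dunn(
    grid: pd.DataFrame,
    reference,
    alpha: float = ALPHA,
) -> FriedmanDunnResult:
    """Friedman test over an animal x timepoint grid, then Dunn's test of
    each timepoint against ``reference`` with Bonferroni adjustment.

    Rows with any missing cell are dropped (listwise deletion).  Dunn's
    z-statistic is (Rbar_i - Rbar_ref) / sqrt(k(k+1)/(6n)) on the
    within-animal ranks.
    """
    if reference not in grid.columns:
        raise ValueError(f"reference timepoint {reference!r} not in grid")
    complete = grid.dropna(axis=0, how="any")
    n, k = complete.shape
    if n < 2:
        raise ValueError("need at least 2 complete animals")
    if k < 2:
        raise ValueError("need at least 2 timepoints")
    if (complete.nunique(axis=1) == 1).all():
        # every animal fully tied across timepoints: degenerate chi-square
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.friedmanchisquare(
            *(complete[c].to_numpy() for c in complete.columns)
        )
    ranks = complete.rank(axis=1)
    rank_means = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    others = [c for c in complete.columns if c != reference]
    m = len(others)
    rows = []
    for c in others:
        z = (rank_means[c] - rank_means[reference]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m)
        rows.append(
            {
                "timepoint": c,
                "z": float(z),
                "p_raw": float(p_raw),
                "p_adj": float(p_adj),
                "significant": bool(p_adj < alpha),
            }
        )
    return FriedmanDunnResult(
        statistic=float(stat),
        pvalue=float(p),
        n=int(n),
        k=int(k),
        rank_means=rank_means,
        comparisons=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------- Wilcoxon


def wilcoxon_signed_rank(x, y=None, exact_max_n: int = 25):
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Pass paired samples (x, y) or differences (x alone).  Zero differences
    are dropped; the exact null distribution is used for n <= ``exact_max_n``
    untied differences, the normal approximation otherwise.
    Returns (W, p) with W the signed-rank statistic of scipy's convention.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------ Mann-Whitney


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of sample a: pairs with a > b plus half the tied pairs."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_u(group_a, group_b, exact_max_total: int = 12):
    """Mann-Whitney U test, two-sided.

    Exact p by complete enumeration of the C(n_a+n_b, n_a) group labelings
    when the pooled size is <= ``exact_max_total`` (correct under ties);
    tie-corrected normal approximation with continuity correction above.
    Returns (U_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    n_tot = a.size + b.size
    if n_tot <= exact_max_total:
        pooled = np.concatenate([a, b])
        mu = a.size * b.size / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = comb(n_tot, a.size)
        idx = np.arange(n_tot)
        for pick in combinations(idx, a.size):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(pick)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


# ------------------------------------------------------------- fold change


@dataclass(frozen=True)
class FoldChange:
    gene: str
    mean_avb: float
    mean_intact: float
    fold: float  # reported to 2 decimals, half-up
    flagged: bool


def fold_change_flag(mean_avb: float, mean_intact: float, gene: str = "") -> FoldChange:
    """Fold change vs intact with the >=2 / <=0.5 report flag.

    The flag is applied to the 2-decimal reported value, so a fold printing
    as exactly 2.00 or 0.50 is flagged.
    """
    if mean_avb <= 0 or mean_intact <= 0:
        raise ValueError("group means must be positive")
    fold = float(
        Decimal(repr(mean_avb / mean_intact)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return FoldChange(gene, mean_avb, mean_intact, fold, fold >= 2.0 or fold <= 0.5)


def flag_fold_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the fold-change flag to a table with a ``fold_change`` column."""
    out = df.copy()
    out["flagged"] = (out["fold_change"] >= 2.0) | (out["fold_change"] <= 0.5)
    return out


# ------------------------------------------------------------- range check


def range_check(value: float, low: float, high: float) -> str:
    """Boundary-inclusive membership in a physiological range.

    Returns 'within', 'outside-low' or 'outside-high'.
    """
    if not low < high:
        raise ValueError("range requires low < high")
    if value < low:
        return "outside-low"
    if value > high:
        return "outside-high"
    return "within"
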