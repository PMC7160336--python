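"""Group-wise statistics and clustering for cohort comparisons.

Two flavors of the Wilcoxon test back every group comparison in the
pipeline: the unpaired rank-sum (Mann–Whitney U) test for contrasts
between different patients (e.g. AHSCT vs NTZ) and the paired signed-rank
test for within-patient t0 vs t24 contrasts.  Small tie-free samples
(combined n ≤ 12) use the exact null distribution; larger or tied samples
the normal approximation with tie correction, as R's ``wilcox.test`` does.

Hierarchical clustering of correlation matrices uses correlation-based
distance d = 1 − r; degree heatmaps cluster observation rows by Euclidean
distance.  Both delegate to :mod:`scipy.cluster.hierarchy`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

EXACT_MAX_COMBINED_N = 12


@dataclass(slots=True)
class GroupComparison:
    statistic_name: str
    group_a: str
    group_b: str
    test: str  # 'rank_sum_unpaired' | 'signed_rank_paired'
    method: str  # 'exact' | 'asymptotic' | 'degenerate'
    n_a: int
    n_b: int
    statistic_value: float
    p_value: float
    note: str = ""


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def group_compare(
    values_a,
    values_b,
    test: str = "rank_sum_unpaired",
    statistic_name: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-sided Wilcoxon comparison of two value vectors.

    Unpaired: Mann–Whitney U, exact when combined n ≤ 12 without ties.
    Paired: signed-rank on matched-order vectors; all-zero differences are
    a degenerate no-shift case, flagged with p = NaN rather than tested.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if test == "rank_sum_unpaired":
        if a.size == 0 or b.size == 0:
            raise ValueError("both groups must be non-empty")
        pooled = np.concatenate([a, b])
        exact = a.size + b.size <= EXACT_MAX_COMBINED_N and not _has_ties(pooled)
        method = "exact" if exact else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p, note = float(res.statistic), float(res.pvalue), ""
    elif test == "signed_rank_paired":
        if a.size != b.size:
            raise ValueError(
                f"paired test needs equal lengths, got {a.size} and {b.size}"
            )
        if a.size == 0:
            raise ValueError("paired test needs at least one pair")
        d = a - b
        if np.all(d == 0):
            stat, p = 0.0, float("nan")
            method, note = "degenerate", "all differences zero (no shift)"
        else:
            exact = a.size <= EXACT_MAX_COMBINED_N and not _has_ties(
                np.abs(d[d != 0])
            ) and not np.any(d == 0)
            method = "exact" if exact else "asymptotic"
            res = sps.wilcoxon(a, b, alternative="two-sided", method=method)
            stat, p, note = float(res.statistic), float(res.pvalue), ""
    else:
        raise ValueError(f"unknown test: {test!r}")
    return GroupComparison(
        statistic_name=statistic_name, group_a=group_a, group_b=group_b,
        test=test, method=method, n_a=int(a.size), n_b=int(b.size),
        statistic_value=stat, p_value=p, note=note,
    )


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    """Long table of comparisons with BH-adjusted p-values and star markers."""
    rows = [
        {
            "statistic": c.statistic_name,
            "group_a": c.group_a,
            "group_b": c.group_b,
            "test": c.test,
            "method": c.method,
            "n_a": c.n_a,
            "n_b": c.n_b,
            "statistic_value": c.statistic_value,
            "p_value": c.p_value,
            "note": c.note,
        }
        for c in comparisons
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    padj = np.full(len(df), np.nan)
    ok = df["p_value"].notna().to_numpy()
    if ok.any():
        padj[ok] = sps.false_discovery_control(df.loc[ok, "p_value"].to_numpy())
    df["p_adj_bh"] = padj
    df["significance"] = [
        "**" if p < 0.01 else "*" if p < 0.05 else ""
        for p in df["p_value"].fillna(1.0)
    ]
    return df


@dataclass(slots=True)
class ClusteringResult:
    distance: str
    linkage_method: str
    merges: np.ndarray  # scipy linkage matrix (n−1 × 4)
    leaf_order: list[str] = field(default_factory=list)


def hierarchical_cluster(
    matrix,
    distance: str = "one_minus_pearson",
    linkage: str = "average",
    labels=None,
) -> ClusteringResult:
    """Agglomerative clustering of a correlation/distance/observation matrix.

    distance='one_minus_pearson': *matrix* is a square symmetric correlation
    matrix, converted via d = 1 − r.  distance='precomputed': a square
    symmetric distance matrix used as-is.  distance='euclidean': rows of
    *matrix* are observations; pairwise Euclidean distances are computed.
    The merge tree and leaf order are deterministic for a given input.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.index)
        matrix = matrix.to_numpy()
    m = np.asarray(matrix, dtype=float)
    if distance in ("one_minus_pearson", "precomputed"):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("square matrix required for this distance mode")
        if not np.allclose(m, m.T, atol=1e-10, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        d = 1.0 - m if distance == "one_minus_pearson" else m.copy()
        # r can exceed 1 by round-off; forgive only that
        d[(d < 0) & (d > -1e-9)] = 0.0
        np.fill_diagonal(d, 0.0)
        condensed = squareform(d, checks=False)
    elif distance == "euclidean":
        condensed = pdist(m, metric="euclidean")
    else:
        raise ValueError(f"unknown distance: {distance!r}")
    merges = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(merges)
    if labels is None:
        labels = list(range(m.shape[0]))
    return ClusteringResult(
        distance=distance,
        linkage_method=linkage,
        merges=merges,
        leaf_order=[labels[i] for i in order],
    )
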