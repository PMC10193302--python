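"""Differential expression and variance-driven gene clustering.

The differential test is the same NB Wald machinery used for chromatin
occupancy, applied to gene-level 3'-end counts, with the significance flag
at |log2FC| > 1 and BH-adjusted p < 0.05.  Downstream, counts are
variance-stabilized (shifted log of normalized counts), the top-variance
genes selected, Z-scored and clustered by Ward-linkage agglomeration with
the number of clusters picked by the elbow (maximum second difference of
the within-cluster sum of squares).  Per-cluster responsiveness of
co-occupied (ETNN) versus other genes is compared by the two-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import mannwhitneyu

from .occupancy import nb_wald_test

LFC_CUTOFF = 1.0
PADJ_CUTOFF = 0.05


def de_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
    size_factors: Mapping[str, float],
    dispersions: np.ndarray | None = None,
    lfc_cutoff: float = LFC_CUTOFF,
    padj_cutoff: float = PADJ_CUTOFF,
) -> pd.DataFrame:
    """Gene-level NB Wald differential expression test.

    Identical contract to the occupancy test (shared implementation), plus a
    ``significant`` flag at |log2FC| > ``lfc_cutoff`` and padj < ``padj_cutoff``.
    """
    res = nb_wald_test(counts, design, contrast, size_factors, dispersions)
    res["significant"] = (np.abs(res["log2fc"]) > lfc_cutoff) & (
        res["padj"] < padj_cutoff
    )
    return res


def vst_transform(
    counts: pd.DataFrame,
    size_factors: Mapping[str, float],
    zscore: bool = False,
) -> pd.DataFrame:
    """Shifted-log variance stabilization: ``log2(count / s + 1)``.

    A proxy for the regularized transforms of NB differential tools: simple,
    monotone and variance-flattening across the mean range.  With
    ``zscore=True`` rows are centred and scaled to unit variance (constant
    rows stay 0).
    """
    s = np.array([size_factors[c] for c in counts.columns], dtype=float)
    x = np.log2(counts.to_numpy(dtype=float) / s + 1.0)
    out = pd.DataFrame(x, index=counts.index, columns=counts.columns)
    if zscore:
        mu = out.mean(axis=1)
        sd = out.std(axis=1, ddof=0)
        out = out.sub(mu, axis=0).div(sd.replace(0.0, 1.0), axis=0)
    return out


def top_variance_genes(stabilized: pd.DataFrame, n: int = 3000) -> list[str]:
    """Top-``n`` genes by row variance, ties broken by gene id."""
    if n > len(stabilized):
        raise ValueError(f"requested {n} genes but matrix has {len(stabilized)}")
    var = stabilized.var(axis=1, ddof=0)
    order = sorted(stabilized.index, key=lambda g: (-var[g], str(g)))
    return list(order[:n])


def _wss_for_labels(x: np.ndarray, labels: np.ndarray) -> float:
    tot = 0.0
    for lab in np.unique(labels):
        sub = x[labels == lab]
        tot += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return tot


def cluster_genes(
    matrix: pd.DataFrame,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 10),
) -> tuple[pd.DataFrame, int]:
    """Ward-linkage hierarchical clustering with elbow-selected k.

    Rows are Z-scored, Euclidean distances taken and Ward agglomeration
    applied (deterministic; no random initialization).  When ``k`` is not
    given it is chosen over ``k_range`` as the argmax of the second
    difference of the within-cluster sum of squares (the elbow).

    Returns ``(assignments, k)``; assignments has columns ``cluster_id``
    (1..k) and the Z-scored profile columns.
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 genes to cluster")
    x = matrix.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    if np.allclose(z, z[0]):
        warnings.warn("all profiles identical; single cluster")
        out = pd.DataFrame({"cluster_id": np.ones(len(matrix), dtype=int)}, index=matrix.index)
        return pd.concat([out, pd.DataFrame(z, index=matrix.index, columns=matrix.columns)], axis=1), 1
    link = linkage(z, method="ward")
    if k is None:
        lo, hi = k_range
        hi = min(hi, len(matrix) - 1)
        ks = np.arange(max(lo - 1, 1), hi + 2)
        wss = np.array(
            [_wss_for_labels(z, fcluster(link, t=kk, criterion="maxclust")) for kk in ks]
        )
        # second difference WSS(k-1) - 2 WSS(k) + WSS(k+1), maximised over interior
        second = wss[:-2] - 2 * wss[1:-1] + wss[2:]
        interior = ks[1:-1]
        mask = (interior >= lo) & (interior <= hi)
        k = int(interior[mask][np.argmax(second[mask])])
    labels = fcluster(link, t=k, criterion="maxclust")
    out = pd.DataFrame({"cluster_id": labels}, index=matrix.index)
    return (
        pd.concat([out, pd.DataFrame(z, index=matrix.index, columns=matrix.columns)], axis=1),
        int(k),
    )


def ward_merge_heights(matrix: pd.DataFrame) -> np.ndarray:
    """Agglomeration merge heights of the Ward tree (non-decreasing)."""
    x = matrix.to_numpy(dtype=float)
    return linkage(x, method="ward")[:, 2]


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_max: int = 8
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when ``min(n, m) <= exact_max`` and there are no ties;
    otherwise the normal approximation with tie correction.
    Returns NaN when either group is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def group_lfc_compare(
    de_results: pd.DataFrame,
    clusters: pd.DataFrame,
    etnn_genes: set[str],
) -> pd.DataFrame:
    """Per-cluster comparison of DE fold changes: ETNN vs non-ETNN genes.

    For each cluster, the log2 fold changes of member genes in the ETNN set
    are compared to those of the remaining members by the two-sided Wilcoxon
    rank-sum test.  Clusters with an empty group report NaN.
    """
    rows = []
    for cid, sub in clusters.groupby("cluster_id"):
        members = sub.index
        in_set = [g for g in members if g in etnn_genes and g in de_results.index]
        out_set = [g for g in members if g not in etnn_genes and g in de_results.index]
        lx = de_results.loc[in_set, "log2fc"].to_numpy()
        ly = de_results.loc[out_set, "log2fc"].to_numpy()
        p = wilcoxon_rank_sum(lx, ly)
        rows.append(
            {
                "cluster_id": cid,
                "n_etnn": len(lx),
                "n_other": len(ly),
                "median_lfc_etnn": float(np.median(lx)) if len(lx) else np.nan,
                "median_lfc_other": float(np.median(ly)) if len(ly) else np.nan,
                "wilcoxon_p": p,
            }
        )
    return pd.DataFrame(rows)
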