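"""Spike-in-normalized negative-binomial differential occupancy.

Counts over a consensus region set are modelled per region as
``K_ij ~ NB(mean = s_j * q_g(j), dispersion = alpha_i)`` with
``Var = mu + alpha * mu^2``; ``s_j`` is a per-sample size factor (spike-in
derived or median-of-ratios) and ``q_g`` a per-group mean concentration.
The contrast log2 fold change is ``log2(q_B / q_A)``; its Wald statistic
uses the asymptotic per-group Fisher information, two-sided p-values come
from the normal reference, and multiplicity is controlled by
Benjamini-Hochberg.  On top sits the combinatorial loss/gain classifier:
regions are grouped by the strict sign pattern of their per-factor fold
changes and retained if at least one factor's adjusted p falls under a
permissive screen (default 0.5), the two-step filter behind the concordant
"TNN loss" class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .intervals import multi_overlap

ALPHA_FLOOR = 1e-8


@dataclass
class SampleMeta:
    """Per-sample metadata for one ChIP library."""

    sample_id: str
    factor: str
    genotype: str
    condition: str
    replicate: int
    spikein_count: int
    library_count: int

    def __post_init__(self) -> None:
        if self.spikein_count < 0:
            raise ValueError(f"{self.sample_id}: spikein_count must be >= 0")
        if self.library_count <= 0:
            raise ValueError(f"{self.sample_id}: library_count must be > 0")


def spikein_scaling(samples: Sequence[SampleMeta]) -> dict[str, float]:
    """Multiplicative normalization factors from exogenous spike-in reads.

    ``factor_i`` is proportional to ``1 / spikein_count_i`` and the set is
    rescaled to geometric mean 1, so a sample with twice the spike-in depth
    is scaled down twofold relative to the rest.
    """
    counts = np.array([s.spikein_count for s in samples], dtype=float)
    if np.any(counts == 0):
        bad = [s.sample_id for s, c in zip(samples, counts) if c == 0]
        raise ValueError(
            f"zero spike-in count for {bad}; use estimate_size_factors instead"
        )
    raw = 1.0 / counts
    raw /= np.exp(np.mean(np.log(raw)))
    return {s.sample_id: float(f) for s, f in zip(samples, raw)}


def estimate_size_factors(counts: pd.DataFrame) -> dict[str, float]:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each region present (nonzero) in every sample, the ratio of each
    sample's count to the region's geometric mean is taken; a sample's
    factor is the median of its ratios.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no region with nonzero counts in all samples")
    sub = mat[all_nonzero]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return {s: float(f) for s, f in zip(counts.columns, factors)}


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: Mapping[str, float],
    groups: Mapping[str, str] | None = None,
    prior_df: float = 10.0,
) -> np.ndarray:
    """Per-region NB dispersion ``alpha`` with mean-trend shrinkage.

    Method-of-moments within-group residual variance gives a raw per-region
    estimate; a trend ``alpha(mu) = a/mu + b`` is fit across regions and the
    final estimate shrinks the raw value toward the trend on the log scale
    with weight ``prior_df`` against the residual degrees of freedom.
    Estimates are floored at ``ALPHA_FLOOR``.

    Raises if any group has fewer than 2 replicates.
    """
    s = np.array([size_factors[c] for c in counts.columns], dtype=float)
    if groups is None:
        groups = {c: "all" for c in counts.columns}
    labels = np.array([groups[c] for c in counts.columns])
    uniq = np.unique(labels)
    for g in uniq:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has <2 replicates; cannot estimate alpha")
    x = counts.to_numpy(dtype=float) / s  # normalized counts
    n = x.shape[1]
    df = n - len(uniq)
    mu = np.zeros_like(x)
    for g in uniq:
        idx = labels == g
        mu[:, idx] = x[:, idx].mean(axis=1, keepdims=True)
    resid_var = ((x - mu) ** 2).sum(axis=1) / max(df, 1)
    mu_bar = x.mean(axis=1)
    # Var(K/s) = mu/s + alpha mu^2  =>  alpha = (v - mu * E[1/s]) / mu^2
    shot = mu_bar * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (resid_var - shot) / np.maximum(mu_bar, 1e-12) ** 2
    raw = np.clip(raw, ALPHA_FLOOR, 10.0)
    # trend alpha(mu) = a/mu + b on informative regions
    ok = (mu_bar > 1) & (raw > ALPHA_FLOOR * 2)
    if ok.sum() >= 10:
        A = np.column_stack([1.0 / mu_bar[ok], np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(A, raw[ok], rcond=None)
        a, b = float(max(coef[0], 0.0)), float(max(coef[1], ALPHA_FLOOR))
    else:
        a, b = 0.0, float(np.median(raw))
    trend = np.clip(a / np.maximum(mu_bar, 1e-12) + b, ALPHA_FLOOR, 10.0)
    w = prior_df / (prior_df + df)
    alpha = np.exp((1.0 - w) * np.log(raw) + w * np.log(trend))
    return np.clip(alpha, ALPHA_FLOOR, 10.0)


def _fit_group_mean(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-region NB MLE of the group concentration q.

    Solves the score equation ``sum_j (K_j - s_j q) / (1 + alpha s_j q) = 0``
    by Newton iteration.  Returns (q_hat, var_log_q) with the variance from
    the observed Fisher information; regions with all-zero counts get q=0
    and infinite variance.
    """
    tot_k = k.sum(axis=1)
    tot_s = s.sum()
    q = np.maximum(tot_k / tot_s, 1e-12)
    for _ in range(n_iter):
        denom = 1.0 + alpha[:, None] * s[None, :] * q[:, None]
        score = ((k - s[None, :] * q[:, None]) / denom).sum(axis=1)
        dscore = (
            -(s[None, :] * (1.0 + alpha[:, None] * k)) / denom**2
        ).sum(axis=1)
        step = score / np.where(dscore < 0, dscore, -1e-12)
        q = np.maximum(q - step, 1e-12)
    info = (s[None, :] * q[:, None] / (1.0 + alpha[:, None] * s[None, :] * q[:, None])).sum(
        axis=1
    ) * (1.0 / np.maximum(q, 1e-12))
    var_log_q = np.where(info > 0, 1.0 / np.maximum(info * q, 1e-300), np.inf)
    zero = tot_k == 0
    q = np.where(zero, 0.0, q)
    var_log_q = np.where(zero, np.inf, var_log_q)
    return q, var_log_q


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    contrast: tuple[str, str, str],
    size_factors: Mapping[str, float],
    dispersions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region two-group NB Wald test.

    ``design`` maps sample ids (index) to covariates; ``contrast`` is
    ``(column, group_B, group_A)`` and the reported log2 fold change is
    B over A.  Regions with all-zero counts in both groups are flagged
    (``degenerate``) with p = 1.  Adjusted p-values are Benjamini-Hochberg
    over all tested regions.
    """
    col, gB, gA = contrast
    samples_A = design.index[design[col] == gA]
    samples_B = design.index[design[col] == gB]
    if len(samples_A) == 0 or len(samples_B) == 0:
        raise ValueError(f"contrast groups {gA!r}/{gB!r} not both present in design")
    if dispersions is None:
        sub = counts[list(samples_A) + list(samples_B)]
        groups = {c: gA for c in samples_A} | {c: gB for c in samples_B}
        dispersions = estimate_dispersions(sub, size_factors, groups)
    alpha = np.asarray(dispersions, dtype=float)
    kA = counts[list(samples_A)].to_numpy(dtype=float)
    kB = counts[list(samples_B)].to_numpy(dtype=float)
    sA = np.array([size_factors[c] for c in samples_A], dtype=float)
    sB = np.array([size_factors[c] for c in samples_B], dtype=float)
    qA, varA = _fit_group_mean(kA, sA, alpha)
    qB, varB = _fit_group_mean(kB, sB, alpha)
    ln2 = np.log(2.0)
    qA_f = np.maximum(qA, 1e-8)
    qB_f = np.maximum(qB, 1e-8)
    log2fc = (np.log(qB_f) - np.log(qA_f)) / ln2
    se = np.sqrt(varA + varB) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), log2fc / se, 0.0)
    pvals = 2.0 * norm.sf(np.abs(z))
    degenerate = (kA.sum(axis=1) == 0) & (kB.sum(axis=1) == 0)
    pvals = np.where(degenerate, 1.0, pvals)
    log2fc = np.where(degenerate, 0.0, log2fc)
    n_tot = np.concatenate([sA, sB]).sum()
    base_mean = (kA.sum(axis=1) + kB.sum(axis=1)) / n_tot
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_p": pvals,
            "padj": bh_adjust(pvals),
            "degenerate": degenerate,
        },
        index=counts.index,
    )


def bh_adjust(pvals: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaNs are propagated and excluded from the number of tests m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    m = len(q)
    if m == 0:
        return out
    order = np.argsort(q, kind="mergesort")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def combinatorial_classes(
    results_by_factor: Mapping[str, pd.DataFrame],
    fdr_cut: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step combinatorial loss/gain classification across factors.

    Step 1 groups every region by the strict signs of its per-factor log2
    fold changes (any exactly-zero LFC excludes the region from sign
    grouping; those are reported separately).  Step 2 retains a region only
    if the minimum of the factors' adjusted p-values is below ``fdr_cut``
    ("FDR screened in at least one factor").  For the three co-repressor
    factors the all-negative group is the concordant-loss ("TNN loss")
    class.

    Returns ``(classified, excluded_zero_lfc)``; ``classified`` has columns
    ``group`` (e.g. ``Ncor1-&Ncor2-&Tbl1x-``), ``concordant`` (loss / gain /
    mixed), ``min_fdr`` and per-factor ``lfc_<factor>`` columns.
    """
    factors = list(results_by_factor)
    if len(factors) == 0:
        raise ValueError("no factor results given")
    idx = results_by_factor[factors[0]].index
    for f in factors[1:]:
        if not results_by_factor[f].index.equals(idx):
            raise ValueError(f"region index of factor {f!r} does not match")
    lfc = pd.DataFrame({f: results_by_factor[f]["log2fc"] for f in factors})
    padj = pd.DataFrame({f: results_by_factor[f]["padj"] for f in factors})
    zero = (lfc == 0.0).any(axis=1)
    min_fdr = padj.min(axis=1)
    keep = (~zero) & (min_fdr < fdr_cut)
    signs = np.sign(lfc[keep])
    group = signs.apply(
        lambda row: "&".join(f"{f}{'+' if row[f] > 0 else '-'}" for f in factors),
        axis=1,
    ) if keep.any() else pd.Series(dtype=object)
    concordant = signs.apply(
        lambda row: "loss"
        if (row < 0).all()
        else ("gain" if (row > 0).all() else "mixed"),
        axis=1,
    ) if keep.any() else pd.Series(dtype=object)
    classified = pd.DataFrame(
        {
            "group": group,
            "concordant": concordant,
            "min_fdr": min_fdr[keep],
        }
    )
    for f in factors:
        classified[f"lfc_{f}"] = lfc.loc[keep, f]
    excluded = lfc[zero].copy()
    return classified, excluded


def concordant_loss_label(factors: Sequence[str]) -> str:
    """Group label of the all-factors-lost class (e.g. TNN loss)."""
    return "&".join(f"{f}-" for f in factors)


def condition_peak_dynamics(
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    label_a: str = "SR",
    label_b: str = "PD",
) -> pd.DataFrame:
    """Partition two conditions' peaks into A-specific / common / B-specific.

    The union of both sets is merged; a merged region is "common" when both
    conditions contribute >= 1 bp, otherwise specific to its sole
    contributor.  The partition is exhaustive and disjoint over the union.
    """
    classes, _ = multi_overlap({label_a: peaks_a, label_b: peaks_b})
    mapping = {
        label_a: f"{label_a}-specific",
        label_b: f"{label_b}-specific",
        "&".join(sorted([label_a, label_b])): "common",
    }
    return classes.assign(category=classes["members"].map(mapping))
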