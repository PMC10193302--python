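"""Replicate reproducibility (IDR) and merged reference peak-set construction.

The irreproducible discovery rate model treats each peak's pair of replicate
scores as a draw from a two-component Gaussian copula mixture: a
"reproducible" component with correlated latent scores (mean ``mu``, sd
``sigma``, correlation ``rho``) and an "irreproducible" standard-normal
component with independent coordinates.  Scores are rank-transformed to
pseudo-values through the inverse mixture marginal CDF and the mixture is
fit by EM; a peak's local idr is its posterior probability of coming from
the irreproducible component, and the global idr at a rank cutoff is the
expected irreproducibility among peaks at or above that rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .intervals import INTERVAL_COLS, merge_intervals, sort_intervals, validate_intervals

#: Below this many score pairs the copula fit is unstable; fall back to
#: plain replicate intersection.
MIN_PAIRS_FOR_IDR = 50


def pair_replicate_peaks(
    peaks_rep1: pd.DataFrame, peaks_rep2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Greedy best-overlap one-to-one matching of two replicate peak sets.

    Candidate pairs are all (rep1, rep2) peaks sharing >= 1 bp; pairs are
    taken in decreasing overlap length (ties broken by coordinates) with
    each peak used at most once.  Returns ``(pairs, unmatched1, unmatched2)``;
    the pair interval is the union span of its two peaks.
    """
    validate_intervals(peaks_rep1, "rep1")
    validate_intervals(peaks_rep2, "rep2")
    p1 = sort_intervals(peaks_rep1).reset_index(drop=True)
    p2 = sort_intervals(peaks_rep2).reset_index(drop=True)
    cands: list[tuple[int, str, int, int, int, int]] = []
    for i, r1 in p1.iterrows():
        sub = p2[
            (p2["chrom"] == r1["chrom"])
            & (p2["start"] < r1["end"])
            & (p2["end"] > r1["start"])
        ]
        for j, r2 in sub.iterrows():
            ov = min(int(r1["end"]), int(r2["end"])) - max(
                int(r1["start"]), int(r2["start"])
            )
            cands.append((-ov, r1["chrom"], int(r1["start"]), int(r2["start"]), i, j))
    cands.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    rows = []
    for _, _, _, _, i, j in cands:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        r1, r2 = p1.iloc[i], p2.iloc[j]
        rows.append(
            {
                "chrom": r1["chrom"],
                "start": min(int(r1["start"]), int(r2["start"])),
                "end": max(int(r1["end"]), int(r2["end"])),
                "score_rep1": float(r1.get("score", 0.0)),
                "score_rep2": float(r2.get("score", 0.0)),
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "score_rep1", "score_rep2"]
    )
    unmatched1 = p1.drop(index=list(used1)).reset_index(drop=True)
    unmatched2 = p2.drop(index=list(used2)).reset_index(drop=True)
    if len(pairs) == 0:
        warnings.warn("no overlapping peaks between replicates; empty pairing")
    return pairs, unmatched1, unmatched2


@dataclass
class IdrFit:
    """Fitted copula-mixture parameters and per-peak idr values."""

    pi1: float  # reproducible proportion
    rho: float
    mu: float
    sigma: float
    local_idr: np.ndarray
    global_idr: np.ndarray
    n_iter: int
    converged: bool
    #: log pseudo-likelihood trajectories, one array per EM stage (pseudo-
    #: values are fixed within a stage, so each trajectory is non-decreasing)
    loglik_traces: list[np.ndarray] = field(default_factory=list)
    method: str = "idr"


def _mixture_marginal_inverse(
    u: np.ndarray, pi1: float, mu: float, sigma: float
) -> np.ndarray:
    lo = min(-8.0, mu - 8.0 * sigma)
    hi = max(8.0, mu + 8.0 * sigma)
    grid = np.linspace(lo, hi, 4096)
    cdf = (1.0 - pi1) * norm.cdf(grid) + pi1 * norm.cdf((grid - mu) / sigma)
    return np.interp(u, cdf, grid)


def _bivariate_logpdf(
    z1: np.ndarray, z2: np.ndarray, mu: float, sigma: float, rho: float
) -> np.ndarray:
    s2 = sigma * sigma
    det = s2 * s2 * (1.0 - rho * rho)
    a = (z1 - mu) / sigma
    b = (z2 - mu) / sigma
    quad = (a * a - 2.0 * rho * a * b + b * b) / (1.0 - rho * rho)
    return -np.log(2.0 * np.pi) - 0.5 * np.log(det) - 0.5 * quad


def _em_step(
    z1: np.ndarray,
    z2: np.ndarray,
    pi1: float,
    rho: float,
    mu: float,
    sigma: float,
) -> tuple[float, float, float, float, float]:
    """One EM iteration on fixed pseudo-values; returns (ll, new params)."""
    n = len(z1)
    a = np.log(pi1) + _bivariate_logpdf(z1, z2, mu, sigma, rho)
    b = np.log1p(-pi1) + norm.logpdf(z1) + norm.logpdf(z2)
    m = np.maximum(a, b)
    log_mix = m + np.log(np.exp(a - m) + np.exp(b - m))
    ll = float(np.sum(log_mix))
    gamma = np.exp(a - log_mix)
    sg = float(np.sum(gamma))
    pi1 = float(np.clip(sg / n, 1e-4, 1.0 - 1e-4))
    if sg > 0:
        mu = float(np.sum(gamma * (z1 + z2)) / (2.0 * sg))
        var = float(np.sum(gamma * ((z1 - mu) ** 2 + (z2 - mu) ** 2)) / (2.0 * sg))
        sigma = float(np.sqrt(max(var, 1e-6)))
        rho = float(
            np.clip(
                np.sum(gamma * (z1 - mu) * (z2 - mu)) / (sg * sigma * sigma),
                -0.999,
                0.999,
            )
        )
    return ll, pi1, rho, mu, sigma


def fit_idr(
    scores1: np.ndarray,
    scores2: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
    init: tuple[float, float, float, float] = (0.5, 0.8, 2.0, 1.0),
    param_tol: float = 1e-4,
) -> IdrFit:
    """Fit the two-component copula mixture to a pair of score vectors.

    Scores are rank-transformed (average ranks) to uniforms and mapped
    through the inverse mixture marginal CDF to pseudo-values.  Fitting has
    two phases: a tracking phase in which the pseudo-values are refreshed
    from the current parameters before every EM iteration (the estimates
    follow the moving target until parameter changes fall below
    ``param_tol``), then a final phase on frozen pseudo-values in which
    plain EM runs to a log-likelihood change below ``tol`` — within this
    phase the log pseudo-likelihood is monotone non-decreasing.

    Raises ``RuntimeError`` if the final EM phase fails to converge within
    ``max_iter`` iterations.
    """
    x = np.asarray(scores1, dtype=float)
    y = np.asarray(scores2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score vectors must be 1-D and equal length")
    n = len(x)
    u1 = (rankdata(x) - 0.5) / n
    u2 = (rankdata(y) - 0.5) / n
    pi1, rho, mu, sigma = init
    track_trace = []
    total_iter = 0
    for _ in range(max_iter):
        total_iter += 1
        z1 = _mixture_marginal_inverse(u1, pi1, mu, sigma)
        z2 = _mixture_marginal_inverse(u2, pi1, mu, sigma)
        ll, npi, nrho, nmu, nsig = _em_step(z1, z2, pi1, rho, mu, sigma)
        track_trace.append(ll)
        delta = max(
            abs(npi - pi1), abs(nrho - rho), abs(nmu - mu), abs(nsig - sigma)
        )
        pi1, rho, mu, sigma = npi, nrho, nmu, nsig
        if delta < param_tol:
            break
    # final phase: frozen pseudo-values, monotone EM to likelihood tolerance
    z1 = _mixture_marginal_inverse(u1, pi1, mu, sigma)
    z2 = _mixture_marginal_inverse(u2, pi1, mu, sigma)
    final_trace = []
    last_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        total_iter += 1
        ll, pi1, rho, mu, sigma = _em_step(z1, z2, pi1, rho, mu, sigma)
        final_trace.append(ll)
        if abs(ll - last_ll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        last_ll = ll
    if not converged:
        raise RuntimeError(
            f"IDR EM did not converge in {max_iter} final iterations "
            f"(pi1={pi1:.3f}, rho={rho:.3f}, mu={mu:.3f}, sigma={sigma:.3f})"
        )
    traces = [np.asarray(track_trace), np.asarray(final_trace)]
    # posterior with converged parameters
    z1 = _mixture_marginal_inverse(u1, pi1, mu, sigma)
    z2 = _mixture_marginal_inverse(u2, pi1, mu, sigma)
    log_f1 = _bivariate_logpdf(z1, z2, mu, sigma, rho)
    log_f0 = norm.logpdf(z1) + norm.logpdf(z2)
    a = np.log(pi1) + log_f1
    b = np.log1p(-pi1) + log_f0
    m = np.maximum(a, b)
    log_mix = m + np.log(np.exp(a - m) + np.exp(b - m))
    local_idr = np.exp(b - log_mix)
    order = np.argsort(local_idr, kind="mergesort")
    global_sorted = np.cumsum(local_idr[order]) / np.arange(1, n + 1)
    # peaks with equal local idr share one global idr (last of the tie block)
    lv = local_idr[order]
    block_end = np.concatenate([np.flatnonzero(lv[1:] != lv[:-1]), [n - 1]])
    global_sorted = global_sorted[block_end[np.searchsorted(block_end, np.arange(n))]]
    global_idr = np.empty(n)
    global_idr[order] = global_sorted
    return IdrFit(
        pi1=pi1,
        rho=rho,
        mu=mu,
        sigma=sigma,
        local_idr=local_idr,
        global_idr=global_idr,
        n_iter=total_iter,
        converged=True,
        loglik_traces=traces,
    )


def idr_filter(
    pairs: pd.DataFrame, alpha: float = 0.05, **fit_kwargs
) -> tuple[pd.DataFrame, IdrFit | None]:
    """Retain peak pairs with global IDR <= ``alpha``.

    Returns the audit table (scores, local/global idr, pass flag) restricted
    columns plus the fit.  Below ``MIN_PAIRS_FOR_IDR`` pairs the copula fit
    is skipped and every overlapping pair passes (intersection fallback,
    flagged via a ``method`` column and a warning).
    """
    audit = pairs.copy()
    if len(pairs) < MIN_PAIRS_FOR_IDR:
        warnings.warn(
            f"only {len(pairs)} pairs (<{MIN_PAIRS_FOR_IDR}); "
            "falling back to replicate intersection"
        )
        audit["local_idr"] = 0.0
        audit["global_idr"] = 0.0
        audit["pass"] = True
        audit["method"] = "intersection"
        return audit, None
    fit = fit_idr(
        pairs["score_rep1"].to_numpy(), pairs["score_rep2"].to_numpy(), **fit_kwargs
    )
    audit["local_idr"] = fit.local_idr
    audit["global_idr"] = fit.global_idr
    audit["pass"] = fit.global_idr <= alpha
    audit["method"] = "idr"
    return audit, fit


def idr_filter_multi(
    replicate_peaks: Sequence[pd.DataFrame], alpha: float = 0.05
) -> pd.DataFrame:
    """IDR across >2 replicates: intersection of all pairwise passing sets.

    Each unordered replicate pair is run through pairing + IDR; a peak of the
    first replicate passes overall iff it lies inside a passing pair region in
    every pairwise run it can participate in.  With exactly two replicates
    this reduces to ``idr_filter`` on their pairing.
    """
    k = len(replicate_peaks)
    if k < 2:
        raise ValueError("need >= 2 replicates")
    pass_regions: list[pd.DataFrame] = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs, _, _ = pair_replicate_peaks(replicate_peaks[i], replicate_peaks[j])
            audit, _ = idr_filter(pairs, alpha=alpha)
            pass_regions.append(audit[audit["pass"]][list(INTERVAL_COLS)])
    out = pass_regions[0]
    for other in pass_regions[1:]:
        keep = []
        for _, r in out.iterrows():
            sub = other[
                (other["chrom"] == r["chrom"])
                & (other["start"] < r["end"])
                & (other["end"] > r["start"])
            ]
            keep.append(len(sub) > 0)
        out = out[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    return sort_intervals(out)


def build_consensus(idr_sets: Mapping[tuple | str, pd.DataFrame]) -> pd.DataFrame:
    """Merge high-confidence peaks of all factors/conditions into one
    reference peak-set, retaining per-region provenance.

    Provenance is the ``&``-joined sorted list of input keys contributing at
    least 1 bp to the merged region.
    """
    if len(idr_sets) == 0:
        raise ValueError("need at least one input peak set")
    keys = [k if isinstance(k, str) else "/".join(map(str, k)) for k in idr_sets]
    pooled = pd.concat(
        [df[list(INTERVAL_COLS)] for df in idr_sets.values()], ignore_index=True
    )
    merged = merge_intervals(pooled)
    sources = []
    dfs = list(idr_sets.values())
    for _, row in merged.iterrows():
        hit = []
        for key, df in zip(keys, dfs):
            sub = df[
                (df["chrom"] == row["chrom"])
                & (df["start"] < row["end"])
                & (df["end"] > row["start"])
            ]
            if len(sub):
                hit.append(key)
        sources.append("&".join(sorted(hit)))
    return merged.assign(sources=sources)
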