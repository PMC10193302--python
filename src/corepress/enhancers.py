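"""ROSE-style enhancer stitching, super-enhancer calling and gene linkage.

Acetylated-histone (H3K27ac) peaks outside promoters are chained into
stitched enhancer domains (gaps up to the stitching distance, default
12.5 kb, after removing peaks fully contained in a TSS exclusion window,
default +/- 2.5 kb).  Each domain is scored by its background-subtracted
aggregate signal and ranked; scaling both rank and signal to [0, 1], the
super-enhancer cutoff is the signal at the point where a slope-1 line is
tangent to the ranked curve from below (the discrete tangent rule), and
domains above it are super-enhancers (SE), the rest regular enhancers (RE).
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd

from .intervals import (
    INTERVAL_COLS,
    merge_intervals,
    nearest_gene,
    sort_intervals,
    validate_intervals,
)

STITCH_DISTANCE = 12_500
TSS_EXCLUSION = 2_500


def stitch_enhancers(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    stitch_distance: int = STITCH_DISTANCE,
    tss_exclusion: int = TSS_EXCLUSION,
) -> pd.DataFrame:
    """Chain non-promoter peaks into stitched enhancer domains.

    Peaks fully contained in ``TSS +/- tss_exclusion`` of any gene are
    removed first; partially overlapping peaks are retained.  Remaining
    peaks on a chromosome are chained while consecutive gaps are
    <= ``stitch_distance``.  Returns one row per stitched domain with the
    span, number of constituents and a ``constituents`` column holding
    ``(start, end)`` tuples.
    """
    validate_intervals(peaks)
    peaks = sort_intervals(merge_intervals(peaks))
    keep = []
    for _, p in peaks.iterrows():
        g = genes[genes["chrom"] == p["chrom"]]
        contained = (
            (g["tss"] - tss_exclusion <= p["start"]) & (p["end"] <= g["tss"] + tss_exclusion)
        ).any() if len(g) else False
        keep.append(not contained)
    peaks = peaks[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    rows = []
    for chrom, sub in peaks.groupby("chrom", sort=True):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        chain: list[tuple[int, int]] = [(int(s[0]), int(e[0]))] if len(s) else []
        for i in range(1, len(s)):
            if int(s[i]) - chain[-1][1] <= stitch_distance:
                chain.append((int(s[i]), int(e[i])))
            else:
                rows.append((chrom, chain[0][0], chain[-1][1], tuple(chain)))
                chain = [(int(s[i]), int(e[i]))]
        if chain:
            rows.append((chrom, chain[0][0], chain[-1][1], tuple(chain)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "constituents"])


def _coverage_sum(
    chrom: str, start: int, end: int, track: pd.DataFrame
) -> float:
    """Integral of a bedGraph track over [start, end)."""
    sub = track[(track["chrom"] == chrom) & (track["start"] < end) & (track["end"] > start)]
    if len(sub) == 0:
        return 0.0
    ov = np.minimum(sub["end"].to_numpy(), end) - np.maximum(sub["start"].to_numpy(), start)
    return float(np.sum(ov * sub["value"].to_numpy()))


def score_and_rank(
    stitched: pd.DataFrame,
    signal_track: pd.DataFrame,
    control_track: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score stitched domains by background-subtracted constituent coverage.

    Signal per domain is the sum over constituents of (sample - control)
    coverage integrals, clamped at 0.  Domains with no coverage are warned
    about and scored 0.  Ranks ascend with signal (1 = weakest); ties break
    by span start.
    """
    signals = []
    any_missing = False
    for _, row in stitched.iterrows():
        tot = 0.0
        covered = False
        for cs, ce in row["constituents"]:
            v = _coverage_sum(row["chrom"], cs, ce, signal_track)
            if v != 0.0:
                covered = True
            c = (
                _coverage_sum(row["chrom"], cs, ce, control_track)
                if control_track is not None and len(control_track)
                else 0.0
            )
            tot += v - c
        if not covered:
            any_missing = True
        signals.append(max(tot, 0.0))
    if any_missing:
        warnings.warn("some stitched domains had no signal coverage; scored 0")
    out = stitched.copy()
    out["signal"] = signals
    order = np.lexsort((out["start"].to_numpy(), out["signal"].to_numpy()))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return out.sort_values("rank").reset_index(drop=True)


def split_super(
    ranked: pd.DataFrame, min_prominence: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Label super-enhancers by the tangent-slope-1 rule on the ranked curve.

    Rank and signal are each scaled to [0, 1].  The cutoff point is where a
    line of slope 1 is tangent to the rank-signal curve from below: the
    index maximising (scaled rank - scaled signal), i.e. the point at which
    the finite-difference slope of the curve last rises through 1 (for a
    noisy curve this discrete tangent construction is the stable form of
    the slope rule; a first-crossing scan fires on local jitter).  Ties take
    the highest rank.  Enhancers with signal strictly above the cutoff
    signal are super-enhancers.  A maximum diagonal gap below
    ``min_prominence`` (default: the one-sided Kolmogorov-Smirnov 1%
    critical deviation for n points) means the curve has no convex kink
    distinguishable from a tier-free landscape and none are called;
    all-equal signals likewise yield no SEs (warning).

    Returns ``(table_with_is_super, cutoff_signal)`` on the original scale.
    """
    out = ranked.sort_values("rank").reset_index(drop=True).copy()
    n = len(out)
    if n < 3:
        raise ValueError("need >= 3 enhancers to place a cutoff")
    sig = out["signal"].to_numpy(dtype=float)
    smin, smax = sig.min(), sig.max()
    if smax == smin:
        warnings.warn("all enhancer signals equal; no super-enhancers")
        out["is_super"] = False
        return out, float("inf")
    x = np.arange(n) / (n - 1)
    y = (sig - smin) / (smax - smin)
    gap = x - y
    if min_prominence is None:
        # one-sided KS 1% band: a tier-free landscape (signals with no heavy
        # tail) produces diagonal dips up to ~sqrt(log(1/a)/2n) by chance
        min_prominence = float(np.sqrt(np.log(100.0) / (2.0 * n)))
    if gap.max() < min_prominence:
        # no convex kink: the curve does not dip below its diagonal, so a
        # slope-1 tangent touches only the endpoints -> no SE tier exists
        warnings.warn("rank curve has no tangent kink; no super-enhancers")
        out["is_super"] = False
        return out, float("inf")
    i = int(np.flatnonzero(gap >= gap.max() - 1e-9)[-1])  # ties -> highest rank
    cutoff = y[i] * (smax - smin) + smin
    out["is_super"] = sig > cutoff
    return out, float(cutoff)


def enhancer_gene_sets(
    enhancers: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """Associate each enhancer with its closest gene and split SE/RE genes.

    Returns the table with a ``gene_id`` column plus the deduplicated
    SE-gene and RE-gene sets.
    """
    annotated = nearest_gene(enhancers[list(INTERVAL_COLS) + []], genes)
    out = enhancers.copy()
    out["gene_id"] = annotated["gene_id"].to_numpy()
    se_genes = set(out.loc[out["is_super"] & out["gene_id"].notna(), "gene_id"])
    re_genes = set(out.loc[~out["is_super"] & out["gene_id"].notna(), "gene_id"])
    return out, se_genes, re_genes


def etnn_enhancer_intersection(
    enhancers: pd.DataFrame,
    etnn_regions: pd.DataFrame,
    de_genes_up: set[str],
    de_genes_down: set[str],
) -> dict:
    """Intersect enhancer catalogue with co-occupied (ETNN) regions and DE.

    An enhancer is ETNN-bound iff its span shares >= 1 bp with any ETNN
    region.  Gene sets (SE vs RE, ETNN-restricted) are intersected with the
    up/down differential-expression lists; a 2x2 contingency of
    SE-vs-RE x regulated-vs-not over ETNN-bound enhancer genes is returned
    for enrichment reporting.
    """
    bound = []
    for _, row in enhancers.iterrows():
        sub = etnn_regions[
            (etnn_regions["chrom"] == row["chrom"])
            & (etnn_regions["start"] < row["end"])
            & (etnn_regions["end"] > row["start"])
        ]
        bound.append(len(sub) > 0)
    enh = enhancers.assign(etnn_bound=bound)
    regulated = de_genes_up | de_genes_down
    sets = {}
    for super_flag, label in ((True, "ETNN_SE"), (False, "ETNN_RE")):
        g = set(
            enh.loc[enh["etnn_bound"] & (enh["is_super"] == super_flag), "gene_id"].dropna()
        )
        sets[label] = g
        sets[f"{label}_up"] = g & de_genes_up
        sets[f"{label}_down"] = g & de_genes_down
    table = np.array(
        [
            [len(sets["ETNN_SE"] & regulated), len(sets["ETNN_SE"] - regulated)],
            [len(sets["ETNN_RE"] & regulated), len(sets["ETNN_RE"] - regulated)],
        ]
    )
    a, b = table[0]
    c, d = table[1]
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return {"enhancers": enh, "gene_sets": sets, "contingency": table, "odds_ratio": odds}
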