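"""Independent brute-force oracles used across the test suite.

These deliberately take the dumbest correct path (per-base boolean masks,
exhaustive enumeration, O(m^2) scans) and never share code with the
implementation they check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd


def mask_merge_oracle(intervals: pd.DataFrame, genome_len: int = 100_000):
    """Merged intervals recovered from a per-base boolean mask."""
    out = []
    for chrom in sorted(set(intervals["chrom"])):
        mask = np.zeros(genome_len, dtype=bool)
        sub = intervals[intervals["chrom"] == chrom]
        for _, r in sub.iterrows():
            mask[int(r["start"]) : int(r["end"])] = True
        padded = np.concatenate([[False], mask, [False]])
        diff = np.diff(padded.astype(int))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            out.append((chrom, int(s), int(e)))
    return out


def multi_overlap_oracle(named_sets: dict, genome_len: int = 100_000):
    """Membership classes from per-base masks, regrouped to merged regions."""
    names = list(named_sets)
    pooled = pd.concat([df for df in named_sets.values()], ignore_index=True)
    merged = mask_merge_oracle(pooled, genome_len)
    classes = []
    for chrom, s, e in merged:
        members = []
        for n in names:
            sub = named_sets[n]
            hit = (
                (sub["chrom"] == chrom) & (sub["start"] < e) & (sub["end"] > s)
            ).any()
            if hit:
                members.append(n)
        classes.append((chrom, s, e, tuple(sorted(members))))
    return classes


def stitch_closure_oracle(peaks: pd.DataFrame, stitch_distance: int):
    """Stitched partition by transitive closure of the gap relation."""
    spans = []
    for chrom in sorted(set(peaks["chrom"])):
        sub = peaks[peaks["chrom"] == chrom].sort_values("start")
        items = list(zip(sub["start"], sub["end"]))
        n = len(items)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                gap = max(items[i][0], items[j][0]) - min(items[i][1], items[j][1])
                if gap <= stitch_distance:
                    pi, pj = find(i), find(j)
                    parent[pi] = pj
        groups: dict[int, list] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(items[i])
        for members in groups.values():
            spans.append(
                (chrom, min(m[0] for m in members), max(m[1] for m in members))
            )
    return sorted(spans)


def bh_oracle(pvals):
    """O(m^2) Benjamini-Hochberg: padj_i = min over thresholds t >= p_i of
    m * t / #{p_j <= t}."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    out = np.empty(m)
    for i in range(m):
        cands = [p[j] * m / np.sum(p <= p[j]) for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(cands))
    return out


def wilcoxon_exact_oracle(x, y):
    """Exact two-sided rank-sum p by exhaustive enumeration of all
    C(n+m, n) group assignments of the pooled sample (no ties assumed)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    n = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    stats = []
    for combo in itertools.combinations(range(1, len(pooled) + 1), n):
        stats.append(sum(combo))
    stats = np.array(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)
    return float(p)


def hypergeom_tail_oracle(overlap, universe, term, query):
    """Upper-tail hypergeometric by direct summation of the pmf."""
    total = 0.0
    for k in range(overlap, min(term, query) + 1):
        total += comb(term, k) * comb(universe - term, query - k)
    return total / comb(universe, query)


def nearest_gene_oracle(region, genes: pd.DataFrame):
    """Exhaustive scan for the closest TSS to the region midpoint."""
    chrom, start, end = region
    mid = (start + end) / 2.0
    best = None
    for _, g in genes[genes["chrom"] == chrom].iterrows():
        d = abs(g["tss"] - mid)
        key = (d, str(g["gene_id"]))
        if best is None or key < best[0]:
            best = (key, str(g["gene_id"]))
    return None if best is None else best[1]


def tangent_cutoff_oracle(signals):
    """Super-enhancer labels by an O(n^2) tangent-line scan.

    For each candidate index, check whether the slope-1 line through its
    scaled point lies at or below every other point (tangency from below);
    among tangent points take the highest rank; label signals strictly
    above that cutoff.  Returns None when the curve never dips below the
    diagonal by more than the noise band (no SE tier).
    """
    sig = np.sort(np.asarray(signals, dtype=float))
    n = len(sig)
    x = np.arange(n) / (n - 1)
    y = (sig - sig.min()) / (sig.max() - sig.min())
    band = np.sqrt(np.log(100.0) / (2.0 * n))
    best = None
    for i in range(n):
        line = y[i] + (x - x[i])
        if np.all(y >= line - 1e-9):
            if best is None or i > best:
                best = i
    if best is None or (x[best] - y[best]) < band:
        return None
    cutoff = y[best] * (sig.max() - sig.min()) + sig.min()
    return cutoff


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=50_000, max_len=500):
    starts = rng.integers(0, max_pos, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(chroms, size=n),
            "start": starts,
            "end": starts + lengths,
        }
    )
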