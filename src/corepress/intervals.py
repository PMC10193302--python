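"""Genomic interval algebra and gene-relative annotation.

Intervals are 0-based half-open ``[start, end)`` and strandless, carried as
pandas DataFrames with at least ``chrom``, ``start``, ``end`` columns
(BED-like).  Gene models are DataFrames with ``gene_id``, ``chrom``,
``start``, ``end``, ``strand`` and ``tss`` columns.

These primitives back every chromatin stage: replicate consensus building,
multi-factor co-occupancy classification, enhancer stitching and
region-to-gene assignment.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

INTERVAL_COLS = ("chrom", "start", "end")

#: Annotation priority, highest first.  A region overlapping several
#: categories receives the first one it hits.
FEATURE_PRIORITY = (
    "Promoter",
    "5'UTR",
    "3'UTR",
    "Exon",
    "Intron",
    "Downstream",
    "Intergenic",
)


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Check interval invariants (start < end, start >= 0).

    Raises ``ValueError`` naming the first offending record.
    """
    for col in INTERVAL_COLS:
        if col not in df.columns:
            raise ValueError(f"{name}: missing required column {col!r}")
    start = np.asarray(df["start"], dtype=np.int64)
    end = np.asarray(df["end"], dtype=np.int64)
    bad = (start < 0) | (start >= end)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        rec = df.iloc[i]
        raise ValueError(
            f"{name}: malformed interval at row {i}: "
            f"{rec['chrom']}:{rec['start']}-{rec['end']}"
        )
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals into a disjoint sorted set.

    Touching intervals (``end == start`` of the next) are merged.  Scores and
    any other extra columns are dropped: a merged region no longer has a
    single source score.
    """
    validate_intervals(df)
    if len(df) == 0:
        return pd.DataFrame(columns=list(INTERVAL_COLS))
    df = sort_intervals(df[list(INTERVAL_COLS)])
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        cur_s, cur_e = int(s[0]), int(e[0])
        for i in range(1, len(s)):
            if s[i] <= cur_e:  # overlap or touching
                cur_e = max(cur_e, int(e[i]))
            else:
                chroms.append(chrom)
                starts.append(cur_s)
                ends.append(cur_e)
                cur_s, cur_e = int(s[i]), int(e[i])
        chroms.append(chrom)
        starts.append(cur_s)
        ends.append(cur_e)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})


def _overlaps_any(chrom: str, start: int, end: int, other: pd.DataFrame) -> bool:
    sub = other[other["chrom"] == chrom]
    return bool(((sub["start"] < end) & (sub["end"] > start)).any())


def multi_overlap(
    named_sets: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, pd.Series]:
    """Merged-overlap classification of several named peak sets.

    The union of all intervals is merged; each merged region is labelled with
    the set of input names contributing at least 1 bp of overlap.  Returns
    ``(classes, counts)`` where ``classes`` has columns ``chrom, start, end,
    members`` (members is a sorted ``&``-joined label) and ``counts`` is a
    Series over member combinations summing to the number of merged regions.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("multi_overlap requires at least 2 named sets")
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    for name, df in named_sets.items():
        validate_intervals(df, name=name)
    pooled = pd.concat(
        [df[list(INTERVAL_COLS)] for df in named_sets.values()], ignore_index=True
    )
    merged = merge_intervals(pooled)
    members: list[str] = []
    for _, row in merged.iterrows():
        hit = [
            n
            for n in names
            if _overlaps_any(row["chrom"], row["start"], row["end"], named_sets[n])
        ]
        members.append("&".join(sorted(hit)))
    classes = merged.assign(members=members)
    counts = classes["members"].value_counts().sort_index()
    counts.name = "n_regions"
    return classes, counts


def _signed_tss_distance(mid: np.ndarray, tss: int, strand: str) -> np.ndarray:
    d = mid - tss
    return d if strand == "+" else -d


def annotate_features(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window: tuple[int, int] = (3000, 3000),
    downstream_window: int = 3000,
    exons: pd.DataFrame | None = None,
    utr5: pd.DataFrame | None = None,
    utr3: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each region exactly one genomic feature label.

    Overlap categories are resolved by the fixed priority Promoter > 5'UTR >
    3'UTR > Exon > Intron > Downstream > Intergenic.  Gene models without
    explicit UTR/exon tables never yield those labels (gene-body hits become
    Intron).  The promoter window is ``TSS - up / + down`` in the gene's
    reading direction; Downstream extends ``downstream_window`` past the TES.
    Regions on chromosomes absent from the gene table are warned about and
    labelled Intergenic.

    Returns a DataFrame with ``feature``, ``gene_id`` and signed
    ``distance_to_tss`` (region midpoint relative to the assigned gene's TSS,
    positive in the direction of transcription).
    """
    validate_intervals(regions)
    up, down = promoter_window
    out_feature = []
    out_gene = []
    out_dist = []
    gene_chroms = set(genes["chrom"]) if len(genes) else set()
    warned: set[str] = set()
    for _, r in regions.iterrows():
        chrom, start, end = r["chrom"], int(r["start"]), int(r["end"])
        mid = (start + end) / 2.0
        if chrom not in gene_chroms:
            if chrom not in warned:
                warnings.warn(f"region chromosome {chrom!r} absent from gene models")
                warned.add(chrom)
            out_feature.append("Intergenic")
            out_gene.append(None)
            out_dist.append(np.nan)
            continue
        g = genes[genes["chrom"] == chrom]
        # candidate (priority_index, |tss distance|, gene_id) per category hit
        best: tuple[int, float, str] | None = None

        def consider(prio: int, gene_row) -> None:
            nonlocal best
            tss = int(gene_row["tss"])
            dist = abs(mid - tss)
            cand = (prio, dist, str(gene_row["gene_id"]))
            if best is None or cand < best:
                best = cand

        for _, gr in g.iterrows():
            tss = int(gr["tss"])
            strand = gr["strand"]
            if strand == "+":
                prom_s, prom_e = tss - up, tss + down
                down_s, down_e = int(gr["end"]), int(gr["end"]) + downstream_window
            else:
                prom_s, prom_e = tss - down, tss + up
                down_s, down_e = int(gr["start"]) - downstream_window, int(gr["start"])
            if start < prom_e and end > prom_s:
                consider(0, gr)
            if start < int(gr["end"]) and end > int(gr["start"]):
                consider(4, gr)  # gene body -> Intron unless an exon/UTR hit wins
            if start < down_e and end > down_s:
                consider(5, gr)
        for tbl, prio in ((utr5, 1), (utr3, 2), (exons, 3)):
            if tbl is None or len(tbl) == 0:
                continue
            sub = tbl[
                (tbl["chrom"] == chrom) & (tbl["start"] < end) & (tbl["end"] > start)
            ]
            for _, xr in sub.iterrows():
                gid = str(xr["gene_id"])
                gr = g[g["gene_id"] == gid]
                if len(gr):
                    consider(prio, gr.iloc[0])
        if best is None:
            out_feature.append("Intergenic")
            out_gene.append(None)
            out_dist.append(np.nan)
        else:
            prio, _, gid = best
            out_feature.append(FEATURE_PRIORITY[prio])
            gr = g[g["gene_id"] == gid].iloc[0]
            out_gene.append(gid)
            out_dist.append(
                float(_signed_tss_distance(np.array([mid]), int(gr["tss"]), gr["strand"])[0])
            )
    out = regions.reset_index(drop=True).copy()
    out["feature"] = out_feature
    out["gene_id"] = out_gene
    out["distance_to_tss"] = out_dist
    return out


def nearest_gene(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each region the gene whose TSS is closest to its midpoint.

    Ties on |midpoint - TSS| break to the lexicographically smaller gene_id.
    Regions on chromosomes with no genes are left unassigned (NaN).
    Returned distance is signed (midpoint - TSS in the gene's direction).
    """
    validate_intervals(regions)
    gene_ids = []
    dists = []
    for _, r in regions.iterrows():
        g = genes[genes["chrom"] == r["chrom"]]
        if len(g) == 0:
            gene_ids.append(None)
            dists.append(np.nan)
            continue
        mid = (int(r["start"]) + int(r["end"])) / 2.0
        absd = np.abs(g["tss"].to_numpy() - mid)
        order = sorted(
            range(len(g)), key=lambda i: (absd[i], str(g.iloc[i]["gene_id"]))
        )
        best = g.iloc[order[0]]
        gene_ids.append(str(best["gene_id"]))
        dists.append(
            float(
                _signed_tss_distance(np.array([mid]), int(best["tss"]), best["strand"])[0]
            )
        )
    out = regions.reset_index(drop=True).copy()
    out["gene_id"] = gene_ids
    out["distance_to_tss"] = dists
    return out


def read_bed(path) -> pd.DataFrame:
    """Read a BED3/BED6 file into an interval DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = cols
    return validate_intervals(df)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write intervals as BED6 (name/score filled with defaults if absent)."""
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = [f"region_{i}" for i in range(len(out))]
    if "score" not in out.columns:
        out["score"] = 0
    out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )
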