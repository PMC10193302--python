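"""Synthetic fixtures with planted ground truth for every pipeline stage.

All generators draw from a single explicitly passed seed (no global
randomness): the same seed reproduces byte-identical fixtures.  Planted
structure — which regions are co-occupied by every factor, which carry a
negative fold change, where the super-enhancer domains sit, which peptides
follow which dynamics template — is returned in a :class:`SimulationTruth`
so downstream recovery can be scored without re-inference.

The generators emulate the shape of the real inputs (replicated scored
peak sets, negative-binomial region counts with a global per-sample
spike-in scale, a heavy-tailed acetylation landscape, TMT 10-plex reporter
tables over a 0/1.5/5/15/30-minute course) but not read-level detail:
no FASTQ, no fragment model, no genome sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phospho import DEFAULT_TIMEPOINTS, N_CHANNELS, REPORTER_COLS


@dataclass
class SimulationTruth:
    """Planted ground truth of one synthetic fixture."""

    seed: int
    planted_cooccupancy_regions: list[dict] = field(default_factory=list)
    planted_lfc: dict = field(default_factory=dict)
    planted_spikein_scale: dict = field(default_factory=dict)
    planted_superenhancers: list[dict] = field(default_factory=list)
    planted_de_genes: dict = field(default_factory=dict)
    planted_phospho_clusters: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class ScoreModel:
    """Score distributions for synthetic peaks.

    True peaks draw a per-region log strength from N(signal_mu, signal_sd)
    shared across replicates, plus independent per-replicate noise of sd
    ``rep_noise_sd`` — reproducible ranks.  Noise peaks draw independent
    per-replicate scores from N(noise_mu, noise_sd) on the log scale — the
    irreproducible component.
    """

    signal_mu: float = 4.0
    signal_sd: float = 0.5
    rep_noise_sd: float = 0.2
    noise_mu: float = 1.0
    noise_sd: float = 1.0
    n_noise: int = 300


def gen_genome(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    seed: int,
    gene_length_range: tuple[int, int] = (2_000, 15_000),
    min_gap: int = 5_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy genome: chromosome sizes plus non-overlapping gene models.

    Genes are packed on an even grid per chromosome with at least
    ``min_gap`` between neighbours; raises when the requested count cannot
    fit.  Returns ``(genes, chrom_sizes)``; genes carry gene_id, chrom,
    start, end, strand and tss.
    """
    if n_chroms < 1 or chrom_length < 10_000 or n_genes < 0:
        raise ValueError("need n_chroms >= 1, chrom_length >= 10000, n_genes >= 0")
    rng = np.random.default_rng(seed)
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    sizes = pd.DataFrame({"chrom": chrom_names, "length": chrom_length})
    if n_genes == 0:
        genes = pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
        )
        return genes, sizes
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    lo, hi = gene_length_range
    rows = []
    gi = 0
    for chrom, npc in zip(chrom_names, per_chrom):
        if npc == 0:
            continue
        slot = chrom_length // npc
        if slot < hi + min_gap:
            raise ValueError(
                f"cannot pack {npc} genes of up to {hi} bp plus {min_gap} bp gaps "
                f"into {chrom_length} bp of {chrom}"
            )
        for j in range(npc):
            length = int(rng.integers(lo, hi + 1))
            offset = int(rng.integers(min_gap // 2, slot - length - min_gap // 2 + 1))
            start = j * slot + offset
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            rows.append(
                {
                    "gene_id": f"gene{gi:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "tss": tss,
                }
            )
            gi += 1
    genes = pd.DataFrame(rows)
    return genes, sizes


def _allocate_slots(
    sizes: pd.DataFrame, n_slots: int, slot_width: int, rng: np.random.Generator,
    max_retries: int = 5,
) -> list[tuple[str, int]]:
    """Pick n_slots non-colliding anchor positions across chromosomes."""
    total = int(sizes["length"].sum())
    capacity = total // slot_width
    if n_slots > capacity:
        raise ValueError(
            f"cannot place {n_slots} regions of footprint {slot_width} bp in "
            f"{total} bp of genome"
        )
    for _ in range(max_retries):
        picks = rng.choice(capacity, size=n_slots, replace=False)
        picks.sort()
        out = []
        for p in picks:
            pos = int(p) * slot_width
            for _, row in sizes.iterrows():
                if pos < row["length"]:
                    out.append((row["chrom"], pos + slot_width // 4))
                    break
                pos -= int(row["length"])
        if len(out) == n_slots:
            return out
    raise RuntimeError("slot allocation failed after retries")


def gen_peaksets(
    genome: tuple[pd.DataFrame, pd.DataFrame],
    factors: Sequence[str],
    n_shared: int,
    n_private_per_factor: int,
    n_replicates: int = 2,
    jitter_sd: float = 30.0,
    score_model: ScoreModel | None = None,
    seed: int = 0,
    peak_width: tuple[int, int] = (200, 400),
) -> tuple[dict[str, list[pd.DataFrame]], SimulationTruth]:
    """Replicated per-factor peak sets with a planted all-factor shared core.

    ``n_shared`` regions are occupied by every factor; ``n_private_per_factor``
    regions by exactly one.  Replicate boundaries are jittered by
    N(0, jitter_sd); per the score model each factor/replicate additionally
    carries reproducibly-positioned but irreproducibly-scored noise peaks.
    Region anchors sit on a spaced grid so membership is never ambiguous.
    """
    if len(factors) < 2:
        raise ValueError("need >= 2 factors")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    sm = score_model or ScoreModel()
    genes, sizes = genome
    rng = np.random.default_rng(seed)
    wlo, whi = peak_width
    slot_width = whi + 2 * int(3 * jitter_sd + 100)
    n_regions = n_shared + n_private_per_factor * len(factors) + sm.n_noise
    anchors = _allocate_slots(sizes, n_regions, slot_width, rng)
    truth = SimulationTruth(seed=seed)
    regions = []
    for i, (chrom, pos) in enumerate(anchors):
        width = int(rng.integers(wlo, whi + 1))
        if i < n_shared:
            members = sorted(factors)
            kind = "shared"
        elif i < n_shared + n_private_per_factor * len(factors):
            members = [factors[(i - n_shared) // max(n_private_per_factor, 1)]]
            kind = "private"
        else:
            members = sorted(factors)  # noise regions appear for every factor
            kind = "noise"
        regions.append((chrom, pos, pos + width, members, kind))
        if kind != "noise":
            truth.planted_cooccupancy_regions.append(
                {"chrom": chrom, "start": pos, "end": pos + width, "members": members}
            )
    out: dict[str, list[pd.DataFrame]] = {}
    for f in factors:
        strengths = {}
        for i, (chrom, s, e, members, kind) in enumerate(regions):
            if f in members and kind != "noise":
                strengths[i] = rng.normal(sm.signal_mu, sm.signal_sd)
        reps = []
        for _r in range(n_replicates):
            rows = []
            for i, (chrom, s, e, members, kind) in enumerate(regions):
                if f not in members:
                    continue
                js = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
                je = int(round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
                start = max(0, s + js)
                end = max(start + 50, e + je)
                if kind == "noise":
                    score = float(np.exp(rng.normal(sm.noise_mu, sm.noise_sd)))
                else:
                    score = float(
                        np.exp(strengths[i] + rng.normal(0.0, sm.rep_noise_sd))
                    )
                rows.append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "name": f"{f}_rep{_r + 1}_pk{i}",
                        "score": score,
                    }
                )
            reps.append(pd.DataFrame(rows))
        out[f] = reps
    return out, truth


def gen_counts(
    regions: pd.DataFrame,
    design: pd.DataFrame,
    lfc: np.ndarray | Mapping[int, float],
    dispersion: float,
    mean_range: tuple[float, float] = (50.0, 500.0),
    spikein_scale: Mapping[str, float] | None = None,
    seed: int = 0,
    treated_group: str = "B",
    group_col: str = "group",
    spike_base: float = 1_000_000.0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Negative-binomial region counts with planted fold changes and a
    global per-sample spike-in scale.

    ``counts[i, j] ~ NB(mean_i * 2^{lfc_i * treated_j} * scale_j, alpha)``
    with ``Var = mu + alpha mu^2``.  The exogenous spike-in column scales
    with the same per-sample factor (constant spiked material sequenced at
    the sample's depth).  Returns ``(counts, spikein_counts, truth)``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion alpha must be > 0")
    n = len(regions)
    rng = np.random.default_rng(seed)
    samples = list(design.index)
    if spikein_scale is None:
        spikein_scale = {s: 1.0 for s in samples}
    scales = np.array([spikein_scale[s] for s in samples], dtype=float)
    if np.any(scales <= 0):
        raise ValueError("all spike-in scales must be > 0")
    lo, hi = mean_range
    if lo <= 0:
        raise ValueError("means must be positive")
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    lfc_vec = np.zeros(n)
    if isinstance(lfc, Mapping):
        for i, v in lfc.items():
            lfc_vec[int(i)] = float(v)
    else:
        lfc_vec = np.asarray(lfc, dtype=float)
    treated = (design[group_col] == treated_group).to_numpy()
    mu = base_mean[:, None] * (2.0 ** (lfc_vec[:, None] * treated[None, :])) * scales[None, :]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    idx = (
        regions.index
        if regions.index.is_unique and len(regions.index) == n
        else pd.RangeIndex(n)
    )
    counts_df = pd.DataFrame(counts, index=idx, columns=samples)
    spike = rng.poisson(spike_base * scales)
    spike_df = pd.DataFrame({"sample_id": samples, "spikein_count": spike}).set_index(
        "sample_id"
    )
    truth = SimulationTruth(
        seed=seed,
        planted_lfc={int(i): float(v) for i, v in enumerate(lfc_vec) if v != 0.0},
        planted_spikein_scale={s: float(v) for s, v in zip(samples, scales)},
    )
    return counts_df, spike_df, truth


def gen_h3k27ac_landscape(
    genome: tuple[pd.DataFrame, pd.DataFrame],
    n_regular: int,
    n_super: int,
    super_signal_multiplier: float = 50.0,
    seed: int = 0,
    constituents_per_super: int = 4,
    constituent_spacing: int = 3_000,
    peak_width: int = 600,
    tss_clearance: int = 4_000,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Acetylation peak landscape with a heavy-tailed planted SE minority.

    ``n_regular`` isolated peaks carry baseline signal; ``n_super`` planted
    domains each hold ``constituents_per_super`` nearby peaks whose signal
    is ``super_signal_multiplier`` times the baseline, so their stitched
    sums form the heavy tail of the rank curve.  Peaks are kept
    ``tss_clearance`` away from every TSS so the exclusion window never
    removes planted structure.
    """
    if super_signal_multiplier <= 1:
        raise ValueError("super_signal_multiplier must be > 1")
    genes, sizes = genome
    rng = np.random.default_rng(seed)
    domain_span = constituents_per_super * constituent_spacing + peak_width
    slot_width = domain_span + 2 * STITCH_MARGIN
    anchors = _allocate_slots(sizes, n_regular + n_super, slot_width, rng)
    tss = genes["tss"].to_numpy() if len(genes) else np.array([])
    tss_chrom = genes["chrom"].to_numpy() if len(genes) else np.array([])

    def clear_of_tss(chrom: str, start: int, end: int) -> bool:
        sel = tss_chrom == chrom
        if not sel.any():
            return True
        t = tss[sel]
        return bool(np.all((t + tss_clearance <= start) | (t - tss_clearance >= end)))

    rows = []
    truth = SimulationTruth(seed=seed)
    for i, (chrom, pos) in enumerate(anchors):
        if i < n_regular:
            if not clear_of_tss(chrom, pos, pos + peak_width):
                pos += tss_clearance + peak_width  # deterministic nudge
            # flat baseline: the heavy tail comes from planted domains only
            signal = float(rng.uniform(0.5, 1.5))
            rows.append(
                {"chrom": chrom, "start": pos, "end": pos + peak_width, "signal": signal}
            )
        else:
            if not clear_of_tss(chrom, pos, pos + domain_span):
                pos += tss_clearance + domain_span
            for c in range(constituents_per_super):
                s = pos + c * constituent_spacing
                signal = float(
                    super_signal_multiplier * np.exp(rng.normal(0.0, 0.25))
                )
                rows.append(
                    {"chrom": chrom, "start": s, "end": s + peak_width, "signal": signal}
                )
            truth.planted_superenhancers.append(
                {"chrom": chrom, "start": pos, "end": pos + domain_span}
            )
    peaks = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return peaks, truth


STITCH_MARGIN = 15_000  # keeps planted domains from stitching into each other


def peaks_to_bedgraph(peaks: pd.DataFrame) -> pd.DataFrame:
    """Uniform coverage track whose integral over each peak equals its signal."""
    out = peaks.copy()
    out["value"] = out["signal"] / (out["end"] - out["start"])
    return out[["chrom", "start", "end", "value"]]


# phospho dynamics templates: log2 fold change at 0/1.5/5/15/30 min
_TEMPLATE_LIBRARY = np.array(
    [
        [0.0, 1.5, 2.0, 2.2, 2.2],  # fast sustained up
        [0.0, -1.5, -2.0, -2.2, -2.2],  # fast sustained down
        [0.0, 2.0, 1.0, 0.3, 0.0],  # transient up
        [0.0, 0.1, 0.5, 1.5, 2.5],  # late up
        [0.0, -2.0, -1.0, -0.3, 0.0],  # transient down
        [0.0, -0.1, -0.5, -1.5, -2.5],  # late down
    ]
)


def gen_phospho(
    n_peptides: int,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    k_true: int = 3,
    noise_sd: float = 0.1,
    frac_low_intensity: float = 0.1,
    frac_missing_channels: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """TMT 10-plex reporter table over a 5-point time course.

    Each clean peptide (one spectrum each) follows one of ``k_true`` planted
    dynamics templates with per-channel log2 noise of ``noise_sd``; all its
    sites are confidently localised.  The stated fractions of additional
    decoy spectra violate the retention filters: all reporters below the
    intensity floor, or 5-7 missing channels.  Clean spectra that would by
    chance trip a filter are deterministically repaired (one channel raised
    above the floor) so that the retained count equals the planted clean
    count exactly.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if k_true > len(_TEMPLATE_LIBRARY):
        raise ValueError(f"at most {len(_TEMPLATE_LIBRARY)} templates available")
    if len(timepoints) != N_CHANNELS // 2:
        raise ValueError("expected one timepoint per pair of reporter channels")
    rng = np.random.default_rng(seed)
    templates = _TEMPLATE_LIBRARY[:k_true]
    rows = []
    truth = SimulationTruth(seed=seed)
    for i in range(n_peptides):
        cl = int(rng.integers(k_true))
        base = float(np.exp(rng.normal(np.log(5e4), 0.5)))
        seq = f"PEPTIDE{i:04d}K"
        site = f"S{int(rng.integers(2, 9))}"
        inten = np.empty(N_CHANNELS)
        for ch in range(N_CHANNELS):
            t_idx = ch // 2
            inten[ch] = base * 2.0 ** (
                templates[cl, t_idx] + rng.normal(0.0, noise_sd)
            )
        if np.all(inten < 2000.0):  # repair: keep bookkeeping exact
            inten[0] = 2500.0
        rows.append(
            {
                "spectrum_id": f"spec{i:05d}",
                "peptide": seq,
                "site": site,
                "localisation_prob": "0.99",
                **{REPORTER_COLS[c]: inten[c] for c in range(N_CHANNELS)},
            }
        )
        truth.planted_phospho_clusters[f"{seq}|{site}"] = cl + 1
    n_clean = len(rows)
    n_low = int(round(frac_low_intensity * n_clean / (1 - frac_low_intensity - frac_missing_channels)))
    n_miss = int(round(frac_missing_channels * n_clean / (1 - frac_low_intensity - frac_missing_channels)))
    for j in range(n_low):
        inten = rng.uniform(100.0, 1999.0, size=N_CHANNELS)
        rows.append(
            {
                "spectrum_id": f"low{j:05d}",
                "peptide": f"LOWPEP{j:04d}R",
                "site": "S3",
                "localisation_prob": "0.99",
                **{REPORTER_COLS[c]: inten[c] for c in range(N_CHANNELS)},
            }
        )
    for j in range(n_miss):
        inten = np.exp(rng.normal(np.log(5e4), 0.5, size=N_CHANNELS))
        n_gone = int(rng.integers(5, 8))
        gone = rng.choice(N_CHANNELS, size=n_gone, replace=False)
        inten[gone] = np.nan
        rows.append(
            {
                "spectrum_id": f"miss{j:05d}",
                "peptide": f"MISSPEP{j:04d}R",
                "site": "S3",
                "localisation_prob": "0.99",
                **{REPORTER_COLS[c]: inten[c] for c in range(N_CHANNELS)},
            }
        )
    return pd.DataFrame(rows), truth
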