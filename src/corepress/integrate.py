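"""Cross-stage integration: occupancy-vs-expression correlation, the
signal-correlation coregulator screen, over-representation analysis and the
end-to-end demo pipeline.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, rankdata

from . import consensus, enhancers, expression, intervals, occupancy, phospho, simulate
from .occupancy import bh_adjust


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], exact_max: int = 9
) -> tuple[float, float, int]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks handle ties; p comes from the t approximation, replaced by
    an exact permutation enumeration for n <= ``exact_max``.  Returns
    ``(rho, p, n)``; fewer than 3 complete pairs yields NaNs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return float("nan"), float("nan"), n
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-12, 1.0 - rho * rho))
        from scipy.stats import t as tdist

        p = float(2.0 * tdist.sf(abs(t), df=n - 2))
    return rho, float(min(p, 1.0)), n


def chip_expression_correlation(
    links: pd.DataFrame, mark: str
) -> dict:
    """Spearman correlation of a chromatin mark's LFC with expression LFC.

    ``links`` carries one row per region-gene link with ``chip_lfc_<mark>``
    and ``expr_lfc`` columns.  Returns rho, two-sided p and n.
    """
    col = f"chip_lfc_{mark}"
    rho, p, n = spearman_correlation(links[col], links["expr_lfc"])
    return {"mark": mark, "rho": rho, "p": p, "n": n}


def signal_correlation_screen(
    signal_matrix: pd.DataFrame,
    reference_columns: Sequence[str],
    cutoff: float = 0.4,
) -> pd.DataFrame:
    """Coregulator screen: pass datasets correlating with any reference ChIP.

    Pairwise Spearman over the common region index; a dataset passes iff its
    maximum correlation with any reference column is >= ``cutoff``.
    Constant columns have undefined correlations and are excluded with a
    warning.
    """
    usable = []
    for c in signal_matrix.columns:
        if signal_matrix[c].nunique() <= 1:
            warnings.warn(f"column {c!r} is constant; excluded from the screen")
        else:
            usable.append(c)
    mat = signal_matrix[usable]
    corr = mat.corr(method="spearman")
    refs = [c for c in reference_columns if c in usable]
    rows = []
    for c in usable:
        if c in refs:
            continue
        best = corr.loc[c, refs].max()
        rows.append(
            {"dataset": c, "max_corr_with_reference": float(best), "passes": bool(best >= cutoff)}
        )
    return pd.DataFrame(
        rows, columns=["dataset", "max_corr_with_reference", "passes"]
    )


def ora(
    query_genes: set[str],
    term_sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation analysis with BH.

    For a term of size K in a universe of size N with a query of size n and
    overlap k, p = P(X >= k) under the hypergeometric null.  Odds ratios are
    from the 2x2 table (0.5 added only when a margin is zero, for display).
    """
    if len(query_genes) == 0 or len(universe) == 0:
        raise ValueError("query and universe must be non-empty")
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N = len(universe)
    n = len(query_genes)
    rows = []
    for term, genes in term_sets.items():
        genes = genes & universe
        K = len(genes)
        k = len(genes & query_genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append(
            {"term": term, "term_size": K, "overlap": k, "p": p, "odds_ratio": float(odds)}
        )
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# end-to-end demo pipeline

DEFAULT_CONFIG = {
    "seed": 1,
    "n_chroms": 2,
    "chrom_length": 4_000_000,
    "n_genes": 120,
    "factors": ["Erf", "Ncor1", "Ncor2", "Tbl1x"],
    "n_shared": 80,
    "n_private_per_factor": 40,
    "n_replicates": 2,
    "jitter_sd": 20.0,
    "idr_alpha": 0.05,
    "diff_idr_alpha": 0.01,
    "n_loss_regions": 60,
    "loss_lfc": -2.0,
    "dispersion": 0.1,
    "fdr_screen": 0.5,
    "n_regular_enhancers": 150,
    "n_super_enhancers": 8,
    "super_multiplier": 50.0,
    "n_phospho_peptides": 300,
    "phospho_k": 3,
    "n_expr_replicates": 4,
    "expr_lfc": 2.0,
}

REQUIRED_CONFIG_KEYS = ("seed", "factors", "n_shared", "n_replicates")


def config_hash(config: Mapping) -> str:
    payload = json.dumps({k: config[k] for k in sorted(config)}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, chash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run every stage on a self-generated synthetic fixture.

    Stage order: simulate -> replicate IDR -> multi-factor co-occupancy ->
    consensus -> spike-in-normalized differential occupancy + combinatorial
    classes -> enhancer stitching / SE split -> differential expression +
    clustering + ETNN responsiveness -> phospho time course -> integrative
    correlations and ORA.  All tables are written under ``outdir`` with the
    config hash in a header line; a run manifest records config, hash and
    seed.  Deterministic: same config + seed gives byte-identical outputs.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    missing = [k for k in REQUIRED_CONFIG_KEYS if cfg.get(k) is None]
    if missing:
        raise ValueError(f"config missing required keys: {missing}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]

    # --- simulate
    genome = simulate.gen_genome(
        cfg["n_chroms"], cfg["chrom_length"], cfg["n_genes"], seed=stage_seeds[0]
    )
    genes, sizes = genome
    peaksets, peak_truth = simulate.gen_peaksets(
        genome,
        cfg["factors"],
        n_shared=cfg["n_shared"],
        n_private_per_factor=cfg["n_private_per_factor"],
        n_replicates=cfg["n_replicates"],
        jitter_sd=cfg["jitter_sd"],
        seed=stage_seeds[1],
    )

    # --- replicate reproducibility per factor
    idr_sets = {}
    for f, reps in peaksets.items():
        pairs, _, _ = consensus.pair_replicate_peaks(reps[0], reps[1])
        audit, _ = consensus.idr_filter(pairs, alpha=cfg["idr_alpha"])
        idr_sets[f] = audit[audit["pass"]][["chrom", "start", "end"]].reset_index(drop=True)

    # --- co-occupancy classification
    classes, class_counts = intervals.multi_overlap(idr_sets)
    all_label = "&".join(sorted(cfg["factors"]))
    etnn = classes[classes["members"] == all_label][["chrom", "start", "end"]].reset_index(drop=True)
    _write_table(classes, outdir / "cooccupancy_classes.tsv", chash)
    _write_table(class_counts.to_frame(), outdir / "cooccupancy_counts.tsv", chash, index=True)

    # --- consensus + differential occupancy with spike-in normalization
    reference = consensus.build_consensus(idr_sets)
    _write_table(reference, outdir / "consensus_peaks.tsv", chash)
    n_ref = len(reference)
    factors3 = [f for f in cfg["factors"] if f != "Erf"]
    rng = np.random.default_rng(stage_seeds[2])
    n_loss = min(cfg["n_loss_regions"], n_ref)
    loss_idx = np.sort(rng.choice(n_ref, size=n_loss, replace=False))
    design = pd.DataFrame(
        {
            "group": ["A"] * 4 + ["B"] * 4,
        },
        index=[f"WT_{i}" for i in range(1, 5)] + [f"KO_{i}" for i in range(1, 5)],
    )
    results_by_factor = {}
    spike_truths = {}
    for fi, f in enumerate(factors3):
        scale = {s: float(v) for s, v in zip(design.index, np.exp(rng.normal(0, 0.2, size=len(design))))}
        counts, spike, ctruth = simulate.gen_counts(
            reference,
            design,
            lfc={int(i): cfg["loss_lfc"] for i in loss_idx},
            dispersion=cfg["dispersion"],
            spikein_scale=scale,
            seed=stage_seeds[3] + fi,
        )
        metas = [
            occupancy.SampleMeta(
                sample_id=s,
                factor=f,
                genotype="WT" if s.startswith("WT") else "Erf-KO",
                condition="PD",
                replicate=int(s.split("_")[1]),
                spikein_count=int(spike.loc[s, "spikein_count"]),
                library_count=int(counts[s].sum()),
            )
            for s in design.index
        ]
        norm_factors = occupancy.spikein_scaling(metas)
        size_factors = {s: 1.0 / v for s, v in norm_factors.items()}
        res = occupancy.nb_wald_test(counts, design, ("group", "B", "A"), size_factors)
        results_by_factor[f] = res
        spike_truths[f] = ctruth
        _write_table(res, outdir / f"differential_{f}.tsv", chash, index=True)
    classified, _excluded = occupancy.combinatorial_classes(
        results_by_factor, fdr_cut=cfg["fdr_screen"]
    )
    _write_table(classified, outdir / "combinatorial_classes.tsv", chash, index=True)
    tnn_label = occupancy.concordant_loss_label(factors3)
    tnn_loss_idx = classified.index[classified["group"] == tnn_label]

    # --- enhancer landscape
    land, se_truth = simulate.gen_h3k27ac_landscape(
        genome,
        n_regular=cfg["n_regular_enhancers"],
        n_super=cfg["n_super_enhancers"],
        super_signal_multiplier=cfg["super_multiplier"],
        seed=stage_seeds[4],
    )
    stitched = enhancers.stitch_enhancers(land, genes)
    track = simulate.peaks_to_bedgraph(land)
    ranked = enhancers.score_and_rank(stitched, track)
    labelled, se_cutoff = enhancers.split_super(ranked)
    gene_tbl, se_genes, re_genes = enhancers.enhancer_gene_sets(labelled, genes)
    _write_table(
        gene_tbl.drop(columns=["constituents"]).assign(
            n_constituents=[len(c) for c in gene_tbl["constituents"]]
        ),
        outdir / "enhancers.tsv",
        chash,
    )

    # --- expression
    expr_design = pd.DataFrame(
        {"group": ["A"] * cfg["n_expr_replicates"] + ["B"] * cfg["n_expr_replicates"]},
        index=[f"WTx_{i}" for i in range(cfg["n_expr_replicates"])]
        + [f"KOx_{i}" for i in range(cfg["n_expr_replicates"])],
    )
    gene_index = genes["gene_id"].tolist()
    etnn_genes = set(
        intervals.nearest_gene(etnn, genes)["gene_id"].dropna()
    )
    rng_e = np.random.default_rng(stage_seeds[5])
    de_idx = {}
    for gi, g in enumerate(gene_index):
        if g in etnn_genes and rng_e.random() < 0.6:
            de_idx[gi] = cfg["expr_lfc"] * (1 if rng_e.random() < 0.5 else -1)
    gene_regions = genes.rename(columns={"gene_id": "name"})[["chrom", "start", "end", "name"]]
    expr_counts, _, expr_truth = simulate.gen_counts(
        gene_regions.set_index("name"),
        expr_design,
        lfc=de_idx,
        dispersion=cfg["dispersion"],
        seed=stage_seeds[6],
    )
    sf = occupancy.estimate_size_factors(expr_counts)
    de = expression.de_test(expr_counts, expr_design, ("group", "B", "A"), sf)
    _write_table(de, outdir / "differential_expression.tsv", chash, index=True)
    stab = expression.vst_transform(expr_counts, sf)
    top = expression.top_variance_genes(stab, n=min(100, len(stab)))
    clusters, k_hat = expression.cluster_genes(stab.loc[top])
    _write_table(clusters, outdir / "expression_clusters.tsv", chash, index=True)
    compare = expression.group_lfc_compare(de, clusters, etnn_genes)
    _write_table(compare, outdir / "etnn_responsiveness.tsv", chash)
    de_up = set(de.index[de["significant"] & (de["log2fc"] > 0)])
    de_down = set(de.index[de["significant"] & (de["log2fc"] < 0)])
    inter = enhancers.etnn_enhancer_intersection(gene_tbl, etnn, de_up, de_down)
    _write_table(
        pd.DataFrame(
            inter["contingency"],
            index=["SE", "RE"],
            columns=["regulated", "not_regulated"],
        ),
        outdir / "etnn_enhancer_contingency.tsv",
        chash,
        index=True,
    )

    # --- phospho
    spectra, ph_truth = simulate.gen_phospho(
        cfg["n_phospho_peptides"], k_true=cfg["phospho_k"], seed=stage_seeds[7]
    )
    retained, rejected = phospho.filter_spectra(spectra)
    peptides = phospho.group_peptides(retained)
    profiles, _dropped = phospho.profiles_from_peptides(peptides)
    regulated = phospho.regulation_filter(profiles)
    ph_clusters, centroids, wss = phospho.cluster_profiles(
        regulated, k=cfg["phospho_k"], seed=seed
    )
    _write_table(ph_clusters, outdir / "phospho_clusters.tsv", chash, index=True)
    _write_table(rejected, outdir / "phospho_rejected.tsv", chash)

    # --- integration
    links = intervals.nearest_gene(etnn, genes)
    link_rows = []
    ref_mid = reference.assign(pos=np.arange(len(reference)))
    for _, l in links.iterrows():
        if l["gene_id"] is None or l["gene_id"] not in de.index:
            continue
        hit = ref_mid[
            (ref_mid["chrom"] == l["chrom"])
            & (ref_mid["start"] < l["end"])
            & (ref_mid["end"] > l["start"])
        ]
        if len(hit) == 0:
            continue
        ridx = int(hit.iloc[0]["pos"])
        link_rows.append(
            {
                "gene_id": l["gene_id"],
                "chip_lfc_Ncor1": float(results_by_factor[factors3[0]].iloc[ridx]["log2fc"]),
                "expr_lfc": float(de.loc[l["gene_id"], "log2fc"]),
            }
        )
    links_df = pd.DataFrame(link_rows)
    corr = (
        chip_expression_correlation(links_df, factors3[0])
        if len(links_df) >= 3
        else {"mark": factors3[0], "rho": float("nan"), "p": float("nan"), "n": len(links_df)}
    )
    _write_table(pd.DataFrame([corr]), outdir / "chip_expression_correlation.tsv", chash)
    universe = set(gene_index)
    term_sets = {"ETNN_targets": etnn_genes & universe, "SE_genes": se_genes & universe}
    query = de_up | de_down
    ora_tbl = (
        ora(query & universe, term_sets, universe)
        if query & universe
        else pd.DataFrame(columns=["term", "term_size", "overlap", "p", "odds_ratio", "padj"])
    )
    _write_table(ora_tbl, outdir / "ora.tsv", chash)

    manifest = {
        "config": {k: cfg[k] for k in sorted(cfg)},
        "config_hash": chash,
        "seed": seed,
        "n_consensus_regions": int(n_ref),
        "n_etnn_regions": int(len(etnn)),
        "n_tnn_loss": int(len(tnn_loss_idx)),
        "n_super_enhancers": int(labelled["is_super"].sum()),
        "se_cutoff": float(se_cutoff),
        "k_expression": int(k_hat),
        "n_de_up": int(len(de_up)),
        "n_de_down": int(len(de_down)),
        "n_phospho_retained": int(len(retained)),
        "phospho_wss": float(wss),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
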