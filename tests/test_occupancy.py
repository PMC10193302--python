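"""Normalization, dispersion estimation, the NB Wald test and the
combinatorial loss/gain classifier."""

import numpy as np
import pandas as pd
import pytest

from corepress import occupancy, simulate
from corepress.occupancy import SampleMeta

from _oracles import bh_oracle
from conftest import intervals_df


def meta(sample_id, spikein):
    return SampleMeta(
        sample_id=sample_id,
        factor="Ncor1",
        genotype="WT",
        condition="PD",
        replicate=1,
        spikein_count=spikein,
        library_count=1_000_000,
    )


class TestSpikeinScaling:
    def test_two_sample_hand_computation(self):
        # counts 1e6 and 2e6: raw factors 1 and 0.5, geometric mean sqrt(0.5)
        got = occupancy.spikein_scaling([meta("a", 1_000_000), meta("b", 2_000_000)])
        assert got["a"] == pytest.approx(np.sqrt(2))
        assert got["b"] == pytest.approx(np.sqrt(2) / 2)

    def test_equal_counts_give_unit_factors(self):
        got = occupancy.spikein_scaling([meta(s, 5_000_000) for s in "abc"])
        assert all(v == pytest.approx(1.0) for v in got.values())

    def test_zero_spikein_rejected_with_hint(self):
        with pytest.raises(ValueError, match="estimate_size_factors"):
            occupancy.spikein_scaling([meta("a", 0), meta("b", 100)])

    def test_recovers_planted_global_scale_within_5pct(self, two_group_design):
        scales = {s: v for s, v in zip(two_group_design.index, [1.0, 1.3, 0.7, 1.1, 0.9, 1.6, 0.8, 1.2])}
        counts, spike, _ = simulate.gen_counts(
            pd.DataFrame(index=range(300)),
            two_group_design,
            lfc=np.zeros(300),
            dispersion=0.05,
            spikein_scale=scales,
            seed=21,
        )
        metas = [meta(s, int(spike.loc[s, "spikein_count"])) for s in two_group_design.index]
        got = occupancy.spikein_scaling(metas)
        inv = np.array([1.0 / scales[s] for s in two_group_design.index])
        expected = inv / np.exp(np.mean(np.log(inv)))
        for s, e in zip(two_group_design.index, expected):
            assert got[s] == pytest.approx(e, rel=0.05)


class TestSizeFactors:
    def test_doubled_sample_hand_computation(self):
        a = np.array([10, 20, 30, 40])
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        got = occupancy.estimate_size_factors(counts)
        assert got["A"] == pytest.approx(1 / np.sqrt(2))
        assert got["B"] == pytest.approx(np.sqrt(2))

    def test_identical_samples_give_ones(self):
        counts = pd.DataFrame({"A": [5, 8, 2], "B": [5, 8, 2]})
        got = occupancy.estimate_size_factors(counts)
        assert all(v == pytest.approx(1.0) for v in got.values())

    def test_all_zero_regions_rejected(self):
        counts = pd.DataFrame({"A": [0, 5], "B": [3, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            occupancy.estimate_size_factors(counts)

    def test_recovers_planted_depth_within_5pct(self, two_group_design):
        depth = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 0.8, 1.2, 2.5])
        scales = dict(zip(two_group_design.index, depth))
        counts, _, _ = simulate.gen_counts(
            pd.DataFrame(index=range(2000)),
            two_group_design,
            lfc=np.zeros(2000),
            dispersion=0.05,
            spikein_scale=scales,
            seed=23,
        )
        got = occupancy.estimate_size_factors(counts)
        expected = depth / np.exp(np.mean(np.log(depth)))
        for s, e in zip(two_group_design.index, expected):
            assert got[s] == pytest.approx(e, rel=0.05)


class TestDispersions:
    def _counts(self, alpha, n=2000, seed=29, design=None):
        design = design if design is not None else pd.DataFrame(
            {"group": ["A"] * 4 + ["B"] * 4}, index=[f"s{i}" for i in range(8)]
        )
        counts, _, _ = simulate.gen_counts(
            pd.DataFrame(index=range(n)), design, lfc=np.zeros(n),
            dispersion=alpha, seed=seed,
        )
        return counts, design

    def test_median_alpha_recovered_in_band(self):
        counts, design = self._counts(0.1)
        sf = occupancy.estimate_size_factors(counts)
        alpha = occupancy.estimate_dispersions(
            counts, sf, groups=dict(design["group"])
        )
        assert 0.05 <= np.median(alpha) <= 0.2

    def test_poisson_data_sits_near_floor(self):
        counts, design = self._counts(1e-6)
        sf = occupancy.estimate_size_factors(counts)
        alpha = occupancy.estimate_dispersions(counts, sf, groups=dict(design["group"]))
        assert np.median(alpha) < 0.01

    def test_constant_counts_give_floor(self):
        counts = pd.DataFrame(np.full((50, 4), 100), columns=list("abcd"))
        sf = {c: 1.0 for c in counts.columns}
        alpha = occupancy.estimate_dispersions(counts, sf)
        assert np.all(alpha <= 1e-6)

    def test_single_replicate_group_rejected(self):
        counts = pd.DataFrame(np.ones((10, 3), dtype=int) * 5, columns=list("abc"))
        with pytest.raises(ValueError, match="<2 replicates"):
            occupancy.estimate_dispersions(
                counts, {c: 1.0 for c in counts.columns}, groups={"a": "x", "b": "y", "c": "y"}
            )


class TestNbWald:
    def test_null_type_one_error_near_nominal(self, two_group_design):
        counts, _, _ = simulate.gen_counts(
            pd.DataFrame(index=range(2000)), two_group_design,
            lfc=np.zeros(2000), dispersion=0.1, seed=31,
        )
        sf = occupancy.estimate_size_factors(counts)
        res = occupancy.nb_wald_test(counts, two_group_design, ("group", "B", "A"), sf)
        frac = (res["wald_p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_on_planted_lfc(self, two_group_design):
        counts, _, _ = simulate.gen_counts(
            pd.DataFrame(index=range(2000)), two_group_design,
            lfc={i: -2.0 for i in range(500)}, dispersion=0.1,
            mean_range=(200.0, 200.0), seed=33,
        )
        sf = occupancy.estimate_size_factors(counts)
        res = occupancy.nb_wald_test(counts, two_group_design, ("group", "B", "A"), sf)
        assert (res["padj"].iloc[:500] < 0.05).mean() >= 0.9
        # location check with true (unit) size factors: median-of-ratios is
        # mildly biased when a quarter of regions change in one direction
        res_true = occupancy.nb_wald_test(
            counts, two_group_design, ("group", "B", "A"),
            {c: 1.0 for c in counts.columns},
        )
        assert np.median(res_true["log2fc"].iloc[:500]) == pytest.approx(-2.0, abs=0.2)

    def test_identical_group_means_give_null_result(self, two_group_design):
        row = np.array([[100] * 8])
        counts = pd.DataFrame(np.repeat(row, 5, axis=0), columns=two_group_design.index)
        counts.iloc[:, 0] += np.arange(5)  # break exact degeneracy of sf
        sf = {c: 1.0 for c in counts.columns}
        alpha = np.full(5, 0.05)
        res = occupancy.nb_wald_test(
            counts, two_group_design, ("group", "B", "A"), sf, dispersions=alpha
        )
        assert np.all(np.abs(res["log2fc"]) < 0.1)
        assert np.all(res["wald_p"] > 0.5)

    def test_contrast_antisymmetry(self, two_group_design):
        counts, _, _ = simulate.gen_counts(
            pd.DataFrame(index=range(200)), two_group_design,
            lfc={i: 1.5 for i in range(50)}, dispersion=0.1, seed=35,
        )
        sf = occupancy.estimate_size_factors(counts)
        alpha = occupancy.estimate_dispersions(
            counts, sf, groups=dict(two_group_design["group"])
        )
        fwd = occupancy.nb_wald_test(counts, two_group_design, ("group", "B", "A"), sf, alpha)
        rev = occupancy.nb_wald_test(counts, two_group_design, ("group", "A", "B"), sf, alpha)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-6)
        np.testing.assert_allclose(fwd["wald_p"], rev["wald_p"], atol=1e-9)

    def test_all_zero_region_flagged_p_one(self, two_group_design):
        counts = pd.DataFrame(
            np.vstack([np.zeros(8, dtype=int), np.full(8, 50)]),
            columns=two_group_design.index,
        )
        sf = {c: 1.0 for c in counts.columns}
        res = occupancy.nb_wald_test(
            counts, two_group_design, ("group", "B", "A"), sf, dispersions=np.array([0.1, 0.1])
        )
        assert res.loc[0, "degenerate"]
        assert res.loc[0, "wald_p"] == 1.0

    def test_against_pydeseq2_reference(self, two_group_design):
        """Independent cross-check: fold changes and p-values track DESeq2's
        on the same matrix (pydeseq2 is the oracle, never the engine)."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        counts, _, _ = simulate.gen_counts(
            pd.DataFrame(index=range(300)), two_group_design,
            lfc={i: (-2.0 if i < 60 else 2.0) for i in range(120)},
            dispersion=0.1, seed=37,
        )
        sf = occupancy.estimate_size_factors(counts)
        mine = occupancy.nb_wald_test(counts, two_group_design, ("group", "B", "A"), sf)
        meta = two_group_design.rename(columns={"group": "condition"})
        dds = DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        ref = ds.results_df  # str-indexed; compare positionally
        rho = np.corrcoef(mine["log2fc"], ref["log2FoldChange"])[0, 1]
        assert rho > 0.98
        diff = np.abs(mine["log2fc"].to_numpy() - ref["log2FoldChange"].to_numpy())
        assert np.median(diff) < 0.05
        agree = (mine["padj"].to_numpy() < 0.05) == (
            ref["padj"].fillna(1.0).to_numpy() < 0.05
        )
        assert agree.mean() > 0.9


class TestBH:
    def test_stepup_hand_example(self):
        got = occupancy.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert occupancy.bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_matches_quadratic_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 40))
            np.testing.assert_allclose(occupancy.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_nan_propagates_and_excluded_from_m(self):
        got = occupancy.bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(got[1])
        np.testing.assert_allclose(got[[0, 2]], occupancy.bh_adjust([0.01, 0.02]))


class TestCombinatorial:
    def _res(self, lfc, padj):
        return pd.DataFrame({"log2fc": lfc, "padj": padj})

    def test_concordant_loss_hand_example(self):
        results = {
            "Ncor1": self._res([-1.2], [0.6]),
            "Ncor2": self._res([-0.8], [0.3]),
            "Tbl1x": self._res([-2.0], [0.7]),
        }
        classified, _ = occupancy.combinatorial_classes(results)
        assert classified.loc[0, "group"] == "Ncor1-&Ncor2-&Tbl1x-"
        assert classified.loc[0, "concordant"] == "loss"
        assert classified.loc[0, "min_fdr"] == pytest.approx(0.3)

    def test_mixed_signs_not_concordant(self):
        results = {
            "Ncor1": self._res([-1.0], [0.1]),
            "Ncor2": self._res([-1.0], [0.1]),
            "Tbl1x": self._res([1.0], [0.1]),
        }
        classified, _ = occupancy.combinatorial_classes(results)
        assert classified.loc[0, "group"] == "Ncor1-&Ncor2-&Tbl1x+"
        assert classified.loc[0, "concordant"] == "mixed"

    def test_fdr_screen_excludes_and_zero_lfc_reported(self):
        results = {
            "Ncor1": self._res([-1.0, 0.0, -1.0], [0.9, 0.1, 0.6]),
            "Ncor2": self._res([-1.0, -1.0, -1.0], [0.8, 0.1, 0.4]),
        }
        classified, excluded = occupancy.combinatorial_classes(results)
        # region 0 fails the min-padj<0.5 screen; region 1 has a zero LFC
        assert list(classified.index) == [2]
        assert list(excluded.index) == [1]

    def test_group_sizes_sum_to_screen_passing_regions(self, rng):
        n = 400
        results = {
            f: self._res(rng.normal(size=n), rng.random(n)) for f in ("a", "b", "c")
        }
        classified, excluded = occupancy.combinatorial_classes(results)
        lfc = pd.DataFrame({f: results[f]["log2fc"] for f in results})
        padj = pd.DataFrame({f: results[f]["padj"] for f in results})
        expected = (
            ((lfc != 0).all(axis=1)) & (padj.min(axis=1) < 0.5)
        ).sum()
        assert classified.groupby("group").size().sum() == expected

    def test_mismatched_indices_rejected(self):
        results = {
            "a": self._res([1.0], [0.1]),
            "b": pd.DataFrame({"log2fc": [1.0], "padj": [0.1]}, index=[7]),
        }
        with pytest.raises(ValueError, match="does not match"):
            occupancy.combinatorial_classes(results)


class TestConditionDynamics:
    def test_identical_sets_all_common(self):
        peaks = intervals_df(("chr1", 0, 100), ("chr1", 500, 600))
        out = occupancy.condition_peak_dynamics(peaks, peaks)
        assert (out["category"] == "common").all()

    def test_disjoint_sets_no_common(self):
        a = intervals_df(("chr1", 0, 100))
        b = intervals_df(("chr1", 500, 600))
        out = occupancy.condition_peak_dynamics(a, b)
        assert set(out["category"]) == {"SR-specific", "PD-specific"}

    def test_partition_exhaustive_and_disjoint(self, rng):
        from _oracles import random_intervals

        a, b = random_intervals(rng, 60), random_intervals(rng, 60)
        out = occupancy.condition_peak_dynamics(a, b)
        assert out["category"].notna().all()
        # merged regions are pairwise disjoint
        srt = out.sort_values(["chrom", "start"])
        for c, sub in srt.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()
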