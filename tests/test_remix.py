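"""Reference-sample summarization, scaling constant f, reconstruction, planning."""

import numpy as np
import pandas as pd
import pytest

from hampcr import (
    AmpliconMap,
    CountTable,
    RemixSummary,
    SampleMetadata,
    aggregate_by_taxon,
    community_design,
    fourth_root,
    compare_replicates,
    microbial_load,
    plan_remix,
    reconstruct,
    simulate_counts,
    simulate_remix,
    summarize,
)


@pytest.fixture
def two_row_map():
    return AmpliconMap.from_dict({"host_GI": "host", "m": "16S-V4"})


class TestScalingConstant:
    def test_no_remix_gives_f_one(self):
        # reference fractions equal pooled fractions -> f = 1
        s = RemixSummary(h=30, m=70, H=300, M=700)
        assert s.f == pytest.approx(1.0)

    def test_reported_run_fractions(self):
        # reference 19.2% host vs remixed 2.6% host, per 1000 counts
        s = RemixSummary(h=26, m=974, H=192, M=808)
        assert s.f == pytest.approx((192 * 974) / (808 * 26))
        assert s.f == pytest.approx(8.902, abs=1e-3)

    def test_scale_invariance(self):
        a = RemixSummary(h=26, m=974, H=192, M=808)
        b = RemixSummary(h=52, m=1948, H=384, M=1616)
        assert a.f == pytest.approx(b.f)

    def test_undefined_when_mh_zero(self):
        with pytest.raises(ZeroDivisionError):
            RemixSummary(h=0, m=10, H=5, M=5).f


class TestSummarize:
    def test_sums_split_by_reference_flag(self, two_row_map):
        t = CountTable.from_arrays([[10, 2, 192], [90, 98, 808]],
                                   ["host_GI", "m"], ["s1", "s2", "ref"])
        meta = SampleMetadata.from_reference_flags(
            {"s1": False, "s2": False, "ref": True})
        s = summarize(t, two_row_map, meta)
        assert (s.h, s.m, s.H, s.M) == (12, 188, 192, 808)

    def test_multiple_references_count_weighted(self, two_row_map):
        t = CountTable.from_arrays([[10, 100, 50], [90, 900, 950]],
                                   ["host_GI", "m"], ["s1", "r1", "r2"])
        meta = SampleMetadata.from_reference_flags(
            {"s1": False, "r1": True, "r2": True})
        s = summarize(t, two_row_map, meta)
        assert (s.H, s.M) == (150, 1850)

    def test_requires_a_reference(self, two_row_map):
        t = CountTable.from_arrays([[1], [1]], ["host_GI", "m"], ["s1"])
        meta = SampleMetadata.from_reference_flags({"s1": False})
        with pytest.raises(ValueError, match="reference"):
            summarize(t, two_row_map, meta)

    def test_f_invariant_to_reference_depth(self, two_row_map):
        # same reference composition at 10x the depth: identical f
        t1 = CountTable.from_arrays([[5, 19], [95, 81]],
                                    ["host_GI", "m"], ["s1", "ref"])
        t2 = CountTable.from_arrays([[5, 190], [95, 810]],
                                    ["host_GI", "m"], ["s1", "ref"])
        meta = SampleMetadata.from_reference_flags({"s1": False, "ref": True})
        f1 = summarize(t1, two_row_map, meta).f
        f2 = summarize(t2, two_row_map, meta).f
        assert f1 == pytest.approx(f2)


class TestReconstruct:
    def test_f_one_is_identity(self, two_row_map):
        t = CountTable.from_arrays([[30, 30], [70, 70]],
                                   ["host_GI", "m"], ["s1", "ref"])
        s = RemixSummary(h=30, m=70, H=30, M=70)
        out = reconstruct(t, two_row_map, s)
        pd.testing.assert_frame_equal(out, t.counts.astype(float))

    def test_corrected_pooled_host_share_matches_reference(self, two_row_map):
        s = RemixSummary(h=26, m=974, H=192, M=808)
        t = CountTable.from_arrays([[26], [974]], ["host_GI", "m"], ["s1"])
        out = reconstruct(t, two_row_map, s)
        share = out.loc["host_GI", "s1"] / out["s1"].sum()
        assert share == pytest.approx(0.192, abs=1e-3)

    def test_noise_free_remix_recovers_every_sample_ratio_exactly(self, rng):
        # scale host counts of every sample by a common factor, append an
        # exact reference; reconstruction must undo it exactly
        n = 8
        host = rng.integers(100, 5000, size=n).astype(float)
        microbe = rng.integers(1000, 50000, size=n).astype(float)
        df = pd.DataFrame([host, microbe], index=["host_GI", "m"],
                          columns=[f"s{i}" for i in range(n)])
        amap = AmpliconMap.from_dict({"host_GI": "host", "m": "16S-V4"})
        lam = 0.0946
        remixed = df.copy()
        remixed.loc["host_GI"] *= lam
        remixed["ref"] = df.sum(axis=1)  # preserves original pooled ratio
        meta = SampleMetadata.from_reference_flags(
            {**{f"s{i}": False for i in range(n)}, "ref": True})
        s = summarize(remixed, amap, meta)
        assert s.f == pytest.approx(1 / lam)
        out = reconstruct(remixed, amap, s)
        np.testing.assert_allclose(
            out[[f"s{i}" for i in range(n)]].loc["host_GI"], host)

    def test_commutes_with_taxon_aggregation_on_microbial_rows(
            self, small_table, small_map):
        s = RemixSummary(h=10, m=90, H=30, M=70)
        rec_then_agg_microbes = reconstruct(small_table, small_map, s).drop(
            index=["host_GI"])
        agg = aggregate_by_taxon(small_table, small_map)
        agg_map = AmpliconMap.from_dict(
            {"host": "host", "Sphingomonas": "16S-V4", "Pseudomonas": "16S-V4"})
        agg_then_rec = reconstruct(agg, agg_map, s).drop(index=["host"])
        grouped = rec_then_agg_microbes.groupby(
            small_map.table.loc[rec_then_agg_microbes.index, "taxon_label"]).sum()
        pd.testing.assert_frame_equal(
            grouped.sort_index(), agg_then_rec.sort_index(), check_names=False)


class TestEndToEndRecovery:
    def test_simulated_remix_loads_match_prermix_loads(self):
        design = community_design(n_samples=40, n_asvs=40,
                                  pooled_host_fraction=0.22, depth=100_000, seed=11)
        table, amap, _ = simulate_counts(design)
        pre = microbial_load(table, amap)
        remixed, meta, lam = simulate_remix(table, amap, 0.026,
                                            reference_depth=100_000, seed=12)
        summary = summarize(remixed, amap, meta)
        corrected = reconstruct(remixed, amap, summary)
        samples = [s for s in table.sample_ids]
        host_c = corrected.loc["host_GI", samples]
        loads_c = corrected.drop(index="host_GI")[samples].div(host_c, axis=1)
        r2, _, _ = compare_replicates(
            fourth_root(pre.loads.to_numpy()), fourth_root(loads_c.to_numpy()))
        assert r2 >= 0.99

    def test_expectation_mode_recovery_is_exact(self):
        design = community_design(n_samples=10, n_asvs=15, depth=50_000, seed=5)
        table, amap, _ = simulate_counts(design, mode="expectation")
        remixed, meta, lam = simulate_remix(table, amap, 0.05,
                                            mode="expectation")
        summary = summarize(remixed, amap, meta)
        assert summary.f * lam == pytest.approx(1.0)
        corrected = reconstruct(remixed, amap, summary)
        np.testing.assert_allclose(
            corrected[table.sample_ids].to_numpy(),
            table.counts.to_numpy().astype(float), rtol=1e-9)


class TestPlanRemix:
    def test_target_equal_current_keeps_composition(self):
        plan = plan_remix(0.22, 0.22)
        assert plan.proportions["host"] == pytest.approx(0.22)
        assert plan.proportions["microbial"] == pytest.approx(0.78)

    def test_host_volume_share_algebra(self):
        # 22% -> 5% host with fraction molarities proportional to pool shares
        plan = plan_remix(0.22, 0.05)
        expected_ratio = (0.05 / 0.95) * (0.78 / 0.22)
        got = plan.volume_shares["host"] / plan.volume_shares["microbial"]
        assert got == pytest.approx(expected_ratio)
        # recompute the resulting molar fraction from the volumes
        molar_host = plan.volume_shares["host"] * plan.host_molarity
        molar_microbe = plan.volume_shares["microbial"] * plan.microbial_molarity
        assert molar_host / (molar_host + molar_microbe) == pytest.approx(0.05)

    def test_reference_spike_ins_reduce_other_shares_proportionally(self):
        base = plan_remix(0.22, 0.05)
        with_refs = plan_remix(0.22, 0.05, n_references=4,
                               reference_fraction_each=0.01)
        assert with_refs.proportions["reference"] == pytest.approx(0.04)
        assert with_refs.proportions["host"] == pytest.approx(
            base.proportions["host"] * 0.96)
        assert sum(with_refs.proportions.values()) == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [0.0, 1.0, -0.2, 1.5])
    def test_infeasible_target_rejected(self, target):
        with pytest.raises(ValueError):
            plan_remix(0.22, target)
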