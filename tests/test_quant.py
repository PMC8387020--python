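"""Relative abundance, microbial load, transforms, replicate statistics."""

import numpy as np
import pandas as pd
import pytest

from hampcr import (
    AmpliconMap,
    CountTable,
    SimulationDesign,
    compare_replicates,
    copy_number_normalize,
    fourth_root,
    microbial_load,
    min_abundance_filter,
    mixture_mass_fraction,
    relative_abundance,
    simulate_counts,
    titration_expectation,
)


class TestRelativeAbundance:
    def test_drop_host_rescales_microbes_to_one(self, small_table, small_map):
        ra = relative_abundance(small_table, small_map, drop_host=True)
        assert ra.fractions.loc["m1", "s1"] == pytest.approx(0.5)
        assert ra.fractions.loc["m2", "s1"] == pytest.approx(0.5)
        assert not ra.host_included

    def test_keep_host(self, small_table, small_map):
        ra = relative_abundance(small_table, small_map, drop_host=False)
        assert ra.fractions.loc["host_GI", "s1"] == pytest.approx(0.5)
        assert ra.fractions.loc["m1", "s1"] == pytest.approx(0.25)

    def test_matches_counts_over_depth_brute_force(self, random_table):
        ra = relative_abundance(random_table)
        brute = random_table.counts / random_table.counts.sum(axis=0)
        pd.testing.assert_frame_equal(ra.fractions, brute)

    def test_zero_depth_column_flagged_as_zeros(self):
        t = CountTable.from_arrays([[3, 0], [1, 0]], ["a", "b"], ["s1", "s2"])
        with pytest.warns(UserWarning, match="s2"):
            ra = relative_abundance(t)
        assert ra.zero_depth_samples == ("s2",)
        assert (ra.fractions["s2"] == 0).all()


class TestMicrobialLoad:
    def test_load_arithmetic(self):
        t = CountTable.from_arrays([[4], [96]], ["h", "m"], ["s"])
        amap = AmpliconMap.from_dict({"h": "host", "m": "16S-V4"})
        lt = microbial_load(t, amap)
        assert lt.total_load["s"] == pytest.approx(24.0)

    def test_zero_microbes_gives_zero_load(self):
        t = CountTable.from_arrays([[500], [0]], ["h", "m"], ["s"])
        amap = AmpliconMap.from_dict({"h": "host", "m": "16S-V4"})
        assert microbial_load(t, amap).total_load["s"] == 0

    def test_zero_host_flagged_not_valued(self):
        t = CountTable.from_arrays([[0], [10]], ["h", "m"], ["s"])
        amap = AmpliconMap.from_dict({"h": "host", "m": "16S-V4"})
        lt = microbial_load(t, amap)
        assert lt.undefined_samples == ("s",)
        assert np.isnan(lt.loads.loc["m", "s"])

    def test_no_host_in_map_is_config_error(self, small_table):
        amap = AmpliconMap.from_dict(
            {a: "16S-V4" for a in small_table.asv_ids})
        with pytest.raises(Exception, match="host"):
            microbial_load(small_table, amap)

    def test_host_variants_sum_into_denominator(self):
        t = CountTable.from_arrays([[3], [1], [8]], ["h1", "h2", "m"], ["s"])
        amap = AmpliconMap.from_dict({"h1": "host", "h2": "host", "m": "16S"})
        assert microbial_load(t, amap).total_load["s"] == pytest.approx(2.0)

    def test_scale_invariance_of_loads(self, small_table, small_map):
        # multiplying a whole count column by k leaves loads unchanged
        k = 7
        scaled = CountTable(small_table.counts * k)
        a = microbial_load(small_table, small_map).loads
        b = microbial_load(scaled, small_map).loads
        pd.testing.assert_frame_equal(a, b)


class TestCopyNumber:
    def test_division(self):
        t = CountTable.from_arrays([[10], [80]], ["h", "m"], ["s"])
        amap = AmpliconMap.from_dict({"h": "host", "m": "16S"},
                                     copy_numbers={"h": 1, "m": 4})
        lt = copy_number_normalize(microbial_load(t, amap), amap)
        assert lt.loads.loc["m", "s"] == pytest.approx(2.0)

    def test_unit_copy_numbers_are_identity(self, small_table, small_map):
        lt = microbial_load(small_table, small_map)
        out = copy_number_normalize(lt, small_map)
        pd.testing.assert_frame_equal(out.loads, lt.loads)

    def test_random_table_matches_elementwise_brute_force(self, random_table, rng):
        ids = random_table.asv_ids
        cns = {a: float(rng.uniform(1, 10)) for a in ids}
        amap = AmpliconMap.from_dict(
            {ids[0]: "host", **{a: "16S" for a in ids[1:]}}, copy_numbers=cns)
        lt = microbial_load(random_table, amap)
        out = copy_number_normalize(lt, amap)
        for a in ids[1:]:
            expected = lt.loads.loc[a] / cns[a]
            pd.testing.assert_series_equal(out.loads.loc[a], expected)


class TestTransformsAndFilter:
    @pytest.mark.parametrize("x,expected", [(0, 0), (16, 2), (0.0001, 0.1)])
    def test_fourth_root_values(self, x, expected):
        assert fourth_root(np.array([x]))[0] == pytest.approx(expected)

    def test_fourth_root_rejects_negative(self):
        with pytest.raises(ValueError):
            fourth_root(np.array([-1.0]))

    def test_min_abundance_filter_drops_subthreshold_row(self, small_table, small_map):
        ra = relative_abundance(small_table, small_map, drop_host=True)
        low = ra.fractions.copy()
        low.loc["rare"] = 0.0004  # below the 0.05% default in every sample
        low = low.div(low.sum(axis=0), axis=1)
        from hampcr.quant import RelAbundanceTable
        padded = RelAbundanceTable(low, host_included=False)
        out = min_abundance_filter(padded)  # default threshold 0.0005
        assert "rare" not in out.fractions.index

    def test_threshold_zero_is_identity(self, small_table, small_map):
        ra = relative_abundance(small_table, small_map, drop_host=True)
        out = min_abundance_filter(ra, threshold=0.0)
        pd.testing.assert_frame_equal(out.fractions, ra.fractions)

    def test_matches_brute_force_row_scan(self, random_table, rng):
        ra = relative_abundance(random_table)
        thr = 0.02
        for rule in ("any-sample", "mean"):
            out = min_abundance_filter(ra, threshold=thr, rule=rule)
            survivors = set()
            for a in ra.fractions.index:
                row = ra.fractions.loc[a]
                ok = (row >= thr).any() if rule == "any-sample" else row.mean() >= thr
                if ok:
                    survivors.add(a)
            assert set(out.fractions.index) == survivors


class TestCompareReplicates:
    def test_identical_replicates(self, rng):
        v = rng.uniform(size=100)
        r2, ks, p = compare_replicates(v, v)
        assert r2 == pytest.approx(1.0)
        assert ks == pytest.approx(0.0)

    def test_independent_noise_has_near_zero_r2(self, rng):
        a, b = rng.uniform(size=1000), rng.uniform(size=1000)
        r2, _, _ = compare_replicates(a, b)
        assert r2 < 0.02

    def test_multinomial_replicates_at_deep_coverage(self, rng):
        # two draws at depth 1e5 from one composition: near-perfect fidelity
        p = rng.dirichlet(np.full(100, 0.5))
        a = rng.multinomial(100_000, p) / 100_000
        b = rng.multinomial(100_000, p) / 100_000
        r2, _, pval = compare_replicates(fourth_root(a), fourth_root(b))
        assert r2 >= 0.99
        assert pval > 0.05

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            compare_replicates([1.0, 2.0], [1.0, 2.0])


class TestTitrationExpectation:
    def test_pure_endpoint_returns_component_load(self):
        m = pd.Series({"x": 10.0}); out = titration_expectation(m, 2.0, m * 0, 1.0, 7, 0)
        assert out["x"] == pytest.approx(5.0)

    def test_equal_volume_mix_is_ratio_of_weighted_sums(self):
        # (1*10 + 1*0) / (1*1 + 1*1) = 5, not the mean of 10 and 0 ratios
        out = titration_expectation(pd.Series({"x": 10.0}), 1.0,
                                    pd.Series({"x": 0.0}), 1.0, 1, 1)
        assert out["x"] == pytest.approx(5.0)

    def test_monotone_in_high_load_component_volume(self):
        hi, lo = pd.Series({"x": 50.0}), pd.Series({"x": 1.0})
        loads = [titration_expectation(hi, 1.0, lo, 1.0, v, 7 - v)["x"]
                 for v in range(8)]
        assert all(a < b for a, b in zip(loads, loads[1:]))

    def test_zero_host_denominator_flagged_nan(self):
        out = titration_expectation(pd.Series({"x": 1.0}), 0.0,
                                    pd.Series({"x": 2.0}), 0.0, 1, 1)
        assert np.isnan(out["x"])

    def test_both_volumes_zero_rejected(self):
        with pytest.raises(ValueError):
            titration_expectation(pd.Series({"x": 1.0}), 1.0,
                                  pd.Series({"x": 1.0}), 1.0, 0, 0)


class TestMixtureMassFraction:
    def test_extreme_design_points(self):
        # 240 uL bacterial + 760 uL plant, both 10 ng/uL -> 24% bacterial
        assert mixture_mass_fraction(760, 10, 240, 10) == pytest.approx(0.24)
        # 2.5 uL bacterial + 997.5 uL plant -> 0.25%
        assert mixture_mass_fraction(997.5, 10, 2.5, 10) == pytest.approx(0.0025)


class TestHostInclusionDoesNotDistort:
    def test_ra_with_host_then_drop_equals_ra_without_host(self, rng):
        # same microbial templates, with and without a host amplicon present
        samples = [f"s{i}" for i in range(6)]
        microbes = pd.DataFrame(rng.lognormal(0, 1, size=(20, 6)),
                                index=[f"m{i}" for i in range(20)], columns=samples)
        with_host = SimulationDesign(
            host_templates=pd.Series(microbes.sum(axis=0) * 0.3, index=samples),
            microbial_templates=microbes, depth=200_000, seed=3)
        without_host = SimulationDesign(
            host_templates=pd.Series(1e-9, index=samples),
            microbial_templates=microbes, depth=200_000, seed=4)
        t1, m1, _ = simulate_counts(with_host)
        t2, m2, _ = simulate_counts(without_host)
        ra1 = relative_abundance(t1, m1, drop_host=True).fractions
        ra2 = relative_abundance(t2, m2, drop_host=True).fractions
        r2, _, _ = compare_replicates(fourth_root(ra1.to_numpy()),
                                      fourth_root(ra2.to_numpy()))
        assert r2 >= 0.99
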