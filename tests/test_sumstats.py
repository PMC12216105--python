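"""Summary-statistics engine: hand-computed examples, brute-force oracle
equivalence, and structural invariants."""

import numpy as np
import pytest

from demoml.demography import SampleDesign
from demoml.simulate import LocusData
from demoml.sumstats import (
    StatConfig,
    afibs_features,
    aggregate_features,
    build_schema,
    classic_stats,
    cross_pop_features,
    ibs_features,
    ibs_m_values,
    ld_bin_edges,
    ld_features,
    locus_stat_vector,
    sfs_features,
    window_haplo_het,
)

import _bruteforce as bf
from conftest import random_tiny_locus


class TestClassicStats:
    def test_hand_example(self):
        # 4 haplotypes, derived counts {1, 2}, L=1000
        hap = np.array([[1, 1], [0, 1], [0, 0], [0, 0]])
        pos = np.array([100.0, 500.0])
        res = classic_stats(hap, pos, 1000.0)
        assert res["S"] == pytest.approx(0.002)
        assert res["PI_mean"] == pytest.approx((0.5 + 2 / 3) / 2)
        assert res["D"] == pytest.approx(0.59, abs=0.005)

    def test_monomorphic_masks_d(self):
        hap = np.zeros((4, 0), dtype=int)
        res = classic_stats(hap, np.array([]), 1000.0)
        assert res["S"] == 0
        assert np.isnan(res["D"]) and np.isnan(res["PI_mean"])

    def test_per_site_het_is_pairwise_difference_fraction(self):
        rng = np.random.default_rng(1)
        hap = rng.integers(0, 2, size=(6, 5))
        hap[:, 0] = [1, 0, 0, 0, 0, 0]  # ensure at least one segregating site
        res = classic_stats(hap, np.arange(5, dtype=float), 100.0)
        ref = bf.bf_classic(hap, np.arange(5, dtype=float), 100.0)
        for k in res:
            np.testing.assert_allclose(res[k], ref[k], rtol=1e-12)


class TestWindowHet:
    def test_empty_window_and_distinct_haplotypes(self):
        # window 1 has no SNPs -> H=0; window 0 has all-distinct haplotypes
        hap = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        pos = np.array([10.0, 20.0])
        res = window_haplo_het(hap, pos, 100_000.0, 50_000.0)
        # exactly 2 windows: H = {0.75, 0.0}
        assert res["WinH_mean"] == pytest.approx(0.375)
        assert res["WinH_sd"] == pytest.approx(0.375)

    def test_window_count_tiling(self):
        hap = np.ones((4, 1), dtype=int)
        hap[0, 0] = 0
        for L, w, n_win in ((100_000, 50_000, 2), (120_000, 50_000, 3)):
            res = bf.bf_window_het(hap, [1.0], L, w)
            mine = window_haplo_het(hap, np.array([1.0]), float(L), float(w))
            assert mine["WinH_mean"] == pytest.approx(res["WinH_mean"])


class TestSfs:
    def test_single_singleton(self):
        hap = np.zeros((20, 1), dtype=int)
        hap[0, 0] = 1
        res = sfs_features(hap, np.array([10.0]), range(1, 20))
        assert res["SFS_1"] == 100.0
        assert all(res[f"SFS_{i}"] == 0.0 for i in range(2, 20))
        assert all(np.isnan(res[f"SFS_gapsd_{i}"]) for i in range(1, 20))

    def test_gap_sd_uses_physical_distance(self):
        hap = np.zeros((4, 3), dtype=int)
        hap[:2, :] = 1  # all three sites at derived count 2
        pos = np.array([100.0, 300.0, 700.0])
        res = sfs_features(hap, pos, range(1, 4))
        assert res["SFS_gapsd_2"] == pytest.approx(np.std([200.0, 400.0]))

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            locus = random_tiny_locus(rng)
            res = sfs_features(locus.haplotypes, locus.positions,
                               range(1, locus.n_hap))
            total = sum(v for k, v in res.items()
                        if k.startswith("SFS_") and "gapsd" not in k)
            assert total == pytest.approx(100.0, abs=1e-9)


class TestLd:
    def test_perfect_ld_and_equilibrium(self):
        edges = np.array([0.0, 1e6])
        # identical columns -> r^2 = 1
        hap = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        res = ld_features(hap, np.array([10.0, 500.0]), edges)
        assert res["LD_1_mean"] == pytest.approx(1.0)
        # p_AB = p_A p_B exactly -> r^2 = 0
        hap = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        res = ld_features(hap, np.array([10.0, 500.0]), edges)
        assert res["LD_1_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_three_sites_match_brute_force(self):
        rng = np.random.default_rng(3)
        hap = np.array([[1, 0, 1], [1, 1, 0], [0, 1, 1], [0, 0, 0]])
        pos = np.array([100.0, 200.0, 400.0])
        edges = np.array([0.0, 1000.0])
        res = ld_features(hap, pos, edges, rng=rng)
        ref = bf.bf_ld(hap, pos, edges)
        np.testing.assert_allclose(res["LD_1_mean"], ref["LD_1_mean"], rtol=1e-12)
        np.testing.assert_allclose(res["LD_1_sd"], ref["LD_1_sd"], rtol=1e-12)

    def test_bin_edges_span_printed_means(self):
        edges = ld_bin_edges(StatConfig())
        assert len(edges) == 20
        gmeans = np.sqrt(edges[:-1] * edges[1:])
        assert gmeans[0] == pytest.approx(282.0, rel=1e-6)
        assert gmeans[-1] == pytest.approx(1.4e6, rel=1e-6)

    def test_pair_cap_subsamples_deterministically(self):
        rng = np.random.default_rng(0)
        locus = random_tiny_locus(rng, n_per_pop=3, max_sites=8)
        edges = np.array([0.0, 1e6])
        a = ld_features(locus.haplotypes, locus.positions, edges, pair_cap=2,
                        rng=np.random.default_rng(5))
        b = ld_features(locus.haplotypes, locus.positions, edges, pair_cap=2,
                        rng=np.random.default_rng(5))
        assert a == b


class TestIbs:
    def test_no_differences_gives_locus_length(self):
        # all haplotypes identical: no subset-polymorphic site, one segment
        hap = np.ones((4, 2), dtype=int)
        res = ibs_features(hap, np.array([10.0, 20.0]), 10_000.0, [2])
        assert all(v == 10_000.0 for v in res.values())

    def test_pair_partition_example(self):
        # m=2, single subset (the pair), differing sites at 1000 and 5000
        hap = np.array([[1, 1], [0, 0]])
        res = ibs_features(hap, np.array([1000.0, 5000.0]), 10_000.0, [2])
        expected = np.quantile([1000.0, 4000.0, 5000.0],
                               np.arange(1, 10) / 10.0, method="linear")
        got = [res[f"IBS_m2_d{k}"] for k in range(1, 10)]
        np.testing.assert_allclose(got, expected)

    def test_deciles_non_decreasing(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            locus = random_tiny_locus(rng)
            res = ibs_features(locus.haplotypes, locus.positions,
                               locus.locus_length, ibs_m_values(locus.n_hap),
                               rng=np.random.default_rng(1))
            for m in ibs_m_values(locus.n_hap):
                dec = [res[f"IBS_m{m}_d{k}"] for k in range(1, 10)]
                assert all(a <= b + 1e-12 for a, b in zip(dec, dec[1:]))

    def test_m_larger_than_sample_rejected(self):
        hap = np.ones((4, 1), dtype=int)
        with pytest.raises(ValueError, match="m=8"):
            ibs_features(hap, np.array([1.0]), 100.0, [8])


class TestAfibs:
    def test_boundary_scan_example(self):
        # 4 haplotypes; focal SNP at 5000 carried by rows 0,1 which differ
        # at 2000 and 8000 -> segment = 8000 - 2000 = 6000
        hap = np.array([
            [1, 1, 0],
            [0, 1, 1],
            [0, 0, 0],
            [0, 0, 0],
        ])
        pos = np.array([2000.0, 5000.0, 8000.0])
        res = afibs_features(hap, pos, 10_000.0, [2])
        assert res["AFIBS_2_mean"] == pytest.approx(6000.0)

    def test_uninterrupted_carriers_span_locus(self):
        hap = np.array([[1], [1], [0], [0]])
        res = afibs_features(hap, np.array([5000.0]), 10_000.0, [2])
        assert res["AFIBS_2_mean"] == pytest.approx(10_000.0)

    def test_lengths_bounded_by_locus(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            locus = random_tiny_locus(rng)
            res = afibs_features(locus.haplotypes, locus.positions,
                                 locus.locus_length, range(1, locus.n_hap + 1))
            for k, v in res.items():
                if np.isfinite(v) and k.endswith("_mean"):
                    assert 0 < v <= locus.locus_length


class TestCrossPop:
    def test_fixed_difference_fst_one(self):
        hap1 = np.ones((4, 3), dtype=int)
        hap2 = np.zeros((4, 3), dtype=int)
        res = cross_pop_features(hap1, hap2, np.array([1.0, 2.0, 3.0]), 1000.0)
        assert res["Fst"] == pytest.approx(1.0)
        assert res["JSFS_4_0"] == pytest.approx(100.0)

    def test_private_singleton_jsfs_cell(self):
        hap1 = np.zeros((4, 1), dtype=int)
        hap1[0, 0] = 1
        hap2 = np.zeros((4, 1), dtype=int)
        res = cross_pop_features(hap1, hap2, np.array([5.0]), 1000.0)
        assert res["JSFS_1_0"] == pytest.approx(100.0)
        others = [v for k, v in res.items() if k.startswith("JSFS") and k != "JSFS_1_0"]
        assert all(v == 0.0 for v in others)

    def test_matches_brute_force_pairwise(self):
        hap1 = np.array([[1, 0, 1], [0, 1, 1]])
        hap2 = np.array([[0, 0, 1], [0, 1, 0]])
        pos = np.array([10.0, 20.0, 30.0])
        res = cross_pop_features(hap1, hap2, pos, 100.0)
        ref = bf.bf_cross(hap1, hap2, pos, 100.0)
        for k in ref:
            np.testing.assert_allclose(res[k], ref[k], rtol=1e-12, err_msg=k)


class TestAggregation:
    def test_mean_median_variance(self):
        schema = _tiny_schema()
        per_locus = [{"S_p1": v} for v in (1.0, 2.0, 4.0)]
        fv = aggregate_features(per_locus, schema)
        mu, med, var = fv.values
        assert mu == pytest.approx(7 / 3)
        assert med == pytest.approx(2.0)
        assert var == pytest.approx(7 / 3)  # sample variance, n-1 denominator

    def test_masked_locus_ignored(self):
        schema = _tiny_schema()
        per_locus = [{"S_p1": v} for v in (1.0, np.nan, 3.0)]
        fv = aggregate_features(per_locus, schema)
        assert fv.values[0] == pytest.approx(2.0)
        assert fv.n_missing[0] == 1

    def test_fully_masked_imputed_zero(self):
        schema = _tiny_schema()
        fv = aggregate_features([{"S_p1": np.nan}] * 3, schema)
        assert (fv.values == 0.0).all()
        assert (fv.n_missing == 3).all()


def _tiny_schema():
    from demoml.sumstats import FeatureSchema

    return FeatureSchema(
        names=("S_p1-mu", "S_p1-med", "S_p1-var"),
        base_names=("S_p1",) * 3,
        classes=("S",) * 3,
        scopes=("p1",) * 3,
    )


class TestSchema:
    def test_default_design_has_3024_features(self):
        schema = build_schema(SampleDesign())
        assert len(schema) == 3024

    def test_fixture_design_enumerates_consistently(self):
        design = SampleDesign(n_diploid_per_pop=4, n_loci=2, locus_length=100_000)
        schema = build_schema(design)
        # same enumeration rule at reduced scale: 2 pops of 8 haplotypes,
        # pooled 16; counted by the explicit composition
        per_pop = 6 + 2 * 8 + 38 + 9 * len(ibs_m_values(8)) + 2 * 8
        pooled = 6 + 2 * 15 + 38 + 9 * len(ibs_m_values(16)) + 2 * 15
        cross = 2 + 9 * 9
        assert len(schema) == 3 * (2 * per_pop + pooled + cross)

    def test_schema_deterministic_and_unique(self):
        a = build_schema(SampleDesign())
        b = build_schema(SampleDesign())
        assert a.names == b.names
        assert len(set(a.names)) == len(a.names)

    def test_all_eleven_classes_present(self):
        schema = build_schema(SampleDesign())
        assert set(schema.classes) == {
            "S", "D", "PI", "WinH", "SFS", "LD", "IBS", "AFIBS", "Fst", "Dxy", "JSFS",
        }


class TestOracleEquivalence:
    """Every statistic class equals an independent brute-force implementation
    on random tiny haplotype matrices."""

    @pytest.mark.parametrize("trial", range(20))
    def test_all_classes_match_brute_force(self, trial):
        rng = np.random.default_rng(1000 + trial)
        locus = random_tiny_locus(rng, n_per_pop=int(rng.integers(2, 4)))
        L = locus.locus_length
        edges = np.array([0.0, 2000.0, 5000.0, L + 1])
        for scope_hap in (locus.pop_matrix(0), locus.pop_matrix(1), locus.haplotypes):
            present = scope_hap.sum(axis=0) > 0
            hap = scope_hap[:, present]
            pos = locus.positions[present]
            n = hap.shape[0]
            freqs = range(1, n + 1)
            checks = [
                (classic_stats(hap, pos, L), bf.bf_classic(hap, pos, L)),
                (window_haplo_het(hap, pos, L, 2000.0), bf.bf_window_het(hap, pos, L, 2000.0)),
                (sfs_features(hap, pos, freqs), bf.bf_sfs(hap, pos, freqs)),
                (ld_features(hap, pos, edges, pair_cap=10**9), bf.bf_ld(hap, pos, edges)),
                (
                    ibs_features(hap, pos, L, ibs_m_values(n), n_subsets=10**6),
                    bf.bf_ibs(hap, pos, L, ibs_m_values(n)),
                ),
                (afibs_features(hap, pos, L, freqs), bf.bf_afibs(hap, pos, L, freqs)),
            ]
            for mine, ref in checks:
                assert set(mine) == set(ref)
                for k in ref:
                    np.testing.assert_allclose(
                        mine[k], ref[k], rtol=1e-9, atol=1e-9, err_msg=k
                    )
        mine = cross_pop_features(locus.pop_matrix(0), locus.pop_matrix(1),
                                  locus.positions, L)
        ref = bf.bf_cross(locus.pop_matrix(0), locus.pop_matrix(1), locus.positions, L)
        for k in ref:
            np.testing.assert_allclose(mine[k], ref[k], rtol=1e-9, atol=1e-9, err_msg=k)


class TestInvariants:
    def test_bounded_statistics_on_random_matrices(self):
        rng = np.random.default_rng(77)
        design = SampleDesign(n_diploid_per_pop=2, n_loci=1, locus_length=10_000)
        for _ in range(10):
            locus = random_tiny_locus(rng, n_per_pop=2)
            vec = locus_stat_vector(locus, design)
            for key, v in vec.items():
                if not np.isfinite(v):
                    continue
                if key.startswith(("LD_", "PI_", "WinH_")) and key.endswith(("_mean_p1", "_mean_p2", "_mean_all")):
                    assert -1e-12 <= v <= 1 + 1e-12, key
                if key.startswith(("IBS_", "AFIBS_")) and "_mean" in key:
                    assert 0 < v <= locus.locus_length + 1e-9, key
                if key.startswith("Fst"):
                    assert v <= 1 + 1e-12
                if key.startswith("Dxy"):
                    assert v >= 0

    def test_jsfs_sums_to_100(self):
        rng = np.random.default_rng(88)
        locus = random_tiny_locus(rng, n_per_pop=3)
        res = cross_pop_features(locus.pop_matrix(0), locus.pop_matrix(1),
                                 locus.positions, locus.locus_length)
        total = sum(v for k, v in res.items() if k.startswith("JSFS"))
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_row_permutation_within_population_invariant(self):
        rng = np.random.default_rng(99)
        design = SampleDesign(n_diploid_per_pop=3, n_loci=1, locus_length=10_000)
        locus = random_tiny_locus(rng, n_per_pop=3)
        base = locus_stat_vector(locus, design)
        perm = np.concatenate([rng.permutation(3), 3 + rng.permutation(3)])
        shuffled = LocusData(locus.haplotypes[perm], locus.positions,
                             locus.pop_labels, locus.locus_length)
        other = locus_stat_vector(shuffled, design)
        assert set(base) == set(other)
        for k in base:
            np.testing.assert_allclose(base[k], other[k], rtol=1e-9, atol=1e-12,
                                       err_msg=k)


# ---------------------------------------------------------------------------
# property-based invariants
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    hap=hnp.arrays(np.int8, shape=st.tuples(st.just(6), st.integers(1, 8)),
                   elements=st.integers(0, 1)),
)
def test_sfs_normalization_property(hap):
    """SFS percentages sum to 100 whenever the scope has qualifying sites."""
    counts = hap.sum(axis=0)
    if not ((counts > 0) & (counts <= 6)).any():
        return
    keep = counts > 0
    hap = hap[:, keep]
    pos = np.arange(1.0, hap.shape[1] + 1)
    res = sfs_features(hap, pos, range(1, 7))
    total = sum(v for k, v in res.items() if not k.startswith("SFS_gapsd"))
    assert total == pytest.approx(100.0, abs=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=10),
)
def test_aggregation_matches_numpy_property(values):
    """Cross-locus aggregation equals numpy mean/median/sample variance."""
    schema = _tiny_schema()
    fv = aggregate_features([{"S_p1": v} for v in values], schema)
    arr = np.array(values)
    assert fv.values[0] == pytest.approx(arr.mean(), rel=1e-12, abs=1e-12)
    assert fv.values[1] == pytest.approx(np.median(arr), rel=1e-12, abs=1e-12)
    expected_var = arr.var(ddof=1) if arr.size >= 2 else 0.0
    assert fv.values[2] == pytest.approx(expected_var, rel=1e-9, abs=1e-9)
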