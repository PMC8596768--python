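"""Summary statistics against brute-force pairwise oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lsd import (
    CoverageModel,
    LocusData,
    divergence_stats,
    diversity_stats,
    emulate_pool_reads,
    sfs_stats,
    simulate_locus,
    stat_names,
    stats_vector,
    two_deme_im_model,
)


def make_locus(matrix, labels, L=1000):
    matrix = np.asarray(matrix, dtype=np.uint8)
    pos = (np.arange(matrix.shape[1]) + 0.5) / max(matrix.shape[1], 1)
    return LocusData(matrix, pos, L, list(labels))


def brute_pi_within(matrix):
    n = matrix.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(matrix[i] != matrix[j]))
    return total / (n * (n - 1) / 2)


def brute_pi_between(ma, mb):
    total = sum(
        int(np.sum(a != b)) for a in np.asarray(ma) for b in np.asarray(mb)
    )
    return total / (len(ma) * len(mb))


class TestDiversity:
    def test_two_haplotypes_three_differences(self):
        locus = make_locus([[0, 0, 0], [1, 1, 1]], ["p", "p"])
        s, priv, pi, tw, td = diversity_stats(locus, "p")
        assert (s, priv) == (3, 3)
        assert pi == pytest.approx(3.0)
        assert tw == pytest.approx(3.0)
        assert np.isnan(td) or td == 0.0  # variance degenerates at n = 2

    def test_watterson_harmonic_normalization(self):
        # n=4, S=5 -> theta_W = 5 / (1 + 1/2 + 1/3)
        m = np.array(
            [[1, 0, 0, 1, 0], [0, 1, 0, 1, 0], [0, 0, 1, 0, 0], [0, 0, 0, 0, 1]]
        )
        locus = make_locus(m, ["p"] * 4)
        s, _, _, tw, _ = diversity_stats(locus, "p")
        assert s == 5
        assert tw == pytest.approx(5.0 / (1 + 0.5 + 1 / 3))

    def test_tajima_d_missing_when_no_segregation(self):
        locus = make_locus(np.zeros((4, 0)), ["p"] * 4)
        s, _, pi, tw, td = diversity_stats(locus, "p")
        assert s == 0 and pi == 0.0 and np.isnan(td)

    def test_single_haplotype_yields_missing_sentinels(self):
        locus = make_locus([[1, 0]], ["p"])
        s, _, pi, tw, td = diversity_stats(locus, "p")
        assert np.isnan(pi) and np.isnan(tw) and np.isnan(td)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_pi_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n, s = rng.integers(2, 8), rng.integers(1, 12)
        m = rng.integers(0, 2, size=(n, s))
        locus = make_locus(m, ["p"] * n)
        _, _, pi, _, _ = diversity_stats(locus, "p")
        assert pi == pytest.approx(brute_pi_within(m))


class TestDivergence:
    def test_random_split_of_one_population_has_zero_expected_fst(self):
        # a single panmictic sample split into two labels: E[F_ST] = 0
        from lsd import Deme, DemographicModel

        model = DemographicModel([Deme("d", 500.0)], mutation_rate=5e-6)
        rng = np.random.default_rng(21)
        vals = []
        for _ in range(300):
            locus = simulate_locus(model, {}, {"d": 20}, 1000, rng)
            relabeled = LocusData(
                locus.haplotypes, locus.positions, locus.locus_length,
                ["a", "b"] * 10,
            )
            fst, _ = divergence_stats(relabeled, "a", "b")
            vals.append(fst)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_fixed_difference_gives_fst_one(self):
        m = np.array([[1], [1], [0], [0]])
        locus = make_locus(m, ["a", "a", "b", "b"], L=5000)
        fst, dxy = divergence_stats(locus, "a", "b")
        assert fst == pytest.approx(1.0)
        assert dxy == pytest.approx(1.0 / 5000)

    def test_no_between_diversity_is_missing(self):
        locus = make_locus(np.zeros((4, 0)), ["a", "a", "b", "b"])
        fst, dxy = divergence_stats(locus, "a", "b")
        assert np.isnan(fst) and dxy == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.integers(1, 10)
        ma = rng.integers(0, 2, size=(3, s))
        mb = rng.integers(0, 2, size=(3, s))
        locus = make_locus(np.vstack([ma, mb]), ["a"] * 3 + ["b"] * 3, L=100)
        fst, dxy = divergence_stats(locus, "a", "b")
        pi_b = brute_pi_between(ma, mb)
        assert dxy == pytest.approx(pi_b / 100)
        if pi_b > 0:
            expected = 1 - 0.5 * (brute_pi_within(ma) + brute_pi_within(mb)) / pi_b
            assert fst == pytest.approx(np.clip(expected, -1, 1))

    def test_label_swap_leaves_fst_and_dxy_unchanged(self):
        rng = np.random.default_rng(4)
        m = rng.integers(0, 2, size=(6, 9))
        locus = make_locus(m, ["a"] * 3 + ["b"] * 3)
        assert divergence_stats(locus, "a", "b") == divergence_stats(locus, "b", "a")


class TestSfs:
    def test_singletons_fill_the_lowest_bin(self):
        m = np.eye(5, dtype=int)
        locus = make_locus(m, ["p"] * 5)
        bins = sfs_stats(locus, "p", 4)
        assert bins[0] == 1.0 and bins[1:].sum() == 0.0

    def test_no_segregation_gives_zero_vector(self):
        locus = make_locus(np.zeros((4, 0)), ["p"] * 4)
        assert np.array_equal(sfs_stats(locus, "p", 5), np.zeros(5))

    def test_bins_sum_to_one_when_polymorphic(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 2, size=(6, 20))
        locus = make_locus(m, ["p"] * 6)
        assert sfs_stats(locus, "p", 5).sum() == pytest.approx(1.0)


class TestPooling:
    def test_huge_fixed_depth_recovers_pool_frequencies(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, size=(20, 30))
        locus = make_locus(m, ["p"] * 20)
        pool = emulate_pool_reads(locus, {"p": 10}, CoverageModel(5000, fixed=True), rng)
        freqs = pool.frequencies()[:, 0]
        truth = m.mean(axis=0)
        assert np.max(np.abs(freqs - truth)) < 0.05

    def test_fixed_derived_site_gives_only_derived_reads(self):
        locus = make_locus(np.ones((8, 3)), ["p"] * 8)
        pool = emulate_pool_reads(locus, {"p": 4}, CoverageModel(30, fixed=True), 0)
        assert np.array_equal(pool.derived, pool.depth)

    def test_negative_binomial_depth_mean(self):
        rng = np.random.default_rng(2)
        locus = make_locus(rng.integers(0, 2, size=(10, 10_000)), ["p"] * 10)
        pool = emulate_pool_reads(locus, {"p": 5}, CoverageModel(30.0, dispersion=5.0), rng)
        mean, disp = 30.0, 5.0
        var = mean + mean**2 / disp
        se = np.sqrt(var / 10_000)
        assert abs(pool.depth[:, 0].mean() - mean) < 3 * se

    def test_oversized_pool_rejected(self):
        locus = make_locus(np.zeros((4, 2)), ["p"] * 4)
        with pytest.raises(ValueError):
            emulate_pool_reads(locus, {"p": 3}, CoverageModel(30, fixed=True), 0)

    def test_invalid_coverage_parameters_rejected(self):
        with pytest.raises(ValueError):
            CoverageModel(-1.0)
        with pytest.raises(ValueError):
            CoverageModel(10.0, dispersion=0.0)

    def test_haplotype_and_infinite_coverage_paths_agree_on_pi(self):
        model = two_deme_im_model(n1=500, n2=500, mutation_rate=5e-6)
        rng = np.random.default_rng(3)
        locus = simulate_locus(model, {"M12": 2.0, "M21": 2.0},
                               {"deme1": 20, "deme2": 20}, 2000, rng)
        direct = stats_vector(locus, ["deme1", "deme2"])
        pool = emulate_pool_reads(
            locus, {"deme1": 10, "deme2": 10}, CoverageModel(20000, fixed=True), rng
        )
        pooled = stats_vector(pool, ["deme1", "deme2"])
        for col in ("pi_deme1", "pi_deme2", "dxy_deme1_deme2"):
            assert pooled[col] == pytest.approx(direct[col], rel=0.05)


class TestStatsVector:
    def test_ordering_fixed_and_stable(self):
        locus = make_locus(np.eye(4, dtype=int), ["a", "a", "b", "b"])
        v1 = stats_vector(locus, ["a", "b"], sfs_bins=3)
        v2 = stats_vector(locus, ["a", "b"], sfs_bins=3)
        assert list(v1.index) == stat_names(["a", "b"], 3)
        assert v1.equals(v2)

    def test_missing_sentinels_propagate_never_become_zero(self):
        locus = make_locus(np.array([[1, 0]]), ["a"])  # single haplotype
        v = stats_vector(locus, ["a"])
        assert np.isnan(v["pi_a"]) and np.isnan(v["tajD_a"])
        assert v["S_a"] == 0.0  # counts remain defined

    def test_theta_w_and_pi_share_expectation_under_neutrality(self):
        # paired comparison across coalescent loci: E[pi - theta_W] = 0
        from lsd import Deme, DemographicModel

        model = DemographicModel([Deme("d", 500.0)], mutation_rate=5e-6)
        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(2000):
            locus = simulate_locus(model, {}, {"d": 10}, 1000, rng)
            v = stats_vector(locus, ["d"])
            diffs.append(v["pi_d"] - v["thetaW_d"])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se
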