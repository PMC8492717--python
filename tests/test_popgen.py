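import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopop.alignment import from_strings
from mitopop.popgen import (
    PopgenError,
    amova,
    amova_from_distances,
    diff_matrix,
    haplotype_diversity,
    mean_pairwise_differences,
    mismatch_distribution,
    pairwise_fst,
)
from tests.conftest import random_alignment


def nei_oracle(counts):
    """Independent plug-in evaluation of Nei's h and V(h)."""
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    p = [c / n for c in counts]
    s2 = sum(x**2 for x in p)
    s3 = sum(x**3 for x in p)
    h = n / (n - 1) * (1 - s2)
    v = 2 / (n * (n - 1)) * (2 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return h, max(v, 0.0) ** 0.5


class TestHaplotypeDiversity:
    def test_six_unique_matches_published_row(self):
        # 6 samples / 6 haplotypes: 1.0000 +/- 0.0962
        d = haplotype_diversity([1] * 6)
        assert f"{d.h:.4f}" == "1.0000"
        assert f"{d.se_h:.4f}" == "0.0962"

    def test_single_haplotype_thirty_samples(self):
        d = haplotype_diversity([30])
        assert d.h == 0.0 and d.se_h == 0.0 and d.k == 1

    def test_direct_formula_evaluation(self):
        d = haplotype_diversity([2, 1, 1])
        assert d.h == pytest.approx(4 / 3 * (1 - (1 / 4 + 1 / 16 + 1 / 16)))
        assert d.h == pytest.approx(0.833333333333)

    def test_h_zero_iff_single_haplotype(self):
        assert haplotype_diversity([5]).h == 0.0
        assert haplotype_diversity([4, 1]).h > 0.0

    def test_error_below_two(self):
        with pytest.raises(PopgenError):
            haplotype_diversity([1])

    def test_thousand_random_vectors_match_oracle(self, rng):
        for _ in range(1000):
            k = int(rng.integers(1, 8))
            counts = rng.integers(1, 20, size=k).tolist()
            if sum(counts) < 2:
                continue
            d = haplotype_diversity(counts)
            h, se = nei_oracle(counts)
            assert abs(d.h - h) < 1e-12
            assert abs(d.se_h - se) < 1e-12


class TestPairwiseDifferences:
    def test_identical(self):
        a = from_strings(["ACGT"] * 3, pops=["p"] * 3)
        assert mean_pairwise_differences(a, "p") == 0.0

    def test_two_sequences_three_diffs(self):
        a = from_strings(["AAAAAA", "TTTAAA"], pops=["p", "p"])
        assert mean_pairwise_differences(a, "p") == 3.0

    def test_matches_double_loop_oracle(self, rng):
        a = random_alignment(rng, 10, 50, pops=["p"] * 10)
        total, npairs = 0, 0
        for i in range(10):
            for j in range(i + 1, 10):
                total += sum(
                    a.seqs[i, k] != a.seqs[j, k] for k in range(50)
                )
                npairs += 1
        assert mean_pairwise_differences(a, "p") == pytest.approx(total / npairs)

    def test_between_population_variant(self):
        a = from_strings(
            ["AAAA", "AAAT", "TTTT", "TTTA"], pops=["x", "x", "y", "y"]
        )
        # cross pairs: 4,3,3,4 -> mean 3.5 (uncorrected)
        assert mean_pairwise_differences(a, ("x", "y")) == pytest.approx(3.5)

    def test_insufficient(self):
        a = from_strings(["ACGT"], pops=["p"])
        with pytest.raises(PopgenError):
            mean_pairwise_differences(a, "p")

    def test_pairwise_policy_ignores_missing(self):
        a = from_strings(["ANAA", "ATAT"], pops=["p", "p"])
        # site 1 skipped (N); only site 3 differs
        assert mean_pairwise_differences(a, "p", missing_policy="pairwise") == 1.0


class TestMismatch:
    def test_identical_three(self):
        a = from_strings(["AAAA"] * 3, pops=["p"] * 3)
        assert mismatch_distribution(a, "p") == {0: 3}

    def test_hand_count(self):
        a = from_strings(["AAAA", "AAAT", "AATT"], pops=["p"] * 3)
        assert mismatch_distribution(a, "p") == {1: 2, 2: 1}

    def test_total_is_n_choose_2(self, rng):
        a = random_alignment(rng, 9, 30, pops=["p"] * 9)
        hist = mismatch_distribution(a, "p")
        assert sum(hist.values()) == 9 * 8 // 2

    def test_matches_bruteforce(self, rng):
        a = random_alignment(rng, 8, 40, pops=["p"] * 8)
        hist = mismatch_distribution(a, "p")
        from collections import Counter

        oracle = Counter(
            int(sum(a.seqs[i, k] != a.seqs[j, k] for k in range(40)))
            for i in range(8)
            for j in range(i + 1, 8)
        )
        assert hist == dict(sorted(oracle.items()))


def amova_oracle_one_level(d2, pops):
    """Explicit sums-of-squares AMOVA oracle (independent loops)."""
    pops = list(pops)
    N = len(pops)
    names = sorted(set(pops))
    ssd_t = sum(d2[i][j] for i in range(N) for j in range(N)) / (2 * N)
    ssd_wp = 0.0
    sizes = {}
    for p in names:
        rows = [i for i in range(N) if pops[i] == p]
        sizes[p] = len(rows)
        ssd_wp += sum(d2[i][j] for i in rows for j in rows) / (2 * len(rows))
    ssd_ap = ssd_t - ssd_wp
    df_ap, df_wp = len(names) - 1, N - len(names)
    sigma_c = ssd_wp / df_wp
    n_coef = (N - sum(v**2 for v in sizes.values()) / N) / df_ap
    sigma_a = (ssd_ap / df_ap - sigma_c) / n_coef
    return ssd_t, ssd_ap, ssd_wp, sigma_a, sigma_c


class TestAmova:
    def test_identical_populations_zero_among(self):
        a = from_strings(
            ["AAAA", "AATT"] * 2, pops=["x", "x", "y", "y"]
        )
        res = amova(a)
        among = res.components[0]
        assert among.percentage == pytest.approx(0.0, abs=1e-9)

    def test_fixed_divergent_populations(self, toy_two_pop):
        res = amova(toy_two_pop)
        assert res.phi_st == pytest.approx(1.0)
        assert res.components[0].percentage == pytest.approx(100.0)

    def test_three_pop_toy_matches_ssd_oracle(self, rng):
        a = random_alignment(rng, 18, 25, pops=["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        d2 = diff_matrix(a).astype(float) ** 2
        res = amova(a)
        ssd_t, ssd_ap, ssd_wp, sigma_a, sigma_c = amova_oracle_one_level(
            d2.tolist(), a.pop_labels()
        )
        assert res.components[0].ss == pytest.approx(ssd_ap)
        assert res.components[1].ss == pytest.approx(ssd_wp)
        assert res.components[0].variance == pytest.approx(sigma_a)
        assert res.components[1].variance == pytest.approx(sigma_c)
        # total SSD equals the sum of the partition SSDs
        assert ssd_t == pytest.approx(sum(c.ss for c in res.components))

    def test_percentages_sum_and_df(self, rng):
        a = random_alignment(rng, 15, 20, pops=["a"] * 5 + ["b"] * 4 + ["c"] * 6)
        res = amova(a)
        assert sum(c.percentage for c in res.components) == pytest.approx(100.0)
        assert res.total_df == 14

    def test_two_level_structure(self, rng):
        pops = ["a"] * 5 + ["b"] * 5 + ["c"] * 5 + ["d"] * 5
        a = random_alignment(rng, 20, 30, pops=pops)
        res = amova(a, groups={"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert len(res.components) == 3
        assert res.total_df == 19
        assert sum(c.percentage for c in res.components) == pytest.approx(100.0)
        assert res.phi_ct is not None and res.phi_sc is not None

    def test_single_population_error(self):
        a = from_strings(["AAAA", "AAAT"], pops=["x", "x"])
        with pytest.raises(PopgenError):
            amova(a)

    def test_permutation_pvalues_deterministic(self, toy_two_pop):
        r1 = amova(toy_two_pop, n_perm=99, seed=5)
        r2 = amova(toy_two_pop, n_perm=99, seed=5)
        assert r1.p_values == r2.p_values
        assert 0 < r1.p_values["phi_st"] <= 1

    def test_seed_required_for_permutations(self, toy_two_pop):
        with pytest.raises(PopgenError, match="seed"):
            amova(toy_two_pop, n_perm=10)


class TestPairwiseFst:
    def test_duplicate_population_zero(self):
        a = from_strings(
            ["AAAA", "AATT", "AAAA", "AATT"], pops=["x", "x", "y", "y"]
        )
        f = pairwise_fst(a)
        assert f.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_fixed_divergent_one(self, toy_two_pop):
        f = pairwise_fst(toy_two_pop)
        assert f.values[0, 1] == pytest.approx(1.0)

    def test_diagonal_and_symmetry(self, rng):
        a = random_alignment(rng, 16, 20, pops=["a", "b", "c", "d"] * 4)
        f = pairwise_fst(a)
        assert np.allclose(np.diag(f.values), 0.0)
        assert np.allclose(f.values, f.values.T)

    def test_cells_equal_fresh_two_pop_amova(self, rng):
        pops = ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + ["d"] * 4
        a = random_alignment(rng, 16, 30, pops=pops)
        f = pairwise_fst(a)
        for i, p in enumerate(f.populations):
            for j, q in enumerate(f.populations):
                if i >= j:
                    continue
                keep = [
                    sid for sid in a.sample_ids
                    if a.labels[sid].breed in (p, q)
                ]
                sub = a.subset(keep)
                assert f.values[i, j] == pytest.approx(amova(sub).phi_st)

    def test_invariant_to_sample_order(self, rng):
        pops = ["a"] * 5 + ["b"] * 5
        a = random_alignment(rng, 10, 25, pops=pops)
        perm = rng.permutation(10)
        from mitopop.alignment import Alignment

        b = Alignment([a.sample_ids[i] for i in perm], a.seqs[perm], dict(a.labels))
        fa = pairwise_fst(a)
        fb = pairwise_fst(b)
        ia = {p: i for i, p in enumerate(fa.populations)}
        ib = {p: i for i, p in enumerate(fb.populations)}
        for p in ia:
            for q in ia:
                assert fa.values[ia[p], ia[q]] == pytest.approx(
                    fb.values[ib[p], ib[q]]
                )

    def test_no_differentiation_mean_near_zero(self):
        # random label assignment: mean Phi_ST over replicates ~ 0
        vals = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            a = random_alignment(r, 20, 40, pops=list(r.permutation(["x"] * 10 + ["y"] * 10)))
            vals.append(pairwise_fst(a).values[0, 1])
        assert abs(np.mean(vals)) < 0.05

    def test_small_population_flagged(self):
        a = from_strings(["AAAA", "AATT", "TTTT"], pops=["x", "x", "y"])
        f = pairwise_fst(a)
        assert "y" in f.flagged


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_total_ssd_decomposition_random_instances(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 15))
    pops = [f"p{rng.integers(0, 3)}" for _ in range(n)]
    if len(set(pops)) < 2 or min(pops.count(p) for p in set(pops)) < 1:
        return
    if n - len(set(pops)) < 1:
        return
    a = random_alignment(rng, n, 15, pops=pops)
    d2 = diff_matrix(a).astype(float) ** 2
    res = amova_from_distances(d2, pops)
    ssd_t = d2.sum() / (2 * n)
    assert ssd_t == pytest.approx(sum(c.ss for c in res.components))
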