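"""Single-pair MB-MDR steps, maxT adjustment, and their oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from mbmdr import (
    GenotypeMatrix,
    ScanSettings,
    Trait,
    association_test,
    hlo_classify,
    maxt_adjust,
    pair_statistic,
    partition_pair,
)
from mbmdr.core import pair_statistic_from_scratch, permutation_indices
from mbmdr.engine import scan_matrix


def ids(n, prefix="i"):
    return tuple(f"{prefix}{k}" for k in range(n))


def make_gm(columns):
    arr = np.column_stack(columns).astype(np.int8)
    return GenotypeMatrix(arr, ids(arr.shape[1], "s"), ids(arr.shape[0]))


class TestPartition:
    def test_cell_index_definition(self):
        g = make_gm([[0, 1, 2], [0, 1, 2]])
        part = partition_pair(g, 0, 1)
        np.testing.assert_array_equal(part.cell_index, [0, 4, 8])

    def test_sizes_partition_everything(self, make_dataset):
        g, _ = make_dataset(n=200, m=3)
        part = partition_pair(g, 0, 2)
        assert part.cell_sizes.sum() == 200
        np.testing.assert_array_equal(
            part.cell_sizes, np.bincount(3 * g.values[:, 0] + g.values[:, 2], minlength=9)
        )

    def test_monomorphic_second_locus(self):
        g = make_gm([[0, 1, 2, 1], [0, 0, 0, 0]])
        part = partition_pair(g, 0, 1)
        assert set(np.flatnonzero(part.cell_sizes)) <= {0, 3, 6}

    def test_same_snp_rejected(self, make_dataset):
        g, _ = make_dataset()
        with pytest.raises(ValueError):
            partition_pair(g, 1, 1)


class TestAssociationTest:
    def test_matches_pooled_t(self, rng):
        y = Trait(rng.normal(size=40), ids(40))
        ind = (rng.random(40) < 0.4).astype(float)
        t, p, df = association_test(y, ind)
        ref = stats.ttest_ind(y.values[ind == 1], y.values[ind == 0], equal_var=True)
        assert df == 38
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_sign_is_group1_minus_group2(self):
        y = Trait([0.0, 1.0, 0.5, 5.0, 6.0, 5.5], ids(6))
        ind = np.array([0, 0, 0, 1, 1, 1.0])
        t, _, _ = association_test(y, ind)
        assert t > 0
        t_rev, _, _ = association_test(y, 1 - ind)
        assert t_rev == pytest.approx(-t, abs=1e-12)

    def test_wald_matches_normal_equations_oracle(self, rng):
        # brute-force OLS via explicit normal equations, n=50, 1 covariate
        n = 50
        y = Trait(rng.normal(size=n), ids(n))
        D = rng.normal(size=(n, 1))
        ind = (rng.random(n) < 0.5).astype(float)
        t, p, df = association_test(y, ind, D)

        X = np.column_stack([np.ones(n), D, ind])
        beta = np.linalg.solve(X.T @ X, X.T @ y.values)
        resid = y.values - X @ beta
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[-1, -1])
        assert df == n - 3
        assert t == pytest.approx(beta[-1] / se, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(beta[-1] / se), n - 3), abs=1e-10)

    def test_constant_trait_no_evidence(self):
        y = Trait(np.ones(10), ids(10))
        ind = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 0.0])
        t, p, _ = association_test(y, ind)
        assert t == 0.0 and p == 1.0

    def test_perfect_separation_p_zero_with_warning(self):
        y = Trait([1.0, 1.0, 2.0, 2.0], ids(4))
        ind = np.array([0, 0, 1, 1.0])
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            t, p, _ = association_test(y, ind)
        assert np.isinf(t) and t > 0 and p == 0.0


class TestHLOClassify:
    settings = ScanSettings(alpha1=0.1, min_cell=10, permutations=19)

    def test_constant_trait_all_o(self, make_dataset):
        g, _ = make_dataset(n=120, m=2)
        y = Trait(np.full(120, 3.0), g.sample_ids)
        labels = hlo_classify(partition_pair(g, 0, 1), y, None, self.settings)
        assert (labels.labels == "O").all()

    def test_strongly_shifted_cell_is_h(self, rng):
        # one cell of 200 samples shifted +5 sd against 800 null samples
        ga = np.r_[np.zeros(800, int), np.ones(200, int)]
        gb = ga.copy()
        g = make_gm([ga, gb])
        y_vals = rng.normal(size=1000)
        y_vals[800:] += 5.0
        y = Trait(y_vals, ids(1000))
        part = partition_pair(g, 0, 1)
        labels = hlo_classify(part, y, None, self.settings)
        assert labels.labels[4] == "H"  # cell (1,1)
        # oracle: direct cell-vs-rest t-test
        t_ref = stats.ttest_ind(y_vals[800:], y_vals[:800], equal_var=True)
        assert labels.step1_stats[4] == pytest.approx(t_ref.statistic, abs=1e-10)

    def test_small_cell_is_o_regardless_of_trait(self):
        ga = np.r_[np.zeros(50, int), np.ones(3, int)]
        gb = np.zeros(53, int)
        g = make_gm([ga, gb])
        y_vals = np.r_[np.zeros(50), np.full(3, 100.0)]
        y = Trait(y_vals, ids(53))
        labels = hlo_classify(partition_pair(g, 0, 1), y, None, self.settings)
        assert labels.labels[3] == "O"  # size 3 < min_cell 10


class TestPairStatistic:
    def test_all_o_gives_zero(self, make_dataset):
        g, _ = make_dataset(n=100, m=2)
        y = Trait(np.full(100, 1.0), g.sample_ids)
        st = ScanSettings(min_cell=5, permutations=19)
        part = partition_pair(g, 0, 1)
        labels = hlo_classify(part, y, None, st)
        assert pair_statistic(labels, part, y, None) == 0.0

    def test_matches_two_group_oracle(self, make_dataset):
        g, y = make_dataset(n=400, m=2, maf=0.4,
                            effect=lambda G: 0.8 * (G[:, 0] * G[:, 1] >= 2))
        st = ScanSettings(alpha1=0.2, min_cell=5, permutations=19)
        part = partition_pair(g, 0, 1)
        labels = hlo_classify(part, y, None, st)
        got = pair_statistic(labels, part, y, None)
        # recompute both sides from the raw groups with scipy
        candidates = [0.0]
        for mask, sign in ((labels.h_cells, 1), (labels.l_cells, -1)):
            if mask.any():
                in_group = mask[part.cell_index]
                t = stats.ttest_ind(
                    y.values[in_group], y.values[~in_group], equal_var=True
                ).statistic
                candidates.append(sign * t)
        assert got == pytest.approx(max(candidates), abs=1e-10)

    def test_invariant_under_affine_trait_transform(self, make_dataset):
        g, y = make_dataset(n=300, m=2, effect=lambda G: 0.5 * G[:, 0])
        st = ScanSettings(alpha1=0.2, min_cell=5, permutations=19)
        s1 = pair_statistic_from_scratch(g, y, 0, 1, st)
        y2 = y.with_values(2.5 * y.values - 7.0)
        s2 = pair_statistic_from_scratch(g, y2, 0, 1, st)
        assert s1 == pytest.approx(s2, rel=1e-10)


def naive_step_down_maxt(observed, perm_stats):
    """Independent loop-based Westfall-Young step-down maxT (test oracle)."""
    m = len(observed)
    B = perm_stats.shape[1]
    order = sorted(range(m), key=lambda i: -observed[i])
    p = {}
    for rank, i in enumerate(order):
        count = 0
        for b in range(B):
            u = max(perm_stats[j, b] for j in order[rank:])
            if u >= observed[i]:
                count += 1
        p[i] = (1 + count) / (B + 1)
    # monotonicity down the ranking
    running = 0.0
    for i in order:
        running = max(running, p[i])
        p[i] = running
    return np.array([p[i] for i in range(m)])


class TestMaxT:
    def test_single_hypothesis_is_marginal_permutation_p(self, rng):
        obs = np.array([2.0])
        perm = rng.normal(size=(1, 99))
        p = maxt_adjust(obs, perm)
        expected = (1 + (perm[0] >= 2.0).sum()) / 100
        assert p[0] == pytest.approx(expected)

    def test_lower_bound_and_monotonicity(self, rng):
        obs = rng.normal(size=8)
        perm = rng.normal(size=(8, 49))
        p = maxt_adjust(obs, perm)
        assert (p >= 1 / 50 - 1e-12).all() and (p <= 1).all()
        order = np.argsort(-obs, kind="stable")
        assert (np.diff(p[order]) >= -1e-12).all()

    def test_matches_naive_oracle_random_instances(self, rng):
        for _ in range(5):
            obs = rng.normal(size=6)
            perm = rng.normal(size=(6, 37))
            np.testing.assert_allclose(
                maxt_adjust(obs, perm), naive_step_down_maxt(obs, perm), atol=1e-12
            )

    def test_exhaustive_permutation_oracle_n7_m3(self):
        # tiny instance where the full permutation group is enumerable:
        # all 5040 trait orderings give the exact maxT distribution
        rng = np.random.default_rng(7)
        n, m = 7, 3
        g = GenotypeMatrix(
            rng.integers(0, 3, size=(n, m)), ids(m, "s"), ids(n)
        )
        y = rng.normal(size=n)
        settings = ScanSettings(alpha1=0.5, min_cell=2, permutations=19)
        perms = np.array(list(itertools.permutations(range(n))))
        assert perms.shape[0] == 5040
        # identity ordering is row 0 of itertools output
        Y = y[perms.T]
        stats_all = scan_matrix(g, Y, settings, None, order=2)
        observed = stats_all[:, 0]

        # oracle: exact step-down distribution over the whole group,
        # p = #{permutations with successive max >= observed} / N
        def exhaustive_p(obs, all_cols):
            m, N = all_cols.shape
            order = sorted(range(m), key=lambda i: -obs[i])
            p = {}
            for rank, i in enumerate(order):
                tail = all_cols[order[rank:], :].max(axis=0)
                p[i] = (tail >= obs[i]).sum() / N
            running = 0.0
            for i in order:
                running = max(running, p[i])
                p[i] = running
            return np.array([p[i] for i in range(m)])

        p_exhaustive = exhaustive_p(observed, stats_all)
        # the identity column always exceeds its own threshold, so the
        # Monte Carlo formula over the N-1 non-identity permutations,
        # (1 + count)/(B + 1) with B = N - 1, equals the exact count/N
        p_pkg = maxt_adjust(observed, stats_all[:, 1:])
        np.testing.assert_allclose(p_pkg, p_exhaustive, atol=1e-12)


class TestPermutationIndices:
    def test_reproducible_and_distinct(self):
        a = permutation_indices(30, 5, seed=99)
        b = permutation_indices(30, 5, seed=99)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a[0], a[1])
        for row in a:
            np.testing.assert_array_equal(np.sort(row), np.arange(30))
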