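"""Group statistics: t/d, cluster permutation test, effect-size maps."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from megpac import (cluster_permutation, comodulogram_effect_size, d_from_t,
                    independent_t, t_from_d)


class TestIndependentT:
    def test_hand_computed_example(self):
        # pooled SD = 1, t = -1 / (1 * sqrt(1/3 + 1/3)) = -1.2247, d = -1
        r = independent_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert r.t == pytest.approx(-1.224744871, abs=1e-8)
        assert r.df == 4
        assert r.d == pytest.approx(-1.0, abs=1e-12)

    def test_identical_samples_rejected_for_zero_variance(self):
        with pytest.raises(ValueError):
            independent_t([1.0, 1.0], [1.0, 1.0])

    def test_near_identical_groups_give_zero_t(self):
        r = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.d == 0.0 and r.p == pytest.approx(1.0)

    def test_agrees_with_scipy_and_pingouin(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0.5, 1.0, 18), rng.normal(0.0, 1.0, 16)
        r = independent_t(a, b)
        t_sp, p_sp = sps.ttest_ind(a, b)
        assert r.t == pytest.approx(t_sp, rel=1e-12)
        assert r.p == pytest.approx(p_sp, rel=1e-9)
        pingouin = pytest.importorskip("pingouin")
        tab = pingouin.ttest(a, b, correction=False)
        assert r.d == pytest.approx(abs(tab["cohen_d"].iloc[0]) * np.sign(r.t), rel=1e-6)

    def test_paper_sized_design_has_df_32(self):
        rng = np.random.default_rng(1)
        r = independent_t(rng.normal(size=18), rng.normal(size=16))
        assert r.df == 32


class TestTDConversion:
    def test_zero_maps_to_zero(self):
        assert t_from_d(0.0, 18, 16) == 0.0

    def test_round_trip_is_algebraic_inverse(self):
        for t in (-3.2, -0.5, 0.215, 2.147):
            assert t_from_d(d_from_t(t, 18, 16), 18, 16) == pytest.approx(t, abs=1e-12)

    def test_consistency_with_computed_group_test(self):
        rng = np.random.default_rng(2)
        r = independent_t(rng.normal(0.7, 1, 18), rng.normal(0, 1, 16))
        assert t_from_d(r.d, r.n_a, r.n_b) == pytest.approx(r.t, abs=1e-12)


def brute_force_cluster_p(data_a, data_b, t_crit, connectivity=4):
    """Independent enumeration oracle for the permutation test.

    Recomputes, with plain loops and scipy.stats.ttest_ind, the exact
    per-tail permutation distribution of the largest max-|t| cluster
    statistic, and the p of every observed cluster.
    """
    def t_map(a, b):
        return sps.ttest_ind(a, b, axis=0).statistic

    def clusters_of(tm, sign):
        mask = (sign * tm) > t_crit
        seen = np.zeros_like(mask, dtype=bool)
        found = []
        for i in range(mask.shape[0]):
            for j in range(mask.shape[1]):
                if mask[i, j] and not seen[i, j]:
                    stack, members = [(i, j)], []
                    seen[i, j] = True
                    while stack:
                        ci, cj = stack.pop()
                        members.append((ci, cj))
                        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
                        if connectivity == 8:
                            steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
                        for di, dj in steps:
                            ni, nj = ci + di, cj + dj
                            if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                                    and mask[ni, nj] and not seen[ni, nj]):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                    found.append(max(abs(tm[m]) for m in members))
        return found

    pooled = np.concatenate([data_a, data_b])
    n1 = len(data_a)
    obs = t_map(data_a, data_b)
    null = {+1: [], -1: []}
    for idx in combinations(range(len(pooled)), n1):
        sel = np.array(idx)
        rest = np.array([k for k in range(len(pooled)) if k not in idx])
        tm = t_map(pooled[sel], pooled[rest])
        for sign in (+1, -1):
            cl = clusters_of(tm, sign)
            null[sign].append(max(cl) if cl else 0.0)
    out = []
    for sign in (+1, -1):
        for stat in clusters_of(obs, sign):
            p = np.mean(np.asarray(null[sign]) >= stat - 1e-12)
            out.append((sign, stat, p))
    return out


class TestClusterPermutation:
    def test_all_zero_comodulograms_give_empty_cluster_list(self):
        a = np.zeros((5, 4, 6))
        b = np.zeros((4, 4, 6))
        res = cluster_permutation(a, b, n_perm=100, seed=0)
        assert res.clusters == []
        assert np.all(res.t_map == 0)

    def test_exact_enumeration_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.0, 1.0, (3, 3, 4))
        a[:, 1, 1:3] += 4.0  # strong localised difference
        b = rng.normal(0.0, 1.0, (3, 3, 4))
        res = cluster_permutation(a, b, exact=True, seed=None)
        t_crit = sps.t.isf(0.025, 4)
        oracle = brute_force_cluster_p(a, b, t_crit)
        got = sorted([(c.sign, round(c.stat, 9), round(c.p_perm, 9))
                      for c in res.clusters])
        want = sorted([(s, round(st, 9), round(p, 9)) for s, st, p in oracle])
        assert got == want

    def test_random_permutation_p_close_to_exact(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, (4, 2, 3))
        a[:, 0, 0] += 3.0
        b = rng.normal(0.0, 1.0, (4, 2, 3))
        exact = cluster_permutation(a, b, exact=True)
        with pytest.warns(UserWarning, match="distinct relabelings"):
            rand = cluster_permutation(a, b, n_perm=4000, seed=5)
        pe = {(c.sign, round(c.stat, 6)): c.p_perm for c in exact.clusters}
        for c in rand.clusters:
            assert c.p_perm == pytest.approx(pe[(c.sign, round(c.stat, 6))], abs=0.05)

    def test_label_exchange_flips_sign_keeps_p(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.4, 1.0, (4, 3, 3))
        b = rng.normal(0.0, 1.0, (4, 3, 3))
        r_ab = cluster_permutation(a, b, exact=True)
        r_ba = cluster_permutation(b, a, exact=True)
        ab = sorted((c.sign, round(c.stat, 9), round(c.p_perm, 9)) for c in r_ab.clusters)
        ba = sorted((-c.sign, round(c.stat, 9), round(c.p_perm, 9)) for c in r_ba.clusters)
        assert ab == ba

    def test_injected_block_detected_as_significant_cluster(self):
        rng = np.random.default_rng(7)
        shape = (7, 34)
        a = rng.normal(0.0, 0.05, (18,) + shape)
        b = rng.normal(0.0, 0.05, (16,) + shape)
        # phase rows 1-2 (8-9 Hz), amp cols 10-21 (54-76 Hz): group B stronger
        b[:, 1:3, 10:22] += 0.15
        pf = np.arange(7.0, 14.0)
        af = np.arange(34.0, 101.0, 2.0)
        res = cluster_permutation(a, b, n_perm=500, seed=8)
        res.phase_freqs, res.amp_freqs = pf, af
        sig = [c for c in res.clusters if c.p_perm < 0.025 and c.sign < 0]
        assert len(sig) == 1
        block = {(i, j) for i in (1, 2) for j in range(10, 22)}
        assert block & set(sig[0].bins)

    def test_four_connectivity_clusters_nest_in_eight(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0.0, 1.0, (6, 5, 5))
        a[:, ::2, ::2] += 2.0  # checkerboard: separate under 4, joined under 8
        b = rng.normal(0.0, 1.0, (6, 5, 5))
        r4 = cluster_permutation(a, b, n_perm=50, seed=10, connectivity=4)
        r8 = cluster_permutation(a, b, n_perm=50, seed=10, connectivity=8)
        bins4 = [set(c.bins) for c in r4.clusters]
        bins8 = [set(c.bins) for c in r8.clusters]
        for c4 in bins4:
            assert any(c4 <= c8 for c8 in bins8)
        assert len(r4.clusters) >= len(r8.clusters)

    def test_type_one_error_rate_within_binomial_bounds(self):
        # identical generators: any-significant-cluster rate should be ~5%
        rng = np.random.default_rng(11)
        hits = 0
        n_runs = 30
        for _ in range(n_runs):
            a = rng.normal(0.0, 1.0, (10, 5, 8))
            b = rng.normal(0.0, 1.0, (9, 5, 8))
            res = cluster_permutation(a, b, n_perm=300, seed=int(rng.integers(2 ** 31)))
            hits += bool(res.significant())
        assert hits <= 5  # P(X > 5 | Bin(30, 0.05)) < 1%

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster_permutation(np.zeros((3, 2, 2)), np.zeros((3, 2, 3)), n_perm=10)


class TestEffectSizeMap:
    def test_identical_groups_give_zero_map(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, (5, 3, 3))
        es = comodulogram_effect_size(a, a.copy())
        np.testing.assert_allclose(es.d, 0.0, atol=1e-12)

    def test_single_bin_shift_matches_scalar_cohens_d(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.0, 1.0, (8, 2, 2))
        b = rng.normal(0.0, 1.0, (7, 2, 2))
        a[:, 1, 0] += 1.0
        es = comodulogram_effect_size(a, b)
        scalar = independent_t(a[:, 1, 0], b[:, 1, 0]).d
        assert es.d[1, 0] == pytest.approx(scalar, rel=1e-12)

    def test_max_bin_reported_in_hz(self):
        from megpac.stats import EffectSizeMap
        es = EffectSizeMap(d=np.array([[0.1, 0.9], [0.2, 0.3]]),
                           phase_freqs=np.array([7.0, 8.0]),
                           amp_freqs=np.array([34.0, 36.0]))
        assert es.max_d == 0.9
        assert es.max_bin_hz == (7.0, 36.0)
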