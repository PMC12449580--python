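import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilmnet.errors import ParameterError, ValidationError
from biofilmnet.stats import (
    DistanceMatrix,
    beta_dispersion,
    bray_curtis,
    pairwise_permanova,
    pcoa,
    permanova,
    shannon,
)

from conftest import make_metadata


class TestShannon:
    def test_uniform_community_reaches_log_richness(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(math.log(4), abs=1e-9)

    def test_single_taxon_is_zero(self):
        assert shannon([7, 0, 0]) == 0.0

    def test_direct_summation_oracle(self):
        # H = -sum p ln p for p = (0.1, 0.2, 0.3, 0.4)
        expected = -sum(p * math.log(p) for p in (0.1, 0.2, 0.3, 0.4))
        assert shannon([1, 2, 3, 4]) == pytest.approx(expected, abs=1e-9)
        assert round(expected, 6) == 1.279854

    def test_zero_total_is_an_error(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])

    @given(st.lists(st.integers(0, 1000), min_size=2, max_size=30).filter(lambda x: sum(x) > 0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_log_richness(self, counts):
        h = shannon(counts)
        assert 0 <= h <= math.log(len(counts)) + 1e-12


class TestBrayCurtis:
    def test_identical_samples_have_zero_distance(self):
        d = bray_curtis(np.array([[3.0, 4.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_have_distance_one(self):
        d = bray_curtis(np.array([[1.0, 0.0], [0.0, 1.0]]))
        assert d.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_formula(self):
        # 1 - 2*(min(6,2)+min(4,4)+min(0,4)) / (10+10) = 1 - 12/20
        d = bray_curtis(np.array([[6.0, 4.0, 0.0], [2.0, 4.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(0.4, abs=1e-12)

    def test_depth_invariance_on_relative_abundances(self):
        rng = np.random.default_rng(8)
        x = rng.integers(1, 50, size=(6, 10)).astype(float)
        scaled = x * rng.integers(1, 20, size=(6, 1))
        rel = lambda m: m / m.sum(axis=1, keepdims=True)
        d1 = bray_curtis(rel(x))
        d2 = bray_curtis(rel(scaled))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)
        # but the raw dissimilarity is scale-dependent by definition
        assert not np.allclose(bray_curtis(x).values, bray_curtis(scaled).values)

    def test_zero_total_sample_is_an_error(self):
        with pytest.raises(ValidationError):
            bray_curtis(np.array([[1.0, 1.0], [0.0, 0.0]]))


class TestPcoa:
    def test_collinear_points_recover_pairwise_distances(self):
        pts = np.array([0.0, 3.0, 10.0])
        d = DistanceMatrix(["a", "b", "c"], np.abs(pts[:, None] - pts[None, :]))
        res = pcoa(d)
        axis1 = res.coordinates[:, 0]
        got = np.abs(axis1[:, None] - axis1[None, :])
        np.testing.assert_allclose(got, d.values, atol=1e-9)

    def test_identical_samples_give_zero_coordinates(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(d)
        assert res.coordinates.size == 0 or np.allclose(res.coordinates, 0)

    def test_full_rank_reconstruction_of_euclidean_input(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        d = DistanceMatrix([f"s{i}" for i in range(7)], squareform(pdist(pts)))
        res = pcoa(d)
        rec = squareform(pdist(res.coordinates))
        np.testing.assert_allclose(rec, d.values, atol=1e-8)

    def test_eigenvalues_match_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        x = rng.random((8, 12))
        d = bray_curtis(x)
        mine = pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.sample_ids))
        np.testing.assert_allclose(
            mine.eigenvalues,
            ref.eigvals.to_numpy()[: len(mine.eigenvalues)],
            atol=1e-8,
        )


def _two_group_distance(n_per=6, seed=0, shift=0.0):
    rng = np.random.default_rng(seed)
    x = rng.random((2 * n_per, 15))
    x[n_per:] += shift
    labels = ["a"] * n_per + ["b"] * n_per
    ids = [f"s{i}" for i in range(2 * n_per)]
    return bray_curtis(x, ids), make_metadata(labels)


class TestPermanova:
    def test_duplicated_samples_across_groups_give_high_p(self):
        base = np.random.default_rng(1).random((3, 10))
        x = np.vstack([base, base])  # group b duplicates group a
        d = bray_curtis(x, [f"s{i}" for i in range(6)])
        m = make_metadata(["a"] * 3 + ["b"] * 3)
        res = permanova(d, m, "treatment", n_perm=999, seed=0)
        assert np.isfinite(res.F)
        assert res.p > 0.5

    def test_pseudo_f_matches_reference_implementation(self):
        skbio = pytest.importorskip("skbio")
        d, m = _two_group_distance(seed=2)
        res = permanova(d, m, "treatment", n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.sample_ids),
            ["a"] * 6 + ["b"] * 6,
            permutations=99,
        )
        assert res.F == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_exact_enumeration_matches_brute_force_oracle(self):
        d, m = _two_group_distance(n_per=3, seed=3, shift=0.2)
        res = permanova(d, m, "treatment", method="exact")

        # independent oracle: loop-based SS over all 20 assignments of 3 a's
        def loop_f(labels):
            n = len(labels)
            d2 = d.values**2
            sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
            ssw = 0.0
            for g in ("a", "b"):
                idx = [i for i, l in enumerate(labels) if l == g]
                ssw += sum(
                    d2[i, j] for i in idx for j in idx if i < j
                ) / len(idx)
            ssb = sst - ssw
            return (ssb / 1) / (ssw / (n - 2))

        obs = loop_f(["a", "a", "a", "b", "b", "b"])
        count = 0
        for combo in itertools.combinations(range(6), 3):
            labels = ["a" if i in combo else "b" for i in range(6)]
            count += loop_f(labels) >= obs - 1e-12
        assert res.n_perm == 20
        assert res.p == pytest.approx(count / 20, abs=1e-12)
        assert res.F == pytest.approx(obs, abs=1e-10)

    def test_r2_is_between_ss_ratio_complement(self):
        d, m = _two_group_distance(seed=5, shift=0.3)
        res = permanova(d, m, "treatment", n_perm=9, seed=0)
        # R2 + SS_within/SS_total = 1 exactly; recompute SS by loops
        n = 12
        d2 = d.values**2
        sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
        ssw = 0.0
        for g, idx in (("a", range(6)), ("b", range(6, 12))):
            ssw += sum(d2[i, j] for i in idx for j in idx if i < j) / 6
        assert res.R2 + ssw / sst == pytest.approx(1.0, abs=1e-12)

    def test_seeded_p_values_reproducible(self):
        d, m = _two_group_distance(seed=6, shift=0.1)
        p1 = permanova(d, m, "treatment", n_perm=199, seed=11).p
        p2 = permanova(d, m, "treatment", n_perm=199, seed=11).p
        assert p1 == p2

    def test_strata_restrict_permutations(self):
        d, m = _two_group_distance(seed=7)
        res = permanova(d, m, "treatment", n_perm=99, strata="panel", seed=1)
        assert 0 < res.p <= 1

    def test_constant_factor_is_an_error(self):
        d, m = _two_group_distance(seed=8)
        with pytest.raises(ParameterError):
            permanova(d, make_metadata(["a"] * 12), "treatment")


class TestBetaDispersion:
    def test_mirror_image_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 4))
        x = np.vstack([pts, -pts]) + 10.0  # mirrored spread, all positive
        d = bray_curtis(x, [f"s{i}" for i in range(12)])
        m = make_metadata(["a"] * 6 + ["b"] * 6)
        res = beta_dispersion(d, m, "treatment", n_perm=999, seed=0)
        assert res.p > 0.2

    def test_zero_spread_group_detected(self):
        rng = np.random.default_rng(11)
        tight = np.tile(rng.random(8) + 0.5, (6, 1))
        spread = rng.random((6, 8)) + 0.5
        d = bray_curtis(np.vstack([tight, spread]), [f"s{i}" for i in range(12)])
        m = make_metadata(["a"] * 6 + ["b"] * 6)
        res = beta_dispersion(d, m, "treatment", n_perm=999, seed=0)
        assert res.p < 0.05

    def test_exact_enumeration_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.random((6, 8))
        x[3:] *= 3.0
        d = bray_curtis(x, [f"s{i}" for i in range(6)])
        m = make_metadata(["a"] * 3 + ["b"] * 3)
        res = beta_dispersion(d, m, "treatment", method="exact")

        from biofilmnet.stats import _dispersion_distances

        z = _dispersion_distances(d, np.array(["a"] * 3 + ["b"] * 3, dtype=object))

        def loop_f(labels):
            groups = sorted(set(labels))
            grand = z.mean()
            ssb = ssw = 0.0
            for g in groups:
                zi = z[[i for i, l in enumerate(labels) if l == g]]
                ssb += len(zi) * (zi.mean() - grand) ** 2
                ssw += ((zi - zi.mean()) ** 2).sum()
            return (ssb / 1) / (ssw / 4)

        obs = loop_f(["a", "a", "a", "b", "b", "b"])
        count = 0
        for combo in itertools.combinations(range(6), 3):
            labels = ["a" if i in combo else "b" for i in range(6)]
            count += loop_f(labels) >= obs - 1e-12
        assert res.p == pytest.approx(count / 20, abs=1e-12)


class TestPairwisePermanova:
    def test_two_groups_single_comparison_unadjusted(self):
        d, m = _two_group_distance(seed=13)
        results = pairwise_permanova(d, m, "treatment", n_perm=99, seed=0)
        assert len(results) == 1
        assert results[0].p_adj == pytest.approx(results[0].p)

    def test_bh_adjustment_matches_hand_computation(self):
        rng = np.random.default_rng(14)
        x = rng.random((18, 12))
        x[6:12] += 0.15
        x[12:] += 0.3
        d = bray_curtis(x, [f"s{i}" for i in range(18)])
        m = make_metadata(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        results = pairwise_permanova(d, m, "treatment", n_perm=199, seed=3)
        raw = [r.p for r in results]
        # BH by hand: p_(i) * m / i, monotone from the largest downwards
        order = np.argsort(raw)
        mtot = len(raw)
        adj = [None] * mtot
        prev = 1.0
        for rank_pos, idx in enumerate(reversed(order), start=0):
            i = mtot - rank_pos
            val = min(prev, raw[idx] * mtot / i)
            adj[idx] = val
            prev = val
        for r, expected in zip(results, adj):
            assert r.p_adj == pytest.approx(expected, abs=1e-12)

    def test_bonferroni_option(self):
        d, m = _two_group_distance(seed=15)
        res = pairwise_permanova(d, m, "treatment", n_perm=99,
                                 correction="bonferroni", seed=0)
        assert res[0].p_adj == pytest.approx(min(1.0, res[0].p), abs=1e-12)
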