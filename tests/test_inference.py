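import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biofilmnet.errors import EmptyResultError, ParameterError
from biofilmnet.inference import (
    ClrMatrix,
    build_network,
    clr_transform,
    default_lambda_path,
    edge_instability,
    f1_score_edges,
    infer_association_network,
    lambda_max,
    neighborhood_lasso,
    stars_select,
    wmc_filter,
)
from biofilmnet.tables_io import CountTable


def cd_lasso(X, y, lam, n_iter=5000, tol=1e-13):
    """Independent coordinate-descent oracle for
    min (1/2n)||y - Xb||^2 + lam * ||b||_1."""
    n, p = X.shape
    b = np.zeros(p)
    a = (X**2).sum(axis=0) / n
    r = y - X @ b
    for _ in range(n_iter):
        delta = 0.0
        for k in range(p):
            old = b[k]
            c = X[:, k] @ r / n + a[k] * old
            new = np.sign(c) * max(abs(c) - lam, 0.0) / a[k] if a[k] > 0 else 0.0
            if new != old:
                r += X[:, k] * (old - new)
                b[k] = new
                delta = max(delta, abs(new - old))
        if delta < tol:
            break
    return b


def standardized(x):
    return (x - x.mean(axis=0)) / x.std(axis=0)


class TestWmcFilter:
    def _table(self, counts):
        n, p = counts.shape
        return CountTable([f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)], counts)

    def test_low_read_feature_removed(self):
        counts = np.array([[1, 500, 500, 500], [1, 500, 500, 500], [0, 500, 500, 500]])
        t = wmc_filter(self._table(counts), min_total_reads=3, min_mean_rel_abund=0.0)
        assert t.feature_ids == ["f1", "f2", "f3"]

    def test_abundant_feature_kept(self):
        # feature 0 at ~0.3% mean abundance with 100 reads total
        counts = np.column_stack([np.full(4, 25), np.full(4, 4000), np.full(4, 4000)])
        t = wmc_filter(self._table(counts), min_total_reads=3, min_mean_rel_abund=0.0025)
        assert "f0" in t.feature_ids

    def test_matches_exhaustive_rule_application(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 60, size=(8, 30))
        counts[:, 0] += 10
        t = self._table(counts)
        got = wmc_filter(t, min_total_reads=5, min_mean_rel_abund=0.02)
        rel = counts / counts.sum(axis=1, keepdims=True)
        expected = [
            f"f{j}"
            for j in range(30)
            if counts[:, j].sum() >= 5 and rel[:, j].mean() >= 0.02
        ]
        assert got.feature_ids == expected

    def test_too_few_survivors_is_an_error(self):
        counts = np.ones((4, 4), dtype=int)
        with pytest.raises(EmptyResultError):
            wmc_filter(self._table(counts), min_total_reads=100)


class TestClrTransform:
    def test_equal_parts_map_to_zero(self):
        c = clr_transform(np.array([[1.0, 1.0, 1.0, 1.0]]), pseudocount=0)
        np.testing.assert_allclose(c.values, 0, atol=1e-12)

    def test_two_part_row_hand_value(self):
        c = clr_transform(np.array([[2.0, 8.0]]), pseudocount=0)
        np.testing.assert_allclose(c.values, [[-np.log(2), np.log(2)]], atol=1e-12)

    def test_zero_pseudocount_with_zeros_rejected(self):
        with pytest.raises(ParameterError):
            clr_transform(np.array([[0.0, 1.0]]), pseudocount=0)

    @given(
        st.lists(
            st.lists(st.integers(0, 500), min_size=3, max_size=8),
            min_size=2,
            max_size=6,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    @settings(max_examples=50, deadline=None)
    def test_rows_always_sum_to_zero(self, rows):
        c = clr_transform(np.array(rows, dtype=float), pseudocount=1.0)
        assert np.abs(c.values.sum(axis=1)).max() < 1e-9


def random_clr(n, p, seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 200, size=(n, p)) + 1
    return clr_transform(counts.astype(float), pseudocount=1.0)


class TestNeighborhoodLasso:
    def test_all_zero_at_and_above_lambda_max(self):
        c = random_clr(20, 8, seed=0)
        lam = lambda_max(c.values)
        b = neighborhood_lasso(c, lam * 1.0001)
        assert np.all(b == 0)

    def test_duplicated_columns_select_each_other(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 12))
        x[:, 1] = x[:, 0]  # exact duplicate pair among noise
        vals = x - x.mean(axis=1, keepdims=True)  # make rows CLR-like
        c = ClrMatrix([str(i) for i in range(40)], [f"f{j}" for j in range(12)], vals, 1.0)
        b = neighborhood_lasso(c, 0.3)
        assert b[0, 1] > 0.5 and b[1, 0] > 0.5
        others = np.abs(b).copy()
        others[0, 1] = others[1, 0] = 0.0
        assert others.max() < 0.3

    def test_matches_coordinate_descent_oracle(self):
        c = random_clr(25, 6, seed=2)
        x = standardized(c.values)
        lam = 0.5 * lambda_max(c.values)
        b = neighborhood_lasso(c, lam)
        for j in range(6):
            others = [k for k in range(6) if k != j]
            expected = cd_lasso(x[:, others], x[:, j], lam)
            np.testing.assert_allclose(b[j, others], expected, atol=1e-6)


class TestStars:
    def test_full_data_subsamples_have_zero_instability(self):
        # subsample == full data -> identical graphs at every penalty
        c = random_clr(12, 5, seed=3)
        res = stars_select(c, n_subsamples=5, subsample_size=12, seed=0)
        assert np.allclose(res.instability_path, 0)
        assert res.selected_index == len(res.lambda_path) - 1  # densest graph

    def test_half_frequency_edge_instability_formula(self):
        assert edge_instability(np.array(0.5)) == pytest.approx(0.5)
        assert edge_instability(np.array(0.0)) == 0.0
        assert edge_instability(np.array(1.0)) == 0.0

    def test_monotonized_path_never_decreases(self):
        c = random_clr(30, 8, seed=4)
        res = stars_select(c, n_subsamples=10, seed=1)
        assert np.all(np.diff(res.instability_path) >= 0)
        assert res.instability_at_selection <= 0.05 or res.selected_index == 0

    def test_reproducible_under_fixed_seed(self):
        c = random_clr(30, 8, seed=5)
        r1 = stars_select(c, n_subsamples=8, seed=42)
        r2 = stars_select(c, n_subsamples=8, seed=42)
        assert r1.lambda_selected == r2.lambda_selected
        np.testing.assert_array_equal(r1.edge_stability, r2.edge_stability)


class TestBuildNetwork:
    def _clr(self, p):
        return ClrMatrix(
            ["s1", "s2"], [f"f{j}" for j in range(p)], np.zeros((2, p)), 1.0
        )

    def test_agreeing_coefficients_averaged(self):
        b = np.zeros((3, 3))
        b[0, 1], b[1, 0] = 0.4, 0.2
        net = build_network(self._clr(3), b)
        assert net.n_edges == 1
        edge = net.edges.iloc[0]
        assert edge["weight"] == pytest.approx(0.3)
        assert edge["sign"] == "+"

    def test_no_edge_for_double_zero(self):
        net = build_network(self._clr(3), np.zeros((3, 3)))
        assert net.n_edges == 0

    def test_sign_conflict_resolved_by_larger_magnitude(self):
        b = np.zeros((2, 2))
        b[0, 1], b[1, 0] = 0.3, -0.1
        net = build_network(self._clr(2), b)
        edge = net.edges.iloc[0]
        assert edge["weight"] == pytest.approx(0.3)
        assert edge["sign"] == "+"

    def test_and_rule_requires_both_directions(self):
        b = np.zeros((3, 3))
        b[0, 1] = 0.4  # only one direction
        assert build_network(self._clr(3), b, rule="and").n_edges == 0
        assert build_network(self._clr(3), b, rule="or").n_edges == 1


class TestEndToEnd:
    def _dataset(self, seed=0, n=80, p=15):
        from biofilmnet.synthetic import SimulationDesign, make_graph, simulate_counts

        g = make_graph(p, "band", seed=seed, bandwidth=1)
        d = SimulationDesign(
            groups=[("gracilaria", "seaweed", "exp1", n)],
            depth_mean=8000,
            effect_size=0.0,
            seed=seed + 100,
        )
        t, _, _ = simulate_counts(g, d)
        return g, t

    def test_inference_reproducible_bit_exactly(self):
        _, t = self._dataset(seed=6)
        n1 = infer_association_network(t, apply_wmc_filter=False, n_lambda=10,
                                       n_subsamples=8, seed=5)
        n2 = infer_association_network(t, apply_wmc_filter=False, n_lambda=10,
                                       n_subsamples=8, seed=5)
        assert n1.edges.equals(n2.edges)
        assert n1.lambda_selected == n2.lambda_selected

    def test_invariant_to_feature_input_order(self):
        g, t = self._dataset(seed=7)
        perm = list(np.random.default_rng(0).permutation(t.feature_ids))
        t_perm = t.select_features(perm)
        n1 = infer_association_network(t, apply_wmc_filter=False, n_lambda=10,
                                       n_subsamples=8, seed=9)
        n2 = infer_association_network(t_perm, apply_wmc_filter=False, n_lambda=10,
                                       n_subsamples=8, seed=9)
        assert n1.edge_set() == n2.edge_set()

    def test_f1_score_edges_definition(self):
        truth = {("a", "b"), ("b", "c")}
        pred = {("b", "a"), ("c", "d")}
        # precision 1/2, recall 1/2
        assert f1_score_edges(pred, truth) == pytest.approx(0.5)
        assert f1_score_edges(set(), truth) == 0.0
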