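"""Time-varying DBN: segments, binding matrices, solver, networks."""

import numpy as np
import pandas as pd
import pytest

from dyngrn.dbn import (SolverError, TimeVaryingDbn, assemble_networks,
                        common_links, cv_error, dbn_objective,
                        segment_cis_region, segment_mean_lr,
                        select_hyperparameters, solve_gene_weights,
                        variance_explained)
from dyngrn.io import CisRegion


def region_of(length, gid="g"):
    return CisRegion(gid, "chr1", 0, length, length,
                     np.ones(length, dtype=bool))


class TestSegments:
    @pytest.mark.parametrize("length,expected_k", [
        (40_000, 7_991), (50, 1), (60, 3), (55, 2),
    ])
    def test_segment_count(self, length, expected_k):
        seg = segment_cis_region(region_of(length))
        assert seg.n_segments == expected_k

    def test_intervals_of_short_region(self):
        seg = segment_cis_region(region_of(60))
        assert [seg.interval(k) for k in range(3)] == [(0, 50), (5, 55), (10, 60)]

    def test_adjacent_overlap_is_45(self):
        seg = segment_cis_region(region_of(500))
        (s0, e0), (s1, e1) = seg.interval(0), seg.interval(1)
        assert e0 - s1 == 45

    def test_too_short_region_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_cis_region(region_of(49))

    def test_segment_mean_matches_slice_mean(self):
        rng = np.random.default_rng(0)
        lr = rng.random(300)
        seg = segment_cis_region(region_of(300))
        means = segment_mean_lr(lr, seg)
        for k in (0, 7, seg.n_segments - 1):
            s, e = seg.interval(k)
            assert means[k] == pytest.approx(lr[s:e].mean())


class TestBindingMatrix:
    def test_pi_adjustment_values(self, dbn_dataset, dbn_inputs):
        """B = segment-mean LR for supported edges, x 0.25 otherwise, 0 without a hit."""
        ds = dbn_dataset
        _, binding, _ = dbn_inputs
        checked_supported = checked_default = False
        for gid, gb in binding.items():
            bm = gb.matrices[0]
            mean_lr = segment_mean_lr(ds.truth.lr_tracks[gid][0], gb.segments)
            for j, tf in enumerate(bm.tf_names):
                pi = 1.0 if ds.truth.P.P.at[gid, tf] == 1 else 0.25
                rows = np.nonzero(bm.hit_mask[:, j])[0]
                if rows.size:
                    np.testing.assert_allclose(bm.B[rows, j],
                                               mean_lr[rows] * pi)
                    checked_supported |= pi == 1.0
                    checked_default |= pi == 0.25
                # no hit -> exactly zero
                off = np.nonzero(~bm.hit_mask[:, j])[0]
                assert (bm.B[off, j] == 0.0).all()
        assert checked_supported and checked_default

    def test_entries_bounded_by_max_segment_lr(self, dbn_dataset, dbn_inputs):
        ds = dbn_dataset
        _, binding, _ = dbn_inputs
        for gid, gb in binding.items():
            for t, bm in enumerate(gb.matrices):
                mean_lr = segment_mean_lr(ds.truth.lr_tracks[gid][t], gb.segments)
                assert (bm.B >= 0).all()
                assert (bm.B <= mean_lr.max() + 1e-12).all()

    def test_only_abundant_tfs_enter(self, dbn_dataset, dbn_inputs):
        ds = dbn_dataset
        _, binding, _ = dbn_inputs
        for gb in binding.values():
            for t, bm in enumerate(gb.matrices):
                for tf in bm.tf_names:
                    assert ds.expr.fpkm.at[tf, ds.stages[t]] > 25.0


def random_instance(rng, T=4):
    K = int(rng.integers(1, 6))
    p = int(rng.integers(1, 5))
    B = [np.abs(rng.normal(0, 1, (K, p))) * (rng.random((K, p)) < 0.6)
         for _ in range(T - 1)]
    X = [np.abs(rng.normal(2, 1, p)) for _ in range(T - 1)]
    x = rng.normal(2, 1, T)
    return x, B, X


def slsqp_objective(x, B, X, l1, l2, loss="squared"):
    """Independent epigraph-QP solve of the same objective via SLSQP."""
    from scipy.optimize import minimize

    T1 = len(B)
    K = B[0].shape[0]
    p = B[0].shape[1]
    n = T1 * K
    M = np.zeros((T1, n))
    y = np.empty(T1)
    for t in range(T1):
        M[t, t * K:(t + 1) * K] = B[t] @ X[t]
        y[t] = x[t + 1]
    blocks = [l1 * np.eye(n)] if l1 > 0 else []
    for t in range(T1 - 1):
        G = np.zeros((p, n))
        G[:, t * K:(t + 1) * K] = B[t].T
        G[:, (t + 1) * K:(t + 2) * K] = -B[t + 1].T
        blocks.append(l2 * G)
    D = np.vstack(blocks) if blocks else np.empty((0, n))
    m = D.shape[0]

    def f(zz):
        z, a = zz[:n], zz[n:]
        r = y - M @ z
        return float(r @ r + a.sum())

    def grad(zz):
        g = np.empty(n + m)
        g[:n] = -2 * M.T @ (y - M @ zz[:n])
        g[n:] = 1.0
        return g

    cons = [
        {"type": "ineq", "fun": lambda zz: zz[n:] - D @ zz[:n],
         "jac": lambda zz: np.hstack([-D, np.eye(m)])},
        {"type": "ineq", "fun": lambda zz: zz[n:] + D @ zz[:n],
         "jac": lambda zz: np.hstack([D, np.eye(m)])},
    ]
    res = minimize(f, np.zeros(n + m), jac=grad, constraints=cons,
                   method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14})
    return f(res.x)


class TestSolver:
    def test_one_dimensional_least_squares(self):
        # single segment, single TF, B = 1, one transition (2, 1):
        # u minimizes (1 - 2u)^2 -> u = 0.5
        sw = solve_gene_weights(np.array([2.0, 1.0]), [np.array([[1.0]])],
                                [np.array([2.0])], 0.0, 0.0)
        assert sw.U[0, 0] == pytest.approx(0.5)

    def test_large_lambda1_zeroes_everything(self):
        rng = np.random.default_rng(2)
        x, B, X = random_instance(rng)
        sw = solve_gene_weights(x, B, X, 1e4, 0.0)
        np.testing.assert_allclose(sw.U, 0.0)
        expected = sum(x[t + 1] ** 2 for t in range(3))
        assert sw.objective == pytest.approx(expected)

    def test_matches_independent_solver_on_random_instances(self):
        rng = np.random.default_rng(1)
        for trial in range(20):
            x, B, X = random_instance(rng)
            l1 = float(rng.uniform(0, 0.5))
            l2 = float(rng.uniform(0, 0.5))
            sw = solve_gene_weights(x, B, X, l1, l2)
            oracle = slsqp_objective(x, B, X, l1, l2)
            assert sw.objective == pytest.approx(oracle, rel=1e-5, abs=1e-9)

    def test_objective_monotone_in_penalties(self):
        rng = np.random.default_rng(4)
        x, B, X = random_instance(rng)
        objs_l1 = [solve_gene_weights(x, B, X, l1, 0.1).objective
                   for l1 in (0.0, 0.05, 0.2, 1.0)]
        assert all(a <= b + 1e-8 for a, b in zip(objs_l1, objs_l1[1:]))
        objs_l2 = [solve_gene_weights(x, B, X, 0.1, l2).objective
                   for l2 in (0.0, 0.05, 0.2, 1.0)]
        assert all(a <= b + 1e-8 for a, b in zip(objs_l2, objs_l2[1:]))

    def test_l1_norm_non_increasing_in_lambda1(self):
        rng = np.random.default_rng(6)
        x, B, X = random_instance(rng)
        norms = [np.abs(solve_gene_weights(x, B, X, l1, 0.05).U).sum()
                 for l1 in (0.01, 0.05, 0.2, 1.0)]
        assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_large_lambda2_smooths_network_rows(self):
        rng = np.random.default_rng(8)
        x, B, X = random_instance(rng)
        sw = solve_gene_weights(x, B, X, 0.0, 1e4)
        rows = [sw.U[t] @ B[t] for t in range(3)]
        for a, b in zip(rows, rows[1:]):
            np.testing.assert_allclose(a, b, atol=1e-4)

    def test_abs_loss_supported(self):
        rng = np.random.default_rng(10)
        x, B, X = random_instance(rng)
        sw = solve_gene_weights(x, B, X, 0.05, 0.05, loss="abs")
        direct = dbn_objective(sw.U, x, B, X, 0.05, 0.05, loss="abs")
        assert sw.objective == pytest.approx(direct)
        # the squared-loss optimum evaluated under abs loss can only be worse
        sq = solve_gene_weights(x, B, X, 0.05, 0.05, loss="squared")
        assert sw.objective <= dbn_objective(sq.U, x, B, X, 0.05, 0.05,
                                             loss="abs") + 1e-6

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            solve_gene_weights(np.zeros(2), [np.ones((1, 1))],
                               [np.ones(1)], -1.0, 0.0)

    def test_empty_segment_set(self):
        sw = solve_gene_weights(np.array([2.0, 1.0]), [np.zeros((0, 1))],
                                [np.ones(1)], 0.1, 0.1)
        assert sw.U.shape == (1, 0)
        assert sw.objective == pytest.approx(1.0)


class TestHyperparameterCv:
    def test_single_point_grid_returned(self, dbn_inputs):
        _, _, gene_data = dbn_inputs
        sub = {g: gene_data[g] for g in list(gene_data)[:3]}
        l1, l2, table = select_hyperparameters(sub, [0.02], [0.05])
        assert (l1, l2) == (0.02, 0.05)

    def test_cv_error_matches_recompute(self, dbn_inputs):
        """The tabulated CV error equals recomputing it gene by gene."""
        _, _, gene_data = dbn_inputs
        ids = sorted(gene_data)[:4]
        sub = {g: gene_data[g] for g in ids}
        _, _, table = select_hyperparameters(sub, [0.01], [0.1])
        expected = np.mean([cv_error(*sub[g], lambda1=0.01, lambda2=0.1)
                            for g in ids])
        assert table["cv_error"].iloc[0] == pytest.approx(expected)

    def test_extreme_shrinkage_hurts_cv(self):
        """Shrinking everything to zero predicts the held-out transition
        worse than a light penalty on sparse-truth data."""
        rng = np.random.default_rng(0)
        T, K, p = 4, 8, 3
        B0 = np.abs(rng.normal(0.5, 0.2, (K, p))) * (rng.random((K, p)) < 0.4)
        B = [B0] * (T - 1)
        X = [np.abs(rng.normal(2, 0.5, p)) for _ in range(T - 1)]
        u_true = np.zeros(K)
        u_true[2] = 0.8
        x = np.empty(T)
        x[0] = 2.0
        for t in range(T - 1):
            x[t + 1] = u_true @ (B0 @ X[t]) + rng.normal(0, 0.05)
        assert cv_error(x, B, X, 0.02, 0.0) < cv_error(x, B, X, 1e4, 0.0)

    def test_one_se_rule_prefers_sparser_within_band(self, dbn_inputs):
        """When CV errors are statistically indistinguishable the 1-SE rule
        returns a sparser pair than the plain arg-min."""
        _, _, gene_data = dbn_inputs
        sub = {g: gene_data[g] for g in sorted(gene_data)[:8]}
        grid1, grid2 = [0.001, 0.01], [0.1]
        l1_min, _, _ = select_hyperparameters(sub, grid1, grid2, rule="min")
        l1_1se, _, _ = select_hyperparameters(sub, grid1, grid2, rule="1se")
        assert l1_1se >= l1_min

    def test_too_few_transitions_rejected(self):
        with pytest.raises(ValueError, match="transitions"):
            cv_error(np.array([1.0, 2.0]), [np.ones((2, 1))],
                     [np.ones(1)], 0.1, 0.1)

    def test_empty_grid_rejected(self, dbn_inputs):
        _, _, gene_data = dbn_inputs
        with pytest.raises(ValueError, match="grid"):
            select_hyperparameters(gene_data, [], [0.1])


class TestNetworks:
    def test_zero_weights_give_empty_edge_list(self, dbn_dataset, dbn_inputs):
        _, binding, _ = dbn_inputs
        model = TimeVaryingDbn(lambda1=1e5, lambda2=0.0)
        model.fit(dbn_dataset.expr, binding)
        for t in range(3):
            assert model.positive_edges(t) == []
        edges, tfbs = assemble_networks(model)
        assert len(edges) == 0 and len(tfbs) == 0

    def test_edges_match_dense_product(self, dbn_dataset, dbn_inputs):
        _, binding, _ = dbn_inputs
        model = TimeVaryingDbn(lambda1=0.01, lambda2=0.1)
        model.fit(dbn_dataset.expr, binding)
        for t in (0, 2):
            A = model.networks_[t]
            expected = set()
            for gid, gb in binding.items():
                row = model.weights_[gid].U[t] @ gb.matrices[t].B
                for j, tf in enumerate(gb.matrices[t].tf_names):
                    if row[j] > model.edge_tol:
                        expected.add((gid, tf))
            got = {(tgt, reg) for tgt, reg, _ in model.positive_edges(t)}
            assert got == expected

    def test_single_edge_toy(self):
        from dyngrn.dbn import BindingMatrix, GeneBinding
        from dyngrn.io import ExpressionMatrix
        seg = segment_cis_region(region_of(50, "gT"))
        mask = np.ones((1, 1), dtype=bool)
        B = np.array([[0.05]])
        mats = [BindingMatrix("gT", t, B, ["gR"], seg, mask, np.array([0.25]))
                for t in range(2)]
        expr = ExpressionMatrix(pd.DataFrame(
            {"S0": [1.0, 40.0], "S1": [1.0, 40.0], "S2": [1.0, 40.0]},
            index=["gT", "gR"],
        ))
        model = TimeVaryingDbn(lambda1=0.0, lambda2=0.0)
        model.fit(expr, {"gT": GeneBinding("gT", seg, mats)})
        edges, _ = assemble_networks(model)
        assert set(edges["regulator"]) == {"gR"}
        assert set(edges["target"]) == {"gT"}

    def test_variance_explained_perfect_and_hand_worked(self):
        from dyngrn.io import ExpressionMatrix
        # 3-gene toy: compare against a hand-computed R^2
        X = pd.DataFrame({"S0": [1.0, 2.0, 3.0], "S1": [1.5, 1.0, 2.5]},
                         index=["a", "b", "c"])
        expr = ExpressionMatrix(np.expm1(X))

        class Fake:
            stages_ = ["S0", "S1"]
            networks_ = [pd.DataFrame(
                [[0.0, 0.75, 0.0], [0.5, 0.0, 0.0], [0.0, 0.0, 0.8]],
                index=["a", "b", "c"], columns=["a", "b", "c"])]

            def predict(self, expr, t):
                xt = expr.X["S0"].to_numpy()
                return pd.Series(self.networks_[0].to_numpy() @ xt,
                                 index=["a", "b", "c"])

        pred = np.array([0.75 * 2.0, 0.5 * 1.0, 0.8 * 3.0])
        obs = np.array([1.5, 1.0, 2.5])
        expected = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
        got = variance_explained(expr, Fake())
        assert got["S1"] == pytest.approx(expected)

    def test_variance_explained_zero_for_zero_prediction(self):
        from dyngrn.io import ExpressionMatrix
        X = pd.DataFrame({"S0": [1.0, 2.0], "S1": [1.0, -1.0]}, index=["a", "b"])
        expr = ExpressionMatrix(np.clip(np.expm1(X), 0, None))

        class Fake:
            stages_ = ["S0", "S1"]
            networks_ = [pd.DataFrame(np.zeros((2, 2)), index=["a", "b"],
                                      columns=["a", "b"])]

            def predict(self, expr, t):
                return pd.Series([0.0, 0.0], index=["a", "b"])

        # X^{t+1} = (1, 0) after FPKM clipping; centered: R^2 = 1 - RSS/TSS
        got = variance_explained(expr, Fake())
        obs = expr.X["S1"].to_numpy()
        expected = 1 - np.sum(obs ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert got["S1"] == pytest.approx(expected)

    def test_common_links_identity_and_disjoint(self):
        class Fake:
            networks_ = [None, None]
            edge_tol = 1e-8

            def __init__(self, sets):
                self._sets = sets
                self.networks_ = [None] * len(sets)

            def positive_edges(self, t):
                return [(a, b, 1.0) for a, b in self._sets[t]]

        same = Fake([{("a", "x"), ("b", "y")}, {("a", "x"), ("b", "y")}])
        assert common_links(same)["n_common"].tolist() == [2]
        disjoint = Fake([{("a", "x")}, {("b", "y")}])
        assert common_links(disjoint)["n_common"].tolist() == [0]
        triple = Fake([{("a", "x")}, {("a", "x"), ("b", "y")}, {("b", "y")}])
        got = common_links(triple)
        assert got.set_index(["transition_a", "transition_b"])["n_common"].to_dict() \
            == {(0, 1): 1, (0, 2): 0, (1, 2): 1}
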