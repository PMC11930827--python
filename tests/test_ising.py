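"""eLasso network estimation: conditionals, path fits, EBIC, symmetrization."""

from __future__ import annotations

import numpy as np
import pytest

import comorbnet as cn
from comorbnet._kernels import logistic_lasso_path
from comorbnet.ising import fit_node, lambda_path, symmetrize


def small_net(w12=0.0, b=(0.0, 0.0)):
    w = np.array([[0.0, w12], [w12, 0.0]])
    return cn.IsingNetwork(w, np.array(b), ["A", "B"])


class TestConditionalProbability:
    def test_zero_model_is_half(self):
        net = small_net()
        assert cn.conditional_probability(net, [0, 1], "A") == pytest.approx(0.5)

    def test_single_neighbor_logistic_value(self):
        net = small_net(w12=1.0)
        p = cn.conditional_probability(net, [0, 1], "A")
        assert p == pytest.approx(0.7310586, abs=1e-6)

    def test_large_negative_threshold_limit(self):
        net = small_net(b=(-40.0, 0.0))
        assert cn.conditional_probability(net, [0, 1], "A") < 1e-12

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            cn.conditional_probability(small_net(), [0, 1], "Z")


class TestFitNode:
    def test_ebic_reduces_to_bic_at_gamma_zero(self):
        rng = np.random.default_rng(1)
        X = (rng.random((300, 4)) < 0.4).astype(np.int8)
        f = fit_node(X, 0, ebic_gamma=0.0)
        df = (f.coefs != 0).sum(axis=1)
        bic = -2 * f.loglik + df * np.log(300)
        assert np.allclose(f.ebic, bic)
        assert np.isfinite(f.ebic).all()
        assert f.selected == int(np.argmin(f.ebic))

    def test_independent_columns_select_empty_model(self):
        """Independent Bernoulli columns: EBIC should pick zero slopes for
        (nearly) every seed."""
        empty = 0
        seeds = 10
        for s in range(seeds):
            rng = np.random.default_rng(100 + s)
            X = (rng.random((2000, 5)) < 0.35).astype(np.int8)
            f = fit_node(X, 0)
            empty += (f.selected_coefs == 0).all()
        assert empty >= seeds - 1

    def test_two_node_slope_consistency(self):
        """Node-wise logistic slope estimates the coupling: mean over 10
        seeds within +-0.15 of the true w=1 at n=5000."""
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        gt = cn.GroundTruth(w, np.array([-0.5, -0.5]), ["A", "B"])
        slopes = []
        for s in range(10):
            X = cn.gibbs_sample(gt, 5000, seed=300 + s, as_array=True)
            f = fit_node(X, 0)
            slopes.append(f.selected_coefs[0])
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.15)

    def test_constant_column_degenerate(self):
        X = np.ones((50, 3), dtype=np.int8)
        X[:, 1] = np.random.default_rng(0).integers(0, 2, 50)
        f = fit_node(X, 0)
        assert f.degenerate
        assert (f.selected_coefs == 0).all()
        # smoothed empirical log-odds of an all-ones column
        assert f.selected_intercept == pytest.approx(np.log(50.5 / 0.5))

    def test_penalized_objective_matches_fista_oracle(self):
        """Independent proximal-gradient oracle agrees to 1e-6 in objective."""
        rng = np.random.default_rng(7)
        n, q = 150, 3
        Z = (rng.random((n, q)) < 0.5).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + Z @ [0.9, -0.6, 0.0])))
             ).astype(float)
        lams = lambda_path(Z, y, n_lambda=5)
        coefs, ints, _ = logistic_lasso_path(Z, y, lams, np.ones(q))

        def objective(lam, b0, b):
            eta = b0 + Z @ b
            nll = np.mean(np.log1p(np.exp(-np.abs(eta)))
                          + np.maximum(eta, 0) - y * eta)
            return nll + lam * np.abs(b).sum()

        X = np.column_stack([np.ones(n), Z])
        lip = 0.25 * np.linalg.norm(X, 2) ** 2 / n
        for li, lam in enumerate(lams):
            wv = np.zeros(q + 1)
            v, t = wv.copy(), 1.0
            for _ in range(30000):
                pr = 1 / (1 + np.exp(-(X @ v)))
                step = v - X.T @ (pr - y) / n / lip
                step[1:] = np.sign(step[1:]) * np.maximum(
                    np.abs(step[1:]) - lam / lip, 0)
                tn = (1 + np.sqrt(1 + 4 * t * t)) / 2
                v = step + (t - 1) / tn * (step - wv)
                wv, t = step, tn
            assert abs(objective(lam, ints[li], coefs[li])
                       - objective(lam, wv[0], wv[1:])) < 1e-6


class TestSymmetrize:
    def _fits(self, c01, c10):
        X = np.array([[0, 1], [1, 0], [1, 1], [0, 0]] * 5, dtype=np.int8)
        f0 = fit_node(X, 0)
        f1 = fit_node(X, 1)
        f0.coefs[f0.selected, 0] = c01
        f1.coefs[f1.selected, 0] = c10
        return [f0, f1]

    def test_and_rule_means_both_nonzero(self):
        net = symmetrize(self._fits(0.4, 0.6), "AND")
        assert net.weights[0, 1] == pytest.approx(0.5)

    def test_and_drops_or_keeps_one_sided(self):
        fits = self._fits(0.4, 0.0)
        assert symmetrize(fits, "AND").weights[0, 1] == 0.0
        assert symmetrize(fits, "OR").weights[0, 1] == pytest.approx(0.4)

    def test_output_exactly_symmetric(self):
        rng = np.random.default_rng(3)
        X = (rng.random((200, 4)) < 0.5).astype(np.int8)
        net = cn.fit_ising(X)
        assert np.array_equal(net.weights, net.weights.T)

    def test_unknown_rule(self):
        with pytest.raises(ValueError):
            symmetrize(self._fits(0.1, 0.1), "XOR")


class TestFitIsing:
    def test_planted_triangles_recovered(self):
        gt = cn.make_planted_network(6, 2, 1.5, b=-1.0, seed=0)
        hits = 0
        for s in range(3):
            X = cn.gibbs_sample(gt, 10000, seed=500 + s)
            net = cn.fit_ising(X)
            est = {(int(i), int(j))
                   for i, j in zip(*np.nonzero(np.triu(net.weights, 1)))}
            within_pos = all(net.weights[i, j] > 0 for i, j in gt.edge_set())
            hits += (est == gt.edge_set() and within_pos)
        assert hits >= 2

    def test_degenerate_scale_runs(self):
        rng = np.random.default_rng(0)
        X = (rng.random((10, 38)) < 0.3).astype(np.int8)
        net = cn.fit_ising(X)
        assert net.p == 38

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = (rng.random((400, 4)) < 0.4).astype(np.int8)
        net1 = cn.fit_ising(X)
        net2 = cn.fit_ising(X[rng.permutation(400)])
        assert np.allclose(net1.weights, net2.weights)
        assert np.allclose(net1.thresholds, net2.thresholds)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_edge_sign_semantics(self, sign):
        """A single planted positive (negative) coupling is recovered with a
        positive (negative) weight."""
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = sign * 1.2
        gt = cn.GroundTruth(w, np.zeros(3), list("ABC"))
        X = cn.gibbs_sample(gt, 8000, seed=21)
        net = cn.fit_ising(X)
        assert sign * net.weights[0, 1] > 0

    def test_and_edges_subset_of_or_edges(self):
        gt = cn.make_planted_network(5, 2, 0.9, b=-0.5, seed=8)
        X = cn.gibbs_sample(gt, 1500, seed=8)
        e_and = cn.fit_ising(X, rule="AND").weights != 0
        e_or = cn.fit_ising(X, rule="OR").weights != 0
        assert not np.any(e_and & ~e_or)

    def test_recovery_f1_monotone_in_n(self):
        """Edge-set F1 against ground truth improves (weakly) with sample
        size, averaged over 10 seeds."""
        gt = cn.make_planted_network(6, 2, 1.5, b=-1.0, seed=0)
        true = gt.edge_set()

        def f1_at(n, seed):
            X = cn.gibbs_sample(gt, n, seed=seed)
            net = cn.fit_ising(X)
            est = {(int(i), int(j))
                   for i, j in zip(*np.nonzero(np.triu(net.weights, 1)))}
            tp = len(true & est)
            prec = tp / len(est) if est else 0.0
            rec = tp / len(true)
            return 2 * prec * rec / (prec + rec) if prec + rec else 0.0

        small = np.mean([f1_at(500, 700 + s) for s in range(10)])
        large = np.mean([f1_at(4000, 800 + s) for s in range(10)])
        assert large >= small
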