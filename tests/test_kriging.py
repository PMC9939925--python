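import numpy as np
import pytest

from stabkrig.geometry import make_mesh, pairwise_distance
from stabkrig.kriging import SingularSystemError, predict, predict_grid, solve_weights
from stabkrig.laa_data import from_counts, with_external_variance
from stabkrig.semivariogram import CovarianceModel, SphericalVariogram

from conftest import random_table


def qp_oracle(A, c0):
    """Constrained quadratic minimizer via null-space reduction.

    Minimizes w'Aw - 2 w'c0 subject to sum(w) = 1 by parametrizing
    w = e1 + N z with N a basis of the constraint's null space — a route
    entirely independent of the bordered-system solve.
    """
    m = A.shape[0]
    w0 = np.zeros(m)
    w0[0] = 1.0
    # null space of [1 ... 1]: columns e_i - e_{i+1}
    N = np.zeros((m, m - 1))
    for j in range(m - 1):
        N[j, j] = 1.0
        N[j + 1, j] = -1.0
    z = np.linalg.solve(N.T @ A @ N, N.T @ (c0 - A @ w0))
    return w0 + N @ z


def system_matrices(table, model, flavor, target):
    mask = table.usable
    coords = table.coords[mask]
    v = table.variances[mask]
    D = pairwise_distance(coords, coords)
    A = np.asarray(model(D))
    diag = {
        "stabilized": model.tau2 + v,
        "traditional": np.full(v.shape, model.tau2),
        "nugget_adjusted": np.full(v.shape, model.tau2 + model.variogram.nugget),
    }[flavor]
    np.fill_diagonal(A, diag)
    d0 = pairwise_distance(coords, np.array([target]))[:, 0]
    return A, np.asarray(model(d0))


class TestSolveWeights:
    def test_single_area_forced_weight_one(self, simple_model):
        for flavor in ("stabilized", "traditional", "nugget_adjusted"):
            t = from_counts([("only", (0, 0), 10, 1000.0)])
            w = solve_weights(t, simple_model, (3.0, 3.0), flavor=flavor)
            assert w.weights == pytest.approx([1.0])

    def test_traditional_exact_interpolation_at_centroid(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, n=7)
        model = CovarianceModel(SphericalVariogram(0.0, 0.4, 1.2))
        theta = t.log_rates
        for j in range(7):
            target = tuple(t.coords[j])
            w = solve_weights(t, model, target, flavor="traditional")
            pred = float(w.weights @ theta)
            assert pred == pytest.approx(theta[j], abs=1e-10)
            assert w.weights[j] == pytest.approx(1.0, abs=1e-10)

    def test_zero_case_area_gets_weight_zero(self, four_area_table, simple_model):
        w = solve_weights(four_area_table, simple_model, (0.5, 0.5), flavor="stabilized")
        assert "b" not in w.contributing_ids  # infinite variance -> excluded, weight 0
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_three_area_toy_matches_qp_oracle(self):
        """Spec'd covariances: weights equal the constrained-QP solution."""
        tau2 = 1.0
        v = np.array([0.5, 0.25, 0.1])
        A = np.array(
            [[tau2 + v[0], 0.3, 0.1], [0.3, tau2 + v[1], 0.2], [0.1, 0.2, tau2 + v[2]]]
        )
        c0 = np.array([0.4, 0.5, 0.2])
        expected = qp_oracle(A, c0)
        M = np.zeros((4, 4))
        M[:3, :3] = A
        M[3, :3] = M[:3, 3] = 1.0
        got = np.linalg.solve(M, np.append(c0, 1.0))[:3]
        assert np.abs(got - expected).max() < 1e-8
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_random_systems_match_qp_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            t = random_table(rng, n=n)
            model = CovarianceModel(
                SphericalVariogram(
                    float(rng.uniform(0, 0.1)), float(rng.uniform(0.1, 0.6)),
                    float(rng.uniform(0.3, 2.0)),
                )
            )
            target = tuple(rng.uniform(0, 1, 2))
            for flavor in ("stabilized", "traditional", "nugget_adjusted"):
                w = solve_weights(t, model, target, flavor=flavor)
                mask = t.usable
                A, c0 = system_matrices(t, model, flavor, target)
                assert np.abs(w.weights - qp_oracle(A, c0)).max() < 1e-8

    def test_weights_sum_to_one_with_negative_weights_allowed(self):
        rng = np.random.default_rng(4)
        t = random_table(rng, n=10)
        model = CovarianceModel(SphericalVariogram(0.01, 0.5, 1.5))
        for _ in range(20):
            target = tuple(rng.uniform(-0.5, 1.5, 2))
            w = solve_weights(t, model, target, flavor="stabilized")
            assert abs(w.weights.sum() - 1.0) < 1e-10

    def test_duplicate_points_singular_for_traditional(self):
        t = with_external_variance(
            [("a", (0, 0), -7.0, 0.01), ("b", (0, 0), -6.5, 0.01), ("c", (1, 1), -7.2, 0.01)]
        )
        model = CovarianceModel(SphericalVariogram(0.0, 0.4, 2.0))
        with pytest.raises(SingularSystemError, match="singular"):
            solve_weights(t, model, (0.5, 0.5), flavor="traditional")

    def test_no_usable_areas_fails(self, simple_model):
        t = from_counts([("a", (0, 0), 0, 100.0)])
        with pytest.raises(ValueError, match="no areas"):
            solve_weights(t, simple_model, (1.0, 1.0))

    def test_shrinkage_monotone_in_own_variance(self):
        """At a fixed centroid, the stabilized self-weight never grows with v."""
        coords = [(0.0, 0.0), (1.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        model = CovarianceModel(SphericalVariogram(0.0, 0.4, 2.0))
        weights = []
        for vj in np.geomspace(1e-6, 10.0, 12):
            t = with_external_variance(
                [("j", coords[0], -7.0, vj)]
                + [(f"o{i}", c, -7.1, 0.05) for i, c in enumerate(coords[1:])]
            )
            w = solve_weights(t, model, coords[0], flavor="stabilized")
            weights.append(w.weights[0])
        assert all(a >= b - 1e-12 for a, b in zip(weights, weights[1:]))


class TestPredict:
    def test_constant_field_predicts_constant(self):
        t = with_external_variance(
            [(f"a{i}", (float(i % 3), float(i // 3)), -6.5, 0.02) for i in range(6)]
        )
        model = CovarianceModel(SphericalVariogram(0.05, 0.3, 2.0))
        for flavor in ("stabilized", "traditional", "nugget_adjusted"):
            theta = predict_grid(t, model, np.array([[0.4, 0.7], [2.5, 1.5]]), flavor=flavor)
            assert np.allclose(theta, -6.5, atol=1e-10)

    def test_stabilized_equals_traditional_when_variances_vanish(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 1, (8, 2))
        theta = rng.normal(-7, 0.3, 8)
        t = with_external_variance(
            [(f"a{i}", tuple(coords[i]), theta[i], 1e-300) for i in range(8)]
        )
        model = CovarianceModel(SphericalVariogram(0.02, 0.4, 1.0))
        mesh = make_mesh((0, 1, 0, 1), 20, 20)
        stab = predict_grid(t, model, mesh.points, flavor="stabilized")
        trad = predict_grid(t, model, mesh.points, flavor="traditional")
        assert np.abs(stab - trad).max() < 1e-12

    def test_stabilized_converges_to_traditional_as_variance_shrinks(self):
        rng = np.random.default_rng(10)
        coords = rng.uniform(0, 1, (8, 2))
        theta = rng.normal(-7, 0.3, 8)
        model = CovarianceModel(SphericalVariogram(0.0, 0.4, 1.0))
        mesh = make_mesh((0, 1, 0, 1), 10, 10)
        trad = predict_grid(
            with_external_variance(
                [(f"a{i}", tuple(coords[i]), theta[i], 1e-12) for i in range(8)]
            ),
            model, mesh.points, flavor="traditional",
        )
        sups = []
        for v in (1e-1, 1e-3, 1e-5, 1e-7):
            stab = predict_grid(
                with_external_variance(
                    [(f"a{i}", tuple(coords[i]), theta[i], v) for i in range(8)]
                ),
                model, mesh.points, flavor="stabilized",
            )
            sups.append(np.abs(stab - trad).max())
        assert all(a > b for a, b in zip(sups, sups[1:]))
        assert sups[-1] < 1e-6

    def test_batch_matches_per_target_solves(self):
        rng = np.random.default_rng(12)
        t = random_table(rng, n=9)
        model = CovarianceModel(SphericalVariogram(0.01, 0.4, 1.0))
        targets = rng.uniform(0, 1, (15, 2))
        batch = predict_grid(t, model, targets, flavor="stabilized")
        theta = t.log_rates[t.usable]
        for j in range(15):
            w = solve_weights(t, model, tuple(targets[j]), flavor="stabilized")
            assert abs(batch[j] - float(w.weights @ theta)) < 1e-12

    def test_predict_returns_solutions_with_rates(self, four_area_table, simple_model):
        sols = predict(four_area_table, simple_model, [(0.5, 0.5)], flavor="stabilized")
        assert len(sols) == 1
        s = sols[0]
        assert s.rate == pytest.approx(np.exp(s.log_rate))
        assert np.isfinite(s.log_rate)
        assert s.weights.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_bounded_predictions_when_weights_in_unit_interval(self):
        rng = np.random.default_rng(13)
        t = random_table(rng, n=6)
        model = CovarianceModel(SphericalVariogram(0.0, 0.3, 1.5))
        theta = t.log_rates[t.usable]
        lo, hi = theta.min(), theta.max()
        sols = predict(t, model, rng.uniform(-1, 2, (30, 2)), flavor="stabilized")
        for s in sols:
            w = s.weights.weights
            if np.all((w >= -1e-12) & (w <= 1 + 1e-12)):
                assert lo - 1e-9 <= s.log_rate <= hi + 1e-9
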