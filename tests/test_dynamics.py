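"""Built-in dynamics models, rhs evaluation, equilibrium integration."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from netreduce import (
    NodePartition,
    WeightedDigraph,
    affine_model,
    builtin_model,
    full_rhs,
    homogeneous_block_fixture,
    integrate_to_equilibrium,
    reduce_network,
    reduced_rhs,
)

from conftest import random_positive_net

MODELS = ["neuronal", "sis", "ecological"]


class TestBuiltinModels:
    def test_neuronal_sigmoid_midpoint_and_no_first_arg(self):
        m = builtin_model("neuronal", tau=0.7, mu_thr=4.0)
        assert m.g(np.array(123.0), np.array(4.0)) == pytest.approx(0.5)
        assert not m.depends_on_first_arg
        assert np.all(m.g1(np.zeros(3), np.ones(3)) == 0)

    def test_sis_saturation(self):
        m = builtin_model("sis")
        y = np.linspace(0, 1, 5)
        assert np.all(m.g(np.ones(5), y) == 0)

    def test_ecological_uncoupled_roots_at_zero_migration(self):
        # with B=0 the cubic's roots are exactly {0, C, K_cap}
        m = builtin_model("ecological", B=1e-300, C=1.0, K_cap=5.0)
        for root in (0.0, 1.0, 5.0):
            assert m.f(np.array(root)) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_model_and_bad_params(self):
        with pytest.raises(ValueError, match="unknown model"):
            builtin_model("kuramoto")
        with pytest.raises(ValueError, match="gamma"):
            builtin_model("sis", gamma=-1.0)
        with pytest.raises(ValueError, match="K_cap"):
            builtin_model("ecological", C=5.0, K_cap=1.0)

    @pytest.mark.parametrize("name", MODELS)
    def test_partial_derivatives_match_finite_differences(self, name):
        m = builtin_model(name)
        xs = np.linspace(0.05, 8.0, 20)
        X, Y = np.meshgrid(xs, xs)
        h = 1e-6
        fd1 = (m.g(X + h, Y) - m.g(X - h, Y)) / (2 * h)
        fd2 = (m.g(X, Y + h) - m.g(X, Y - h)) / (2 * h)
        assert np.allclose(m.g1(X, Y), fd1, atol=1e-8)
        assert np.allclose(m.g2(X, Y), fd2, atol=1e-8)


class TestFullRhs:
    def test_uncoupled_reduces_to_self_dynamics(self, rng):
        m = builtin_model("ecological")
        net = WeightedDigraph(np.zeros((4, 4)))
        x = rng.uniform(0.1, 4.0, 4)
        assert np.allclose(full_rhs(m, net, x), m.f(x))

    def test_sis_self_loop_fixed_point(self):
        # single node, self-weight w > 1: endemic state at 1 - 1/w
        w = 2.5
        net = WeightedDigraph(np.array([[w]]))
        m = builtin_model("sis", gamma=1.0)
        assert full_rhs(m, net, np.array([1 - 1 / w]))[0] == pytest.approx(0.0, abs=1e-14)

    def test_matches_double_loop(self, rng):
        m = builtin_model("neuronal")
        net = random_positive_net(rng, 5)
        x = rng.uniform(0, 12, 5)
        naive = np.array(
            [
                m.f(x[i]) + sum(net.weights[i, j] * m.g(x[i], x[j]) for j in range(5))
                for i in range(5)
            ]
        )
        assert np.allclose(full_rhs(m, net, x), naive, atol=1e-12)

    def test_reports_first_bad_index(self):
        net = WeightedDigraph(np.ones((3, 3)))
        with pytest.raises(ValueError, match="node 1"):
            full_rhs(builtin_model("sis"), net, np.array([0.0, np.nan, 0.0]))


class TestReducedRhs:
    def test_correction_vanishes_when_mu_equals_reduced_adjacency(self, rng):
        net = homogeneous_block_fixture([3, 2], [[0.4, 0.8], [0.2, 0.6]])
        part = NodePartition.from_sizes([3, 2])
        rsys = reduce_network(net, part, "homogeneous")
        assert np.allclose(rsys.correction, rsys.reduced_adjacency, atol=1e-12)
        m = builtin_model("sis")
        X = rng.uniform(0, 1, 2)
        with_c = reduced_rhs(m, rsys, X, with_correction=True)
        without = reduced_rhs(m, rsys, X, with_correction=False)
        assert np.allclose(with_c, without, atol=1e-14)

    def test_neuronal_correction_is_noop(self, rng):
        net, part = random_positive_net(rng, 6), NodePartition.from_sizes([3, 3])
        rsys = reduce_network(net, part, "spectral")
        m = builtin_model("neuronal")
        X = rng.uniform(0, 12, 2)
        assert np.allclose(
            reduced_rhs(m, rsys, X, with_correction=True),
            reduced_rhs(m, rsys, X, with_correction=False),
        )

    @pytest.mark.parametrize("name", MODELS)
    def test_singleton_partition_reproduces_full_rhs(self, name, rng):
        net = random_positive_net(rng, 6)
        rsys = reduce_network(net, NodePartition.singletons(6), "spectral")
        m = builtin_model(name)
        x = rng.uniform(0.1, 2.0, 6)
        assert np.allclose(full_rhs(m, net, x), reduced_rhs(m, rsys, x), atol=1e-12)


class TestIntegrateToEquilibrium:
    def test_linear_decay(self):
        res = integrate_to_equilibrium(lambda x: -x, np.array([1.0]), tol=1e-10)
        assert res.converged
        assert abs(res.state[0]) < 1e-9

    def test_sis_single_node_closed_form(self):
        net = WeightedDigraph(np.array([[2.0]]))
        m = builtin_model("sis")
        res = integrate_to_equilibrium(
            lambda x: full_rhs(m, net, x), np.array([0.9]), tol=1e-12
        )
        assert res.converged
        assert res.state[0] == pytest.approx(0.5, abs=1e-9)

    def test_ecological_high_root(self):
        m = builtin_model("ecological")
        res = integrate_to_equilibrium(
            lambda x: m.f(x), np.array([6.0]), tol=1e-12
        )
        f_scalar = lambda x: float(m.f(np.asarray(x)))
        high_root = brentq(f_scalar, 4.0, 6.0, xtol=1e-12)
        assert res.converged
        assert res.state[0] == pytest.approx(high_root, abs=1e-8)

    def test_blowup_flagged_not_raised(self):
        res = integrate_to_equilibrium(lambda x: x, np.array([1.0]), tol=1e-9, t_max=100.0)
        assert not res.converged


class TestAffineExactness:
    @pytest.mark.parametrize(
        "make_setup",
        [
            pytest.param(lambda: ("fixture", [3, 4]), id="homogeneous-fixture"),
            pytest.param(lambda: ("singleton", 6), id="singleton-partition"),
        ],
    )
    def test_reduced_trajectory_matches_projection(self, make_setup, rng):
        """Affine f, g + exactly solved compatibility equations: the reduced
        observables reproduce the projected full trajectory."""
        kind, arg = make_setup()
        if kind == "fixture":
            net = homogeneous_block_fixture(arg, [[0.5, 0.2], [0.3, 0.4]])
            part = NodePartition.from_sizes(arg)
        else:
            net = random_positive_net(rng, arg, low=0.05, high=0.4)
            part = NodePartition.singletons(arg)
        model = affine_model(0.2, -1.0, 0.1, -0.3, 0.5)
        rsys = reduce_network(net, part, "spectral")
        x0 = rng.uniform(0, 2, net.n_nodes)
        X0 = rsys.observe(x0)
        sol_full = solve_ivp(
            lambda t, x: full_rhs(model, net, x), (0, 50), x0,
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        sol_red = solve_ivp(
            lambda t, X: reduced_rhs(model, rsys, X), (0, 50), X0,
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        assert sol_full.success and sol_red.success
        for t in np.linspace(0, 50, 40):
            assert np.allclose(
                rsys.observe(sol_full.sol(t)), sol_red.sol(t), atol=1e-7
            )
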