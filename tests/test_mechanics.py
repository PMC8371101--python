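"""Spring mechanics: energies, forces, equilibria, and the stretch protocol."""

import numpy as np
import pytest

from alveonet.constitutive import PRESETS, finalize_rest_lengths, initialize_isotropy
from alveonet.experiments import build_specimen
from alveonet.mechanics import (
    Constraints,
    boundary_force,
    equilibrate,
    incremental_modulus,
    nodal_forces,
    recruitment_fraction,
    run_stretch_protocol,
    segment_energy,
    strain_grid,
    stress_from_force,
    total_energy,
)
from alveonet.netgen import COLLAGEN, EDGE, ELASTIN, NetworkConfig, Segment, generate_network
from conftest import make_toy_network


@pytest.mark.parametrize(
    "d,seg_type,r0,k,expected",
    [
        (0.8, "collagen", 1.0, 5.0, 0.0),  # slack collagen stores nothing
        (1.0, "collagen", 1.0, 5.0, 0.0),  # at rest length
        (1.0, "elastin", 1.0, 2.0, 0.0),
        (1.5, "elastin", 1.0, 2.0, 0.25),  # 0.5*2*0.25
        (0.5, "elastin", 1.0, 2.0, 0.25),  # elastin resists compression
        (1.5, "collagen", 1.0, 2.0, 0.25),  # recruited collagen
        (1.5, "edge", 1.0, 2.0, 0.25),
    ],
)
def test_segment_energy(d, seg_type, r0, k, expected):
    seg = Segment(0, 0, 1, seg_type, r0, k, 0)
    assert np.isclose(segment_energy(d, seg), expected)


@pytest.fixture(scope="module")
def random_small_network():
    net = generate_network(NetworkConfig(n=10, alpha=0.5, rho=0.9, seed=6))
    rng = np.random.default_rng(99)
    initialize_isotropy(net, rng)
    pos = net.node_xy + rng.normal(0, 0.02, net.node_xy.shape)
    return net, pos


class TestEnergyAndForces:
    def test_total_energy_matches_per_segment_oracle(self, random_small_network):
        net, pos = random_small_network
        d = net.segment_lengths(pos)
        oracle = sum(segment_energy(d[s.id], s) for s in net.segments)
        assert np.isclose(total_energy(net, pos), oracle, rtol=1e-12)

    def test_energy_zero_at_rest(self):
        net = generate_network(NetworkConfig(n=8, seed=3))
        # as built, r0 equals the geometric length everywhere
        assert total_energy(net, net.node_xy) < 1e-20

    def test_forces_match_finite_differences(self, random_small_network):
        net, pos = random_small_network
        forces = nodal_forces(net, pos)
        h = 1e-7
        fd = np.zeros_like(forces)
        for i in range(net.n_nodes):
            for axis in range(2):
                pp, pm = pos.copy(), pos.copy()
                pp[i, axis] += h
                pm[i, axis] -= h
                fd[i, axis] = -(total_energy(net, pp) - total_energy(net, pm)) / (2 * h)
        scale = max(1.0, np.abs(forces).max())
        assert np.allclose(forces, fd, atol=1e-6 * scale)

    def test_single_spring_hooke(self):
        net = make_toy_network(
            [[0.2, 0.5], [0.7, 0.5]], [(0, 1, ELASTIN, 1.0, 1.0)], stage="final"
        )
        pos = np.array([[0.0, 0.0], [1.5, 0.0]])
        f = nodal_forces(net, pos)
        assert np.allclose(f[0], [0.5, 0.0])
        assert np.allclose(f[1], [-0.5, 0.0])

    def test_slack_collagen_contributes_no_force(self):
        net = make_toy_network(
            [[0.2, 0.5], [0.7, 0.5]], [(0, 1, COLLAGEN, 1.0, 100.0)], stage="final"
        )
        pos = np.array([[0.0, 0.0], [0.9, 0.0]])
        assert np.allclose(nodal_forces(net, pos), 0.0)


class TestEquilibrate:
    def _two_spring_net(self, k1, r01, k2, r02):
        # left wall node (x=0), free interior node, right wall node (x=1)
        return make_toy_network(
            [[0.0, 0.5], [0.4, 0.5], [1.0, 0.5]],
            [(0, 1, ELASTIN, r01, k1), (1, 2, ELASTIN, r02, k2)],
            stage="final",
        )

    @pytest.mark.parametrize("method", ["lbfgs", "scipy"])
    @pytest.mark.parametrize(
        "k1,r01,k2,r02", [(1.0, 0.3, 1.0, 0.3), (5.0, 0.2, 1.0, 0.5), (2.0, 0.5, 3.0, 0.3)]
    )
    def test_two_spring_closed_form(self, method, k1, r01, k2, r02):
        net = self._two_spring_net(k1, r01, k2, r02)
        cons = Constraints.from_network(net, strain=0.0)
        state = equilibrate(net, cons, net.node_xy, force_tol=1e-10, method=method)
        # force balance: k1 (x - r01) = k2 (1 - x - r02)
        x_expected = (k1 * r01 + k2 * (1.0 - r02)) / (k1 + k2)
        assert state.converged
        assert np.isclose(state.positions[1, 0], x_expected, atol=1e-8)

    def test_spring_at_rest_is_unchanged(self):
        net = self._two_spring_net(1.0, 0.4, 1.0, 0.6)
        cons = Constraints.from_network(net, strain=0.0)
        state = equilibrate(net, cons, net.node_xy)
        assert state.converged
        assert state.max_residual < 1e-10
        assert np.allclose(state.positions, net.node_xy)

    def test_methods_agree_on_elastin_network(self):
        # without slack collagen the energy is strictly convex near the
        # minimum, so the own solver and scipy must find the same state
        net = generate_network(NetworkConfig(n=12, alpha=0.0, rho=0.9, seed=8))
        rng = np.random.default_rng(5)
        initialize_isotropy(net, rng)
        cons = Constraints.frame(net)
        s1 = equilibrate(net, cons, net.node_xy, force_tol=1e-4, method="lbfgs")
        s2 = equilibrate(net, cons, net.node_xy, force_tol=1e-4, method="scipy")
        assert s1.converged and s2.converged
        assert np.isclose(s1.total_energy, s2.total_energy, rtol=1e-6)
        assert np.allclose(s1.positions, s2.positions, atol=1e-4)

    def test_tether_leaves_stress_unchanged(self):
        cfg = NetworkConfig(n=24, alpha=0.5, rho=0.85, seed=31)
        net, pos = build_specimen(cfg, PRESETS["healthy"])
        cons = Constraints.from_network(net, strain=0.2)
        start = pos.copy()
        start[:, 0] *= 1.2
        # tight tolerance so solver noise does not mask the tether's effect
        s0 = equilibrate(net, cons, start, force_tol=1e-6, max_evals=200_000)
        s1 = equilibrate(net, cons, start, force_tol=1e-6, max_evals=200_000,
                         tether=1e-8)
        f0 = boundary_force(net, s0.positions, cons)
        f1 = boundary_force(net, s1.positions, cons)
        assert abs(f1 - f0) <= 1e-4 * max(1.0, abs(f0))


@pytest.fixture(scope="module")
def healthy_result():
    cfg = NetworkConfig(n=24, alpha=0.5, rho=0.85, seed=17)
    net, pos = build_specimen(cfg, PRESETS["healthy"])
    return net, pos, run_stretch_protocol(net, pos, keep_positions=True)


class TestStretchProtocol:
    def test_grid_is_21_steps(self):
        g = strain_grid()
        assert len(g) == 21
        assert g[0] == 0.0 and g[-1] == 1.0
        assert np.allclose(np.diff(g), 0.05)

    def test_all_steps_converged_and_energy_monotone_per_step(self, healthy_result):
        net, pos0, res = healthy_result
        assert res.converged.all()
        assert np.all(res.max_residual <= 1e-2)
        # relaxation can only lower the energy from the warm start
        prev_width = 1.0
        pos = pos0.copy()
        for step, eps in enumerate(res.strain):
            cons = Constraints.from_network(net, strain=float(eps))
            width = 1.0 + float(eps)
            pos[:, 0] *= width / prev_width
            prev_width = width
            warm = total_energy(net, cons.apply(pos))
            assert res.energy[step] <= warm + 1e-12
            pos = res.positions[step].copy()

    def test_force_balance_across_sample(self, healthy_result):
        net, _, res = healthy_result
        for step in (0, 10, 20):
            pos = res.positions[step]
            f = nodal_forces(net, pos)
            cons = Constraints.from_network(net, strain=float(res.strain[step]))
            left = f[cons.left_nodes, 0].sum()
            right = f[cons.right_nodes, 0].sum()
            assert abs(left + right) <= 10 * 1e-2

    def test_collagen_all_slack_at_baseline(self, healthy_result):
        net, pos0, res = healthy_result
        # in the reference equilibrium every collagen segment has w > 1 slack
        assert recruitment_fraction(net, pos0) == 0.0

    def test_recruitment_mostly_non_decreasing(self, healthy_result):
        _, _, res = healthy_result
        drops = np.clip(-np.diff(res.recruitment), 0, None)
        assert drops.max() <= 0.05  # small refluctuations only
        assert res.recruitment[-1] > res.recruitment[0]

    def test_stress_positive_and_grows(self, healthy_result):
        _, _, res = healthy_result
        assert np.all(res.force >= 0)
        assert res.stress[-1] > res.stress[5] > 0

    def test_determinism(self):
        from alveonet.experiments import simulate_stretch

        r1 = simulate_stretch(seed=23, n=24)
        r2 = simulate_stretch(seed=23, n=24)
        assert np.array_equal(r1.stress, r2.stress)
        assert np.array_equal(r1.recruitment, r2.recruitment)
        assert np.array_equal(r1.percolated, r2.percolated)

    def test_elastin_only_network_is_nearly_linear(self):
        # remove collagen entirely: the remaining elastin/edge network has a
        # close-to-linear stress-strain curve; recruitment is the source of
        # the nonlinearity in the full model
        cfg = NetworkConfig(n=24, alpha=0.0, rho=0.85, seed=41)
        rng = cfg.rng()
        net = generate_network(cfg, rng)
        initialize_isotropy(net, rng)
        cons = Constraints.frame(net)
        state = equilibrate(net, cons, net.node_xy, max_evals=200_000)
        finalize_rest_lengths(net, net.segment_lengths(state.positions),
                              PRESETS["healthy"], rng)
        res = run_stretch_protocol(net, state.positions, keep_positions=False)
        mod = incremental_modulus(res)
        assert np.all(res.recruitment == 0.0)
        # after the initial geometric reorientation transient (free top/bottom
        # necking in once the frame is released) the modulus is nearly flat
        inner = mod[res.strain >= 0.3]
        assert inner.max() - inner.min() <= 0.2 * np.abs(inner).max()
        # and over the whole range it changes far less than the full model,
        # whose recruitment drives orders-of-magnitude stiffening
        assert mod.max() / mod.min() < 5.0


class TestReadouts:
    def test_stress_from_force(self):
        assert stress_from_force(0.0, 0.3) == 0.0
        assert stress_from_force(2.5, 0.3) == 2.5  # unit reference section
        assert stress_from_force(2.0, 0.3, area_mode="current", current_height=0.5) == 4.0
        with pytest.raises(ValueError):
            stress_from_force(1.0, 0.0, area_mode="bogus")

    def test_recruitment_fraction_counts(self):
        # 12 collagen springs between a wall pair, 3 taut
        nodes = [[0.0, 0.1 * i] for i in range(12)] + [[1.0, 0.1 * i] for i in range(12)]
        r0s = [0.9] * 3 + [1.5] * 9
        segs = [(i, 12 + i, COLLAGEN, r0s[i], 1.0) for i in range(12)]
        net = make_toy_network(nodes, segs, stage="final")
        frac = recruitment_fraction(net, net.node_xy)
        assert np.isclose(frac, 0.25)

    def test_recruitment_errors_without_collagen(self):
        net = make_toy_network(
            [[0.0, 0.5], [1.0, 0.5]], [(0, 1, ELASTIN, 1.0, 1.0)], stage="final"
        )
        with pytest.raises(ValueError):
            recruitment_fraction(net, net.node_xy)

    def test_incremental_modulus(self):
        strain = strain_grid()
        assert np.allclose(incremental_modulus(strain, 3.0 * strain), 3.0)
        assert np.allclose(incremental_modulus(strain, np.ones_like(strain)), 0.0)
        with pytest.raises(ValueError):
            incremental_modulus(np.array([0.0]), np.array([1.0]))
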