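"""Graph construction, min-cut solve, oracle equivalence, constraints."""

import numpy as np
import pytest

import rfaseg as rs
from rfaseg.errors import (
    InfeasibleConstraintError,
    InvalidParameterError,
    OutOfBoundsError,
    SizeGuardError,
    StructuralError,
    UnreachableConstraintError,
)
from rfaseg.graphcut import derive_cost_threshold, node_excess

from conftest import random_node_grid


def _params(template, n_nodes, delta_r, theta=None):
    return rs.GraphCutParams(
        delta_r=delta_r,
        nodes_per_ray=n_nodes,
        max_radius_mm=float(n_nodes),
        template_level=template.level,
        cost_scale=1.0,
        cost_threshold=theta,
    )


# ---------------------------------------------------------------------------
# node sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_radii_follow_uniform_step_rule(self, uniform_volume, icosa_template):
        params = rs.GraphCutParams(
            nodes_per_ray=40, max_radius_mm=40.0, template_level=0
        )
        grid = rs.sample_node_grid(
            uniform_volume, rs.SeedPoint((10.0, 10.0, 10.0)), icosa_template,
            params, 40.0,
        )
        assert np.allclose(grid.radii, np.arange(1, 41))
        assert np.all(np.diff(grid.radii) > 0)

    def test_constant_volume_gives_zero_cost_in_bounds(
        self, uniform_volume, icosa_template
    ):
        params = rs.GraphCutParams(
            nodes_per_ray=8, max_radius_mm=8.0, template_level=0
        )
        grid = rs.sample_node_grid(
            uniform_volume, rs.SeedPoint((10.0, 10.0, 10.0)), icosa_template,
            params, 40.0,
        )
        assert np.all(grid.cost[grid.in_bounds] <= 1e-9)
        assert np.all(grid.cost >= 0.0)

    def test_trilinear_interpolation_on_linear_ramp(self, icosa_template):
        # intensity = 2x + 3y + 5z is reproduced exactly by trilinear sampling
        idx = np.indices((25, 25, 25), dtype=float)
        values = 2 * idx[0] + 3 * idx[1] + 5 * idx[2]
        vol = rs.ImageVolume(values, spacing=(1.0, 1.0, 1.0))
        params = rs.GraphCutParams(
            nodes_per_ray=5, max_radius_mm=5.0, template_level=0
        )
        grid = rs.sample_node_grid(
            vol, rs.SeedPoint((12.0, 12.0, 12.0)), icosa_template, params, 0.0
        )
        p = grid.positions[grid.in_bounds]
        expected = 2 * p[:, 0] + 3 * p[:, 1] + 5 * p[:, 2]
        assert np.allclose(grid.gray[grid.in_bounds], expected, atol=1e-9)

    def test_near_face_seed_flags_out_of_bounds(self, uniform_volume, icosa_template):
        params = rs.GraphCutParams(
            nodes_per_ray=40, max_radius_mm=40.0, template_level=0
        )
        grid = rs.sample_node_grid(
            uniform_volume, rs.SeedPoint((5.0, 10.0, 10.0)), icosa_template,
            params, 40.0,
        )
        assert not np.all(grid.in_bounds)
        penalty = grid.cost[~grid.in_bounds]
        assert np.all(penalty > grid.cost[grid.in_bounds].max())

    def test_seed_outside_raises(self, uniform_volume, icosa_template):
        params = rs.GraphCutParams(nodes_per_ray=4, max_radius_mm=4.0)
        with pytest.raises(OutOfBoundsError):
            rs.sample_node_grid(
                uniform_volume, rs.SeedPoint((-5.0, 0.0, 0.0)), icosa_template,
                params, 40.0,
            )


# ---------------------------------------------------------------------------
# parameters and network structure
# ---------------------------------------------------------------------------

class TestStructure:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"nodes_per_ray": 1},
            {"nodes_per_ray": 41},
            {"delta_r": -1},
            {"delta_r": 8, "nodes_per_ray": 8},
            {"max_radius_mm": 0.0},
            {"template_level": 7},
            {"cost_scale": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            rs.GraphCutParams(**kwargs)

    def test_ray_count_mismatch_raises(self, icosa_template, template_l2):
        rng = np.random.default_rng(0)
        grid = random_node_grid(rng, icosa_template, 6)
        with pytest.raises(StructuralError):
            rs.build_flow_network(grid, template_l2, _params(template_l2, 6, 1))

    @pytest.mark.parametrize("delta_r", [0, 1, 2])
    def test_inter_edges_span_at_most_delta_r_levels(self, icosa_template, delta_r):
        rng = np.random.default_rng(1)
        n = 6
        grid = random_node_grid(rng, icosa_template, n)
        net = rs.build_flow_network(
            grid, icosa_template, _params(icosa_template, n, delta_r, theta=50.0)
        )
        inter = (
            (net.edges_u < net.source)
            & (net.edges_v < net.source)
            & (net.edges_u // n != net.edges_v // n)
        )
        lvl_u = net.edges_u[inter] % n
        lvl_v = net.edges_v[inter] % n
        assert np.all(lvl_v == np.maximum(0, lvl_u - delta_r))

    def test_infinite_edges_exceed_total_sink_capacity(self, icosa_template):
        rng = np.random.default_rng(2)
        grid = random_node_grid(rng, icosa_template, 6)
        net = rs.build_flow_network(
            grid, icosa_template, _params(icosa_template, 6, 1, theta=50.0)
        )
        sink_caps = net.edges_cap[net.edges_v == net.sink]
        assert net.infinity > int(sink_caps.sum())

    def test_node_zero_always_on_source_side(self, icosa_template):
        # even when every node looks like background, the seed stays foreground
        rng = np.random.default_rng(3)
        grid = random_node_grid(rng, icosa_template, 5, cost_low=90, cost_high=100)
        net = rs.build_flow_network(
            grid, icosa_template, _params(icosa_template, 5, 1, theta=10.0)
        )
        cut = rs.solve_min_cut(net)
        assert np.all(cut.cut_index == 0)


# ---------------------------------------------------------------------------
# oracle equivalence and cut properties
# ---------------------------------------------------------------------------

class TestMinCut:
    @pytest.mark.parametrize("seed", range(40))
    def test_min_cut_matches_brute_force_exactly(self, icosa_template, seed):
        """Solver objective equals the exhaustive feasible minimum, exactly."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(6, 9))
        delta_r = int(rng.integers(0, 3))
        theta = float(rng.integers(20, 80))
        grid = random_node_grid(rng, icosa_template, n)
        net = rs.build_flow_network(
            grid, icosa_template, _params(icosa_template, n, delta_r, theta=theta)
        )
        cut = rs.solve_min_cut(net)
        oracle = rs.brute_force_cut(grid, icosa_template, delta_r, cost_threshold=theta)
        assert cut.boundary_cost == pytest.approx(oracle.boundary_cost, abs=1e-9)
        assert cut.feasible
        # min-cut value identity: flow = boundary cost + source-link slack
        assert cut.flow_value == pytest.approx(
            cut.boundary_cost + net.source_slack / net.cost_scale, abs=1e-9
        )
        assert cut.flow_value < net.infinity / net.cost_scale

    @pytest.mark.parametrize("seed", range(10))
    def test_delta_r_zero_forces_sphere(self, icosa_template, seed):
        rng = np.random.default_rng(2000 + seed)
        grid = random_node_grid(rng, icosa_template, 8)
        net = rs.build_flow_network(
            grid, icosa_template, _params(icosa_template, 8, 0, theta=50.0)
        )
        cut = rs.solve_min_cut(net)
        assert len(np.unique(cut.cut_index)) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_cost_non_increasing_in_delta_r(self, icosa_template, seed):
        rng = np.random.default_rng(3000 + seed)
        grid = random_node_grid(rng, icosa_template, 8)
        costs = []
        for delta_r in (0, 1, 2, 3):
            net = rs.build_flow_network(
                grid, icosa_template, _params(icosa_template, 8, delta_r, theta=50.0)
            )
            costs.append(rs.solve_min_cut(net).boundary_cost)
        assert all(b <= a + 1e-9 for a, b in zip(costs, costs[1:]))

    def test_unconstrained_delta_r_gives_per_ray_minima(self, icosa_template):
        rng = np.random.default_rng(77)
        n = 7
        grid = random_node_grid(rng, icosa_template, n)
        oracle = rs.brute_force_cut(
            grid, icosa_template, n - 1, cost_threshold=50.0
        )
        excess = np.cumsum(node_excess(grid.cost, 50.0), axis=1)
        per_ray = excess.min(axis=1).sum()
        assert oracle.boundary_cost == pytest.approx(per_ray)

    def test_tie_break_lexicographic_in_oracle(self, icosa_template):
        # costs exactly at the margin: every vote is zero, every cut ties
        grid = random_node_grid(np.random.default_rng(0), icosa_template, 5)
        grid.cost[:] = 30.0
        oracle = rs.brute_force_cut(grid, icosa_template, 1, cost_threshold=30.0)
        assert np.all(oracle.cut_index == 0)
        # the solver reports the maximal tied cut instead; same objective value
        net = rs.build_flow_network(
            grid, icosa_template, _params(icosa_template, 5, 1, theta=30.0)
        )
        cut = rs.solve_min_cut(net)
        assert np.all(cut.cut_index == 4)
        assert cut.boundary_cost == pytest.approx(oracle.boundary_cost)

    def test_brute_force_size_guard(self):
        tpl = rs.build_ray_template(1)  # 32 rays: too many to enumerate
        rng = np.random.default_rng(0)
        grid = random_node_grid(rng, tpl, 4)
        with pytest.raises(SizeGuardError):
            rs.brute_force_cut(grid, tpl, 1)

    def test_derived_threshold_is_half_contrast(self, icosa_template):
        grid = random_node_grid(np.random.default_rng(0), icosa_template, 6)
        grid.gray[:] = 110.0
        grid.reference_value = 40.0
        assert derive_cost_threshold(grid) == pytest.approx(35.0)


# ---------------------------------------------------------------------------
# boundary constraints
# ---------------------------------------------------------------------------

class TestConstraints:
    def _solve_with_constraints(self, template, grid, delta_r, constraints):
        net = rs.build_flow_network(
            grid, template, _params(template, grid.n_nodes, delta_r, theta=50.0)
        )
        net = rs.apply_boundary_constraints(net, grid, constraints)
        return rs.solve_min_cut(net)

    def test_constraint_pins_cut_on_nearest_ray(self, icosa_template):
        rng = np.random.default_rng(5)
        grid = random_node_grid(rng, icosa_template, 8)
        ray = 3
        point = tuple(grid.positions[ray, 3])  # node index 3 of ray 3
        cut = self._solve_with_constraints(
            icosa_template, grid, 7, [rs.BoundaryConstraint(point)]
        )
        assert cut.cut_index[ray] == 3

    def test_constraint_with_delta_r_zero_sets_sphere_radius(self, icosa_template):
        rng = np.random.default_rng(6)
        grid = random_node_grid(rng, icosa_template, 8)
        point = tuple(grid.positions[5, 3])
        cut = self._solve_with_constraints(
            icosa_template, grid, 0, [rs.BoundaryConstraint(point)]
        )
        assert np.all(cut.cut_index == 3)

    def test_conflicting_constraints_detected(self, icosa_template):
        rng = np.random.default_rng(7)
        grid = random_node_grid(rng, icosa_template, 8)
        pairs = icosa_template.adjacency_pairs()
        a, b = pairs[0]
        constraints = [
            rs.BoundaryConstraint(tuple(grid.positions[a, 1])),
            rs.BoundaryConstraint(tuple(grid.positions[b, 6])),
        ]
        with pytest.raises(InfeasibleConstraintError):
            self._solve_with_constraints(icosa_template, grid, 1, constraints)

    def test_unreachable_constraint_raises(self, icosa_template):
        rng = np.random.default_rng(8)
        grid = random_node_grid(rng, icosa_template, 8)
        net = rs.build_flow_network(
            grid, icosa_template, _params(icosa_template, 8, 1, theta=50.0)
        )
        with pytest.raises(UnreachableConstraintError):
            rs.apply_boundary_constraints(
                net, grid, [rs.BoundaryConstraint((100.0, 0.0, 0.0))]
            )
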