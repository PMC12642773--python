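"""Tangency points, mortality/ordering manifolds and separation probes.

The brute-force simulation classifier is the oracle throughout: a manifold
is accepted exactly when probe pairs straddling it classify to its two
advertised outcomes.
"""

import numpy as np
import pytest

from viadeco import (
    NotAJointFatalCorner,
    NotAMortalityPoint,
    classify_state,
    find_joint_fatal_corners,
    find_tangency_points,
    linear_field,
    mortality_manifold,
    normal_flow,
    ordering_manifold,
    reduced_system,
    verify_separation,
)
from viadeco.decomposition import Manifold, PointNotOnFacet
from viadeco import box_region


class TestNormalFlow:
    def test_inward_flow_is_negative(self, scenario_a):
        field, region, _ = scenario_a
        assert normal_flow(field, region, "x1_upper", (1.0, 0.5)) == pytest.approx(-0.5)

    def test_outward_flow_is_positive(self, scenario_b):
        field, region, _ = scenario_b
        assert normal_flow(field, region, "x1_upper", (1.0, 0.5)) == pytest.approx(0.5)

    def test_tangent_flow_is_zero(self):
        field = linear_field([[0.0, -1.0], [1.0, 0.0]], (0.0, 0.0))
        region = box_region([(-1, 1), (-1, 1)])
        assert normal_flow(field, region, "x1_upper", (1.0, 0.0)) == pytest.approx(0.0)

    def test_off_facet_point_rejected(self, scenario_a):
        field, region, _ = scenario_a
        with pytest.raises(PointNotOnFacet):
            normal_flow(field, region, "x1_upper", (0.5, 0.5))


class TestTangencyPoints:
    def test_all_inward_facets_have_no_tangency(self, scenario_a):
        field, region, _ = scenario_a
        for con in region.constraints:
            assert find_tangency_points(field, region, con.id) == []

    def test_rotation_field_tangency_at_facet_midline(self):
        field = linear_field([[0.0, -1.0], [1.0, 0.0]], (0.0, 0.0))
        region = box_region([(-1, 1), (-1, 1)])
        tps = find_tangency_points(field, region, "x1_upper")
        assert len(tps) == 1
        assert np.allclose(tps[0].location, [1.0, 0.0], atol=1e-9)

    def test_scenario_c_tangency_matches_closed_form(
        self, scenario_c, scenario_c_attractors
    ):
        field, region, spec = scenario_c
        tps = find_tangency_points(
            field, region, "x2_upper", attractors=scenario_c_attractors
        )
        assert len(tps) == 1
        tp = tps[0]
        # closed form: omega x1 + lam x2 = 0 on the facet x2 = 0.5
        assert np.allclose(tp.location, spec.expected_facts["tangency"], atol=1e-6)
        assert tp.normal_residual <= 1e-9
        assert tp.forward_fate.status == "asymptotically_viable"
        assert tp.organizing

    def test_doubling_scan_resolution_finds_nothing_new(
        self, scenario_c, scenario_c_attractors
    ):
        field, region, _ = scenario_c
        coarse = find_tangency_points(
            field, region, "x2_upper", scan_resolution=128,
            attractors=scenario_c_attractors,
        )
        fine = find_tangency_points(
            field, region, "x2_upper", scan_resolution=256,
            attractors=scenario_c_attractors,
        )
        assert len(coarse) == len(fine)
        for a, b in zip(coarse, fine):
            assert np.allclose(a.location, b.location, atol=1e-9)


@pytest.fixture(scope="module")
def c_manifold(scenario_c, scenario_c_attractors):
    field, region, _ = scenario_c
    tp = find_tangency_points(
        field, region, "x2_upper", attractors=scenario_c_attractors
    )[0]
    return mortality_manifold(field, region, tp), tp


class TestMortalityManifold:
    def test_seed_equality_and_kind(self, c_manifold):
        man, tp = c_manifold
        assert man.kind == "mortality"
        assert np.allclose(man.points[0], tp.location, atol=1e-10)
        assert not man.degenerate

    def test_all_points_inside_closed_region(self, c_manifold, scenario_c):
        _, region, _ = scenario_c
        man, _ = c_manifold
        slack = 1e-8  # event refinement leaves the endpoint within atol
        for p in man.points:
            assert all(c.value(p) <= slack for c in region.constraints)

    def test_separates_asymptotic_from_transient(
        self, c_manifold, scenario_c, scenario_c_attractors
    ):
        field, region, _ = scenario_c
        man, _ = c_manifold
        report = verify_separation(
            man,
            lambda x: classify_state(
                field, region, x, attractors=scenario_c_attractors
            ).status,
            n_probes=100,
            band=1e-2,
            seed=1234,
            region=region,
        )
        assert report.perfect
        assert report.counterexamples == []

    def test_forward_flow_from_manifold_returns_to_seed_facet(
        self, c_manifold, scenario_c
    ):
        from viadeco import integrate

        field, region, _ = scenario_c
        man, tp = c_manifold
        # an interior manifold point flows forward back to the seed's facet
        # neighbourhood before any other exit
        mid = man.points[len(man.points) // 3]
        traj = integrate(field, mid, 50.0, events=region)
        if traj.termination.reason == "event":
            assert traj.termination.constraint_ids == (tp.constraint_id,)

    def test_straight_chord_fails_separation(
        self, scenario_c, scenario_c_attractors
    ):
        field, region, _ = scenario_c
        chord = Manifold(
            kind="mortality",
            seed=np.array([0.05, 0.5]),
            points=np.array([[0.05, 0.5], [-0.6, -0.6]]),
            times=np.array([0.0, -1.0]),
            labels_either_side=("asymptotically_viable", "transiently_viable"),
        )
        report = verify_separation(
            chord,
            lambda x: classify_state(
                field, region, x, attractors=scenario_c_attractors
            ).status,
            n_probes=100,
            band=1e-2,
            seed=1234,
            region=region,
        )
        assert report.fraction < 1.0
        assert report.counterexamples

    def test_non_organizing_tangency_rejected(self, scenario_c):
        field, region, _ = scenario_c
        # without attractors the forward fate cannot be asymptotic
        tp = find_tangency_points(field, region, "x2_upper")[0]
        assert tp.forward_fate.status != "asymptotically_viable"
        with pytest.raises(NotAMortalityPoint):
            mortality_manifold(field, region, tp)


class TestJointFatalCorners:
    def test_two_cell_corner_found_with_outward_flows(self, two_cell):
        system, spec = two_cell
        field, region = reduced_system(system, {"blue", "purple"})
        scan = find_joint_fatal_corners(field, region)
        assert len(scan.fatal) == 1
        corner = scan.fatal[0]
        assert np.allclose(
            corner.location, spec.expected_facts["joint_fatal_corner"]
        )
        assert all(nf > 0 for nf in corner.normal_flows)

    def test_all_inward_region_has_no_fatal_corner(self, scenario_a):
        field, region, _ = scenario_a
        scan = find_joint_fatal_corners(field, region)
        assert scan.fatal == []

    def test_marginal_corner_excluded_but_reported(self):
        # flow exactly tangent to one facet at the corner (1, 1)
        field = linear_field(np.diag([0.0, 1.0]), (1.0, 0.0))
        region = box_region([(0, 1), (0, 1)])
        scan = find_joint_fatal_corners(field, region)
        fatal_locs = [tuple(c.location) for c in scan.fatal]
        assert (1.0, 1.0) not in fatal_locs
        assert any(
            np.allclose(c.location, [1.0, 1.0]) for c in scan.marginal
        )


class TestOrderingManifold:
    def test_separates_which_cell_dies_first(self, two_cell):
        from viadeco import simulate_hybrid

        system, _ = two_cell
        field, region = reduced_system(system, {"blue", "purple"})
        corner = find_joint_fatal_corners(field, region).fatal[0]
        man = ordering_manifold(field, region, corner)
        assert man.kind == "ordering"
        assert np.allclose(man.points[0], corner.location, atol=1e-10)
        assert set(man.labels_either_side) == {"blue:b_min", "purple:p_min"}

        def first_to_die(x):
            events = simulate_hybrid(system, x, 50.0).events
            return events[0].constraint_ids[0]

        report = verify_separation(
            man, first_to_die, n_probes=60, band=1e-2, seed=7, region=region
        )
        assert report.perfect

    def test_non_fatal_corner_rejected(self, two_cell):
        from viadeco.decomposition import Corner

        system, _ = two_cell
        field, region = reduced_system(system, {"blue", "purple"})
        bogus = Corner(np.array([0.1, 0.05]), ("blue:b_min", "purple:p_min"), (-0.1, 0.2))
        with pytest.raises(NotAJointFatalCorner):
            ordering_manifold(field, region, bogus)


class TestVerifySeparation:
    def test_zero_probes_rejected(self, scenario_c):
        man = Manifold(
            kind="mortality",
            seed=np.array([0.0, 0.0]),
            points=np.array([[0.0, 0.0], [1.0, 1.0]]),
            times=np.array([0.0, -1.0]),
            labels_either_side=("a", "b"),
        )
        with pytest.raises(ValueError):
            verify_separation(man, lambda x: "a", n_probes=0)

    def test_probe_count_accounting(self, scenario_c, scenario_c_attractors):
        field, region, _ = scenario_c
        tp = find_tangency_points(
            field, region, "x2_upper", attractors=scenario_c_attractors
        )[0]
        man = mortality_manifold(field, region, tp)
        report = verify_separation(
            man, lambda x: "asymptotically_viable", n_probes=50, band=1e-2,
            seed=3, region=region,
        )
        assert report.n_evaluated + report.n_skipped == 50
        # constant classifier cannot separate anything
        assert report.fraction == 0.0
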