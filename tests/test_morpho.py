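"""Sholl profiles, branch morphometrics, zone density, SWC round trip."""

import numpy as np
import pytest

from neuroagg import (
    Arbor,
    ArborSpec,
    MorphometryParams,
    ShollParams,
    ZoneSpec,
    branch_morphometrics,
    gen_arbor,
    read_swc,
    sholl_profile,
    write_swc,
    zone_density,
)

from oracles import dense_sholl


def make_arbor(nodes):
    """nodes: list of (id, x, y, parent)."""
    ids = [n[0] for n in nodes]
    xyz = [(n[1], n[2], 0.0) for n in nodes]
    parents = [n[3] for n in nodes]
    return Arbor(ids=np.array(ids), xyz=np.array(xyz), parents=np.array(parents))


def random_specs(n, base_seed=0):
    specs = []
    for k in range(n):
        specs.append(
            ArborSpec(
                n_main_branches=1 + k % 4,
                junctions_per_branch=k % 4,
                segment_length=12.0 + (k % 5) * 7.0,
                branch_angle_spread=10.0 + (k % 3) * 15.0,
                side_branch_length=[None, 6.0, 15.0, 4.9, 5.1][k % 5],
                seed=base_seed + k,
            )
        )
    return specs


class TestShollProfile:
    def test_single_straight_process(self):
        arbor = make_arbor([(1, 0, 0, -1), (2, 100.0, 0, 1)])
        prof = sholl_profile(arbor, ShollParams(step=10.0))
        assert list(prof.radii) == [10.0 * k for k in range(1, 11)]
        # one crossing at 10..90; the terminal at r=100 sits on the circle
        assert list(prof.crossings[:9]) == [1] * 9

    def test_y_tree_crossings(self):
        arbor = make_arbor([
            (1, 0, 0, -1),
            (2, 50.0, 0, 1),
            (3, 90.0, 30.0, 2),
            (4, 90.0, -30.0, 2),
        ])
        prof = sholl_profile(arbor, ShollParams(step=10.0, r_max=90.0))
        below = prof.crossings[prof.radii < 50]
        above = prof.crossings[(prof.radii > 50) & (prof.radii < 90)]
        assert np.all(below == 1)
        assert np.all(above == 2)

    def test_vertex_on_circle_counts_once(self):
        # bifurcation vertex exactly at r = 50: shared by three edges
        arbor = make_arbor([
            (1, 0, 0, -1),
            (2, 50.0, 0, 1),
            (3, 100.0, 20.0, 2),
            (4, 100.0, -20.0, 2),
        ])
        prof = sholl_profile(arbor, ShollParams(step=50.0, r_max=50.0))
        assert prof.crossings[0] == 1

    def test_soma_only_arbor_is_all_zero(self):
        arbor = make_arbor([(1, 0, 0, -1)])
        prof = sholl_profile(arbor, ShollParams(step=5.0, r_max=20.0))
        assert np.all(prof.crossings == 0)

    def test_matches_dense_sampling_oracle(self):
        for spec in random_specs(12, base_seed=100):
            arbor, _ = gen_arbor(spec)
            prof = sholl_profile(arbor, ShollParams(step=5.0))
            oracle = dense_sholl(arbor, prof.radii, step=0.01)
            assert np.array_equal(prof.crossings, oracle), f"spec={spec}"

    def test_rigid_motion_invariance(self):
        arbor, _ = gen_arbor(ArborSpec(seed=21))
        prof0 = sholl_profile(arbor)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ])
        moved = Arbor(
            ids=arbor.ids.copy(),
            xyz=arbor.xyz @ rot.T + np.array([123.4, -56.7, 8.9]),
            parents=arbor.parents.copy(),
        )
        prof1 = sholl_profile(moved)
        assert np.array_equal(prof0.crossings, prof1.crossings)
        m0 = branch_morphometrics(arbor)
        m1 = branch_morphometrics(moved)
        assert m0.n_main_branches == m1.n_main_branches
        assert m0.n_junctions == m1.n_junctions
        assert m0.total_process_length == pytest.approx(m1.total_process_length, abs=1e-9)
        assert m0.longest_main_branch == pytest.approx(m1.longest_main_branch, abs=1e-9)


class TestBranchMorphometrics:
    def test_single_unbranched_process(self):
        arbor = make_arbor([(1, 0, 0, -1), (2, 50.0, 0, 1)])
        res = branch_morphometrics(arbor)
        assert res.n_main_branches == 1
        assert res.longest_main_branch == pytest.approx(50.0)
        assert res.total_process_length == pytest.approx(50.0)
        assert res.n_junctions == 0

    def test_hand_computed_mixed_arbor(self):
        # branch A: 100 um trunk, 20 um side branch at its midpoint;
        # branch B: 30 um unbranched; stub C: 3 um unbranched
        arbor = make_arbor([
            (1, 0, 0, -1),
            (2, 50.0, 0, 1),        # A midpoint
            (3, 100.0, 0, 2),       # A terminal
            (4, 50.0, 20.0, 2),     # A side branch
            (5, 0.0, 30.0, 1),      # B terminal
            (6, -3.0, 0.0, 1),      # C stub
        ])
        res = branch_morphometrics(arbor)
        assert res.n_main_branches == 2
        assert res.n_junctions == 1
        assert res.longest_main_branch == pytest.approx(100.0)
        assert res.total_process_length == pytest.approx(153.0)

    def test_short_side_branch_is_not_a_junction(self):
        arbor = make_arbor([
            (1, 0, 0, -1),
            (2, 50.0, 0, 1),
            (3, 100.0, 0, 2),
            (4, 50.0, 3.0, 2),  # 3 um side branch: below the 5 um filter
        ])
        res = branch_morphometrics(arbor)
        assert res.n_junctions == 0
        # sub-5 um stubs still contribute to total process length
        assert res.total_process_length == pytest.approx(103.0)

    @pytest.mark.parametrize("side,expected", [(4.9, 0), (5.1, 1)])
    def test_junction_filter_edge(self, side, expected):
        arbor = make_arbor([
            (1, 0, 0, -1),
            (2, 50.0, 0, 1),
            (3, 100.0, 0, 2),
            (4, 50.0, side, 2),
        ])
        assert branch_morphometrics(arbor).n_junctions == expected

    def test_exact_threshold_side_branch_counts(self):
        arbor = make_arbor([
            (1, 0, 0, -1), (2, 50.0, 0, 1), (3, 100.0, 0, 2), (4, 50.0, 5.0, 2),
        ])
        assert branch_morphometrics(arbor).n_junctions == 1

    def test_generator_round_trip(self):
        for spec in random_specs(30, base_seed=7):
            arbor, truth = gen_arbor(spec)
            res = branch_morphometrics(arbor)
            exp = truth.true_morphometrics
            assert res.n_main_branches == exp.n_main_branches, spec
            assert res.n_junctions == exp.n_junctions, spec
            assert res.longest_main_branch == pytest.approx(exp.longest_main_branch), spec
            assert res.total_process_length == pytest.approx(exp.total_process_length), spec


class TestZoneDensity:
    def test_hand_placed_points(self):
        spec = ZoneSpec(aggregate_center=(0.0, 0.0), aggregate_radius=250.0)
        pts = np.array([[350.0, 0.0], [0.0, 550.0], [950.0, 0.0]])  # d = 100, 300, 700
        res = zone_density(pts, spec)
        assert list(res.table["count"]) == [1, 1, 0]
        assert res.n_unassigned == 1

    def test_analytic_annulus_area_and_density(self):
        spec = ZoneSpec(aggregate_radius=250.0)
        res = zone_density(np.array([[350.0, 0.0]]), spec)
        area = float(res.table.loc[0, "area_mm2"])
        assert area == pytest.approx(np.pi * (450.0**2 - 300.0**2) / 1e6, abs=1e-12)
        assert float(res.table.loc[0, "density_per_mm2"]) == pytest.approx(1.0 / area)

    def test_no_points(self):
        res = zone_density(np.empty((0, 2)))
        assert np.all(res.table["count"] == 0)
        assert np.all(res.table["density_per_mm2"] == 0.0)
        assert np.all(res.table["area_mm2"] > 0)

    def test_point_inside_aggregate_warns_and_unassigned(self):
        with pytest.warns(UserWarning):
            res = zone_density(np.array([[10.0, 0.0]]), ZoneSpec(aggregate_radius=250.0))
        assert res.n_unassigned == 1

    def test_density_conservation(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(-1200, 1200, (200, 2))
        res = zone_density(pts, ZoneSpec(aggregate_radius=250.0))
        assert int(res.table["count"].sum()) + res.n_unassigned == 200


class TestSwcIO:
    def test_round_trip_preserves_structure(self, tmp_path):
        arbor, _ = gen_arbor(ArborSpec(seed=3))
        path = tmp_path / "cell.swc"
        write_swc(arbor, path)
        back = read_swc(path)
        assert np.array_equal(back.ids, arbor.ids)
        assert np.array_equal(back.parents, arbor.parents)
        assert np.allclose(back.xyz, arbor.xyz, atol=1e-6)

    def test_same_seed_byte_identical(self, tmp_path):
        a1, _ = gen_arbor(ArborSpec(seed=8))
        a2, _ = gen_arbor(ArborSpec(seed=8))
        p1, p2 = tmp_path / "a1.swc", tmp_path / "a2.swc"
        write_swc(a1, p1)
        write_swc(a2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            Arbor(ids=np.array([1, 2]), xyz=np.zeros((2, 3)),
                  parents=np.array([2, 1]))

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError):
            Arbor(ids=np.array([1, 2]), xyz=np.zeros((2, 3)),
                  parents=np.array([-1, -1]))
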