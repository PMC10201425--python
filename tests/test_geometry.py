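"""Geometric analysis: reaction coordinates, fitness, RMSD, fluctuations, H-bonds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ribomech as rm
from ribomech.geometry import B_FACTOR, InlineFitnessCriteria, kabsch
from ribomech.trajectory import AtomMap, Frame, MissingAtomError, Topology, Trajectory

AMAP = AtomMap.default_synthetic()


def make_frame(n3, h, n1g, o6, cm, n1a) -> Frame:
    top = Topology(
        atom_names=("N3", "H3", "N1", "N1", "O6", "CM"),
        residue_ids=np.array([10, 10, 63, 91, 91, 91]),
        residue_names=("C", "C", "A", "6MG", "6MG", "6MG"),
        elements=("N", "H", "N", "N", "O", "C"),
    )
    return Frame(top, np.array([n3, h, n1a, n1g, o6, cm], dtype=float))


class TestReactionCoordinates:
    def test_equidistant_proton_gives_zero_xi_pt(self):
        f = make_frame(
            n3=[0, 1.2, 0], h=[0, 0, 0], n1g=[0, -1.2, 0],
            o6=[3, 0, 0], cm=[4, 0, 0], n1a=[6, 0, 0],
        )
        rc = rm.reaction_coordinates(f, AMAP)
        assert rc.xi_pt == pytest.approx(0.0, abs=1e-12)

    def test_reactant_state_construction(self):
        # d(N3-H)=1.0, d(N1-H)=2.0, d(O6-Cm)=1.45, d(N1a-Cm)=2.95 -> (-1.0, -1.5)
        f = make_frame(
            n3=[0, 1.0, 0], h=[0, 0, 0], n1g=[0, -2.0, 0],
            o6=[0, 0, 5.0], cm=[1.45, 0, 5.0], n1a=[1.45 + 2.95, 0, 5.0],
        )
        rc = rm.reaction_coordinates(f, AMAP)
        assert rc.xi_pt == pytest.approx(-1.0, abs=1e-12)
        assert rc.xi_mt == pytest.approx(-1.5, abs=1e-12)

    def test_matches_pairwise_distance_oracle_on_random_frames(self):
        rng = np.random.default_rng(0)
        top = make_frame([0] * 3, [0] * 3, [0] * 3, [0] * 3, [0] * 3, [0] * 3).topology
        coords = rng.normal(scale=3.0, size=(1000, 6, 3))
        traj = Trajectory(top, coords)
        xis = rm.trajectory_reaction_coordinates(traj, AMAP)
        idx = AMAP.resolve(top)

        def dist(frame, a, b):
            return math.dist(tuple(frame[idx[a]]), tuple(frame[idx[b]]))

        for i in range(0, 1000, 37):
            f = coords[i]
            pt = dist(f, "C10:N3", "H(N3)") - dist(f, "O6mG:N1", "H(N3)")
            mt = dist(f, "O6mG:O6", "Cm") - dist(f, "A63:N1", "Cm")
            assert xis[i, 0] == pytest.approx(pt, abs=1e-12)
            assert xis[i, 1] == pytest.approx(mt, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_xi_pt_bounded_by_n3_n1_distance(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(scale=4.0, size=(6, 3))
        f = make_frame(c[0], c[1], c[2], c[3], c[4], c[5])
        rc = rm.reaction_coordinates(f, AMAP)
        idx = AMAP.resolve(f.topology)
        bound = np.linalg.norm(f.coords[idx["C10:N3"]] - f.coords[idx["O6mG:N1"]])
        assert abs(rc.xi_pt) <= bound + 1e-9

    def test_missing_atom_names_role(self):
        f = make_frame([0] * 3, [0] * 3, [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1])
        bad = AtomMap(
            {**AMAP.mapping, "Cm": (91, "CX")}
        )
        with pytest.raises(MissingAtomError, match="Cm"):
            rm.reaction_coordinates(f, bad)


class TestInlineFitness:
    @staticmethod
    def traj_with(dist, angle):
        return rm.gen_active_site_traj(
            5, {"kind": "point", "value": dist}, {"kind": "point", "value": angle}, seed=0
        )

    def test_inside_box_scores_positive(self):
        res = rm.inline_fitness(self.traj_with(3.0, 160.0), AMAP)
        assert res.fraction == 1.0
        assert np.all(res.scores > 0)

    def test_outside_distance_bound_scores_zero(self):
        res = rm.inline_fitness(self.traj_with(3.6, 160.0), AMAP)
        assert res.fraction == 0.0
        assert np.all(res.scores == 0)

    def test_graded_score_is_product_of_ramps(self):
        res = rm.inline_fitness(self.traj_with(3.0, 160.0), AMAP)
        expected = ((3.5 - 3.0) / 0.75) * ((160.0 - 140.0) / 40.0)
        assert res.scores[0] == pytest.approx(expected, abs=1e-9)

    def test_widening_box_never_decreases_fraction(self):
        traj = rm.gen_active_site_traj(
            2000,
            {"kind": "uniform", "low": 2.0, "high": 5.0},
            {"kind": "uniform", "low": 100.0, "high": 180.0},
            seed=4,
        )
        narrow = InlineFitnessCriteria(2.9, 3.3, 150.0, 175.0)
        wide = InlineFitnessCriteria(2.75, 3.6, 140.0, 180.0)
        f_narrow = rm.inline_fitness(traj, AMAP, narrow).fraction
        f_wide = rm.inline_fitness(traj, AMAP, wide).fraction
        assert 0.0 <= f_narrow <= f_wide <= 1.0

    def test_empty_trajectory_rejected(self):
        traj = self.traj_with(3.0, 160.0)
        empty = Trajectory(traj.topology, traj.coords[:0])
        with pytest.raises(ValueError):
            rm.inline_fitness(empty, AMAP)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            InlineFitnessCriteria(dist_min=3.6, dist_max=3.5)


class TestRmsd:
    def test_identical_frames_zero(self):
        traj = rm.gen_active_site_traj(
            1, {"kind": "point", "value": 3.0}, {"kind": "point", "value": 160.0}, seed=0
        )
        f = traj.frame(0)
        assert rm.heavy_atom_rmsd(f, f, superpose=False) == 0.0
        assert rm.heavy_atom_rmsd(f, f, superpose=True) < 1e-12

    def test_rigid_motion_invariance_with_superposition(self):
        rng = np.random.default_rng(1)
        top = rm.gen_toy_structure(4, 3, 0.0, 2, seed=0)[1].topology
        a = Frame(top, rng.normal(size=(top.n_atoms, 3)) * 3)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.4, -1.1, 2.0]).as_matrix()
        b = Frame(top, a.coords @ rot.T + np.array([5.0, -3.0, 2.5]))
        assert rm.heavy_atom_rmsd(a, b, superpose=True) < 1e-9

    def test_uniform_shift_without_superposition(self):
        top = rm.gen_toy_structure(4, 3, 0.0, 2, seed=0)[1].topology
        rng = np.random.default_rng(2)
        a = Frame(top, rng.normal(size=(top.n_atoms, 3)))
        b = Frame(top, a.coords + np.array([1.0, 0.0, 0.0]))
        assert rm.heavy_atom_rmsd(a, b, superpose=False) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_selection_rejected(self):
        top = rm.gen_toy_structure(4, 3, 0.0, 2, seed=0)[1].topology
        rng = np.random.default_rng(3)
        a = Frame(top, rng.normal(size=(top.n_atoms, 3)))
        with pytest.raises(ValueError):
            kabsch(a.coords[:5], a.coords[:7])


class TestFluctuations:
    def test_static_trajectory_zero_sigma(self):
        traj, ref = rm.gen_toy_structure(3, 2, 0.0, 4, seed=0)
        prof = rm.atomic_fluctuations(traj)
        np.testing.assert_allclose(prof.sigma, 0.0, atol=1e-9)

    def test_single_frame_rejected(self):
        traj, _ = rm.gen_toy_structure(3, 2, 0.5, 2, seed=0)
        single = Trajectory(traj.topology, traj.coords[:1])
        with pytest.raises(ValueError):
            rm.atomic_fluctuations(single)

    def test_b_value_constant(self):
        assert rm.sigma_to_bvalue(1.0) == pytest.approx(26.319, abs=5e-4)
        assert B_FACTOR == pytest.approx(8 * math.pi**2 / 3, rel=0)

    def test_b_sigma_roundtrip_exact(self):
        sig = np.array([0.1, 0.5, 1.3, 2.2])
        np.testing.assert_allclose(
            rm.bvalue_to_sigma(rm.sigma_to_bvalue(sig)), sig, atol=1e-12
        )

    def test_correlation_against_reference_bvalues(self):
        traj, ref = rm.gen_toy_structure(
            6, 3, [0.1, 0.2, 0.35, 0.5, 0.7, 0.9], n_models=600, seed=5
        )
        prof = rm.atomic_fluctuations(
            traj, reference=ref, reference_bvalues=traj.bfactors, presuperpose=False
        )
        assert prof.correlation is not None and prof.correlation > 0.95


class TestHbondOccupancy:
    @staticmethod
    def traj_with_geometry(d_da, angle_deg, n_frames=1):
        # donor at origin, H on x-axis, acceptor placed at the requested
        # donor-acceptor distance and donor-H-acceptor angle
        top = Topology(
            atom_names=("OD", "HD", "OA"),
            residue_ids=np.array([1, 1, 2]),
            residue_names=("U", "U", "U"),
            elements=("O", "H", "O"),
        )
        h = np.array([1.0, 0.0, 0.0])
        # place acceptor by rotating about H
        theta = np.radians(180.0 - angle_deg)  # angle at H between D and A
        # solve |A| = d_da with A = H + r*(cos t, sin t, 0), r from law of cosines
        # |A|^2 = 1 + r^2 - 2 r cos(pi - theta_DHA)... easier: direct construction
        # vector H->D is (-1,0,0); want angle between H->D and H->A = angle_deg
        ang = np.radians(angle_deg)
        direction = np.array([-np.cos(ang), np.sin(ang), 0.0])
        # choose r so that |H + r*direction| == d_da
        bq = 2 * h @ direction
        cq = 1 - d_da**2
        r = (-bq + np.sqrt(bq**2 - 4 * cq)) / 2
        a = h + r * direction
        coords = np.tile(np.array([[0, 0, 0], h, a]), (n_frames, 1, 1))
        return Trajectory(top, coords)

    def test_good_geometry_counts_as_bonded(self):
        traj = self.traj_with_geometry(2.8, 170.0)
        frac = rm.hbond_occupancy(traj, [((1, "OD"), (1, "HD"), (2, "OA"))])
        assert frac[0] == 1.0

    def test_long_distance_not_bonded(self):
        traj = self.traj_with_geometry(4.0, 170.0)
        frac = rm.hbond_occupancy(traj, [((1, "OD"), (1, "HD"), (2, "OA"))])
        assert frac[0] == 0.0

    def test_bent_angle_not_bonded(self):
        traj = self.traj_with_geometry(2.8, 100.0)
        frac = rm.hbond_occupancy(traj, [((1, "OD"), (1, "HD"), (2, "OA"))])
        assert frac[0] == 0.0

    def test_known_mixture_fraction(self):
        bonded = self.traj_with_geometry(2.8, 170.0, n_frames=6)
        broken = self.traj_with_geometry(4.2, 170.0, n_frames=4)
        traj = Trajectory(
            bonded.topology, np.concatenate([bonded.coords, broken.coords])
        )
        frac = rm.hbond_occupancy(traj, [((1, "OD"), (1, "HD"), (2, "OA"))])
        assert frac[0] == pytest.approx(0.6, abs=1e-12)

    def test_missing_hydrogen_rejected(self):
        traj = self.traj_with_geometry(2.8, 170.0)
        with pytest.raises(ValueError, match="hydrogen"):
            rm.hbond_occupancy(traj, [((1, "OD"), (1, "HX"), (2, "OA"))])
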