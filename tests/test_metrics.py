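"""Superposition, chi1 dihedrals, rotamer states, flips, distances, BW labels."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from gpcrmem import (
    DihedralSeries,
    HelixDrift,
    build_system,
    bw_number,
    chi1_series,
    classify_rotamer,
    detect_flips,
    generate_trajectory,
    kabsch_fit,
    receptor_like_config,
    residue_distance_series,
    tm_rmsd_series,
)
from gpcrmem.metrics import RotamerWindows, dihedral
from gpcrmem.model import Box, Frame, StructureModel, Trajectory


def _random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_fit(pts, pts)
        assert res.rmsd < 1e-12
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_known_rotation_recovered(self, rng):
        pts = rng.normal(size=(12, 3))
        rot = _random_rotation(rng)
        moved = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        res = kabsch_fit(pts, moved)
        assert res.rmsd < 1e-10
        np.testing.assert_allclose(res.rotation, rot, atol=1e-8)
        assert abs(np.linalg.det(res.rotation) - 1.0) < 1e-8

    def test_matches_quaternion_oracle(self, rng):
        """SVD Kabsch agrees with scipy's quaternion-based align_vectors."""
        for _ in range(50):
            a = rng.normal(size=(12, 3))
            b = rng.normal(size=(12, 3))
            res = kabsch_fit(a, b)
            rot, rssd = Rotation.align_vectors(
                b - b.mean(axis=0), a - a.mean(axis=0)
            )
            oracle_rmsd = rssd / np.sqrt(len(a))
            assert abs(res.rmsd - oracle_rmsd) < 1e-10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_fit(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_fit(line, line + 0.1)

    @given(st.integers(0, 2**31 - 1))
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(8, 3))
        b = rng.normal(size=(8, 3))
        rot = _random_rotation(rng)
        shift = rng.normal(size=3)
        base = kabsch_fit(a, b).rmsd
        moved = kabsch_fit(a @ rot.T + shift, b @ rot.T + shift).rmsd
        assert abs(base - moved) < 1e-9


class TestTMRmsd:
    def test_noise_free_trajectory_is_zero(self, quiet_system):
        _model, traj, _ = quiet_system
        np.testing.assert_allclose(tm_rmsd_series(traj), 0.0, atol=1e-12)

    def test_noise_matches_analytic_expectation(self):
        """i.i.d. sigma noise gives mean post-fit RMSD ~ sigma*sqrt(3)."""
        sigma = 0.02
        cfg = receptor_like_config(
            seed=17, n_frames=50, lipids_per_leaflet=4, n_waters=0, noise_sigma=sigma
        )
        model = build_system(cfg)
        traj, _ = generate_trajectory(model, cfg)
        mean_rmsd = tm_rmsd_series(traj).mean()
        assert abs(mean_rmsd - sigma * np.sqrt(3)) / (sigma * np.sqrt(3)) < 0.02

    def test_drift_variant_exceeds_stable_wildtype(self):
        """Programmed helix drift raises TM RMSD above the stable system."""
        wt_cfg = receptor_like_config(
            seed=18, n_frames=30, lipids_per_leaflet=4, n_waters=0, noise_sigma=0.01
        )
        var_cfg = receptor_like_config(
            seed=18, n_frames=30, lipids_per_leaflet=4, n_waters=0, noise_sigma=0.01,
            helix_drift=HelixDrift(amplitude=0.2),
        )
        wt = tm_rmsd_series(generate_trajectory(build_system(wt_cfg), wt_cfg)[0])
        var = tm_rmsd_series(generate_trajectory(build_system(var_cfg), var_cfg)[0])
        threshold = 0.05
        assert wt.mean() < threshold < var[-10:].mean()

    def test_missing_backbone_atom_named(self, small_model):
        from gpcrmem import Selection

        # rebuild the model without one backbone atom of residue 270
        keep = np.ones(small_model.n_atoms, dtype=bool)
        victim = small_model.select(
            Selection(
                molecule_class="protein", residue_ids=frozenset({270}),
                atom_names=frozenset({"O"}),
            )
        )[0]
        keep[victim] = False
        pruned = StructureModel(
            small_model.serials[keep], small_model.names[keep],
            small_model.elements[keep], small_model.residue_names[keep],
            small_model.residue_ids[keep], small_model.chain_ids[keep],
            small_model.molecule_classes[keep], small_model.coords[keep],
            small_model.box, small_model.helix_table, small_model.bw_anchors,
        )
        traj = Trajectory(
            model=pruned,
            frames=[Frame(time=0.0, coords=pruned.coords, box=pruned.box)],
        )
        with pytest.raises(ValueError, match="270"):
            tm_rmsd_series(traj)


class TestDihedral:
    def test_cis_is_zero(self):
        p = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        assert abs(dihedral(*p)) < 1e-10

    def test_anti_is_180(self):
        p = np.array([[-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        assert abs(dihedral(*p)) == pytest.approx(180.0, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_rigid_motion_and_sign_flips_under_mirror(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(4, 3))
        ang = dihedral(*pts)
        rot = _random_rotation(rng)
        shift = rng.normal(size=3)
        moved = pts @ rot.T + shift
        assert dihedral(*moved) == pytest.approx(ang, abs=1e-8)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        if abs(abs(ang) - 180.0) > 1e-6 and abs(ang) > 1e-6:
            assert dihedral(*mirrored) == pytest.approx(-ang, abs=1e-8)


class TestRotamers:
    @pytest.mark.parametrize(
        "angle,state",
        [(-60.0, "gauche-"), (60.0, "gauche+"), (180.0, "trans"),
         (-150.0, "trans"), (120.0, "trans"), (-119.9, "gauche-"), (0.0, "gauche+")],
    )
    def test_canonical_assignments(self, angle, state):
        assert classify_rotamer(angle) == state

    @given(st.floats(-180, 180, exclude_min=True))
    def test_partition_is_total_and_exclusive(self, angle):
        states = {"gauche-", "gauche+", "trans"}
        assert classify_rotamer(angle) in states

    def test_boundary_is_config_overridable(self):
        assert classify_rotamer(110.0, RotamerWindows(boundary=100.0)) == "trans"


def _series(states):
    n = len(states)
    angle = {"gauche-": -60.0, "gauche+": 60.0, "trans": 180.0}
    return DihedralSeries(
        residue_id=1,
        times=np.arange(n, dtype=float),
        chi1=np.array([angle[s] for s in states]),
        states=list(states),
    )


class TestDetectFlips:
    def test_constant_series_has_no_events(self):
        assert detect_flips(_series(["gauche-"] * 40), min_dwell=5) == []

    def test_programmed_half_split_one_event(self):
        s = _series(["gauche-"] * 50 + ["trans"] * 50)
        events = detect_flips(s, min_dwell=5)
        assert len(events) == 1
        assert (events[0].start, events[0].end) == (49, 50)
        assert (events[0].from_state, events[0].to_state) == ("gauche-", "trans")

    def test_subdwell_spike_ignored(self):
        s = _series(["gauche-"] * 20 + ["trans"] + ["gauche-"] * 20)
        assert detect_flips(s, min_dwell=5) == []

    @given(st.lists(st.sampled_from(["gauche-", "gauche+", "trans"]), min_size=1, max_size=60))
    def test_event_count_monotone_in_min_dwell(self, states):
        s = _series(states)
        counts = [len(detect_flips(s, min_dwell=d)) for d in range(1, 8)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDistances:
    def test_ca_pair_distance(self):
        coords = np.array([[1.0, 1.0, 1.0], [1.5, 1.0, 1.0]])
        model = StructureModel(
            serials=[1, 2], names=["CA", "CA"], elements=["C", "C"],
            residue_names=["ALA", "GLY"], residue_ids=[1, 2],
            chain_ids=["A", "A"], molecule_classes=["protein", "protein"],
            coords=coords, box=Box([10, 10, 10]),
        )
        traj = Trajectory(model=model, frames=[Frame(0.0, coords, model.box)])
        np.testing.assert_allclose(
            residue_distance_series(traj, 1, 2, mode="CA"), [0.5]
        )

    def test_min_heavy_atom_matches_brute_force(self, small_traj):
        series = residue_distance_series(small_traj, 286, 316, mode="min-heavy-atom")
        model = small_traj.model
        ia = np.flatnonzero(model.residue_ids == 286)
        ib = np.flatnonzero(model.residue_ids == 316)
        from gpcrmem import min_image_distance

        for f, fr in enumerate(small_traj.frames):
            brute = min(
                min_image_distance(fr.coords[i], fr.coords[j], fr.box)
                for i in ia for j in ib
            )
            assert series[f] == pytest.approx(brute, abs=1e-12)

    def test_periodic_wrap_uses_nearest_image(self):
        coords = np.array([[0.2, 1.0, 1.0], [9.9, 1.0, 1.0]])
        model = StructureModel(
            serials=[1, 2], names=["CA", "CA"], elements=["C", "C"],
            residue_names=["ALA", "GLY"], residue_ids=[1, 2],
            chain_ids=["A", "A"], molecule_classes=["protein", "protein"],
            coords=coords, box=Box([10, 10, 10]),
        )
        traj = Trajectory(model=model, frames=[Frame(0.0, coords, model.box)])
        np.testing.assert_allclose(
            residue_distance_series(traj, 1, 2, mode="CA"), [0.3], atol=1e-12
        )


class TestBWNumbering:
    def test_landmark_residues(self, small_model):
        assert bw_number(small_model, 286) == "6.48"
        assert bw_number(small_model, 290) == "6.52"
        assert bw_number(small_model, 326) == "7.53"

    def test_anchor_is_x50(self, small_model):
        assert bw_number(small_model, 288) == "6.50"
        assert bw_number(small_model, 323) == "7.50"

    def test_outside_helices_raises(self, small_model):
        with pytest.raises(KeyError):
            bw_number(small_model, 1000)
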