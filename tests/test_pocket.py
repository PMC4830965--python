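"""Pocket definition, grid-void volume oracles, and hydration counts."""

import numpy as np
import pytest
from scipy.spatial import Delaunay
from scipy.spatial.transform import Rotation

from gpcrmem import (
    PocketDefinition,
    build_system,
    define_pocket_residues,
    generate_trajectory,
    hydration_count_series,
    min_image_distance,
    pocket_volume_series,
    receptor_like_config,
)
from gpcrmem.model import Box, Frame, StructureModel, Trajectory


def _model_from_atoms(coords, residue_ids, classes, names=None, elements=None,
                      box=(8.0, 8.0, 8.0)):
    n = len(coords)
    return StructureModel(
        serials=range(1, n + 1),
        names=names if names is not None else ["C1"] * n,
        elements=elements if elements is not None else ["C"] * n,
        residue_names=["UNK" if c == "ligand" else "ALA" for c in classes],
        residue_ids=residue_ids,
        chain_ids=["A"] * n,
        molecule_classes=classes,
        coords=np.asarray(coords, dtype=float),
        box=Box(box),
    )


def _one_frame(model):
    return Trajectory(
        model=model, frames=[Frame(0.0, model.coords.copy(), model.box)]
    )


def _fibonacci_sphere(n, radius, center):
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    pts = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return center + radius * pts


def _shell_system(n_atoms=400, radius=1.0, box=6.0):
    center = np.full(3, box / 2)
    coords = _fibonacci_sphere(n_atoms, radius, center)
    model = _model_from_atoms(
        coords, residue_ids=[1] * n_atoms, classes=["protein"] * n_atoms,
        box=(box, box, box),
    )
    pocket = PocketDefinition(residue_ids=frozenset({1}), source="explicit list")
    return model, pocket, center


def oracle_pocket_volume(pocket_xyz, occl_xyz, radii, seed_point, voxel, probe):
    """Brute-force re-computation of the grid-void volume (no KD-trees)."""
    pad = probe + radii.max()
    lo = pocket_xyz.min(axis=0) - pad
    hi = pocket_xyz.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    axes = [lo[d] + (np.arange(shape[d]) + 0.5) * voxel for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    # all-pairs occlusion, chunked
    occluded = np.zeros(len(centers), dtype=bool)
    thresh = radii + probe
    for start in range(0, len(centers), 20000):
        block = centers[start:start + 20000]
        d = np.linalg.norm(block[:, None, :] - occl_xyz[None, :, :], axis=2)
        occluded[start:start + 20000] = np.any(d <= thresh[None, :], axis=1)
    inside = Delaunay(pocket_xyz).find_simplex(centers) >= 0
    free = (~occluded & inside).reshape(tuple(shape))
    # hand-rolled 6-connected flood fill from the seed cell
    seed_cell = tuple(np.floor((seed_point - lo) / voxel).astype(int))
    if not free[seed_cell]:
        free_cells = np.argwhere(free)
        d = np.linalg.norm((lo + (free_cells + 0.5) * voxel) - seed_point, axis=1)
        if len(free_cells) == 0 or d.min() > 0.3:
            return 0.0
        seed_cell = tuple(free_cells[np.argmin(d)])
    visited = np.zeros_like(free)
    stack = [seed_cell]
    visited[seed_cell] = True
    while stack:
        x, y, z = stack.pop()
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nb = (x + dx, y + dy, z + dz)
            if all(0 <= nb[i] < shape[i] for i in range(3)) and free[nb] and not visited[nb]:
                visited[nb] = True
                stack.append(nb)
    return float(visited.sum()) * voxel**3


class TestDefinePocket:
    def test_near_and_far_residues_split_matches_brute_force(self, rng):
        # ligand at centre, 5 residues just inside 0.7 nm, 10 well outside
        center = np.full(3, 4.0)
        near = center + rng.normal(size=(5, 3)) * 0.05 + np.array([0.6, 0, 0])
        far = center + _fibonacci_sphere(10, 2.5, np.zeros(3))
        coords = np.vstack([center, near, far])
        classes = ["ligand"] + ["protein"] * 15
        rids = [100] + list(range(1, 16))
        model = _model_from_atoms(coords, rids, classes)
        pocket = define_pocket_residues(model, 100, cutoff=0.7)
        brute = {
            rid for rid, xyz in zip(rids[1:], coords[1:])
            if min_image_distance(xyz, center, model.box) <= 0.7
        }
        assert pocket.residue_ids == frozenset(brute)
        assert pocket.residue_ids == frozenset(range(1, 6))

    def test_zero_cutoff_warns_and_is_empty(self):
        model = _model_from_atoms(
            [[4, 4, 4], [4.5, 4, 4]], [100, 1], ["ligand", "protein"]
        )
        with pytest.warns(UserWarning):
            pocket = define_pocket_residues(model, 100, cutoff=0.0)
        assert pocket.residue_ids == frozenset()

    def test_missing_ligand_rejected(self):
        model = _model_from_atoms([[4, 4, 4]], [1], ["protein"])
        with pytest.raises(ValueError, match="ligand"):
            define_pocket_residues(model, 999)


class TestPocketVolume:
    def test_hollow_shell_matches_analytic_and_oracle(self):
        model, pocket, center = _shell_system()
        traj = _one_frame(model)
        series = pocket_volume_series(
            traj, pocket, voxel=0.05, probe=0.14, vdw_table={"C": 0.15}
        )
        free_r = 1.0 - 0.15 - 0.14
        analytic = 4.0 / 3.0 * np.pi * free_r**3
        assert series.volumes[0] == pytest.approx(analytic, rel=0.05)
        radii = np.full(model.n_atoms, 0.15)
        oracle = oracle_pocket_volume(
            model.coords, model.coords, radii, center, 0.05, 0.14
        )
        assert series.volumes[0] == pytest.approx(oracle, abs=1e-12)

    def test_packed_cluster_has_zero_volume(self, rng):
        coords = np.full(3, 4.0) + rng.normal(size=(60, 3)) * 0.05
        model = _model_from_atoms(coords, [1] * 60, ["protein"] * 60)
        pocket = PocketDefinition(residue_ids=frozenset({1}), source="explicit list")
        with pytest.warns(UserWarning):
            series = pocket_volume_series(_one_frame(model), pocket, voxel=0.05)
        assert series.volumes[0] == 0.0

    def test_volume_monotone_in_probe_radius(self):
        model, pocket, _ = _shell_system()
        traj = _one_frame(model)
        vols = [
            pocket_volume_series(
                traj, pocket, voxel=0.05, probe=p, vdw_table={"C": 0.15}
            ).volumes[0]
            for p in (0.10, 0.14, 0.18)
        ]
        assert vols[0] >= vols[1] >= vols[2]

    def test_voxel_refinement_converges(self):
        model, pocket, _ = _shell_system()
        traj = _one_frame(model)
        v_coarse = pocket_volume_series(
            traj, pocket, voxel=0.05, probe=0.14, vdw_table={"C": 0.15}
        ).volumes[0]
        v_fine = pocket_volume_series(
            traj, pocket, voxel=0.025, probe=0.14, vdw_table={"C": 0.15}
        ).volumes[0]
        surface = 4 * np.pi * (1.0 - 0.15 - 0.14) ** 2
        assert abs(v_coarse - v_fine) < 2 * 0.05 * surface

    def test_invariant_under_rigid_transform_of_frame(self, rng):
        model, pocket, _ = _shell_system(n_atoms=200)
        base = pocket_volume_series(
            _one_frame(model), pocket, voxel=0.05, probe=0.14, vdw_table={"C": 0.15}
        ).volumes[0]
        rot = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        pivot = model.coords.mean(axis=0)
        moved = (model.coords - pivot) @ rot.T + pivot + np.array([0.3, -0.2, 0.1])
        traj = Trajectory(model=model, frames=[Frame(0.0, moved, model.box)])
        rotated = pocket_volume_series(
            traj, pocket, voxel=0.05, probe=0.14, vdw_table={"C": 0.15}
        ).volumes[0]
        assert rotated == pytest.approx(base, abs=1e-12)

    def test_enlarged_pocket_wall_gives_larger_volume(self):
        """An outward-displaced pocket wall increases the measured volume."""
        kw = dict(n_frames=3, lipids_per_leaflet=4, n_waters=0, noise_sigma=0.0,
                  include_ligand=True)
        wt_cfg = receptor_like_config(seed=51, **kw)
        var_cfg = receptor_like_config(seed=51, helix_radial_offset={3: 0.3}, **kw)
        wt_model = build_system(wt_cfg)
        ligand_rid = int(wt_model.residue_ids[wt_model.molecule_classes == "ligand"][0])
        pocket = define_pocket_residues(wt_model, ligand_rid, cutoff=0.7)
        wt = pocket_volume_series(
            generate_trajectory(wt_model, wt_cfg)[0], pocket
        ).volumes.mean()
        var_model = build_system(var_cfg)
        var = pocket_volume_series(
            generate_trajectory(var_model, var_cfg)[0], pocket
        ).volumes.mean()
        assert var > wt


class TestHydration:
    def test_cutoff_arithmetic(self):
        ca = np.array([4.0, 4.0, 4.0])
        dists = [0.3, 0.5, 0.79, 0.81, 1.2]
        waters = [ca + np.array([d, 0, 0]) for d in dists]
        coords = np.vstack([ca] + waters)
        model = _model_from_atoms(
            coords,
            residue_ids=[1] + list(range(10, 15)),
            classes=["protein"] + ["water"] * 5,
            names=["CA"] + ["OW"] * 5,
            elements=["C"] + ["O"] * 5,
        )
        counts = hydration_count_series(_one_frame(model), 1, cutoff=0.8)
        assert counts.tolist() == [3]

    def test_no_waters_gives_zero(self):
        model = _model_from_atoms([[4, 4, 4]], [1], ["protein"], names=["CA"])
        assert hydration_count_series(_one_frame(model), 1).tolist() == [0]

    def test_matches_27_image_brute_force(self, small_traj):
        model = small_traj.model
        counts = hydration_count_series(small_traj, 329, cutoff=0.8)
        ca = model.atom_index(329, "CA")
        wat = np.flatnonzero(
            (model.molecule_classes == "water") & (model.elements == "O")
        )
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        )
        for f, fr in enumerate(small_traj.frames):
            brute = 0
            for w in wat:
                images = fr.coords[w] + shifts * fr.box.lengths
                if np.min(np.linalg.norm(images - fr.coords[ca], axis=1)) <= 0.8:
                    brute += 1
            assert counts[f] == brute

    def test_missing_ca_rejected(self):
        model = _model_from_atoms([[4, 4, 4]], [1], ["protein"], names=["CB"])
        with pytest.raises(KeyError, match="CA"):
            hydration_count_series(_one_frame(model), 1)
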