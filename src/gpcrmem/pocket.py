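"""Binding-pocket definition, grid-based pocket volume, and hydration.

The binding pocket is defined the way docking studies define it: every
protein residue with a heavy atom within a cutoff (default 0.7 nm) of a
reference ligand.  Pocket volume is then the non-occluded space enclosed
by those residues, estimated per frame by voxel counting:

1. superpose the frame onto the reference on pocket-residue heavy atoms,
2. lay a voxel grid over the pocket's bounding box (padded by probe +
   the largest van der Waals radius),
3. occlude voxels whose centre lies within vdW(atom) + probe of any
   protein/lipid heavy atom,
4. keep free voxels inside the convex hull of the pocket-residue heavy
   atoms, and
5. keep the 6-connected component containing the pocket-centroid seed.

Volume = voxel count x voxel^3.  Hydration is the per-frame count of
water molecules whose oxygen lies within a cutoff (default 0.8 nm) of a
residue's C-alpha, under the minimum-image convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree

from .metrics import kabsch_fit
from .model import StructureModel, Trajectory
from .pbc import min_image_distance

__all__ = [
    "BONDI_RADII",
    "PocketDefinition",
    "define_pocket_residues",
    "PocketVolumeSeries",
    "pocket_volume_series",
    "hydration_count_series",
]

#: Bondi van der Waals radii, nm; ``default`` is used for unknown elements.
BONDI_RADII: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "P": 0.180,
    "S": 0.180,
    "CL": 0.175,
    "BR": 0.185,
    "I": 0.198,
    "default": 0.170,
}


@dataclass(frozen=True)
class PocketDefinition:
    """The set of protein residues lining the binding pocket."""

    residue_ids: frozenset[int]
    source: str  # "reference-ligand cutoff" or "explicit list"
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.source == "explicit list" and not self.residue_ids:
            raise ValueError("explicit pocket definition must not be empty")


def define_pocket_residues(
    model: StructureModel, ligand_residue_id: int, cutoff: float = 0.7
) -> PocketDefinition:
    """Protein residues with any heavy atom within ``cutoff`` of the ligand.

    Distances are minimum-image over ligand heavy atoms.  A zero cutoff
    yields an empty definition with a warning (useful only as a probe).
    """
    lig_idx = np.flatnonzero(
        (model.residue_ids == ligand_residue_id) & (model.elements != "H")
    )
    if len(lig_idx) == 0:
        raise ValueError(f"no heavy atoms for ligand residue {ligand_residue_id}")
    prot_idx = np.flatnonzero(
        (model.molecule_classes == "protein") & (model.elements != "H")
    )
    d = min_image_distance(
        model.coords[prot_idx][:, None, :], model.coords[lig_idx][None, :, :], model.box
    ).min(axis=1)
    near = model.residue_ids[prot_idx[d <= cutoff]]
    residues = frozenset(int(r) for r in near)
    if not residues:
        warnings.warn(f"no residues within {cutoff} nm of ligand {ligand_residue_id}")
    return PocketDefinition(residue_ids=residues, source="reference-ligand cutoff", cutoff=cutoff)


@dataclass
class PocketVolumeSeries:
    """Per-frame pocket volume, nm^3."""

    times: np.ndarray
    volumes: np.ndarray
    voxel: float
    probe: float

    def __post_init__(self) -> None:
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")


def _vdw_radii(
    elements: np.ndarray, table: Mapping[str, float] | None
) -> np.ndarray:
    radii_table = dict(BONDI_RADII)
    if table:
        radii_table.update({k.upper(): v for k, v in table.items()})
    default = radii_table.get("default", 0.170)
    return np.array([radii_table.get(el.upper(), default) for el in elements])


_SIX_CONNECTED = ndimage.generate_binary_structure(3, 1)


def _pocket_indices(model: StructureModel, pocket: PocketDefinition) -> np.ndarray:
    idx = np.flatnonzero(
        (model.molecule_classes == "protein")
        & (model.elements != "H")
        & np.isin(model.residue_ids, sorted(pocket.residue_ids))
    )
    if len(idx) == 0:
        raise ValueError("pocket residues have no heavy atoms in the model")
    return idx


def pocket_volume_grid(
    pocket_xyz: np.ndarray,
    occl_xyz: np.ndarray,
    occl_radii: np.ndarray,
    seed_point: np.ndarray,
    voxel: float,
    probe: float,
) -> float:
    """Single-configuration grid-void pocket volume (nm^3).

    Exposed separately so oracles can call it on bare coordinates.
    """
    pad = probe + (occl_radii.max() if len(occl_radii) else 0.0)
    lo = pocket_xyz.min(axis=0) - pad
    hi = pocket_xyz.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int), 1)
    centers_axes = [lo[d] + (np.arange(shape[d]) + 0.5) * voxel for d in range(3)]
    gx, gy, gz = np.meshgrid(*centers_axes, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    occluded = np.zeros(centers.shape[0], dtype=bool)
    tree = cKDTree(centers)
    for radius in np.unique(occl_radii):
        atoms = occl_xyz[occl_radii == radius]
        hits = tree.query_ball_point(atoms, r=radius + probe)
        for h in hits:
            occluded[h] = True

    inside = Delaunay(pocket_xyz).find_simplex(centers) >= 0
    free_inside = (~occluded & inside).reshape(tuple(shape))
    labels, n_labels = ndimage.label(free_inside, structure=_SIX_CONNECTED)
    if n_labels == 0:
        warnings.warn("pocket grid has no free voxels; volume 0")
        return 0.0

    seed_cell = np.floor((seed_point - lo) / voxel).astype(int)
    in_grid = np.all((seed_cell >= 0) & (seed_cell < shape))
    if in_grid and labels[tuple(seed_cell)] > 0:
        seed_label = labels[tuple(seed_cell)]
    else:
        free_cells = np.argwhere(labels > 0)
        free_centers = lo + (free_cells + 0.5) * voxel
        dist = np.linalg.norm(free_centers - seed_point, axis=1)
        nearest = int(np.argmin(dist))
        if dist[nearest] > 0.3:
            warnings.warn("pocket seed occluded with no free voxel within 0.3 nm; volume 0")
            return 0.0
        seed_label = labels[tuple(free_cells[nearest])]
    return float(np.count_nonzero(labels == seed_label)) * voxel**3


def pocket_volume_series(
    traj: Trajectory,
    pocket: PocketDefinition,
    voxel: float = 0.08,
    probe: float = 0.14,
    vdw_table: Mapping[str, float] | None = None,
    occlusion_classes: Sequence[str] = ("protein", "lipid"),
) -> PocketVolumeSeries:
    """Pocket volume along a trajectory by per-frame grid-void counting.

    Every frame is first superposed onto the reference model on the
    pocket-residue heavy atoms, so the reported volume is invariant under
    rigid motion of the whole frame.  Occlusion considers heavy atoms of
    the ``occlusion_classes`` (waters and the reference ligand are
    excluded by default: the pocket is the space *available* to ligand
    and solvent).  The seed for the connected-void component is the
    centroid of the pocket residues' C-alpha atoms (falling back to their
    heavy-atom centroid).
    """
    if voxel <= 0 or probe < 0:
        raise ValueError("voxel must be positive and probe non-negative")
    model = traj.model
    pocket_idx = _pocket_indices(model, pocket)
    occl_idx = np.flatnonzero(
        np.isin(model.molecule_classes, list(occlusion_classes)) & (model.elements != "H")
    )
    radii = _vdw_radii(model.elements[occl_idx], vdw_table)

    ca_idx = np.flatnonzero(
        np.isin(model.residue_ids, sorted(pocket.residue_ids)) & (model.names == "CA")
    )
    seed_source = ca_idx if len(ca_idx) else pocket_idx
    ref_pocket = model.coords[pocket_idx]

    volumes = np.empty(len(traj.frames))
    for f, frame in enumerate(traj.frames):
        fit = kabsch_fit(frame.coords[pocket_idx], ref_pocket)
        pocket_xyz = fit.apply(frame.coords[pocket_idx])
        occl_xyz = fit.apply(frame.coords[occl_idx])
        seed = fit.apply(frame.coords[seed_source]).mean(axis=0)
        volumes[f] = pocket_volume_grid(pocket_xyz, occl_xyz, radii, seed, voxel, probe)
    return PocketVolumeSeries(times=traj.times, volumes=volumes, voxel=voxel, probe=probe)


def hydration_count_series(
    traj: Trajectory, residue_id: int, cutoff: float = 0.8
) -> np.ndarray:
    """Waters whose oxygen lies within ``cutoff`` nm of a residue's C-alpha.

    Judged by the water oxygen atom, per frame, minimum image; returns an
    integer count per frame.
    """
    model = traj.model
    ca = model.atom_index(residue_id, "CA")
    water_o = np.flatnonzero(
        (model.molecule_classes == "water") & (model.elements == "O")
    )
    counts = np.zeros(len(traj.frames), dtype=int)
    if len(water_o) == 0:
        return counts
    for f, frame in enumerate(traj.frames):
        d = min_image_distance(frame.coords[ca], frame.coords[water_o], frame.box)
        counts[f] = int(np.count_nonzero(d <= cutoff))
    return counts
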