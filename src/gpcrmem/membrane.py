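"""Bilayer readouts: leaflet assignment, thickness maps, headgroup profiles.

Bilayer thickness is measured the way membrane-MD studies usually report
it: as the distance between the phosphate planes of the two leaflets.
The map estimator grids the membrane plane, takes per-cell leaflet mean
phosphate heights per frame, differences them, and averages over frames;
cells that lack phosphates in either leaflet in a frame contribute no
sample for that frame and stay NaN if never sampled.  Hydrophobic
mismatch around an embedded receptor shows up as local thickening or
thinning in this map.

The headgroup profile tracks individual lipids near a chosen residue and
reports each lipid's time-averaged phosphate position and its mean
signed displacement from its leaflet's plane (negative = pulled toward
the membrane core), the signature of a side chain grabbing a lipid
headgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import Frame, Selection, StructureModel, Trajectory
from .pbc import min_image_distance, wrap_into_box

__all__ = [
    "LeafletAssignment",
    "assign_leaflets",
    "ThicknessMap",
    "thickness_map",
    "thickness_difference",
    "average_thickness_maps",
    "HeadgroupProfile",
    "headgroup_profile",
]

_PHOSPHATE = Selection(molecule_class="lipid", atom_names=frozenset({"P"}))


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels for one frame."""

    lipid_residue_ids: np.ndarray
    labels: np.ndarray  # "upper" / "lower"
    midplane_z: float  # nm

    def label_of(self, residue_id: int) -> str:
        hit = np.flatnonzero(self.lipid_residue_ids == residue_id)
        if len(hit) == 0:
            raise KeyError(f"lipid residue {residue_id} not in assignment")
        return str(self.labels[hit[0]])


def assign_leaflets(
    frame: Frame, model: StructureModel, phosphates: Selection = _PHOSPHATE
) -> LeafletAssignment:
    """Split phosphate-bearing lipids into leaflets about the midplane.

    The midplane is the mean phosphate z of the frame; a lipid is upper
    iff its phosphate lies above the midplane (ties go to upper).  A
    frame with every lipid on one side is legal but suspicious, so it is
    only warned about.
    """
    idx = model.select(phosphates)
    if len(idx) < 2:
        raise ValueError("leaflet assignment needs at least 2 phosphates")
    z = frame.coords[idx, 2]
    midplane = float(np.mean(z))
    labels = np.where(z >= midplane, "upper", "lower")
    if len(set(labels.tolist())) == 1:
        warnings.warn("all lipids assigned to one leaflet; check the frame")
    return LeafletAssignment(
        lipid_residue_ids=model.residue_ids[idx].copy(),
        labels=labels,
        midplane_z=midplane,
    )


@dataclass
class ThicknessMap:
    """Time-averaged leaflet-to-leaflet distance on an xy grid.

    ``values`` holds mean thickness in nm (NaN where no frame produced a
    sample); ``counts`` holds the number of contributing frames per cell.
    """

    origin: np.ndarray  # (2,) nm
    spacing: float  # nm
    values: np.ndarray  # (nx, ny) nm, NaN = undefined
    counts: np.ndarray  # (nx, ny) int

    @property
    def defined(self) -> np.ndarray:
        return self.counts > 0

    def mean_thickness(self) -> float:
        """Mean over defined cells (count-weighted per-frame samples)."""
        if not np.any(self.defined):
            return float("nan")
        return float(np.nanmean(self.values[self.defined]))

    def compatible_with(self, other: "ThicknessMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.spacing, other.spacing)
        )


def _cell_means(
    xy: np.ndarray, z: np.ndarray, nx: int, ny: int, spacing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean of z for points binned on the grid."""
    ix = np.minimum((xy[:, 0] / spacing).astype(int), nx - 1)
    iy = np.minimum((xy[:, 1] / spacing).astype(int), ny - 1)
    flat = ix * ny + iy
    sums = np.bincount(flat, weights=z, minlength=nx * ny)
    counts = np.bincount(flat, minlength=nx * ny)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means.reshape(nx, ny), counts.reshape(nx, ny)


def thickness_map(
    traj: Trajectory,
    grid_spacing: float = 0.2,
    phosphates: Selection = _PHOSPHATE,
) -> ThicknessMap:
    """Frame-averaged phosphate-to-phosphate thickness on an xy grid.

    Per frame, phosphates are wrapped into the primary box, each leaflet's
    mean z is taken per cell, and the cell thickness is the upper minus
    the lower mean; the returned map is the average over frames of the
    per-frame cell values.  Grid origin is the box origin (0, 0).
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    model = traj.model
    idx = model.select(phosphates)
    if len(idx) < 2:
        raise ValueError("thickness map needs at least 2 phosphates")
    lengths = traj.frames[0].box.lengths
    nx = max(1, int(np.ceil(lengths[0] / grid_spacing)))
    ny = max(1, int(np.ceil(lengths[1] / grid_spacing)))
    acc = np.zeros((nx, ny))
    counts = np.zeros((nx, ny), dtype=int)
    for frame in traj.frames:
        assignment = assign_leaflets(frame, model, phosphates)
        coords = wrap_into_box(frame.coords[idx], frame.box)
        upper = assignment.labels == "upper"
        if not np.any(upper) or np.all(upper):
            continue  # no leaflet pair to difference this frame
        up_mean, up_n = _cell_means(coords[upper, :2], coords[upper, 2], nx, ny, grid_spacing)
        lo_mean, lo_n = _cell_means(coords[~upper, :2], coords[~upper, 2], nx, ny, grid_spacing)
        both = (up_n > 0) & (lo_n > 0)
        acc[both] += up_mean[both] - lo_mean[both]
        counts[both] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, acc / np.maximum(counts, 1), np.nan)
    return ThicknessMap(origin=np.zeros(2), spacing=grid_spacing, values=values, counts=counts)


def thickness_difference(map_a: ThicknessMap, map_b: ThicknessMap) -> ThicknessMap:
    """Cell-wise ``a - b`` where both maps are defined; NaN elsewhere."""
    if not map_a.compatible_with(map_b):
        raise ValueError("thickness maps are on different grids")
    both = map_a.defined & map_b.defined
    values = np.full_like(map_a.values, np.nan)
    values[both] = map_a.values[both] - map_b.values[both]
    counts = np.where(both, np.minimum(map_a.counts, map_b.counts), 0)
    return ThicknessMap(
        origin=map_a.origin.copy(), spacing=map_a.spacing, values=values, counts=counts
    )


def average_thickness_maps(maps: list[ThicknessMap]) -> ThicknessMap:
    """Sample-weighted average of maps on identical grids.

    Useful to combine per-replicate maps into one system map; each cell
    is weighted by its per-map frame count.
    """
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if not first.compatible_with(m):
            raise ValueError("thickness maps are on different grids")
    counts = np.sum([m.counts for m in maps], axis=0)
    weighted = np.zeros_like(first.values)
    for m in maps:
        weighted += np.where(m.defined, m.values * m.counts, 0.0)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, weighted / np.maximum(counts, 1), np.nan)
    return ThicknessMap(
        origin=first.origin.copy(), spacing=first.spacing, values=values, counts=counts
    )


@dataclass
class HeadgroupProfile:
    """Per-lipid phosphate statistics near a target residue.

    ``dz`` is the mean signed z-displacement of each tracked lipid's
    phosphate from its leaflet's mean plane, with negative values meaning
    displacement toward the membrane core (for either leaflet).
    """

    target_residue_id: int
    cutoff: float  # nm
    lipid_residue_ids: np.ndarray
    mean_position: np.ndarray  # (n_lipids, 3) nm
    dz: np.ndarray  # (n_lipids,) nm, core-signed
    n_frames: int


def headgroup_profile(
    traj: Trajectory,
    target_residue_id: int,
    cutoff: float = 0.6,
    phosphates: Selection = _PHOSPHATE,
) -> HeadgroupProfile:
    """Track lipid headgroups that approach a residue and their z-pull.

    A lipid is tracked if its phosphate comes within ``cutoff`` nm
    (minimum image) of any heavy atom of the target residue in at least
    one frame.  For each tracked lipid the time-averaged phosphate
    position and the mean core-signed displacement from its per-frame
    leaflet plane are reported (the pulled lipid is excluded from its own
    leaflet-plane estimate so a large pull does not bias the plane).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    model = traj.model
    target_idx = np.flatnonzero(
        (model.residue_ids == target_residue_id) & (model.elements != "H")
    )
    if len(target_idx) == 0:
        raise ValueError(f"target residue {target_residue_id} not found")
    p_idx = model.select(phosphates)
    if len(p_idx) < 2:
        raise ValueError("headgroup profile needs at least 2 phosphates")
    n_frames = len(traj.frames)
    n_lipids = len(p_idx)
    ever_near = np.zeros(n_lipids, dtype=bool)
    pos_sum = np.zeros((n_lipids, 3))
    dz_sum = np.zeros(n_lipids)
    for frame in traj.frames:
        p_xyz = frame.coords[p_idx]
        d = min_image_distance(
            p_xyz[:, None, :], frame.coords[target_idx][None, :, :], frame.box
        ).min(axis=1)
        ever_near |= d <= cutoff
        z = p_xyz[:, 2]
        midplane = float(np.mean(z))
        upper = z >= midplane
        for mask, sign in ((upper, 1.0), (~upper, -1.0)):
            members = np.flatnonzero(mask)
            if len(members) == 0:
                continue
            z_m = z[members]
            if len(members) > 1:
                # leave-one-out leaflet plane per lipid
                plane = (z_m.sum() - z_m) / (len(members) - 1)
            else:
                plane = z_m
            dz_sum[members] += sign * (z_m - plane)
        pos_sum += p_xyz
    tracked = np.flatnonzero(ever_near)
    return HeadgroupProfile(
        target_residue_id=target_residue_id,
        cutoff=cutoff,
        lipid_residue_ids=model.residue_ids[p_idx[tracked]].copy(),
        mean_position=pos_sum[tracked] / n_frames,
        dz=dz_sum[tracked] / n_frames,
        n_frames=n_frames,
    )
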