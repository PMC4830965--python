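"""Synthetic membrane-receptor systems with known ground truth.

Real inputs to this kind of analysis are hundreds of nanoseconds of
all-atom MD of a 7TM receptor in a hydrated phospholipid bilayer.  This
module builds a deterministic, seedable stand-in with the same observable
structure: seven ideal alpha-helices in a two-leaflet lattice of
phosphate-bearing pseudo-lipids plus a water slab, and a trajectory in
which every signal a downstream analysis should detect is *programmed* —
a chi1 rotamer schedule on one probe side chain, a z-pull on one lipid
headgroup, a smooth bilayer-thickness modulation, and linear backbone
drift.  The programmed values are returned as :class:`GroundTruth` so
tests can close the loop between generator and analysis.

Geometry defaults follow textbook ideal-helix parameters (rise 0.15
nm/residue, 100 deg/residue twist, C-alpha radius 0.23 nm).  Lipids are
3-bead pseudo-molecules (choline, phosphate ``P``, tail); only the
phosphate position matters to any analysis here.  The noise model is
isotropic i.i.d. Gaussian displacement per atom per frame, the simplest
model under which analytic RMSD expectations exist.

A single RNG stream is consumed in a documented order: system build draws
water positions; trajectory generation draws (1) per-helix drift
directions when drift is configured, then (2) one noise block for all
frames and atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import Box, Frame, StructureModel, Selection, Trajectory
from .pbc import min_image_distance

__all__ = [
    "LipidPull",
    "ThicknessField",
    "HelixDrift",
    "GeneratorConfig",
    "GroundTruth",
    "build_system",
    "generate_trajectory",
    "receptor_like_config",
    "expected_atom_count",
]


@dataclass(frozen=True)
class LipidPull:
    """Pull one lipid headgroup along z after an onset frame.

    ``dz`` is signed (negative = toward the membrane core for the upper
    leaflet).  If ``lipid_index`` is None the lipid whose phosphate is
    closest (minimum image) to any atom of the target residue is pulled.
    """

    target_residue_id: int
    dz: float = -0.5
    onset_frame: int = 0
    lipid_index: int | None = None


@dataclass(frozen=True)
class ThicknessField:
    """Smooth radial (Gaussian) modulation of bilayer thickness.

    The local bilayer thickness becomes ``base + amplitude *
    exp(-|xy - center|^2 / (2 width^2))``; positive amplitude thickens,
    negative thins.  Both leaflets move symmetrically by half the field.
    """

    amplitude: float
    center_xy: tuple[float, float]
    width: float

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        d2 = np.sum((xy - np.asarray(self.center_xy)) ** 2, axis=-1)
        return self.amplitude * np.exp(-d2 / (2.0 * self.width**2))


@dataclass(frozen=True)
class HelixDrift:
    """Linear-in-time rigid xy drift of helices (backbone instability).

    Each affected helix moves along its own random xy direction, reaching
    ``amplitude`` nm at the final frame.
    """

    amplitude: float
    helices: tuple[int, ...] | None = None  # None = all helices


@dataclass
class GeneratorConfig:
    """Full recipe for one synthetic membrane-receptor system.

    The defaults emulate the study conditions of a single receptor
    trajectory: a 7-helix bundle spanning a bilayer with leaflet
    phosphate planes at +-1.9 nm (a 3.8 nm phosphate-to-phosphate
    thickness, typical of a POPC membrane), 128 lipids per leaflet, and
    100 frames at 2 ns/frame (a 200 ns span).
    """

    seed: int
    n_frames: int = 100
    dt: float = 2.0
    helix_count: int = 7
    residues_per_helix: int = 30
    ring_radius: float = 0.85
    helix_rise: float = 0.15
    helix_twist: float = 100.0
    helix_radius: float = 0.23
    helix_start_ids: tuple[int, ...] | None = None
    helix_radial_offset: dict[int, float] = field(default_factory=dict)
    probe_residue_id: int | None = None
    lipids_per_leaflet: int = 128
    leaflet_z: float = 1.9
    lattice_spacing: float = 0.8
    n_waters: int = 400
    water_slabs: tuple[tuple[float, float], ...] = ((2.4, 3.2), (-3.2, -2.4))
    noise_sigma: float = 0.02
    chi1_initial: float = -60.0
    chi1_schedule: tuple[tuple[tuple[int, int], float], ...] | None = None
    lipid_pull: LipidPull | None = None
    thickness_field: ThicknessField | None = None
    helix_drift: HelixDrift | None = None
    include_ligand: bool = False
    ligand_z: float = 1.2
    bw_anchor_ids: dict[int, int] | None = None
    #: seed of the water-placement stream; defaults to ``seed``.  Sharing
    #: one water_seed across systems emulates variants built into the same
    #: solvated membrane patch, keeping hydration counts comparable.
    water_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.leaflet_z <= 0:
            raise ValueError("upper leaflet plane must lie above the lower one")
        if self.helix_start_ids is not None and len(self.helix_start_ids) != self.helix_count:
            raise ValueError("helix_start_ids must list one start per helix")
        if self.chi1_schedule is not None:
            for (start, end), _angle in self.chi1_schedule:
                if not (0 <= start < end <= self.n_frames):
                    raise ValueError(
                        f"chi1 schedule range [{start}, {end}) outside [0, {self.n_frames})"
                    )
        if self.lipid_pull is not None and not (
            0 <= self.lipid_pull.onset_frame < self.n_frames
        ):
            raise ValueError("lipid_pull onset frame outside trajectory")

    # -- derived layout -------------------------------------------------

    @property
    def helix_starts(self) -> tuple[int, ...]:
        if self.helix_start_ids is not None:
            return self.helix_start_ids
        return tuple(1 + h * self.residues_per_helix for h in range(self.helix_count))

    @property
    def helix_table(self) -> dict[int, tuple[int, int]]:
        return {
            h + 1: (start, start + self.residues_per_helix - 1)
            for h, start in enumerate(self.helix_starts)
        }

    @property
    def bw_anchors(self) -> dict[int, int]:
        if self.bw_anchor_ids is not None:
            return dict(self.bw_anchor_ids)
        # default anchor: mid-helix residue labelled h.50
        return {
            h + 1: start + self.residues_per_helix // 2
            for h, start in enumerate(self.helix_starts)
        }

    @property
    def probe_residue(self) -> int:
        if self.probe_residue_id is not None:
            return self.probe_residue_id
        helix = 6 if self.helix_count >= 6 else 1
        start = self.helix_starts[helix - 1]
        return start + (self.residues_per_helix - 1) // 2

    @property
    def lattice_side(self) -> int:
        return int(np.ceil(np.sqrt(self.lipids_per_leaflet)))

    @property
    def box_lengths(self) -> np.ndarray:
        lxy = self.lattice_side * self.lattice_spacing
        zmax = max(abs(z) for slab in self.water_slabs for z in slab)
        zmax = max(zmax, self.leaflet_z + 0.4,
                   (self.residues_per_helix - 1) * self.helix_rise / 2 + 0.4)
        return np.array([lxy, lxy, 2.0 * (zmax + 0.6)])


def expected_atom_count(config: GeneratorConfig) -> int:
    """Closed-form atom count implied by a config."""
    protein = config.helix_count * config.residues_per_helix * 4 + 2  # + CB, CG
    lipids = 2 * config.lipids_per_leaflet * 3
    ligand = 1 if config.include_ligand else 0
    return protein + lipids + config.n_waters + ligand


@dataclass
class GroundTruth:
    """Programmed signals of a generated trajectory."""

    chi1: np.ndarray  # per-frame true probe chi1, degrees
    base_thickness: float  # nm, leaflet-to-leaflet
    thickness_fn: Callable[[np.ndarray], np.ndarray]  # xy -> true thickness nm
    pulled_lipid_residue_id: int | None
    pulled_dz: float
    pull_onset: int
    drift_rms: np.ndarray  # per-frame backbone displacement rms, nm


# -- geometry helpers ---------------------------------------------------


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom D so that |CD|=bond, angle(B,C,D)=angle and the signed
    torsion A-B-C-D equals ``torsion`` (degrees, IUPAC convention)."""
    ang = np.radians(angle)
    tor = np.radians(-torsion)  # mirror of the local frame's handedness
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _helix_backbone(
    config: GeneratorConfig, helix_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ideal-helix backbone atom positions (N, CA, C, O) for one helix."""
    rph = config.residues_per_helix
    phi = 2.0 * np.pi * (helix_index - 1) / config.helix_count
    radial = config.ring_radius + config.helix_radial_offset.get(helix_index, 0.0)
    axis_xy = radial * np.array([np.cos(phi), np.sin(phi)])
    z0 = -(rph - 1) * config.helix_rise / 2.0
    t = np.arange(rph)
    z = z0 + t * config.helix_rise

    def on_curve(phase_deg: float, dz: float, radius: float) -> np.ndarray:
        theta = np.radians(t * config.helix_twist + phase_deg)
        out = np.empty((rph, 3))
        out[:, 0] = axis_xy[0] + radius * np.cos(theta)
        out[:, 1] = axis_xy[1] + radius * np.sin(theta)
        out[:, 2] = z + dz
        return out

    ca = on_curve(0.0, 0.0, config.helix_radius)
    n = on_curve(-26.0, -0.055, config.helix_radius * 0.96)
    c = on_curve(27.0, 0.055, config.helix_radius * 0.96)
    o = on_curve(29.0, 0.10, config.helix_radius * 1.20)
    return n, ca, c, o


def _first_chi1(config: GeneratorConfig) -> float:
    if config.chi1_schedule:
        return config.chi1_schedule[0][1]
    return config.chi1_initial


def build_system(config: GeneratorConfig) -> StructureModel:
    """Build the reference structure implied by a generator config.

    Helices carry backbone N, CA, C, O per residue; the probe residue
    additionally carries CB and CG placed so that its chi1 equals the
    first scheduled angle.  Lipids are choline/phosphate/tail 3-bead
    pseudo-molecules on two leaflet lattices; waters are single ``OW``
    atoms placed uniformly in the configured z slabs.
    """
    lengths = config.box_lengths
    side = config.lattice_side
    if side * side < config.lipids_per_leaflet:
        raise ValueError("lipid lattice too small for requested lipid count")

    serials: list[int] = []
    names: list[str] = []
    elements: list[str] = []
    res_names: list[str] = []
    res_ids: list[int] = []
    chain_ids: list[str] = []
    classes: list[str] = []
    coords: list[np.ndarray] = []

    def add(name, element, res_name, res_id, chain, cls, xyz):
        serials.append(len(serials) + 1)
        names.append(name)
        elements.append(element)
        res_names.append(res_name)
        res_ids.append(res_id)
        chain_ids.append(chain)
        classes.append(cls)
        coords.append(np.asarray(xyz, dtype=float))

    # protein helices
    probe = config.probe_residue
    for h in range(1, config.helix_count + 1):
        n_xyz, ca_xyz, c_xyz, o_xyz = _helix_backbone(config, h)
        start = config.helix_starts[h - 1]
        for i in range(config.residues_per_helix):
            rid = start + i
            res_name = "TRP" if rid == probe else "ALA"
            add("N", "N", res_name, rid, "A", "protein", n_xyz[i])
            add("CA", "C", res_name, rid, "A", "protein", ca_xyz[i])
            add("C", "C", res_name, rid, "A", "protein", c_xyz[i])
            add("O", "O", res_name, rid, "A", "protein", o_xyz[i])
            if rid == probe:
                cb = _place_atom(c_xyz[i], n_xyz[i], ca_xyz[i], 0.153, 110.0, -122.0)
                cg = _place_atom(n_xyz[i], ca_xyz[i], cb, 0.150, 114.0, _first_chi1(config))
                add("CB", "C", res_name, rid, "A", "protein", cb)
                add("CG", "C", res_name, rid, "A", "protein", cg)

    # lipids on two leaflet lattices (upper first, row-major site order)
    next_res = max(res_ids) + 1 if res_ids else 1
    offset = (side - 1) * config.lattice_spacing / 2.0
    site = 0
    for leaflet_sign in (+1, -1):
        placed = 0
        for i in range(side):
            for j in range(side):
                if placed >= config.lipids_per_leaflet:
                    break
                x = i * config.lattice_spacing - offset
                y = j * config.lattice_spacing - offset
                zp = leaflet_sign * config.leaflet_z
                add("NC3", "N", "POP", next_res, "L", "lipid", (x, y, zp + leaflet_sign * 0.10))
                add("P", "P", "POP", next_res, "L", "lipid", (x, y, zp))
                add("C2", "C", "POP", next_res, "L", "lipid", (x, y, zp - leaflet_sign * 0.80))
                next_res += 1
                placed += 1
                site += 1

    # waters, drawn from the build stream of the seeded RNG
    rng = np.random.default_rng(
        [config.seed if config.water_seed is None else config.water_seed, 0]
    )
    n_slabs = len(config.water_slabs)
    per_slab = [config.n_waters // n_slabs] * n_slabs
    per_slab[0] += config.n_waters - sum(per_slab)
    lxy = lengths[0]
    for (z_lo, z_hi), count in zip(config.water_slabs, per_slab):
        xy = rng.uniform(-lxy / 2 + 0.1, lxy / 2 - 0.1, size=(count, 2))
        z = rng.uniform(z_lo, z_hi, size=count)
        for k in range(count):
            add("OW", "O", "SOL", next_res, "W", "water", (xy[k, 0], xy[k, 1], z[k]))
            next_res += 1

    if config.include_ligand:
        add("C1", "C", "LIG", next_res, "X", "ligand", (0.0, 0.0, config.ligand_z))

    xyz = np.array(coords) + lengths / 2.0  # centre the system in the box
    return StructureModel(
        serials, names, elements, res_names, res_ids, chain_ids, classes, xyz,
        Box(lengths), helix_table=config.helix_table, bw_anchors=config.bw_anchors,
    )


def _chi1_targets(config: GeneratorConfig) -> np.ndarray:
    chi1 = np.full(config.n_frames, _first_chi1(config))
    if config.chi1_schedule:
        for (start, end), angle in config.chi1_schedule:
            chi1[start:end] = angle
    return chi1


def _pulled_lipid(model: StructureModel, config: GeneratorConfig) -> int:
    """Residue id of the lipid to pull (nearest phosphate to the target)."""
    pull = config.lipid_pull
    assert pull is not None
    p_idx = model.select(Selection(molecule_class="lipid", atom_names=frozenset({"P"})))
    if pull.lipid_index is not None:
        return int(model.residue_ids[p_idx[pull.lipid_index]])
    target_idx = np.flatnonzero(
        (model.residue_ids == pull.target_residue_id) & (model.molecule_classes == "protein")
    )
    if len(target_idx) == 0:
        raise ValueError(f"pull target residue {pull.target_residue_id} not found")
    d = min_image_distance(
        model.coords[p_idx][:, None, :], model.coords[target_idx][None, :, :], model.box
    )
    return int(model.residue_ids[p_idx[int(np.argmin(d.min(axis=1)))]])


def generate_trajectory(
    model: StructureModel, config: GeneratorConfig
) -> tuple[Trajectory, GroundTruth]:
    """Emit a trajectory over ``model`` realising every programmed signal.

    Per frame, in order: helix drift (linear ramp), probe-chi1 retarget
    (CG re-placed about the CA-CB axis), lipid-headgroup pull after its
    onset, leaflet displacement by the thickness field, then i.i.d.
    Gaussian noise on every atom.  Identical (seed, config) pairs give
    bit-identical output.
    """
    rng = np.random.default_rng([config.seed, 1])
    n_frames, n_atoms = config.n_frames, model.n_atoms
    ref = model.coords
    center_xy = model.box.lengths[:2] / 2.0

    # -- documented RNG order: drift directions first, then the noise block
    drift_dirs: dict[int, np.ndarray] = {}
    if config.helix_drift is not None:
        helices = config.helix_drift.helices or tuple(range(1, config.helix_count + 1))
        for h in helices:
            v = rng.normal(size=2)
            drift_dirs[h] = v / np.linalg.norm(v)
    noise = (
        rng.normal(scale=config.noise_sigma, size=(n_frames, n_atoms, 3))
        if config.noise_sigma > 0
        else np.zeros((n_frames, n_atoms, 3))
    )

    helix_atom_idx = {
        h: model.select(Selection(molecule_class="protein", residue_range=rng_))
        for h, rng_ in model.helix_table.items()
    }
    protein_idx = model.select(Selection(molecule_class="protein"))

    probe = config.probe_residue
    i_n = model.atom_index(probe, "N")
    i_ca = model.atom_index(probe, "CA")
    i_cb = model.atom_index(probe, "CB")
    i_cg = model.atom_index(probe, "CG")
    chi1_true = _chi1_targets(config)

    pulled_rid: int | None = None
    pull_idx = np.array([], dtype=int)
    if config.lipid_pull is not None:
        pulled_rid = _pulled_lipid(model, config)
        pull_idx = np.flatnonzero(
            (model.residue_ids == pulled_rid)
            & np.isin(model.names, ["NC3", "P"])  # headgroup beads only
        )

    lipid_idx = model.select(Selection(molecule_class="lipid"))
    midplane_z = model.box.lengths[2] / 2.0
    lipid_upper = ref[lipid_idx, 2] > midplane_z
    th_field = config.thickness_field
    if th_field is not None:
        # field evaluated at each lipid's reference phosphate xy
        lipid_rids = model.residue_ids[lipid_idx]
        p_sel = model.select(Selection(molecule_class="lipid", atom_names=frozenset({"P"})))
        p_by_rid = {int(model.residue_ids[i]): ref[i, :2] - center_xy for i in p_sel}
        per_atom_field = np.array([th_field(p_by_rid[int(r)]) for r in lipid_rids])

    drift_rms = np.zeros(n_frames)
    frames: list[Frame] = []
    for f in range(n_frames):
        coords = ref.copy()
        ramp = f / (n_frames - 1) if n_frames > 1 else 0.0
        if drift_dirs:
            for h, direction in drift_dirs.items():
                disp = config.helix_drift.amplitude * ramp * direction
                coords[helix_atom_idx[h], 0] += disp[0]
                coords[helix_atom_idx[h], 1] += disp[1]
            moved = sum(len(helix_atom_idx[h]) for h in drift_dirs)
            drift_rms[f] = config.helix_drift.amplitude * ramp * np.sqrt(
                moved / len(protein_idx)
            )
        if chi1_true[f] != chi1_true[0]:
            # the reference CG already realises the initial angle (and any
            # rigid drift preserves it), so only retargeted frames re-place it
            coords[i_cg] = _place_atom(
                coords[i_n], coords[i_ca], coords[i_cb], 0.150, 114.0, chi1_true[f]
            )
        if pulled_rid is not None and f >= config.lipid_pull.onset_frame:
            coords[pull_idx, 2] += config.lipid_pull.dz
        if th_field is not None:
            sign = np.where(lipid_upper, 0.5, -0.5)
            coords[lipid_idx, 2] += sign * per_atom_field
        coords += noise[f]
        frames.append(Frame(time=f * config.dt, coords=coords, box=model.box))

    base = 2.0 * config.leaflet_z
    if th_field is not None:
        truth_fn = lambda xy: base + th_field(xy)  # noqa: E731
    else:
        truth_fn = lambda xy: base + np.zeros(np.shape(np.atleast_2d(xy))[0])  # noqa: E731
    truth = GroundTruth(
        chi1=chi1_true,
        base_thickness=base,
        thickness_fn=truth_fn,
        pulled_lipid_residue_id=pulled_rid,
        pulled_dz=config.lipid_pull.dz if config.lipid_pull else 0.0,
        pull_onset=config.lipid_pull.onset_frame if config.lipid_pull else 0,
        drift_rms=drift_rms,
    )
    return Trajectory(model=model, frames=frames), truth


def receptor_like_config(seed: int, **overrides) -> GeneratorConfig:
    """Config whose residue numbering mimics the beta2-adrenergic receptor.

    Helix start ids place the familiar landmarks inside their helices
    (Trp286 and Phe290 on TM6, Tyr316/Gly320/Tyr326 on TM7) and the BW
    x.50 anchors at the conserved positions (6.50 = 288, 7.50 = 323).
    The chi1 probe defaults to residue 286.
    """
    defaults = dict(
        helix_start_ids=(29, 67, 103, 147, 197, 267, 301),
        probe_residue_id=286,
        bw_anchor_ids={1: 51, 2: 79, 3: 131, 4: 158, 5: 211, 6: 288, 7: 323},
    )
    defaults.update(overrides)
    return GeneratorConfig(seed=seed, **defaults)
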