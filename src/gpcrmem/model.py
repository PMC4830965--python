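"""Structural data model shared by all analysis stages.

Coordinates are stored in nanometres throughout; angles in degrees.  A
:class:`StructureModel` is the single structural ground truth for a system
(atoms, residues, molecule classes, periodic box, helix annotations), and a
:class:`Trajectory` is an ordered list of :class:`Frame` objects that all
refer back to one model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Box",
    "StructureModel",
    "Frame",
    "Trajectory",
    "Selection",
    "MOLECULE_CLASSES",
    "classify_residue_name",
    "PROTEIN_RESIDUES",
    "LIPID_RESIDUES",
    "WATER_RESIDUES",
]

MOLECULE_CLASSES = ("protein", "lipid", "water", "ligand")

#: Three-letter codes recognised as amino acids (standard 20 plus common
#: protonation-state variants used by MD force fields).
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL HSD HSE HSP HID HIE HIP CYX ASH GLH LYN""".split()
)

#: Phospholipid residue codes.  Only the phosphate position of a lipid is
#: ever used by the analyses, so coarse pseudo-lipids and all-atom lipids
#: are treated alike.
LIPID_RESIDUES = frozenset("POP PPC POC PCL DPP DMP DOP POE PSM".split())

WATER_RESIDUES = frozenset("HOH SOL WAT TIP TP3 SPC W".split())


def classify_residue_name(res_name: str, overrides: Mapping[str, str] | None = None) -> str:
    """Infer the molecule class of a residue from its 3-letter code.

    Lookup order: user overrides, protein table, lipid table, water table;
    anything unrecognised is a ligand.  ``overrides`` lets callers handle
    force-field residue-name dialects (e.g. mapping ``TIP3`` style names).
    """
    name = res_name.strip().upper()
    if overrides:
        normalized = {k.strip().upper(): v for k, v in overrides.items()}
        if name in normalized:
            cls = normalized[name]
            if cls not in MOLECULE_CLASSES:
                raise ValueError(f"unknown molecule class {cls!r} for residue {res_name!r}")
            return cls
    if name in PROTEIN_RESIDUES:
        return "protein"
    if name in LIPID_RESIDUES:
        return "lipid"
    if name in WATER_RESIDUES:
        return "water"
    return "ligand"


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure (coordinates in nm)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    molecule_class: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError("atom serial must be positive")
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(f"unknown molecule class {self.molecule_class!r}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic box, edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (3,) or not np.all(lengths > 0):
            raise ValueError("box lengths must be a positive 3-vector")
        object.__setattr__(self, "lengths", lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Box):
            return NotImplemented
        return bool(np.allclose(self.lengths, other.lengths))


class StructureModel:
    """Atoms, periodic box and helix annotations of one system.

    Atom attributes are stored as parallel numpy arrays for speed; the
    ``atoms`` property offers a per-atom record view.  ``helix_table`` maps
    helix index (1..7 for a GPCR) to an inclusive ``(first, last)``
    residue-id range, and ``bw_anchors`` maps helix index to the residue id
    carrying the Ballesteros-Weinstein x.50 label.
    """

    def __init__(
        self,
        serials: Sequence[int],
        names: Sequence[str],
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        chain_ids: Sequence[str],
        molecule_classes: Sequence[str],
        coords: np.ndarray,
        box: Box,
        helix_table: Mapping[int, tuple[int, int]] | None = None,
        bw_anchors: Mapping[int, int] | None = None,
    ) -> None:
        self.serials = np.asarray(serials, dtype=int)
        self.names = np.asarray(names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.residue_names = np.asarray(residue_names, dtype="U4")
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.chain_ids = np.asarray(chain_ids, dtype="U1")
        self.molecule_classes = np.asarray(molecule_classes, dtype="U7")
        self.coords = np.asarray(coords, dtype=float)
        self.box = box
        self.helix_table = dict(helix_table or {})
        self.bw_anchors = dict(bw_anchors or {})
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        n = len(self.serials)
        for arr, what in [
            (self.names, "names"),
            (self.elements, "elements"),
            (self.residue_names, "residue_names"),
            (self.residue_ids, "residue_ids"),
            (self.chain_ids, "chain_ids"),
            (self.molecule_classes, "molecule_classes"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{what} length {len(arr)} != atom count {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(np.unique(self.serials)) != n:
            dup = self.serials[np.argmax(np.bincount(self.serials))]
            raise ValueError(f"duplicate atom serial {dup}")
        unknown = set(np.unique(self.molecule_classes)) - set(MOLECULE_CLASSES)
        if unknown:
            raise ValueError(f"unknown molecule classes {sorted(unknown)}")
        # molecule_class must be consistent within each (chain, residue)
        keys = {}
        for cid, rid, cls in zip(self.chain_ids, self.residue_ids, self.molecule_classes):
            prev = keys.setdefault((cid, rid), cls)
            if prev != cls:
                raise ValueError(
                    f"residue {cid}/{rid} has inconsistent molecule classes {prev!r}/{cls!r}"
                )
        self._validate_helices()

    def _validate_helices(self) -> None:
        ranges = sorted(self.helix_table.values())
        for (a1, b1), (a2, b2) in zip(ranges, ranges[1:]):
            if a1 > b1 or a2 > b2:
                raise ValueError("helix range must be (first, last) with first <= last")
            if b1 >= a2:
                raise ValueError("helix residue ranges overlap")
        for helix, anchor in self.bw_anchors.items():
            if helix not in self.helix_table:
                raise ValueError(f"anchor given for unannotated helix {helix}")
            lo, hi = self.helix_table[helix]
            if not lo <= anchor <= hi:
                raise ValueError(f"anchor residue {anchor} outside helix {helix} range")

    # -- views ----------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.serials)

    @property
    def atoms(self) -> Iterator[AtomRecord]:
        for i in range(self.n_atoms):
            yield AtomRecord(
                serial=int(self.serials[i]),
                name=str(self.names[i]),
                element=str(self.elements[i]),
                residue_name=str(self.residue_names[i]),
                residue_id=int(self.residue_ids[i]),
                chain_id=str(self.chain_ids[i]),
                molecule_class=str(self.molecule_classes[i]),
                coords=self.coords[i],
            )

    def with_annotations(
        self,
        helix_table: Mapping[int, tuple[int, int]] | None = None,
        bw_anchors: Mapping[int, int] | None = None,
    ) -> "StructureModel":
        """Return a copy with helix table / BW anchors replaced."""
        return StructureModel(
            self.serials, self.names, self.elements, self.residue_names,
            self.residue_ids, self.chain_ids, self.molecule_classes,
            self.coords.copy(), self.box,
            helix_table if helix_table is not None else self.helix_table,
            bw_anchors if bw_anchors is not None else self.bw_anchors,
        )

    def select(self, expr: "Selection") -> np.ndarray:
        """Evaluate a selection; returns atom indices in model order."""
        return expr.evaluate(self)

    def atom_index(self, residue_id: int, name: str) -> int:
        """Index of the unique atom ``name`` in residue ``residue_id``."""
        hits = np.flatnonzero((self.residue_ids == residue_id) & (self.names == name))
        if len(hits) == 0:
            raise KeyError(f"no atom {name!r} in residue {residue_id}")
        if len(hits) > 1:
            raise KeyError(f"atom {name!r} in residue {residue_id} is not unique")
        return int(hits[0])

    def equals(self, other: "StructureModel", coord_tol: float = 1.5e-4) -> bool:
        """Field-wise equality with a coordinate tolerance (nm).

        The default tolerance covers the 10^-3 Angstrom rounding of PDB
        fixed-column output.
        """
        return (
            self.n_atoms == other.n_atoms
            and bool(np.array_equal(self.serials, other.serials))
            and bool(np.array_equal(self.names, other.names))
            and bool(np.array_equal(self.residue_names, other.residue_names))
            and bool(np.array_equal(self.residue_ids, other.residue_ids))
            and bool(np.array_equal(self.chain_ids, other.chain_ids))
            and bool(np.array_equal(self.molecule_classes, other.molecule_classes))
            and self.box == other.box
            and bool(np.allclose(self.coords, other.coords, atol=coord_tol))
        )


@dataclass
class Frame:
    """One trajectory frame: time in ns, coordinates in nm."""

    time: float
    coords: np.ndarray
    box: Box

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coords must be N x 3")


@dataclass
class Trajectory:
    """Ordered frames sharing one :class:`StructureModel`."""

    model: StructureModel
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a trajectory needs at least one frame")
        times = self.times
        if np.any(np.diff(times) < 0):
            raise ValueError("frame times must be non-decreasing")
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != self.model.n_atoms:
                raise ValueError(
                    f"frame {i} has {fr.coords.shape[0]} atoms, model has {self.model.n_atoms}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def coords(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass(frozen=True)
class Selection:
    """Deterministic, order-preserving atom selection predicate.

    All criteria are combined with logical AND; ``None`` means "no
    constraint".  ``residue_range`` is inclusive on both ends.
    """

    molecule_class: str | None = None
    residue_range: tuple[int, int] | None = None
    residue_ids: frozenset[int] | None = None
    residue_name: str | None = None
    atom_names: frozenset[str] | None = None
    chain_id: str | None = None

    def evaluate(self, model: StructureModel) -> np.ndarray:
        mask = np.ones(model.n_atoms, dtype=bool)
        if self.molecule_class is not None:
            mask &= model.molecule_classes == self.molecule_class
        if self.residue_range is not None:
            lo, hi = self.residue_range
            mask &= (model.residue_ids >= lo) & (model.residue_ids <= hi)
        if self.residue_ids is not None:
            mask &= np.isin(model.residue_ids, sorted(self.residue_ids))
        if self.residue_name is not None:
            mask &= model.residue_names == self.residue_name
        if self.atom_names is not None:
            mask &= np.isin(model.names, sorted(self.atom_names))
        if self.chain_id is not None:
            mask &= model.chain_ids == self.chain_id
        return np.flatnonzero(mask)


def select(model: StructureModel, expr: Selection) -> np.ndarray:
    """Functional form of :meth:`StructureModel.select`."""
    return expr.evaluate(model)
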