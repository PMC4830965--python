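"""PDB reading/writing for structures and multi-model trajectories.

Fixed-column PDB is the baseline interchange format: it keeps the package
testable with plain-text fixtures and zero binary-format dependencies.
Parsing and formatting are delegated to :mod:`biotite`; this module adds
unit conversion (PDB Angstrom <-> internal nm), molecule-class inference,
orthorhombic-box validation and the per-frame time convention.

Frame times are carried in header records of the form::

    REMARK 250 FRAME <index> TIME <ns>

written by :func:`write_trajectory` and recognised by
:func:`read_trajectory`; files without them get times equal to the frame
index.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .model import Box, Frame, StructureModel, Trajectory, classify_residue_name

__all__ = [
    "PDBParseError",
    "load_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
]

NM_PER_ANGSTROM = 0.1

_TIME_REMARK = re.compile(r"^REMARK 250 FRAME\s+(\d+)\s+TIME\s+([-+0-9.eE]+)")


class PDBParseError(ValueError):
    """A PDB record could not be parsed; the message names the line."""


def _prevalidate_lines(lines: list[str]) -> None:
    """Check coordinate fields of ATOM/HETATM records parse as floats."""
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"truncated ATOM/HETATM record at line {lineno}")
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"malformed coordinate field in ATOM/HETATM record at line {lineno}"
                ) from None


def _box_from_biotite(box_matrix: np.ndarray | None, coords_nm: np.ndarray) -> Box:
    """Convert a biotite box matrix (Angstrom) to an orthorhombic Box in nm.

    When the file carries no (or a null) CRYST1 record, fall back to a box
    bounding the coordinates with a 1 nm margin, with a warning.
    """
    if box_matrix is not None:
        m = np.asarray(box_matrix, dtype=float)
        diag = np.diag(m)
        if np.any(diag > 0):
            off = m - np.diag(diag)
            if not np.allclose(off, 0.0, atol=1e-4):
                raise ValueError("triclinic boxes are not supported (orthorhombic only)")
            return Box(diag * NM_PER_ANGSTROM)
    warnings.warn("no CRYST1 box in PDB file; using bounding box + 1 nm margin")
    span = coords_nm.max(axis=0) - coords_nm.min(axis=0)
    return Box(np.maximum(span, 0.0) + 2.0)


def _infer_elements(atom_names: np.ndarray, elements: np.ndarray) -> np.ndarray:
    out = elements.astype("U2").copy()
    for i, el in enumerate(out):
        if not el.strip():
            name = atom_names[i].strip().lstrip("0123456789")
            out[i] = name[:1].upper() if name else "X"
    return out


def load_structure(
    path: str | Path,
    format: str = "pdb",
    class_overrides: Mapping[str, str] | None = None,
    helix_table: Mapping[int, tuple[int, int]] | None = None,
    bw_anchors: Mapping[int, int] | None = None,
) -> StructureModel:
    """Read a reference structure (first model of a PDB file).

    Coordinates are converted from Angstrom to nm.  The molecule class of
    each residue is inferred from its residue name via the documented
    lookup (:func:`gpcrmem.model.classify_residue_name`); ``class_overrides``
    extends that lookup for force-field dialects.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    pdb = PDBFile.read(str(path))
    _prevalidate_lines(pdb.lines)
    arr = pdb.get_structure(model=1, extra_fields=["atom_id"])
    coords = arr.coord * NM_PER_ANGSTROM
    elements = _infer_elements(arr.atom_name, arr.element)
    classes = [classify_residue_name(rn, class_overrides) for rn in arr.res_name]
    box = _box_from_biotite(arr.box, coords)
    return StructureModel(
        serials=arr.atom_id,
        names=np.char.strip(arr.atom_name),
        elements=np.char.strip(elements),
        residue_names=np.char.strip(arr.res_name),
        residue_ids=arr.res_id,
        chain_ids=arr.chain_id,
        molecule_classes=classes,
        coords=coords,
        box=box,
        helix_table=helix_table,
        bw_anchors=bw_anchors,
    )


def _to_atom_array(model: StructureModel, coords_nm: np.ndarray) -> struc.AtomArray:
    arr = struc.AtomArray(model.n_atoms)
    arr.coord = np.asarray(coords_nm, dtype=np.float32) / NM_PER_ANGSTROM
    arr.atom_name = model.names
    arr.res_name = model.residue_names
    arr.res_id = model.residue_ids
    arr.chain_id = model.chain_ids
    arr.element = model.elements
    arr.hetero = model.molecule_classes != "protein"
    arr.add_annotation("atom_id", int)
    arr.atom_id = model.serials
    arr.box = np.diag(model.box.lengths / NM_PER_ANGSTROM)
    return arr


def write_structure(model: StructureModel, path: str | Path, format: str = "pdb") -> None:
    """Write a structure as fixed-column PDB (coordinates back to Angstrom).

    Serials above 99999 are encoded with the hybrid-36 dialect, the
    convention used by large-system PDB tooling.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model, model.coords), hybrid36=bool(model.n_atoms > 99999))
    pdb.write(str(path))


def _count_model_atoms(lines: list[str]) -> list[int]:
    """Atoms per MODEL block (one pseudo-block if the file has no MODEL)."""
    counts: list[int] = []
    current = 0
    in_model = False
    seen_model = False
    for line in lines:
        if line.startswith("MODEL"):
            in_model, seen_model, current = True, True, 0
        elif line.startswith("ENDMDL"):
            counts.append(current)
            in_model = False
        elif line.startswith(("ATOM", "HETATM")):
            if in_model or not seen_model:
                current += 1
    if not seen_model:
        counts = [current]
    return counts


def read_trajectory(topology: StructureModel, path: str | Path, format: str = "pdb") -> Trajectory:
    """Read a multi-model PDB file as a trajectory over ``topology``.

    Every MODEL block must contain exactly the topology's atom count; a
    mismatch raises an error naming the offending frame.  Times are taken
    from ``REMARK 250 FRAME ... TIME ...`` records when present, otherwise
    the frame index is used.
    """
    if format != "pdb":
        raise ValueError(f"unsupported trajectory format {format!r}")
    pdb = PDBFile.read(str(path))
    _prevalidate_lines(pdb.lines)
    counts = _count_model_atoms(pdb.lines)
    for i, c in enumerate(counts):
        if c != topology.n_atoms:
            raise ValueError(
                f"frame {i} has {c} atoms but the topology has {topology.n_atoms}"
            )
    times_by_frame: dict[int, float] = {}
    for line in pdb.lines:
        m = _TIME_REMARK.match(line)
        if m:
            times_by_frame[int(m.group(1))] = float(m.group(2))
    structure = pdb.get_structure()
    if isinstance(structure, struc.AtomArray):
        all_coords = structure.coord[np.newaxis]
        boxes = structure.box[np.newaxis] if structure.box is not None else None
    else:
        all_coords = structure.coord
        boxes = structure.box
    frames = []
    for i in range(all_coords.shape[0]):
        coords_nm = all_coords[i] * NM_PER_ANGSTROM
        box_matrix = boxes[i] if boxes is not None else None
        box = _box_from_biotite(box_matrix, coords_nm)
        frames.append(Frame(time=times_by_frame.get(i, float(i)), coords=coords_nm, box=box))
    return Trajectory(model=topology, frames=frames)


def write_trajectory(traj: Trajectory, path: str | Path, format: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB with per-frame time remarks."""
    if format != "pdb":
        raise ValueError(f"unsupported trajectory format {format!r}")
    model = traj.model
    arrays = [_to_atom_array(model, fr.coords) for fr in traj.frames]
    stack = struc.stack(arrays)
    stack.box = np.stack([np.diag(fr.box.lengths / NM_PER_ANGSTROM) for fr in traj.frames])
    pdb = PDBFile()
    pdb.set_structure(stack, hybrid36=bool(model.n_atoms > 99999))
    remarks = [
        f"REMARK 250 FRAME {i} TIME {fr.time:.6f}" for i, fr in enumerate(traj.frames)
    ]
    pdb.lines = remarks + pdb.lines
    pdb.write(str(path))
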