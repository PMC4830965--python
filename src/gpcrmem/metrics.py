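"""Receptor-internal geometry: superposition/RMSD, chi1 rotamers, distances.

The chi1 torsion of the conserved TM6 tryptophan (Trp6.48 in
Ballesteros-Weinstein numbering) is the classic "rotamer toggle switch"
of class A GPCR activation: gauche- in the inactive receptor, trans in
the active one.  This module measures that torsion along trajectories,
classifies rotamer states, and detects persistent state flips, alongside
TM-backbone RMSD against a reference structure and inter-residue
distances under the minimum-image convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import Frame, Selection, StructureModel, Trajectory
from .pbc import min_image_displacement

__all__ = [
    "SuperpositionResult",
    "kabsch_fit",
    "tm_rmsd_series",
    "dihedral_chi1",
    "chi1_series",
    "RotamerWindows",
    "classify_rotamer",
    "DihedralSeries",
    "FlipEvent",
    "detect_flips",
    "residue_distance_series",
    "bw_number",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of a mobile point set onto a reference."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, nm
    rmsd: float  # nm

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch algorithm, SVD form).

    Finds the proper rotation R and translation t minimising
    sum ||R m_i + t - r_i||^2; reflections are excluded by correcting the
    sign of the smallest singular vector.  Raises on fewer than three
    points or a degenerate (collinear) point set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be M x 3")
    m = mobile.shape[0]
    if m < 3:
        raise ValueError("superposition needs at least 3 points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    # collinear sets have two near-zero covariance singular values
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    diff = mob_c @ rot.T - ref_c
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _tm_backbone_indices(
    model: StructureModel,
    helix_table: Mapping[int, tuple[int, int]],
    atom_names: frozenset[str],
) -> np.ndarray:
    idx: list[np.ndarray] = []
    for h in sorted(helix_table):
        lo, hi = helix_table[h]
        sel = model.select(
            Selection(molecule_class="protein", residue_range=(lo, hi), atom_names=atom_names)
        )
        expected = (hi - lo + 1) * len(atom_names)
        if len(sel) != expected:
            have = set(zip(model.residue_ids[sel].tolist(), model.names[sel].tolist()))
            for rid in range(lo, hi + 1):
                for name in sorted(atom_names):
                    if (rid, name) not in have:
                        raise ValueError(
                            f"missing backbone atom {name} in residue {rid} (helix {h})"
                        )
        idx.append(sel)
    return np.concatenate(idx)


def tm_rmsd_series(
    traj: Trajectory,
    helix_table: Mapping[int, tuple[int, int]] | None = None,
    reference: StructureModel | None = None,
    atom_names: frozenset[str] = BACKBONE_ATOMS,
) -> np.ndarray:
    """Per-frame backbone RMSD of the TM helices after optimal fit.

    Each frame's TM backbone (N, CA, C, O by default; pass
    ``frozenset({"CA"})`` for a C-alpha-only fit) is superposed onto the
    reference structure and the post-fit RMSD on the same atoms is
    reported, in nm.  Defaults: helix table and reference taken from the
    trajectory's own model.
    """
    model = traj.model
    reference = reference or model
    helix_table = helix_table or model.helix_table
    if not helix_table:
        raise ValueError("no TM helix ranges available")
    idx_mob = _tm_backbone_indices(model, helix_table, atom_names)
    idx_ref = _tm_backbone_indices(reference, helix_table, atom_names)
    ref_xyz = reference.coords[idx_ref]
    return np.array(
        [kabsch_fit(fr.coords[idx_mob], ref_xyz).rmsd for fr in traj.frames]
    )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion of the planes (p0,p1,p2)/(p1,p2,p3), degrees (-180, 180]."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
    return 180.0 if ang <= -180.0 else float(ang)


def dihedral_chi1(frame: Frame, model: StructureModel, residue_id: int) -> float:
    """chi1 of a residue in one frame: torsion N-CA-CB-CG, degrees."""
    idx = []
    for name in ("N", "CA", "CB", "CG"):
        try:
            idx.append(model.atom_index(residue_id, name))
        except KeyError:
            raise ValueError(f"residue {residue_id} lacks atom {name} needed for chi1") from None
    p = frame.coords[idx]
    return dihedral(p[0], p[1], p[2], p[3])


@dataclass(frozen=True)
class RotamerWindows:
    """Rotamer-state partition of (-180, 180] for chi1.

    ``trans`` covers |chi1| >= boundary; gauche- is (-boundary, 0) and
    gauche+ is [0, boundary).  The default boundary of 120 deg centres
    each state on its canonical angle (180, -60, +60); an exact boundary
    value is assigned to trans (closed bound), a documented tie-break.
    """

    boundary: float = 120.0


def classify_rotamer(angle: float, windows: RotamerWindows = RotamerWindows()) -> str:
    """Map a chi1 angle (degrees) to 'gauche-', 'gauche+' or 'trans'."""
    if not (-180.0 < angle <= 180.0 + 1e-9):
        raise ValueError(f"angle {angle} outside (-180, 180]")
    b = windows.boundary
    if abs(angle) >= b:
        return "trans"
    return "gauche-" if angle < 0 else "gauche+"


@dataclass(frozen=True)
class FlipEvent:
    """One persistent rotamer-state change.

    ``start`` is the last frame index at which the previous accepted
    state was observed, ``end`` the first frame of the new persistent
    state.
    """

    start: int
    end: int
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("flip start must precede end")
        if self.from_state == self.to_state:
            raise ValueError("flip must change state")


@dataclass
class DihedralSeries:
    """Per-frame chi1 of one residue with rotamer labels and flip events."""

    residue_id: int
    times: np.ndarray
    chi1: np.ndarray
    states: list[str]
    events: list[FlipEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chi1 = np.asarray(self.chi1, dtype=float)
        if len(self.states) != len(self.chi1):
            raise ValueError("states and chi1 must have equal length")
        if np.any(np.abs(self.chi1) > 180.0 + 1e-9):
            raise ValueError("chi1 values must lie in (-180, 180]")


def chi1_series(
    traj: Trajectory,
    residue_id: int,
    windows: RotamerWindows = RotamerWindows(),
    min_dwell: int = 5,
    stride: int = 1,
) -> DihedralSeries:
    """chi1 trace of a residue along a trajectory, with states and flips."""
    frames = traj.frames[::stride]
    chi1 = np.array([dihedral_chi1(fr, traj.model, residue_id) for fr in frames])
    states = [classify_rotamer(a, windows) for a in chi1]
    series = DihedralSeries(
        residue_id=residue_id,
        times=np.array([fr.time for fr in frames]),
        chi1=chi1,
        states=states,
    )
    series.events = detect_flips(series, min_dwell=min_dwell)
    return series


def detect_flips(series: DihedralSeries, min_dwell: int = 5) -> list[FlipEvent]:
    """Persistent rotamer transitions in a state sequence.

    A flip is recorded when the state changes and the new state persists
    for at least ``min_dwell`` consecutive frames; shorter excursions are
    ignored -- they neither update the accepted state nor interrupt the
    persistence of the run they sit in (a one-frame noise blip inside a
    long dwell does not split it).  The initial accepted state is the
    first *persistent* state of the trace, so a noisy first frame cannot
    fabricate a flip.  Events come back in time order; the event count is
    monotonically non-increasing in ``min_dwell``.
    """
    if min_dwell < 1:
        raise ValueError("min_dwell must be >= 1")
    states = series.states
    if not states:
        return []
    # run-length encode
    runs: list[tuple[str, int, int]] = []  # (state, first, last)
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((states[start], start, i - 1))
            start = i
    # debounce: a single-frame excursion flanked by one and the same state
    # is absorbed into that state's run.  The rule is independent of
    # min_dwell (so the event count stays monotone in min_dwell) and only
    # applies when min_dwell >= 2, where single frames can never qualify
    # as a persistent state anyway.
    if min_dwell >= 2:
        merged = True
        while merged:
            merged = False
            for i in range(1, len(runs) - 1):
                _state, first, last = runs[i]
                if last == first and runs[i - 1][0] == runs[i + 1][0]:
                    runs[i - 1] = (runs[i - 1][0], runs[i - 1][1], runs[i + 1][2])
                    del runs[i : i + 2]
                    merged = True
                    break
    first_persistent = next(
        (i for i, (_s, f, l) in enumerate(runs) if l - f + 1 >= min_dwell), None
    )
    if first_persistent is None:
        return []
    accepted = runs[first_persistent][0]
    accepted_last = runs[first_persistent][2]
    events: list[FlipEvent] = []
    for state, first, last in runs[first_persistent + 1 :]:
        if state == accepted:
            accepted_last = last
        elif last - first + 1 >= min_dwell:
            events.append(
                FlipEvent(start=accepted_last, end=first, from_state=accepted, to_state=state)
            )
            accepted = state
            accepted_last = last
    return events


def residue_distance_series(
    traj: Trajectory,
    residue_a: int,
    residue_b: int,
    mode: str = "min-heavy-atom",
) -> np.ndarray:
    """Per-frame distance between two residues, nm, minimum-image.

    ``mode`` is ``"CA"`` (alpha-carbon pair) or ``"min-heavy-atom"``
    (smallest pairwise distance over all non-hydrogen atoms).
    """
    model = traj.model
    if mode == "CA":
        ia = np.array([model.atom_index(residue_a, "CA")])
        ib = np.array([model.atom_index(residue_b, "CA")])
    elif mode == "min-heavy-atom":
        ia = np.flatnonzero((model.residue_ids == residue_a) & (model.elements != "H"))
        ib = np.flatnonzero((model.residue_ids == residue_b) & (model.elements != "H"))
        if len(ia) == 0:
            raise ValueError(f"unknown residue {residue_a}")
        if len(ib) == 0:
            raise ValueError(f"unknown residue {residue_b}")
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    out = np.empty(len(traj.frames))
    for f, fr in enumerate(traj.frames):
        disp = min_image_displacement(
            fr.coords[ia][:, None, :], fr.coords[ib][None, :, :], fr.box
        )
        out[f] = np.sqrt(np.sum(disp**2, axis=-1)).min()
    return out


def bw_number(model: StructureModel, residue_id: int) -> str:
    """Ballesteros-Weinstein label "h.nn" of a residue.

    The most conserved residue of helix h (its anchor) is h.50; every
    other residue is offset from it by sequence position.
    """
    for helix in sorted(model.helix_table):
        lo, hi = model.helix_table[helix]
        if lo <= residue_id <= hi:
            if helix not in model.bw_anchors:
                raise KeyError(f"helix {helix} has no BW anchor")
            pos = 50 + residue_id - model.bw_anchors[helix]
            return f"{helix}.{pos:02d}"
    raise KeyError(f"residue {residue_id} lies outside all annotated helices")
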