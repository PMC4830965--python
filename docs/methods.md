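# Methods

This note records the models, estimators, numerical choices and known
limitations behind `gpcrmem`, in the order an analysis pipeline uses them.

## Coordinate model and units

Everything internal is in nanometres and degrees; PDB I/O converts Å↔nm at
the boundary (fixed-column PDB stores 3 decimals in Å, so round-trips are
exact to 10⁻⁴ nm). Boxes are orthorhombic only; triclinic CRYST1 records are
rejected with an explicit error rather than silently mis-wrapped. Residue
numbering is the PDB `resSeq` verbatim — no renumbering — because receptor
positions (82, 286, 290, 320…) are meaningful labels in this field.
Minimum-image displacements wrap each component of b−a into [−L/2, L/2).

Molecule classes (protein / lipid / water / ligand) are inferred from residue
names through a documented lookup covering common force-field dialects
(HOH/SOL/TIP…, POP/DPP/…); the lookup is user-extensible per call and via the
YAML config, since water and lipid residue codes vary by force field.

Multi-model PDB is the trajectory baseline: it keeps the package and its test
fixtures plain text. Per-frame times use a header convention
`REMARK 250 FRAME <i> TIME <ns>`; files without it get frame-index times.
Binary trajectory formats are deliberately out of scope here — adapters can
convert to multi-model PDB upstream.

## Synthetic systems (what the generator emulates, and what not)

The generator stands in for hundreds of nanoseconds of all-atom MD of a
7-TM receptor in a hydrated POPC bilayer. It reproduces the *observables*
those simulations feed into this package, not the physics:

- **Protein**: seven ideal α-helices (rise 0.15 nm/residue, twist
  100°/residue, Cα radius 0.23 nm — textbook helix geometry) on a ring of
  radius 0.85 nm, 30 residues each, backbone N/CA/C/O per residue. The ring
  radius puts the inner helix wall ≈0.6 nm from the bundle axis so that a
  0.7 nm ligand cutoff defines a non-trivial pocket in the lumen. One probe
  residue carries CB and CG placed by torsion geometry so its χ1 equals the
  first scheduled angle exactly.
- **Lipids**: 3-bead pseudo-molecules (choline, phosphate "P", tail) on two
  leaflet lattices with phosphate planes at ±1.9 nm (3.8 nm
  phosphate-to-phosphate thickness, typical of POPC). Only the phosphate
  position enters any analysis, so richer lipid detail would be dead weight.
- **Waters**: single "OW" atoms uniform in slabs above and below the
  membrane. A separate `water_seed` lets several systems share one solvated
  patch, which keeps hydration counts comparable across systems the way
  variants built into the same equilibrated membrane are comparable.
- **Dynamics**: per frame, optional linear helix drift, χ1 retargeting of the
  probe CG (rotation about the CA–CB axis via torsion re-placement), a
  constant z-pull of one lipid headgroup after an onset frame, symmetric
  leaflet displacement by a Gaussian thickness field, then i.i.d. isotropic
  Gaussian noise (σ default 0.02 nm) on every atom. The noise model is the
  simplest under which analytic RMSD expectations exist (mean post-fit RMSD
  ≈ σ√3), which the tests exploit.

One RNG stream is consumed in a documented order (build: water positions;
trajectory: drift directions, then one noise block), so identical
(seed, config) pairs give bit-identical output. At σ=0 with no schedules,
every frame equals the reference bitwise; for that reason the probe CG is
re-placed only on frames whose scheduled angle differs from the initial one.

What the generator does **not** emulate: conformational correlations in time
(noise is white), side chains beyond the probe's CB/CG, lipid tails and
area-per-lipid physics, water structure, and any coupling between the
programmed signals. Passing tests therefore demonstrate that the estimators
recover known signals of realistic magnitude under realistic noise — not that
they are robust to every artefact of real force-field MD (periodic jumps of
whole molecules, leaflet undulations, protein unfolding).

## Estimators

**Superposition / TM RMSD.** Kabsch in SVD form, reflections excluded via the
determinant sign; degenerate (collinear) inputs and M<3 are errors. The TM
selection is backbone N/CA/C/O of the helix-table residues (CA-only is an
option); per frame the fit and the RMSD use the same atoms. An independent
quaternion-method implementation (scipy's `align_vectors`) serves as the
cross-check oracle in the tests, agreeing to 10⁻¹⁰ nm.

**χ1 and rotamer states.** Signed IUPAC torsion of (N,Cα,Cβ)/(Cα,Cβ,Cγ) in
(−180°, 180°]. Windows: trans for |χ1| ≥ 120°, gauche− on (−120°, 0),
gauche+ on [0, 120°); the boundary is config-overridable and an exact
boundary value goes to trans (closed bound) for reproducibility. Positional
noise of σ=0.02 nm translates to roughly 25° of angular noise on the probe's
short CB–CG arm, so states 60° from a window edge classify reliably while
single-frame excursions do occur — which motivates the flip detector below.

**Flip detection.** Runs of equal state are extracted; a flip is recorded
when the state changes and the new state persists ≥ `min_dwell` frames
(default 5 — the notion of a "transient" flip needs an explicit dwell, and
the literature gives none). Two hardening rules, both chosen to keep the
event count provably monotone non-increasing in `min_dwell`: single-frame
excursions flanked by the same state are absorbed before scanning (the rule
does not depend on `min_dwell`, so the run sequence is common to all dwell
values), and the initial accepted state is the first *persistent* run, so a
noisy first frame cannot fabricate a flip. With these rules the event count
equals the number of state changes along the subsequence of persistent runs,
and deleting runs (raising the dwell) can only reduce collapsed changes.

**Leaflets and thickness.** Midplane = mean phosphate z per frame; a lipid is
upper iff its phosphate z ≥ midplane (ties up). Assignment is per-frame,
which tolerates pathological flip-flop in synthetic data; a majority-vote
per-lipid option exists for constancy. The thickness estimator wraps
phosphates into the primary box, takes per-cell leaflet mean z on an xy grid
(default spacing 0.2 nm, origin at the box origin), differences upper−lower
where both leaflets have samples, and averages over frames. Cells without a
leaflet pair in a frame contribute no sample that frame; never-sampled cells
are NaN, not zero, and no interpolation or smoothing is applied by default.
Difference maps require identical grids and are defined only where both
inputs are. Replicates are averaged *after* gridding, weighted by per-cell
sample counts (`average_thickness_maps`).

**Headgroup profiles.** A lipid is tracked if its phosphate comes within the
cutoff (default 0.6 nm; the study pipeline uses 0.8 nm because in the
synthetic geometry the nearest lattice phosphate sits ≈0.6 nm from the
target residue and a pulled lipid moves further away) of any heavy atom of
the target residue in ≥1 frame. Reported dz is the mean signed displacement
from the lipid's per-frame leaflet plane, core-negative for either leaflet;
the lipid is excluded from its own plane estimate so a large pull does not
bias its reference plane.

**Pocket volume.** The pocket is the residues with a heavy atom within
0.7 nm (minimum image) of the reference ligand's heavy atoms. Volume per
frame: superpose the frame onto the reference on pocket heavy atoms; lay a
voxel grid (default 0.08 nm; 0.05 nm for convergence checks) over the pocket
bounding box padded by probe + max vdW; occlude voxels within
vdW(atom)+probe of any protein or lipid heavy atom (Bondi radii,
user-overridable); keep free voxels inside the convex hull of the pocket
heavy atoms; keep the 6-connected component containing the seed (centroid of
pocket Cα atoms, falling back to the heavy-atom centroid, then to the
nearest free voxel within 0.3 nm, else volume 0 with a warning). Waters and
the ligand itself are excluded from occlusion because the quantity of
interest is the space *available* to solvent and ligand. The grid is shared
across frames via the superposition, making the volume invariant under rigid
motion of a frame; an analytically known hollow-shell cavity pins the
absolute scale to within 5% at 0.05 nm voxels.

**Hydration.** Count of water molecules whose *oxygen* lies within 0.8 nm
(minimum image) of the residue's Cα — the oxygen convention is a documented
choice where "water within cutoff" is otherwise ambiguous. Counts are
integer-exact against a 27-image brute force.

## Triage

Replicates are pooled with the unweighted mean of replicate means; the
between-replicate SD is reported as undefined for a single replicate (the
per-frame SD is always available). Flags against the wildtype summary:

- `flip_observed`: flips in a majority of variant replicates and none in any
  wildtype replicate;
- `elevated_rmsd` / `pocket_enlarged`: variant mean above wildtype mean +
  k·SD (k default 2; SD is the between-replicate SD when available, floored
  at 0.005 nm / 0.02 nm³ so a pathologically quiet wildtype cannot make
  everything significant);
- `hydration_changed`: two-sided version of the same rule (floor 0.5 waters);
- `membrane_perturbed`: max |thickness difference| > 0.2 nm or max
  |headgroup dz| > 0.3 nm (absolute thresholds — these perturbations are
  reported against the wildtype map, whose own spread is already inside it).

Label: flip without membrane/pocket damage → activating-candidate; no flags →
neutral-like; anything else flagged → damaging-candidate. The mapping is an
explicit operationalization of a judgement that is narrative in the
literature; every threshold is exposed in `TriageThresholds`, and raising any
threshold can only clear flags, never raise them. Slots are reserved for
externally computed binding free energies (docking/MM-GBSA), which this
package does not produce.

## Problem sizes and defaults

The generator defaults model one trajectory at study scale: 100 frames at
2 ns/frame (a 200 ns span), 7×30 residues, 128 lipids/leaflet, 400 waters,
σ = 0.02 nm. The bundled study pipeline and the acceptance script run five
systems × two replicates at 30–100 frames and 36–128 lipids/leaflet — sizes
chosen so the full study, including per-frame pocket-volume grids, completes
in seconds while every programmed signal remains well above its noise floor
(e.g. a −0.5 nm lipid pull against a per-lipid noise floor of
σ/√n_frames ≈ 0.002 nm).

## Known limitations

- Orthorhombic boxes only; no triclinic wrap.
- No bond perception: atoms are grouped by residue id and name conventions.
- The pocket estimator measures one connected cavity; it does not track
  multiple pockets or score druggability.
- Thickness maps assume a roughly planar bilayer normal to z; strongly
  curved or undulating membranes would need a local-frame estimator.
- The triage is only as meaningful as its inputs: with a single replicate the
  between-replicate SD is undefined and the per-frame SD (which
  underestimates slow variability) takes its place in the flag rules.
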