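"""Build a synthetic membrane-receptor system and look inside it.

The generator emulates a 7-TM receptor in a hydrated phosphatidylcholine
bilayer: ideal alpha-helices on a ring, 3-bead pseudo-lipids on two
leaflet lattices, a water slab on each side.  Residue numbering and
Ballesteros-Weinstein anchors follow the beta2-adrenergic receptor, so
the familiar landmarks carry their familiar labels.
"""

from gpcrmem import Selection, build_system, bw_number, receptor_like_config

cfg = receptor_like_config(seed=1, n_frames=1)
model = build_system(cfg)

n_lipids = len(model.select(Selection(molecule_class="lipid", atom_names=frozenset({"P"}))))
n_waters = len(model.select(Selection(molecule_class="water")))
print(f"atoms: {model.n_atoms}  (lipids: {n_lipids}, waters: {n_waters})")
print(f"box: {model.box.lengths.round(2)} nm")
for rid in (286, 290, 316, 326):
    print(f"residue {rid} -> BW {bw_number(model, rid)}")
# 286 is 6.48, the conserved TM6 tryptophan of the rotamer toggle switch;
# 290 (6.52) is its aromatic-cage neighbour, 326 (7.53) the TM7 tyrosine.
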