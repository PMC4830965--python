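"""TM-backbone RMSD and the chi1 rotamer toggle switch.

Two trajectories of the same receptor: one with constant chi1 (wildtype
behaviour) and one whose probe tryptophan is scheduled to flip
gauche- -> trans -> gauche-, the signature proposed for class A GPCR
activation.  The analysis recovers the programmed flips and shows the
backbone itself stays put.
"""

from gpcrmem import (
    build_system,
    chi1_series,
    generate_trajectory,
    receptor_like_config,
    tm_rmsd_series,
)

common = dict(n_frames=100, lipids_per_leaflet=16, n_waters=40, noise_sigma=0.01)
wt_cfg = receptor_like_config(seed=2, **common)
var_cfg = receptor_like_config(
    seed=3, chi1_schedule=(((0, 40), -60.0), ((40, 70), 180.0), ((70, 100), -60.0)),
    **common,
)

for label, cfg in [("wildtype", wt_cfg), ("variant", var_cfg)]:
    traj, _ = generate_trajectory(build_system(cfg), cfg)
    rmsd = tm_rmsd_series(traj)
    series = chi1_series(traj, 286, min_dwell=5)
    print(f"{label}: mean TM RMSD {rmsd.mean():.4f} nm, "
          f"{len(series.events)} chi1 flip event(s)")
    for e in series.events:
        print(f"  {e.from_state} -> {e.to_state} at frame {e.end}")
# A stable backbone (RMSD ~ noise floor) with chi1 flips is the pattern
# of an activating-like variant rather than a destabilised one.
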