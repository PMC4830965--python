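"""End-to-end variant study: generate, analyse, report.

``default_study`` builds the study conditions: a wildtype receptor with
the characteristic membrane thickening at the TM1/TM7 groove, a
no-signal negative control, and three variant archetypes --

* an *activating-like* variant whose probe tryptophan chi1 is programmed
  to flip transiently gauche- -> trans -> gauche- (the rotamer toggle
  switch),
* a *pocket-enlarging* variant with one pocket wall displaced outward,
* a *membrane-perturbing* variant that pulls one lipid headgroup toward
  the core, loses the TM1/TM7 thickening, and drifts its helices.

``run_study`` runs every analysis on every replicate, writes fixed-format
TSV outputs plus a machine-readable report, and returns the triage.  The
whole pipeline is a pure function of the seed: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import tables
from .membrane import average_thickness_maps, headgroup_profile, thickness_difference, thickness_map
from .metrics import chi1_series, residue_distance_series, tm_rmsd_series
from .pocket import define_pocket_residues, pocket_volume_series
from .pocket import hydration_count_series
from .report import MetricSummary, ReplicateMetrics, TriageThresholds, VariantReport, summarize, triage
from .synth import (
    GeneratorConfig,
    HelixDrift,
    LipidPull,
    ThicknessField,
    build_system,
    generate_trajectory,
    receptor_like_config,
)

__all__ = ["StudyOptions", "default_study", "run_study"]

#: membrane-facing residue used as pull/hydration target (TM7, near the
#: upper leaflet in the synthetic geometry)
PULL_TARGET = 329
#: rotamer-switch probe (TM6 tryptophan) and its aromatic-cage partner on TM7
PROBE_RESIDUE = 286
DISTANCE_PARTNER = 316


@dataclass(frozen=True)
class StudyOptions:
    """Problem sizes and analysis settings of one study run."""

    n_frames: int = 60
    replicates: int = 2
    lipids_per_leaflet: int = 64
    n_waters: int = 200
    noise_sigma: float = 0.02
    grid_spacing: float = 0.2
    headgroup_cutoff: float = 0.8
    min_dwell: int = 5
    pocket_voxel: float = 0.08
    pocket_probe: float = 0.14


def _groove_center() -> tuple[float, float]:
    """xy of the TM1/TM7 groove (midway between helix 1 and 7 axes)."""
    mid = np.radians(-360.0 / 7 / 2)
    r = 1.45
    return (r * float(np.cos(mid)), r * float(np.sin(mid)))


def _replicate_seed(base_seed: int, system_index: int, replicate: int) -> int:
    state = np.random.SeedSequence([base_seed, system_index, replicate]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def default_study(seed: int, options: StudyOptions = StudyOptions()) -> dict[str, list[GeneratorConfig]]:
    """Generator configs per system label, ``options.replicates`` each."""
    thickening = ThicknessField(amplitude=0.4, center_xy=_groove_center(), width=0.8)
    shared_waters = _replicate_seed(seed, 99, 0)  # one solvated patch for all systems

    def base(sys_idx: int, rep: int, **kw) -> GeneratorConfig:
        return receptor_like_config(
            seed=_replicate_seed(seed, sys_idx, rep),
            n_frames=options.n_frames,
            lipids_per_leaflet=options.lipids_per_leaflet,
            n_waters=options.n_waters,
            noise_sigma=options.noise_sigma,
            include_ligand=True,
            water_seed=shared_waters,
            **kw,
        )

    flip_start = options.n_frames // 2
    flip_end = flip_start + max(options.min_dwell * 3, options.n_frames // 4)
    flip_end = min(flip_end, options.n_frames - options.min_dwell)
    systems = {
        "wildtype": [
            base(0, r, thickness_field=thickening) for r in range(options.replicates)
        ],
        "control": [
            base(1, r, thickness_field=thickening) for r in range(options.replicates)
        ],
        "variant-activating": [
            base(
                2,
                r,
                thickness_field=thickening,
                chi1_schedule=(
                    ((0, flip_start), -60.0),
                    ((flip_start, flip_end), 180.0),
                    ((flip_end, options.n_frames), -60.0),
                ),
            )
            for r in range(options.replicates)
        ],
        "variant-pocket": [
            base(
                3,
                r,
                thickness_field=thickening,
                helix_radial_offset={3: 0.3},
            )
            for r in range(options.replicates)
        ],
        "variant-membrane": [
            base(
                4,
                r,
                # thickening lost, one headgroup pulled inward, helices drift
                lipid_pull=LipidPull(target_residue_id=PULL_TARGET, dz=-0.5, onset_frame=0),
                helix_drift=HelixDrift(amplitude=0.15),
            )
            for r in range(options.replicates)
        ],
    }
    return systems


def _analyze_replicate(config: GeneratorConfig, options: StudyOptions, pocket_def):
    model = build_system(config)
    traj, _truth = generate_trajectory(model, config)
    rmsd = tm_rmsd_series(traj)
    series = chi1_series(traj, PROBE_RESIDUE, min_dwell=options.min_dwell)
    volumes = pocket_volume_series(
        traj, pocket_def, voxel=options.pocket_voxel, probe=options.pocket_probe
    )
    hydration = hydration_count_series(traj, PULL_TARGET, cutoff=0.8)
    distance = residue_distance_series(traj, PROBE_RESIDUE, DISTANCE_PARTNER, mode="CA")
    tmap = thickness_map(traj, grid_spacing=options.grid_spacing)
    profile = headgroup_profile(traj, PULL_TARGET, cutoff=options.headgroup_cutoff)
    return traj, series, volumes, hydration, distance, tmap, profile, rmsd


def run_study(
    out_dir: str | Path,
    seed: int,
    options: StudyOptions = StudyOptions(),
    thresholds: TriageThresholds = TriageThresholds(),
) -> tuple[dict[str, VariantReport], dict[str, MetricSummary]]:
    """Run the full study and write all outputs under ``out_dir``.

    Returns (triage reports, metric summaries); the wildtype system is
    the reference for flags and thickness differences.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    systems = default_study(seed, options)

    # the pocket is defined once, on the wildtype reference geometry, and
    # that residue list is reused for every system (the way a binding site
    # defined on a reference crystal structure is reused across variants)
    wt_model = build_system(systems["wildtype"][0])
    ligand_rid = int(wt_model.residue_ids[wt_model.molecule_classes == "ligand"][0])
    pocket_def = define_pocket_residues(wt_model, ligand_rid, cutoff=0.7)

    raw: dict[str, list] = {}
    for label, configs in systems.items():
        raw[label] = [_analyze_replicate(cfg, options, pocket_def) for cfg in configs]

    wt_map = average_thickness_maps([rep[5] for rep in raw["wildtype"]])

    summaries: dict[str, MetricSummary] = {}
    for label, reps in raw.items():
        replicate_metrics = []
        for r, (traj, series, volumes, hydration, distance, tmap, profile, rmsd) in enumerate(reps):
            diff = thickness_difference(tmap, wt_map)
            max_diff = (
                float(np.nanmax(np.abs(diff.values[diff.defined])))
                if np.any(diff.defined)
                else None
            )
            max_dz = float(np.max(np.abs(profile.dz))) if len(profile.dz) else None
            replicate_metrics.append(
                ReplicateMetrics(
                    tm_rmsd=rmsd,
                    pocket_volume=volumes.volumes,
                    hydration=hydration,
                    distance=distance,
                    flip_count=len(series.events),
                    max_abs_thickness_diff=max_diff,
                    max_abs_headgroup_dz=max_dz,
                )
            )
            prefix = out / f"{label}_rep{r}"
            tables.write_rmsd_table(f"{prefix}_rmsd.tsv", traj.times, rmsd)
            tables.write_dihedral_table(f"{prefix}_chi1.tsv", series)
            tables.write_events_table(f"{prefix}_flips.tsv", series)
            tables.write_series_table(
                f"{prefix}_volume.tsv", volumes.times, volumes.volumes, "volume_nm3"
            )
            tables.write_series_table(
                f"{prefix}_hydration.tsv", traj.times, hydration, "n_waters"
            )
            tables.write_series_table(
                f"{prefix}_distance.tsv", traj.times, distance, "distance_nm"
            )
            tables.write_thickness_map(f"{prefix}_thickness.tsv", tmap)
            tables.write_headgroup_profile(f"{prefix}_headgroup.tsv", profile)
        summaries[label] = summarize(label, replicate_metrics)

    reports = {
        label: triage(summaries[label], summaries["wildtype"], summaries["control"], thresholds)
        for label in summaries
        if label != "wildtype"
    }
    tables.write_report_json(out / "report.json", reports, summaries)
    tables.write_report_text(out / "report.txt", reports)
    return reports, summaries
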