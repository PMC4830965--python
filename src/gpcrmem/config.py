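"""YAML analysis configuration.

A config file declares what a PDB file cannot carry: the TM helix
residue ranges, the Ballesteros-Weinstein x.50 anchors, molecule-class
overrides for force-field residue-name dialects, and triage thresholds.

Example::

    helix_table:
      1: [29, 58]
      6: [267, 296]
    bw_anchors:
      6: 288
    molecule_classes:
      TIP3: water
    rotamer_boundary: 120.0
    thresholds:
      k_sd: 2.0
      thickness_diff: 0.2
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .report import TriageThresholds

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    helix_table: dict[int, tuple[int, int]] = field(default_factory=dict)
    bw_anchors: dict[int, int] = field(default_factory=dict)
    molecule_classes: dict[str, str] = field(default_factory=dict)
    rotamer_boundary: float = 120.0
    min_dwell: int = 5
    grid_spacing: float = 0.2
    headgroup_cutoff: float = 0.6
    hydration_cutoff: float = 0.8
    ligand_cutoff: float = 0.7
    pocket_voxel: float = 0.08
    pocket_probe: float = 0.14
    thresholds: TriageThresholds = field(default_factory=TriageThresholds)


def load_config(path: str | Path) -> AnalysisConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = AnalysisConfig()
    if "helix_table" in raw:
        cfg.helix_table = {int(k): (int(v[0]), int(v[1])) for k, v in raw["helix_table"].items()}
    if "bw_anchors" in raw:
        cfg.bw_anchors = {int(k): int(v) for k, v in raw["bw_anchors"].items()}
    if "molecule_classes" in raw:
        cfg.molecule_classes = {str(k): str(v) for k, v in raw["molecule_classes"].items()}
    for key in (
        "rotamer_boundary",
        "grid_spacing",
        "headgroup_cutoff",
        "hydration_cutoff",
        "ligand_cutoff",
        "pocket_voxel",
        "pocket_probe",
    ):
        if key in raw:
            setattr(cfg, key, float(raw[key]))
    if "min_dwell" in raw:
        cfg.min_dwell = int(raw["min_dwell"])
    if "thresholds" in raw:
        cfg.thresholds = TriageThresholds(**{k: float(v) for k, v in raw["thresholds"].items()})
    return cfg
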