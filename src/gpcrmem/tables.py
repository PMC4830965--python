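"""Tabular (TSV) and report serialization.

All tables are tab-separated with a header line and fixed float
formatting, so identical analyses produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .membrane import HeadgroupProfile, ThicknessMap
from .metrics import DihedralSeries
from .report import MetricSummary, VariantReport

__all__ = [
    "write_rmsd_table",
    "write_dihedral_table",
    "write_events_table",
    "write_series_table",
    "write_thickness_map",
    "write_headgroup_profile",
    "write_report_json",
    "write_report_text",
]

_FLOAT = "%.6f"


def _to_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT, lineterminator="\n")


def write_rmsd_table(path: str | Path, times: np.ndarray, rmsd: np.ndarray) -> None:
    _to_tsv(pd.DataFrame({"time_ns": times, "rmsd_nm": rmsd}), path)


def write_dihedral_table(path: str | Path, series: DihedralSeries) -> None:
    _to_tsv(
        pd.DataFrame(
            {"time_ns": series.times, "chi1_deg": series.chi1, "state": series.states}
        ),
        path,
    )


def write_events_table(path: str | Path, series: DihedralSeries) -> None:
    _to_tsv(
        pd.DataFrame(
            [
                {
                    "start_frame": e.start,
                    "end_frame": e.end,
                    "from_state": e.from_state,
                    "to_state": e.to_state,
                }
                for e in series.events
            ],
            columns=["start_frame", "end_frame", "from_state", "to_state"],
        ),
        path,
    )


def write_series_table(
    path: str | Path, times: np.ndarray, values: np.ndarray, column: str
) -> None:
    """Generic (time, value) table, e.g. volume_nm3 or n_waters."""
    _to_tsv(pd.DataFrame({"time_ns": times, column: values}), path)


def write_thickness_map(path: str | Path, tmap: ThicknessMap) -> None:
    """Matrix TSV with a sidecar ``<path>.meta`` header (origin, spacing)."""
    path = Path(path)
    np.savetxt(path, tmap.values, delimiter="\t", fmt=_FLOAT)
    meta = {
        "origin_nm": [float(v) for v in tmap.origin],
        "spacing_nm": float(tmap.spacing),
        "units": "nm",
        "shape": list(tmap.values.shape),
    }
    path.with_suffix(path.suffix + ".meta").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def write_headgroup_profile(path: str | Path, profile: HeadgroupProfile) -> None:
    _to_tsv(
        pd.DataFrame(
            {
                "lipid_id": profile.lipid_residue_ids,
                "mean_x_nm": profile.mean_position[:, 0],
                "mean_y_nm": profile.mean_position[:, 1],
                "mean_z_nm": profile.mean_position[:, 2],
                "dz_nm": profile.dz,
                "n_frames": profile.n_frames,
            }
        ),
        path,
    )


def _stat_dict(stat) -> dict | None:
    if stat is None:
        return None
    return {
        "mean": round(stat.mean, 6),
        "sd_within": round(stat.sd_within, 6),
        "sd_between": None if stat.sd_between is None else round(stat.sd_between, 6),
    }


def summary_dict(summary: MetricSummary) -> dict:
    return {
        "label": summary.label,
        "n_replicates": summary.n_replicates,
        "tm_rmsd_nm": _stat_dict(summary.tm_rmsd),
        "pocket_volume_nm3": _stat_dict(summary.pocket_volume),
        "hydration_waters": _stat_dict(summary.hydration),
        "distance_nm": _stat_dict(summary.distance),
        "flip_counts": summary.flip_counts,
        "max_abs_thickness_diff_nm": None
        if summary.max_abs_thickness_diff is None
        else round(summary.max_abs_thickness_diff, 6),
        "max_abs_headgroup_dz_nm": None
        if summary.max_abs_headgroup_dz is None
        else round(summary.max_abs_headgroup_dz, 6),
        "external": summary.external,
    }


def write_report_json(
    path: str | Path,
    reports: dict[str, VariantReport],
    summaries: dict[str, MetricSummary],
) -> None:
    doc = {
        "systems": {label: summary_dict(s) for label, s in summaries.items()},
        "triage": {
            label: {"flags": r.flags, "label": r.triage_label}
            for label, r in reports.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def write_report_text(path: str | Path, reports: dict[str, VariantReport]) -> None:
    lines = ["variant triage", "=============="]
    for label in sorted(reports):
        r = reports[label]
        raised = ", ".join(k for k, v in sorted(r.flags.items()) if v) or "none"
        lines.append(f"{label}: {r.triage_label} (flags: {raised})")
    Path(path).write_text("\n".join(lines) + "\n")
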