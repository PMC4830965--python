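"""Per-variant metric summaries and activating/damaging triage.

The triage turns the narrative judgement of a variant-screening MD study
into an explicit rule: per-system metrics (TM RMSD, pocket volume,
hydration, a key inter-residue distance, rotamer flips, bilayer
perturbation extrema) are pooled over replicate trajectories, flags are
raised by threshold comparisons against the wildtype system, and the
flags map to a label:

* ``activating-candidate`` -- the rotamer toggle switch fired (flips in a
  majority of variant replicates, none in wildtype) without membrane or
  pocket damage;
* ``neutral-like`` -- no flags at all (the behaviour expected of a
  negative-control system);
* ``damaging-candidate`` -- anything else flagged.

Every threshold is explicit and configurable; the mapping makes no claim
beyond the metrics it is computed from.  Slots are reserved for
externally computed ligand/G-protein binding free energies, which this
package does not produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ReplicateMetrics",
    "MetricSummary",
    "summarize",
    "TriageThresholds",
    "VariantReport",
    "triage",
]


@dataclass
class ReplicateMetrics:
    """Raw per-trajectory metric series for one replicate of one system."""

    tm_rmsd: np.ndarray  # nm, per frame
    pocket_volume: np.ndarray | None = None  # nm^3, per frame
    hydration: np.ndarray | None = None  # waters, per frame
    distance: np.ndarray | None = None  # nm, per frame
    flip_count: int = 0
    max_abs_thickness_diff: float | None = None  # nm, vs reference map
    max_abs_headgroup_dz: float | None = None  # nm


@dataclass
class _Stat:
    mean: float
    sd_within: float  # SD of pooled per-frame samples
    sd_between: float | None  # SD of replicate means; None with 1 replicate


@dataclass
class MetricSummary:
    """Pooled means/SDs of one system's metrics across replicates."""

    label: str
    n_replicates: int
    tm_rmsd: _Stat
    pocket_volume: _Stat | None
    hydration: _Stat | None
    distance: _Stat | None
    flip_counts: list[int]
    max_abs_thickness_diff: float | None
    max_abs_headgroup_dz: float | None
    # reserved for externally computed energies (not produced here)
    external: dict[str, float] = field(default_factory=dict)


def _stat(series: Sequence[np.ndarray | None]) -> _Stat | None:
    present = [np.asarray(s, dtype=float) for s in series if s is not None]
    if not present:
        return None
    rep_means = np.array([s.mean() for s in present])
    pooled = np.concatenate(present)
    return _Stat(
        mean=float(rep_means.mean()),
        sd_within=float(pooled.std(ddof=0)),
        sd_between=float(rep_means.std(ddof=1)) if len(present) > 1 else None,
    )


def summarize(label: str, replicates: Sequence[ReplicateMetrics]) -> MetricSummary:
    """Pool replicate trajectories of one system into a summary.

    The pooled mean is the unweighted mean of replicate means; the
    between-replicate SD is undefined (None) with a single replicate,
    while the per-frame SD is always reported.
    """
    if not replicates:
        raise ValueError("summarize needs at least one replicate")
    rmsd = _stat([r.tm_rmsd for r in replicates])
    assert rmsd is not None

    def opt_max(values: list[float | None]) -> float | None:
        present = [v for v in values if v is not None]
        return max(present) if present else None

    return MetricSummary(
        label=label,
        n_replicates=len(replicates),
        tm_rmsd=rmsd,
        pocket_volume=_stat([r.pocket_volume for r in replicates]),
        hydration=_stat([r.hydration for r in replicates]),
        distance=_stat([r.distance for r in replicates]),
        flip_counts=[r.flip_count for r in replicates],
        max_abs_thickness_diff=opt_max([r.max_abs_thickness_diff for r in replicates]),
        max_abs_headgroup_dz=opt_max([r.max_abs_headgroup_dz for r in replicates]),
    )


@dataclass(frozen=True)
class TriageThresholds:
    """Thresholds of the flag rules (all overridable).

    ``k_sd`` scales the wildtype spread in the "elevated vs wildtype"
    comparisons; ``min_sd_*`` floors guard against a pathologically quiet
    wildtype making every variant look significant.
    """

    k_sd: float = 2.0
    min_sd_rmsd: float = 0.005  # nm
    min_sd_volume: float = 0.02  # nm^3
    min_sd_hydration: float = 0.5  # waters
    thickness_diff: float = 0.2  # nm
    headgroup_dz: float = 0.3  # nm


@dataclass
class VariantReport:
    """Flags and triage label for one variant against its wildtype."""

    label: str
    flags: dict[str, bool]
    triage_label: str
    thresholds: TriageThresholds


def _wt_sd(stat: _Stat, floor: float) -> float:
    sd = stat.sd_between if stat.sd_between is not None else stat.sd_within
    return max(sd, floor)


def triage(
    variant: MetricSummary,
    wildtype: MetricSummary,
    control: MetricSummary | None = None,
    thresholds: TriageThresholds = TriageThresholds(),
) -> VariantReport:
    """Classify one variant system against the wildtype.

    Flag rules:

    * ``flip_observed`` -- rotamer flips in a majority of variant
      replicates and none in any wildtype replicate;
    * ``elevated_rmsd`` -- variant mean TM RMSD above wildtype mean +
      k_sd x wildtype SD;
    * ``pocket_enlarged`` -- same rule on mean pocket volume;
    * ``hydration_changed`` -- |variant - wildtype| mean hydration above
      k_sd x wildtype SD (two-sided);
    * ``membrane_perturbed`` -- thickness-difference or headgroup
      displacement extremum above its absolute threshold.

    The label is a pure function of the flags: flip without membrane or
    pocket damage is activating-candidate, no flags is neutral-like,
    anything else damaging-candidate.  ``control`` is carried for
    reporting only; triage of the control itself uses the same rules.
    """
    t = thresholds
    flips_majority = (
        sum(1 for c in variant.flip_counts if c > 0) * 2 > len(variant.flip_counts)
    )
    wt_quiet = all(c == 0 for c in wildtype.flip_counts)
    flags = {
        "flip_observed": flips_majority and wt_quiet,
        "elevated_rmsd": variant.tm_rmsd.mean
        > wildtype.tm_rmsd.mean + t.k_sd * _wt_sd(wildtype.tm_rmsd, t.min_sd_rmsd),
        "pocket_enlarged": False,
        "hydration_changed": False,
        "membrane_perturbed": False,
    }
    if variant.pocket_volume is not None and wildtype.pocket_volume is not None:
        flags["pocket_enlarged"] = variant.pocket_volume.mean > (
            wildtype.pocket_volume.mean
            + t.k_sd * _wt_sd(wildtype.pocket_volume, t.min_sd_volume)
        )
    if variant.hydration is not None and wildtype.hydration is not None:
        flags["hydration_changed"] = abs(
            variant.hydration.mean - wildtype.hydration.mean
        ) > t.k_sd * _wt_sd(wildtype.hydration, t.min_sd_hydration)
    membrane = False
    if variant.max_abs_thickness_diff is not None:
        membrane |= variant.max_abs_thickness_diff > t.thickness_diff
    if variant.max_abs_headgroup_dz is not None:
        membrane |= variant.max_abs_headgroup_dz > t.headgroup_dz
    flags["membrane_perturbed"] = membrane

    if flags["flip_observed"] and not (flags["membrane_perturbed"] or flags["pocket_enlarged"]):
        label = "activating-candidate"
    elif not any(flags.values()):
        label = "neutral-like"
    else:
        label = "damaging-candidate"
    return VariantReport(
        label=variant.label, flags=flags, triage_label=label, thresholds=thresholds
    )
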