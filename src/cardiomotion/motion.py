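"""Reduce a phase series to per-subject motion summaries.

One :class:`~cardiomotion.masks.PhaseSeries` becomes a
:class:`Trajectory` (per-phase centroids, volumes, and Dice/Hausdorff of
every phase against the 0% reference) and then a
:class:`StructureMotionSummary` — the scalar row behind the cohort
tables: peak-to-peak centroid displacement per patient axis, volume
max/min/mean and variation, Dice max/min/mean and variation, Hausdorff
max/mean.

Variation follows the (max - min) / min convention, as a percentage, for
both volume and Dice.  Displacement is reported as unsigned per-axis
peak-to-peak excursion of the centroid by default — the standard
motion-management amplitude; the mean per-phase distance from the
reference centroid is available as an alternative mode.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .masks import PhaseSeries
from .metrics import centroid_mm, dice, hausdorff_fast, volume_ml

logger = logging.getLogger(__name__)

DISPLACEMENT_MODES = ("peak_to_peak", "mean_from_reference")


@dataclasses.dataclass(eq=False)
class Trajectory:
    """Per-phase quantities of one (subject, state, structure) series.

    ``positions_mm`` is (n_phases, 3) with columns LR, AP, CC;
    ``dsc_vs_ref`` / ``hd_vs_ref_mm`` have one entry per non-reference
    phase, in phase order, comparing that phase to the 0% phase.  The
    pairwise entries are None when the series was reduced without
    overlap metrics (volumes and centroids only).
    """

    positions_mm: np.ndarray
    volumes_ml: np.ndarray
    phase_percents: tuple[int, ...]
    dsc_vs_ref: np.ndarray | None
    hd_vs_ref_mm: np.ndarray | None
    subject_id: str = ""
    state: str = ""
    structure_name: str = ""

    def __post_init__(self) -> None:
        n = len(self.phase_percents)
        if self.positions_mm.shape != (n, 3) or self.volumes_ml.shape != (n,):
            raise ValueError("trajectory arrays inconsistent with phase count")
        if self.dsc_vs_ref is not None and (
            len(self.dsc_vs_ref) != n - 1 or len(self.hd_vs_ref_mm) != n - 1
        ):
            raise ValueError("pairwise metrics must have n_phases - 1 entries")
        if np.any(self.volumes_ml <= 0):
            raise ValueError("trajectory volumes must all be positive")


@dataclasses.dataclass(frozen=True)
class StructureMotionSummary:
    """Scalar motion summary of one (subject, state, structure).

    ``dsc_variation_pct`` is NaN when the minimum Dice against the
    reference is exactly 0 (the ratio is undefined); cohort aggregation
    excludes and logs such values.
    """

    subject_id: str
    state: str
    structure_name: str
    disp_lr_mm: float
    disp_ap_mm: float
    disp_cc_mm: float
    volume_max_ml: float
    volume_min_ml: float
    volume_ave_ml: float
    volume_variation_pct: float
    dsc_max: float
    dsc_min: float
    dsc_ave: float
    dsc_variation_pct: float
    hd_max_mm: float
    hd_ave_mm: float

    def as_row(self) -> dict[str, object]:
        return dataclasses.asdict(self)


#: Column order of the per-subject CSV emitted by the pipeline.
SUMMARY_COLUMNS = tuple(f.name for f in dataclasses.fields(StructureMotionSummary))
METRIC_COLUMNS = SUMMARY_COLUMNS[3:]


def compute_trajectory(series: PhaseSeries, with_pair_metrics: bool = True) -> Trajectory:
    """Centroid and volume per phase, plus Dice and Hausdorff distance of
    each non-reference phase against the 0% reference phase.

    Set ``with_pair_metrics=False`` to skip the overlap metrics when only
    displacement and volume summaries are needed.
    """
    positions = np.stack([centroid_mm(m) for m in series.phases])
    volumes = np.array([volume_ml(m) for m in series.phases])
    dscs = hds = None
    if with_pair_metrics:
        ref = series.phases[0]
        dscs = np.array([dice(ref, m) for m in series.phases[1:]])
        hds = np.array([hausdorff_fast(ref, m) for m in series.phases[1:]])
    return Trajectory(
        positions_mm=positions,
        volumes_ml=volumes,
        phase_percents=series.phase_percents,
        dsc_vs_ref=dscs,
        hd_vs_ref_mm=hds,
        subject_id=series.subject_id,
        state=series.state,
        structure_name=series.structure_name,
    )


def variation_pct(vmax: float, vmin: float) -> float:
    """(max - min) / min as a percentage; NaN when min is 0."""
    if vmin == 0:
        return float("nan")
    return 100.0 * (vmax - vmin) / vmin


def summarize_motion(
    traj: Trajectory, displacement_mode: str = "peak_to_peak"
) -> StructureMotionSummary:
    """Collapse a trajectory to its per-subject scalar summary.

    Displacement per axis is the unsigned peak-to-peak excursion of the
    centroid component over the cycle (mode ``"peak_to_peak"``), or the
    mean per-phase Euclidean offset from the reference projected on each
    axis (mode ``"mean_from_reference"``).  Volume and Dice variations
    use the (max - min)/min percentage; the Dice variation is flagged
    NaN (and logged) when the minimum Dice is 0.
    """
    if displacement_mode not in DISPLACEMENT_MODES:
        raise ValueError(f"displacement_mode must be one of {DISPLACEMENT_MODES}")
    if traj.dsc_vs_ref is None or traj.hd_vs_ref_mm is None:
        raise ValueError("summarize_motion needs a trajectory with pairwise metrics")
    if displacement_mode == "peak_to_peak":
        disp = traj.positions_mm.max(axis=0) - traj.positions_mm.min(axis=0)
    else:
        disp = np.abs(traj.positions_mm[1:] - traj.positions_mm[0]).mean(axis=0)

    v = traj.volumes_ml
    d = traj.dsc_vs_ref
    h = traj.hd_vs_ref_mm
    dsc_var = variation_pct(float(d.max()), float(d.min()))
    if np.isnan(dsc_var):
        logger.warning(
            "DSC variation undefined (min DSC = 0) for subject=%s state=%s structure=%s; "
            "flagged NaN and excluded from cohort averaging",
            traj.subject_id, traj.state, traj.structure_name,
        )
    return StructureMotionSummary(
        subject_id=traj.subject_id,
        state=traj.state,
        structure_name=traj.structure_name,
        disp_lr_mm=float(disp[0]),
        disp_ap_mm=float(disp[1]),
        disp_cc_mm=float(disp[2]),
        volume_max_ml=float(v.max()),
        volume_min_ml=float(v.min()),
        volume_ave_ml=float(v.mean()),
        volume_variation_pct=variation_pct(float(v.max()), float(v.min())),
        dsc_max=float(d.max()),
        dsc_min=float(d.min()),
        dsc_ave=float(d.mean()),
        dsc_variation_pct=dsc_var,
        hd_max_mm=float(h.max()),
        hd_ave_mm=float(h.mean()),
    )


def summarize_series(
    series: PhaseSeries, displacement_mode: str = "peak_to_peak"
) -> StructureMotionSummary:
    """Convenience: trajectory + summary in one call."""
    return summarize_motion(compute_trajectory(series), displacement_mode)
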