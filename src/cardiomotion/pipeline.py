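"""End-to-end orchestration: dataset (or phantom) -> per-subject rows ->
cohort tables -> between-state comparisons, written as CSV reports.

The report bundle mirrors the four-table layout standard for this kind
of study:

* ``table1_displacement.csv`` — per (structure, state) mean ± SD of the
  per-axis peak-to-peak centroid displacement (LR/AP/CC, mm);
* ``table2_volume.csv`` — volume max/min/mean (mL) and variation (%),
  with the within-state p-value of each subject's per-cycle maximum vs
  minimum volume;
* ``table3_dsc.csv`` — same shape for the Dice coefficient against the
  0% reference phase;
* ``table4_hd.csv`` — Hausdorff distance max/mean (mm) against the
  reference phase;
* ``comparisons_between_states.csv`` — paired between-state tests and
  percent changes per structure and metric;
* ``per_subject.csv`` — every per-(subject, state, structure) summary
  row, so each table cell is traceable to the values it aggregates.

Every degenerate or undefined metric exclusion is logged with its
identifiers; partial cells are reported and skipped, never imputed.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import phantom as ph
from .masks import (
    DEFAULT_AXIS_MAP,
    DEFAULT_NAMING,
    STATES,
    STRUCTURES,
    CardioMotionError,
    MaskIOError,
    SeriesError,
    load_series,
    read_mask,
    _pattern_to_regex,
)
from .motion import DISPLACEMENT_MODES, StructureMotionSummary, summarize_series
from .stats import (
    NONNORMAL_TESTS,
    PERCENT_CHANGE_MODES,
    aggregate,
    between_state_comparisons,
    summaries_frame,
    within_state_extreme_tests,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``dataset_dir`` points at an existing per-subject mask tree,
    or ``phantom_spec`` (+ ``n_subjects``) asks for a phantom cohort to
    be generated under the output directory first; the phantom seed
    lives in the spec.
    """

    output_dir: Path
    dataset_dir: Path | None = None
    phantom_spec: ph.PhantomSpec | None = None
    n_subjects: int = 0
    structures: tuple[str, ...] = STRUCTURES
    states: tuple[str, ...] = STATES
    naming_pattern: str = DEFAULT_NAMING
    file_format: str | None = None
    default_axis_map: tuple[str, str, str] = DEFAULT_AXIS_MAP
    displacement_mode: str = "peak_to_peak"
    percent_change_mode: str = "of_means"
    nonnormal_test: str = "mann_whitney"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.dataset_dir is not None:
            self.dataset_dir = Path(self.dataset_dir)
        if self.dataset_dir is None and self.phantom_spec is None:
            raise CardioMotionError("config needs a dataset_dir or a phantom_spec")
        if self.phantom_spec is not None and self.n_subjects < 1:
            raise CardioMotionError("phantom generation requires n_subjects >= 1")
        if self.displacement_mode not in DISPLACEMENT_MODES:
            raise CardioMotionError(f"displacement_mode must be one of {DISPLACEMENT_MODES}")
        if self.percent_change_mode not in PERCENT_CHANGE_MODES:
            raise CardioMotionError(f"percent_change_mode must be one of {PERCENT_CHANGE_MODES}")
        if self.nonnormal_test not in NONNORMAL_TESTS:
            raise CardioMotionError(f"nonnormal_test must be one of {NONNORMAL_TESTS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        spec = d.pop("phantom_spec", None)
        if spec is not None:
            spec = ph.spec_from_dict(spec)
        for key in ("structures", "states", "default_axis_map"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(phantom_spec=spec, **d)


@dataclasses.dataclass(frozen=True)
class Diagnostic:
    """One input problem found by :func:`validate_inputs`."""

    kind: str  # missing_phase | missing_reference | empty_mask | grid_mismatch | unreadable
    subject_id: str
    state: str
    structure: str
    detail: str


@dataclasses.dataclass(eq=False)
class ReportBundle:
    """The in-memory results of one run plus the paths written."""

    per_subject: pd.DataFrame
    table1_displacement: pd.DataFrame
    table2_volume: pd.DataFrame
    table3_dsc: pd.DataFrame
    table4_hd: pd.DataFrame
    comparisons: pd.DataFrame
    paths: dict[str, Path]


def _subject_dirs(dataset_dir: Path) -> list[Path]:
    dirs = sorted(p for p in dataset_dir.iterdir() if p.is_dir() and p.name.startswith("subject"))
    if not dirs:
        raise MaskIOError(f"no subject directories under {dataset_dir}")
    return dirs


def _collect_summaries(config: RunConfig, dataset_dir: Path) -> list[StructureMotionSummary]:
    summaries = []
    for sdir in _subject_dirs(dataset_dir):
        for state in config.states:
            for structure in config.structures:
                try:
                    series = load_series(
                        sdir, structure, state, subject_id=sdir.name,
                        pattern=config.naming_pattern, file_format=config.file_format,
                        default_axis_map=config.default_axis_map,
                    )
                except CardioMotionError as exc:
                    logger.warning(
                        "skipping (%s, %s, %s): %s", sdir.name, state, structure, exc
                    )
                    continue
                summaries.append(summarize_series(series, config.displacement_mode))
    if not summaries:
        raise CardioMotionError(f"no loadable series in {dataset_dir}")
    return summaries


def _wide(cohort: pd.DataFrame, metrics: dict[str, str]) -> pd.DataFrame:
    """Pivot the long cohort table to one row per (structure, state) with
    {label}_mean / {label}_sd columns, in the given metric order."""
    sub = cohort[cohort.metric.isin(metrics)]
    out = None
    for metric, label in metrics.items():
        block = (
            sub[sub.metric == metric]
            .set_index(["structure", "state"])[["mean", "sd"]]
            .rename(columns={"mean": f"{label}_mean", "sd": f"{label}_sd"})
        )
        out = block if out is None else out.join(block)
    return out.reset_index()


def _drop_partial_cells(
    summaries: Sequence[StructureMotionSummary],
) -> list[StructureMotionSummary]:
    """Remove (structure, state) cells with fewer than 2 subjects,
    logging each skipped cell — partial cells are reported and skipped,
    never imputed."""
    counts: dict[tuple[str, str], int] = {}
    for s in summaries:
        counts[(s.structure_name, s.state)] = counts.get((s.structure_name, s.state), 0) + 1
    kept = []
    for s in summaries:
        if counts[(s.structure_name, s.state)] < 2:
            continue
        kept.append(s)
    for (structure, state), n in sorted(counts.items()):
        if n < 2:
            logger.warning(
                "cell (structure=%s, state=%s) has only %d subject(s); "
                "excluded from cohort tables", structure, state, n,
            )
    return kept


def build_tables(
    summaries: Sequence[StructureMotionSummary], nonnormal_test: str = "mann_whitney"
) -> dict[str, pd.DataFrame]:
    """Aggregate per-subject rows into the four cohort tables."""
    summaries = _drop_partial_cells(summaries)
    cohort = aggregate(summaries).table
    t1 = _wide(cohort, {"disp_lr_mm": "lr", "disp_ap_mm": "ap", "disp_cc_mm": "cc"})
    t2 = _wide(cohort, {
        "volume_max_ml": "volume_max", "volume_min_ml": "volume_min",
        "volume_ave_ml": "volume_ave", "volume_variation_pct": "variation",
    })
    vol_p = within_state_extreme_tests(summaries, "volume", nonnormal_test)
    t2 = t2.merge(vol_p[["structure", "state", "p_value"]], on=["structure", "state"])
    t3 = _wide(cohort, {
        "dsc_max": "dsc_max", "dsc_min": "dsc_min",
        "dsc_ave": "dsc_ave", "dsc_variation_pct": "variation",
    })
    dsc_p = within_state_extreme_tests(summaries, "dsc", nonnormal_test)
    t3 = t3.merge(dsc_p[["structure", "state", "p_value"]], on=["structure", "state"])
    t4 = _wide(cohort, {"hd_max_mm": "hd_max", "hd_ave_mm": "hd_ave"})
    return {"table1_displacement": t1, "table2_volume": t2,
            "table3_dsc": t3, "table4_hd": t4}


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and write the CSV report bundle.

    Deterministic for a fixed config (and phantom seed): re-running into
    a fresh directory reproduces every output byte for byte.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cardiomotion")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        dataset_dir = config.dataset_dir
        if config.phantom_spec is not None:
            dataset_dir = out / "dataset"
            logger.info("generating phantom cohort (n=%d) under %s", config.n_subjects, dataset_dir)
            ph.generate_cohort(
                config.phantom_spec, config.n_subjects, config.states, dataset_dir,
                file_format=config.file_format or "fixture",
            )
        assert dataset_dir is not None
        summaries = _collect_summaries(config, dataset_dir)
        per_subject = summaries_frame(summaries)
        tables = build_tables(summaries, config.nonnormal_test)
        comparisons = between_state_comparisons(
            summaries,
            state_pairs=[(a, b) for i, a in enumerate(config.states)
                         for b in config.states[i + 1:]],
            nonnormal_test=config.nonnormal_test,
            percent_change_mode=config.percent_change_mode,
        )
        paths: dict[str, Path] = {}
        frames = {"per_subject": per_subject, **tables,
                  "comparisons_between_states": comparisons}
        for name, frame in frames.items():
            p = out / f"{name}.csv"
            frame.to_csv(p, index=False, float_format=_FLOAT_FMT)
            paths[name] = p
        logger.info("report bundle written to %s", out)
        return ReportBundle(
            per_subject=per_subject,
            table1_displacement=tables["table1_displacement"],
            table2_volume=tables["table2_volume"],
            table3_dsc=tables["table3_dsc"],
            table4_hd=tables["table4_hd"],
            comparisons=comparisons,
            paths=paths,
        )
    finally:
        root.removeHandler(handler)
        handler.close()


def validate_inputs(config: RunConfig) -> list[Diagnostic]:
    """Scan a dataset for problems without computing any metric.

    Reports missing phases (relative to the union of phase percents seen
    for that structure/state across subjects), a missing 0% reference,
    unreadable files, empty masks, and grid mismatches within a series.
    """
    if config.dataset_dir is None:
        raise CardioMotionError("validate_inputs needs a dataset_dir")
    rx = _pattern_to_regex(config.naming_pattern)
    diagnostics: list[Diagnostic] = []
    # first pass: inventory of phase files per (subject, state, structure)
    inventory: dict[tuple[str, str, str], dict[int, Path]] = {}
    for sdir in _subject_dirs(config.dataset_dir):
        for p in sorted(sdir.iterdir()):
            m = rx.fullmatch(p.name)
            if not m:
                continue
            g = m.groupdict()
            key = (sdir.name, g.get("state", ""), g.get("structure", ""))
            inventory.setdefault(key, {})[int(g["percent"])] = p
    expected: dict[tuple[str, str], set[int]] = {}
    for (subj, state, structure), phases in inventory.items():
        expected.setdefault((state, structure), set()).update(phases)
    for (subj, state, structure), phases in sorted(inventory.items()):
        if state not in config.states or structure not in config.structures:
            continue
        for missing in sorted(expected[(state, structure)] - set(phases)):
            kind = "missing_reference" if missing == 0 else "missing_phase"
            diagnostics.append(Diagnostic(kind, subj, state, structure, f"phase {missing}%"))
        ref_grid = None
        for pct in sorted(phases):
            try:
                mask = read_mask(phases[pct], config.file_format,
                                 default_axis_map=config.default_axis_map)
            except CardioMotionError as exc:
                diagnostics.append(Diagnostic("unreadable", subj, state, structure, str(exc)))
                continue
            if mask.is_empty():
                diagnostics.append(
                    Diagnostic("empty_mask", subj, state, structure, f"phase {pct}%")
                )
            grid = (mask.shape, mask.spacing_mm, mask.axis_map)
            if ref_grid is None:
                ref_grid = grid
            elif grid != ref_grid:
                diagnostics.append(
                    Diagnostic("grid_mismatch", subj, state, structure,
                               f"phase {pct}%: {grid[0]} vs {ref_grid[0]}")
                )
    return diagnostics
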