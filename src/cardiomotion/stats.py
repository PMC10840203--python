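"""Cohort aggregation and between-condition statistical comparisons.

Values are aggregated across subjects as mean ± SD per (structure,
state, metric) cell.  Paired comparisons follow a normality-gated test
choice common in the clinical literature: Shapiro–Wilk on the paired
differences at alpha = 0.05, then a two-sided paired t test when
normality is not rejected, otherwise a Mann–Whitney U test on the two
samples.  Mann–Whitney is an *unpaired* rank test; pairing nonnormal
paired data with it mirrors reported practice in this study design, but
the Wilcoxon signed-rank test is the statistically preferable choice and
is available via ``nonnormal_test="wilcoxon"`` (a recommendation is
logged whenever the Mann–Whitney branch is taken).  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .masks import CardioMotionError
from .motion import METRIC_COLUMNS, StructureMotionSummary

logger = logging.getLogger(__name__)

NONNORMAL_TESTS = ("mann_whitney", "wilcoxon")
PERCENT_CHANGE_MODES = ("of_means", "mean_of_ratios")


class AggregationError(CardioMotionError):
    """A cohort cell cannot be aggregated (fewer than 2 subjects)."""


@dataclasses.dataclass(frozen=True)
class PairedComparison:
    """Result of one paired comparison.

    ``test_name`` is ``"paired_t"`` when Shapiro–Wilk did not reject
    normality of the paired differences, otherwise the configured
    nonnormal test; ``"degenerate"`` flags constant differences, for
    which p is reported as 1.
    """

    test_name: str
    statistic: float
    p_value: float
    normality_p: float
    degenerate: bool = False


@dataclasses.dataclass(eq=False)
class CohortTable:
    """Per-(structure, state, metric) cohort summary.

    ``table`` has columns structure, state, metric, mean, sd, n; sd is
    NaN when fewer than 2 defined values remain in a cell after
    excluding NaN-flagged (undefined) per-subject values.
    """

    table: pd.DataFrame
    n_excluded: int = 0

    def get(self, structure: str, state: str, metric: str) -> tuple[float, float, int]:
        t = self.table
        row = t[(t.structure == structure) & (t.state == state) & (t.metric == metric)]
        if row.empty:
            raise KeyError((structure, state, metric))
        r = row.iloc[0]
        return float(r["mean"]), float(r["sd"]), int(r["n"])


def summaries_frame(summaries: Sequence[StructureMotionSummary]) -> pd.DataFrame:
    """Per-subject summaries as a tidy DataFrame (one row each)."""
    return pd.DataFrame([s.as_row() for s in summaries])


def aggregate(summaries: Sequence[StructureMotionSummary]) -> CohortTable:
    """Mean ± SD (ddof=1) across subjects for every metric of every
    (structure, state) cell.

    NaN-flagged per-subject values (e.g. undefined Dice variation) are
    excluded with a logged count.  Fewer than 2 subjects in a cell is an
    error naming the cell.
    """
    if not summaries:
        raise AggregationError("no summaries to aggregate")
    df = summaries_frame(summaries)
    rows = []
    n_excluded = 0
    for (structure, state), grp in df.groupby(["structure_name", "state"], sort=True):
        if len(grp) < 2:
            raise AggregationError(
                f"cell (structure={structure}, state={state}) has n={len(grp)} < 2 subjects"
            )
        for metric in METRIC_COLUMNS:
            vals = grp[metric].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            excl = len(vals) - len(defined)
            if excl:
                n_excluded += excl
                logger.warning(
                    "excluded %d undefined value(s) of %s for (%s, %s)",
                    excl, metric, structure, state,
                )
            n = len(defined)
            mean = float(defined.mean()) if n else float("nan")
            sd = float(defined.std(ddof=1)) if n >= 2 else float("nan")
            if n < 2:
                logger.warning(
                    "cell (%s, %s, %s) has n=%d defined values; sd undefined",
                    structure, state, metric, n,
                )
            rows.append(
                {"structure": structure, "state": state, "metric": metric,
                 "mean": mean, "sd": sd, "n": n}
            )
    return CohortTable(pd.DataFrame(rows), n_excluded)


def compare_paired(
    x: Sequence[float],
    y: Sequence[float],
    alpha_normality: float = 0.05,
    nonnormal_test: str = "mann_whitney",
) -> PairedComparison:
    """Normality-gated two-sided comparison of paired per-subject values.

    Shapiro–Wilk is applied to the differences ``y - x``; if its p-value
    exceeds ``alpha_normality`` a paired t test is used, otherwise the
    configured nonnormal test.  Constant differences (zero variance,
    including x == y) short-circuit to a degenerate result with p = 1.
    """
    if nonnormal_test not in NONNORMAL_TESTS:
        raise ValueError(f"nonnormal_test must be one of {NONNORMAL_TESTS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and paired (equal length)")
    if len(x) < 3:
        raise ValueError("paired comparison needs at least 3 pairs")
    d = y - x
    if np.ptp(d) == 0:
        return PairedComparison(
            test_name="degenerate", statistic=0.0, p_value=1.0,
            normality_p=float("nan"), degenerate=True,
        )
    normality_p = float(sps.shapiro(d).pvalue)
    if normality_p > alpha_normality:
        res = sps.ttest_rel(x, y)
        return PairedComparison("paired_t", float(res.statistic), float(res.pvalue), normality_p)
    if nonnormal_test == "mann_whitney":
        logger.info(
            "nonnormal paired differences compared with the unpaired Mann-Whitney U test; "
            "consider nonnormal_test='wilcoxon' (signed-rank) for a paired alternative"
        )
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        return PairedComparison("mann_whitney_u", float(res.statistic), float(res.pvalue), normality_p)
    res = sps.wilcoxon(x, y, alternative="two-sided")
    return PairedComparison("wilcoxon", float(res.statistic), float(res.pvalue), normality_p)


def percent_change(
    x: Sequence[float], y: Sequence[float], mode: str = "of_means"
) -> float:
    """Percent change of y relative to baseline x across paired subjects.

    ``of_means``: 100 * (mean(y) - mean(x)) / mean(x);
    ``mean_of_ratios``: mean over subjects of 100 * (y_i - x_i) / x_i.
    All baseline values must be positive.
    """
    if mode not in PERCENT_CHANGE_MODES:
        raise ValueError(f"mode must be one of {PERCENT_CHANGE_MODES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("x and y must be paired non-empty 1D sequences")
    if np.any(x <= 0):
        raise ValueError("percent change needs strictly positive baseline values")
    if mode == "of_means":
        return float(100.0 * (y.mean() - x.mean()) / x.mean())
    return float((100.0 * (y - x) / x).mean())


def _paired_frame(
    df: pd.DataFrame, structure: str, metric: str, a: str, b: str
) -> tuple[np.ndarray, np.ndarray]:
    sub = df[df.structure_name == structure]
    pa = sub[sub.state == a].set_index("subject_id")[metric]
    pb = sub[sub.state == b].set_index("subject_id")[metric]
    common = pa.index.intersection(pb.index)
    return pa.loc[common].to_numpy(float), pb.loc[common].to_numpy(float)


def within_state_extreme_tests(
    summaries: Sequence[StructureMotionSummary],
    which: str = "volume",
    nonnormal_test: str = "mann_whitney",
) -> pd.DataFrame:
    """Per (structure, state): paired comparison of each subject's
    maximum vs minimum over the cardiac cycle (volume or Dice) — the
    within-state p-value column of the cohort tables."""
    if which not in ("volume", "dsc"):
        raise ValueError("which must be 'volume' or 'dsc'")
    hi, lo = (f"{which}_max_ml", f"{which}_min_ml") if which == "volume" else ("dsc_max", "dsc_min")
    df = summaries_frame(summaries)
    rows = []
    for (structure, state), grp in df.groupby(["structure_name", "state"], sort=True):
        if len(grp) < 3:
            logger.warning(
                "cell (%s, %s) has only %d subject(s); max-vs-min test skipped",
                structure, state, len(grp),
            )
            rows.append(
                {"structure": structure, "state": state, "metric": which,
                 "test": "insufficient_n", "statistic": float("nan"),
                 "p_value": float("nan"), "normality_p": float("nan"),
                 "degenerate": False, "n": len(grp)}
            )
            continue
        res = compare_paired(
            grp[lo].to_numpy(float), grp[hi].to_numpy(float), nonnormal_test=nonnormal_test
        )
        rows.append(
            {"structure": structure, "state": state, "metric": which,
             "test": res.test_name, "statistic": res.statistic,
             "p_value": res.p_value, "normality_p": res.normality_p,
             "degenerate": res.degenerate, "n": len(grp)}
        )
    return pd.DataFrame(rows)


def between_state_comparisons(
    summaries: Sequence[StructureMotionSummary],
    metrics: Sequence[str] = ("disp_lr_mm", "disp_ap_mm", "disp_cc_mm",
                              "volume_ave_ml", "dsc_ave", "hd_max_mm"),
    state_pairs: Sequence[tuple[str, str]] = (("EIBH", "EEBH"), ("EIBH", "DIBH"), ("EEBH", "DIBH")),
    nonnormal_test: str = "mann_whitney",
    percent_change_mode: str = "of_means",
) -> pd.DataFrame:
    """Paired between-state comparison of per-subject summary metrics,
    one row per (structure, metric, state pair), with percent change of
    the second state relative to the first."""
    df = summaries_frame(summaries)
    rows = []
    for structure in sorted(df.structure_name.unique()):
        for metric in metrics:
            for a, b in state_pairs:
                xa, xb = _paired_frame(df, structure, metric, a, b)
                keep = ~(np.isnan(xa) | np.isnan(xb))
                xa, xb = xa[keep], xb[keep]
                if len(xa) < 3:
                    logger.warning(
                        "skipping comparison (%s, %s, %s vs %s): only %d complete pairs",
                        structure, metric, a, b, len(xa),
                    )
                    continue
                res = compare_paired(xa, xb, nonnormal_test=nonnormal_test)
                try:
                    pct = percent_change(xa, xb, mode=percent_change_mode)
                except ValueError:
                    pct = float("nan")
                rows.append(
                    {"structure": structure, "metric": metric,
                     "state_a": a, "state_b": b, "test": res.test_name,
                     "statistic": res.statistic, "p_value": res.p_value,
                     "normality_p": res.normality_p, "degenerate": res.degenerate,
                     "percent_change": pct, "n": len(xa)}
                )
    return pd.DataFrame(rows)
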