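"""Descriptive per-algorithm metric summaries.

Complements the model-based ranking (P-scores, see
:meth:`propnma.model.NMAResults.p_scores`) with simple unweighted means of
the reported study-level percentages per algorithm, ranked in descending
order of the mean (1 = highest).  Algorithms with no reports are left
unranked.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .data import ALGORITHMS, Metric, StudyRecord

__all__ = ["summarize_metric", "metric_summary_table", "render_summary_markdown"]


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (display convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_metric(
    studies: Sequence[StudyRecord],
    metric: Metric | str,
    algorithms: Iterable[str] = ALGORITHMS,
) -> pd.DataFrame:
    """Per-algorithm count, unweighted mean percentage and rank for one metric.

    Means are plain arithmetic means of the reported percentages, not
    participant-weighted.  Ties share an average rank.  Returns a frame
    indexed by algorithm with columns ``n_studies``, ``mean_pct`` (one
    decimal, half-up), ``mean_pct_exact`` and ``rank`` (NaN when no study
    reports the metric).
    """
    metric = Metric(metric)
    values: dict[str, list[float]] = {a: [] for a in algorithms}
    for s in studies:
        for arm in s.arms:
            if arm.algorithm not in values:
                continue
            obs = arm.observation(metric)
            if obs is not None:
                values[arm.algorithm].append(obs.p * 100.0)
    out = pd.DataFrame(
        {
            "n_studies": {a: len(v) for a, v in values.items()},
            "mean_pct_exact": {a: (sum(v) / len(v) if v else float("nan")) for a, v in values.items()},
        }
    )
    out["mean_pct"] = out["mean_pct_exact"].map(
        lambda x: _round1(x) if x == x else float("nan")
    )
    out["rank"] = out["mean_pct_exact"].rank(ascending=False, method="average")
    out["tied"] = out["mean_pct_exact"].duplicated(keep=False) & out["mean_pct_exact"].notna()
    return out.sort_values(["rank"], na_position="last")


def metric_summary_table(studies: Sequence[StudyRecord]) -> pd.DataFrame:
    """Combined sensitivity/specificity summary (the descriptive
    complement to the network ranking): one row per algorithm."""
    sens = summarize_metric(studies, Metric.sensitivity)
    spec = summarize_metric(studies, Metric.specificity)
    out = pd.DataFrame(
        {
            "n_sensitivity": sens["n_studies"],
            "mean_sensitivity": sens["mean_pct"],
            "rank_sensitivity": sens["rank"],
            "n_specificity": spec["n_studies"],
            "mean_specificity": spec["mean_pct"],
            "rank_specificity": spec["rank"],
        }
    )
    return out.sort_values("rank_sensitivity", na_position="last")


def render_summary_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering of :func:`metric_summary_table` (en dash for
    unreported cells)."""
    lines = [
        "| Algorithm | n (sens) | Mean sensitivity (%) | Rank | n (spec) | Mean specificity (%) | Rank |",
        "|---|---|---|---|---|---|---|",
    ]
    for algo, row in table.iterrows():
        def fmt(x, is_rank=False):
            if x != x:
                return "–"
            return f"{int(x)}" if is_rank and float(x).is_integer() else f"{x:.1f}"
        lines.append(
            f"| {algo} | {int(row['n_sensitivity'])} | {fmt(row['mean_sensitivity'])} "
            f"| {fmt(row['rank_sensitivity'], True)} | {int(row['n_specificity'])} "
            f"| {fmt(row['mean_specificity'])} | {fmt(row['rank_specificity'], True)} |"
        )
    return "\n".join(lines)
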