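"""Ranking cell lines and cell-line sets by max-aggregated per-MOA scores.

A set of cell lines is scored per MOA by the best single-line score within
the set ("max aggregation": a pair detects an MOA if either line does), and
summarised by the mean over eligible MOAs. Robustness of the summary to the
composition of the compound library is estimated by rescoring under random
subsamples of the library (by default 50 draws of 2/3 of the compounds,
without replacement).

Subset search is exhaustive up to ``max_set_size`` — exact and cheap for
panels of a handful of lines (2^6 - 1 subsets for six); a greedy forward
search is available for larger panels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CELL_LINE, COMPOUND, MOA, ROLE, ROLE_COMPOUND, TREATMENT
from .phenoactivity import score_all_phenoactivity
from .phenosimilarity import score_all_phenosimilarity

logger = logging.getLogger(__name__)

__all__ = [
    "LineSetResult",
    "aggregate_set",
    "summarize",
    "improvement",
    "score_task",
    "rank_sets",
    "subsample_distribution",
    "greedy_rank",
]

TASKS = ("phenoactivity", "phenosimilarity")


@dataclass
class LineSetResult:
    """Max-aggregated scores for one set of cell lines on one task."""

    lines: tuple[str, ...]
    task: str
    per_moa_score: pd.Series
    summary: float
    subsample_summaries: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_moas(self) -> int:
        return int(self.per_moa_score.size)

    @property
    def subsample_mean(self) -> float:
        """Mean over draws; draws with no eligible MOA (NaN) are ignored."""
        valid = self.subsample_summaries[~np.isnan(self.subsample_summaries)]
        return float(valid.mean()) if valid.size else float("nan")

    @property
    def subsample_sd(self) -> float:
        valid = self.subsample_summaries[~np.isnan(self.subsample_summaries)]
        return float(valid.std(ddof=1)) if valid.size > 1 else float("nan")


def score_task(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    task: str,
    min_moa_size: int = 1,
    **kwargs,
) -> pd.DataFrame:
    """Dispatch to the single-line scorer for a task."""
    if task == "phenoactivity":
        return score_all_phenoactivity(profiles, annotation, min_moa_size=min_moa_size, **kwargs)
    if task == "phenosimilarity":
        return score_all_phenosimilarity(
            profiles, annotation, min_moa_size=max(2, min_moa_size), **kwargs
        )
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def _tables_by_line(score_table: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        line: sub.set_index(MOA)["score"]
        for line, sub in score_table.groupby(CELL_LINE, sort=True)
    }


def aggregate_set(score_tables: Mapping[str, pd.Series | pd.DataFrame], lines: Sequence[str]) -> pd.Series:
    """Per-MOA maximum score across the chosen lines.

    ``score_tables`` maps line -> (MOA -> score) Series (or a score table
    DataFrame). MOAs are eligible only if scored in every chosen line.
    """
    if not lines:
        raise ValueError("empty line set")
    per_line = []
    for line in lines:
        if line not in score_tables:
            raise ValueError(f"no score table for line {line!r}")
        t = score_tables[line]
        if isinstance(t, pd.DataFrame):
            t = t.set_index(MOA)["score"]
        per_line.append(t)
    moas = per_line[0].index
    for t in per_line[1:]:
        moas = moas.intersection(t.index)
    moas = moas.sort_values()
    stacked = pd.concat([t.loc[moas] for t in per_line], axis=1)
    return stacked.max(axis=1)


def summarize(per_moa_score: pd.Series, stat: str = "mean") -> float:
    """Summary statistic over eligible MOAs (arithmetic mean; median optional)."""
    values = np.asarray(per_moa_score, float)
    if values.size == 0:
        raise ValueError("no eligible MOA to summarize")
    if stat == "mean":
        return float(values.mean())
    if stat == "median":
        return float(np.median(values))
    raise ValueError(f"unknown summary stat {stat!r}")


def improvement(base_summary: float, set_summary: float) -> float:
    """Percent improvement of a set's summary over a baseline summary."""
    if base_summary <= 0:
        raise ValueError("improvement undefined for base summary <= 0")
    return 100.0 * (set_summary - base_summary) / base_summary


def _all_subsets(lines: Sequence[str], max_set_size: int):
    for size in range(1, max_set_size + 1):
        yield from combinations(lines, size)


def rank_sets(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    task: str,
    max_set_size: int = 2,
    min_moa_size: int = 1,
    stat: str = "mean",
    **score_kwargs,
) -> list[LineSetResult]:
    """Exhaustively rank all cell-line subsets up to ``max_set_size``.

    Ordering: summary descending, then fewer lines, then lexicographic line
    names — a deterministic total order.
    """
    table = score_task(profiles, annotation, task, min_moa_size=min_moa_size, **score_kwargs)
    tables = _tables_by_line(table)
    lines = sorted(tables)
    if max_set_size > len(lines):
        raise ValueError(f"max_set_size {max_set_size} exceeds {len(lines)} lines")
    results = []
    for subset in _all_subsets(lines, max_set_size):
        per_moa = aggregate_set(tables, subset)
        results.append(
            LineSetResult(
                lines=tuple(subset),
                task=task,
                per_moa_score=per_moa,
                summary=summarize(per_moa, stat),
            )
        )
    results.sort(key=lambda r: (-r.summary, len(r.lines), r.lines))
    return results


def greedy_rank(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    task: str,
    max_set_size: int = 2,
    min_moa_size: int = 1,
    stat: str = "mean",
    **score_kwargs,
) -> list[LineSetResult]:
    """Greedy forward selection for large panels: grow the set one line at a time."""
    table = score_task(profiles, annotation, task, min_moa_size=min_moa_size, **score_kwargs)
    tables = _tables_by_line(table)
    remaining = sorted(tables)
    chosen: list[str] = []
    path = []
    while remaining and len(chosen) < max_set_size:
        best = min(
            remaining,
            key=lambda l: (-summarize(aggregate_set(tables, [*chosen, l]), stat), l),
        )
        chosen.append(best)
        remaining.remove(best)
        per_moa = aggregate_set(tables, sorted(chosen))
        path.append(
            LineSetResult(
                lines=tuple(sorted(chosen)),
                task=task,
                per_moa_score=per_moa,
                summary=summarize(per_moa, stat),
            )
        )
    return path


def subsample_distribution(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    task: str,
    sets: Sequence[Sequence[str]] | None = None,
    n_draws: int = 50,
    fraction: float = 2.0 / 3.0,
    seed: int = 0,
    min_moa_size: int = 1,
    stat: str = "mean",
    max_set_size: int = 2,
    **score_kwargs,
) -> list[LineSetResult]:
    """Full-library results plus subsample summary distributions per line set.

    Each draw samples ``floor(fraction * N)`` of the profiled, annotated
    compounds without replacement (one stream per draw, derived from ``seed``
    by fixed increments), rescopes every line's score table to the drawn
    compounds and recomputes each set's summary. MOAs falling below the
    eligibility size inside a draw drop out of that draw (logged, never an
    error). ``sets=None`` enumerates all subsets up to ``max_set_size``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")

    full_table = score_task(profiles, annotation, task, min_moa_size=min_moa_size, **score_kwargs)
    tables = _tables_by_line(full_table)
    lines = sorted(tables)
    if sets is None:
        sets = list(_all_subsets(lines, min(max_set_size, len(lines))))
    sets = [tuple(sorted(s)) for s in sets]

    profiled = profiles.loc[profiles[ROLE] == ROLE_COMPOUND, TREATMENT]
    annotated = set(annotation[COMPOUND])
    pool = np.array(sorted(set(profiled) & annotated), dtype=object)
    n_take = int(np.floor(fraction * pool.size))
    if n_take < 1:
        raise ValueError("subsample fraction leaves no compounds")

    draws = np.empty((n_draws, len(sets)))
    for d in range(n_draws):
        rng = np.random.default_rng(seed + d)  # per-draw stream, fixed increments
        keep = set(pool[rng.choice(pool.size, size=n_take, replace=False)])
        sub_ann = annotation.loc[annotation[COMPOUND].isin(keep)]
        mask = (profiles[ROLE] != ROLE_COMPOUND) | profiles[TREATMENT].isin(keep)
        try:
            with warnings.catch_warnings():
                # MOAs shrinking below eligibility inside a draw are routine
                warnings.simplefilter("ignore", UserWarning)
                sub_table = score_task(
                    profiles.loc[mask], sub_ann, task, min_moa_size=min_moa_size, **score_kwargs
                )
        except ValueError:
            logger.info("draw %d left no eligible MOA; summaries set to NaN", d)
            draws[d] = np.nan
            continue
        sub_tables = _tables_by_line(sub_table)
        for s_idx, subset in enumerate(sets):
            usable = [l for l in subset if l in sub_tables]
            if len(usable) < len(subset):
                logger.info("draw %d: lines %s unscored", d, set(subset) - set(usable))
            per_moa = aggregate_set(sub_tables, usable) if usable else pd.Series(dtype=float)
            draws[d, s_idx] = summarize(per_moa, stat) if per_moa.size else np.nan

    results = []
    for s_idx, subset in enumerate(sets):
        per_moa = aggregate_set(tables, subset)
        results.append(
            LineSetResult(
                lines=subset,
                task=task,
                per_moa_score=per_moa,
                summary=summarize(per_moa, stat),
                subsample_summaries=draws[:, s_idx].copy(),
            )
        )
    results.sort(key=lambda r: (-r.summary, len(r.lines), r.lines))
    return results


def ranking_frame(results: Sequence[LineSetResult]) -> pd.DataFrame:
    """Flatten ranked LineSetResults into the ranking CSV layout."""
    return pd.DataFrame(
        {
            "lines": [";".join(r.lines) for r in results],
            "task": [r.task for r in results],
            "summary": [r.summary for r in results],
            "subsample_mean": [r.subsample_mean for r in results],
            "subsample_sd": [r.subsample_sd for r in results],
            "n_moas": [r.n_moas for r in results],
        }
    )
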