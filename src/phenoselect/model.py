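"""Model/results interface over the scoring pipeline.

:class:`PhenotypicScreen` bundles a table of phenotypic profiles with an MOA
annotation; :meth:`PhenotypicScreen.fit` runs both scoring tasks, ranks
cell-line sets under max aggregation, and (optionally) estimates subsample
robustness, returning a :class:`ScreenResults` with the score tables,
rankings and a text :meth:`~ScreenResults.summary`.

Typical use::

    screen = PhenotypicScreen.from_cell_table(cells, annotation)
    res = screen.fit(min_moa_size=5, n_draws=50, seed=17)
    print(res.summary())
    res.phenoactivity          # (cell line, MOA) score table
    res.rankings["phenosimilarity"][0].lines
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CELL_LINE,
    COMPOUND,
    MOA,
    ROLE,
    ROLE_COMPOUND,
    TableSchema,
    validate_annotations,
)
from .optimize import (
    TASKS,
    LineSetResult,
    improvement,
    rank_sets,
    ranking_frame,
    subsample_distribution,
)
from .profiling import profile_screen

__all__ = ["PhenotypicScreen", "ScreenResults"]


class PhenotypicScreen:
    """A profiled multi-cell-line screen ready for scoring.

    Parameters
    ----------
    profiles : DataFrame
        Canonical profile table (compound and control profiles, all lines).
    annotation : DataFrame
        (compound, moa) pairs; multi-MOA compounds on multiple rows.
    """

    def __init__(self, profiles: pd.DataFrame, annotation: pd.DataFrame):
        self.profiles = profiles
        self.annotation = validate_annotations(annotation)
        profiled = set(profiles.loc[profiles[ROLE] == ROLE_COMPOUND, "treatment"])
        if not profiled & set(self.annotation[COMPOUND]):
            raise ValueError("annotation covers no profiled compound")
        self.cell_lines = sorted(profiles[CELL_LINE].unique())

    @classmethod
    def from_cell_table(
        cls,
        cells: pd.DataFrame,
        annotation: pd.DataFrame,
        control_policy: str = "plate",
        per_well: bool = False,
    ) -> "PhenotypicScreen":
        """Build profiles from a per-cell feature table, then construct the model."""
        return cls(profile_screen(cells, control_policy=control_policy, per_well=per_well),
                   annotation)

    def fit(
        self,
        min_moa_size: int = 5,
        max_set_size: int = 2,
        n_draws: int = 50,
        fraction: float = 2.0 / 3.0,
        seed: int = 0,
        tasks: Sequence[str] = TASKS,
        stat: str = "mean",
    ) -> "ScreenResults":
        """Score both tasks, rank line sets, and estimate subsample robustness.

        ``n_draws=0`` skips subsampling (rankings then carry empty subsample
        distributions). ``min_moa_size`` is the reporting filter on MOA size
        (>= 5 by convention).
        """
        score_tables: dict[str, pd.DataFrame] = {}
        rankings: dict[str, list[LineSetResult]] = {}
        max_set_size = min(max_set_size, len(self.cell_lines))
        for task in tasks:
            if n_draws:
                results = subsample_distribution(
                    self.profiles, self.annotation, task,
                    n_draws=n_draws, fraction=fraction, seed=seed,
                    min_moa_size=min_moa_size, stat=stat, max_set_size=max_set_size,
                )
            else:
                results = rank_sets(
                    self.profiles, self.annotation, task,
                    max_set_size=max_set_size, min_moa_size=min_moa_size, stat=stat,
                )
            rankings[task] = results
            from .optimize import score_task

            score_tables[task] = score_task(
                self.profiles, self.annotation, task, min_moa_size=min_moa_size
            )
        return ScreenResults(self, score_tables, rankings,
                             min_moa_size=min_moa_size, n_draws=n_draws,
                             fraction=fraction, seed=seed)


@dataclass
class ScreenResults:
    """Fitted score tables, line-set rankings and subsample distributions."""

    model: PhenotypicScreen
    score_tables: Mapping[str, pd.DataFrame]
    rankings: Mapping[str, list[LineSetResult]]
    min_moa_size: int = 5
    n_draws: int = 0
    fraction: float = 2.0 / 3.0
    seed: int = 0

    @property
    def phenoactivity(self) -> pd.DataFrame:
        return self.score_tables["phenoactivity"]

    @property
    def phenosimilarity(self) -> pd.DataFrame:
        return self.score_tables["phenosimilarity"]

    def best_lines(self, task: str) -> tuple[str, ...]:
        """Top-ranked line set for a task."""
        return self.rankings[task][0].lines

    def best_single_line(self, task: str) -> str:
        singles = [r for r in self.rankings[task] if len(r.lines) == 1]
        return singles[0].lines[0]

    def improvement_over_best_single(self, task: str) -> float:
        """Percent gain of the top-ranked set over the best single line."""
        singles = [r for r in self.rankings[task] if len(r.lines) == 1]
        return improvement(singles[0].summary, self.rankings[task][0].summary)

    def ranking_frame(self, task: str) -> pd.DataFrame:
        return ranking_frame(self.rankings[task])

    def summary(self) -> str:
        """Plain-text summary of per-line summaries and top sets per task."""
        lines = ["Phenotypic screen cell-line selection",
                 "=" * 44,
                 f"cell lines: {', '.join(self.model.cell_lines)}",
                 f"MOA size filter: >= {self.min_moa_size} compounds",
                 f"subsampling: {self.n_draws} draws of {self.fraction:.3f} "
                 f"of compounds (seed {self.seed})"]
        for task, ranked in self.rankings.items():
            lines.append("")
            lines.append(f"[{task}]")
            singles = [r for r in ranked if len(r.lines) == 1]
            for r in singles:
                extra = ""
                if r.subsample_summaries.size:
                    extra = f"  (subsample {r.subsample_mean:.3f} +/- {r.subsample_sd:.3f})"
                lines.append(f"  {r.lines[0]:<12s} mean score {r.summary:.3f} "
                             f"over {r.n_moas} MOAs{extra}")
            best = ranked[0]
            lines.append(f"  best set: {{{', '.join(best.lines)}}} "
                         f"mean score {best.summary:.3f}")
            if len(best.lines) > 1:
                lines.append(
                    f"  gain over best single line: "
                    f"{self.improvement_over_best_single(task):+.2f}%"
                )
        return "\n".join(lines)

    # ---- plotting -------------------------------------------------------

    def plot_score_heatmap(self, task: str, ax=None, top: int = 25):
        """Heatmap of the top-scoring MOAs (rows) by cell line (columns)."""
        import matplotlib.pyplot as plt

        table = self.score_tables[task]
        wide = table.pivot(index=MOA, columns=CELL_LINE, values="score")
        order = wide.max(axis=1).sort_values(ascending=False).index[:top]
        wide = wide.loc[order]
        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.6 * wide.shape[1], 1 + 0.3 * len(wide)))
        im = ax.imshow(wide.to_numpy(), aspect="auto", vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=45, ha="right")
        ax.set_yticks(range(len(wide)), wide.index)
        ax.set_title(f"{task} scores (top {len(wide)} MOAs)")
        ax.figure.colorbar(im, ax=ax, label="score")
        return ax

    def plot_subsample_distributions(self, task: str, ax=None):
        """Boxplots of subsample summaries per line set, shaded by set size."""
        import matplotlib.pyplot as plt

        ranked = [r for r in self.rankings[task] if r.subsample_summaries.size]
        if not ranked:
            raise ValueError("fit was run without subsampling (n_draws=0)")
        ranked = sorted(ranked, key=lambda r: (len(r.lines), -r.summary))
        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.45 * len(ranked), 4))
        data = [r.subsample_summaries[~np.isnan(r.subsample_summaries)] for r in ranked]
        box = ax.boxplot(data, patch_artist=True)
        n_max = max(len(r.lines) for r in ranked)
        cmap = plt.get_cmap("Blues")
        for patch, r in zip(box["boxes"], ranked):
            patch.set_facecolor(cmap(0.3 + 0.7 * len(r.lines) / n_max))
        ax.set_xticks(range(1, len(ranked) + 1),
                      [";".join(r.lines) for r in ranked], rotation=90)
        ax.set_ylabel(f"mean {task} score")
        ax.set_title(f"{task}: subsample distributions by line set")
        return ax
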