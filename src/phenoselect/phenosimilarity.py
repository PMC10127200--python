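"""Phenosimilarity: how tightly an MOA's compounds cluster in profile space.

For an MOA with n compound profiles, two distance multisets are compared:

* ``within`` — all C(n, 2) pairwise Euclidean distances among the MOA's
  compound profiles;
* ``neighbor`` — for each MOA compound, its distances to its k nearest
  neighbors among *all* compound profiles in the library (self excluded, DMSO
  excluded; ties broken by compound identifier for determinism). By default
  k = n - 1 so the two multisets are size-comparable.

The phenosimilarity score is

    score = 1 - max(0, sup_x [F_neighbor(x) - F_within(x)])

which is 1 when the within-MOA distances match (or sit below) each compound's
local neighborhood scale — a tight, mutually-nearest cluster — and falls
toward 0 when the MOA is dispersed across neighborhoods dominated by other
compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import (
    CELL_LINE,
    COMPOUND,
    MOA,
    ROLE,
    ROLE_COMPOUND,
    TREATMENT,
    feature_columns,
)
from .phenoactivity import ecdf_sup_difference

__all__ = [
    "NeighborDistances",
    "neighbor_distances",
    "phenosimilarity_score",
    "score_all_phenosimilarity",
]


@dataclass
class NeighborDistances:
    """Within-MOA pairwise distances and per-compound nearest-neighbor distances."""

    within: np.ndarray
    neighbor: np.ndarray

    def __post_init__(self):
        self.within = np.asarray(self.within, float)
        self.neighbor = np.asarray(self.neighbor, float)
        if (self.within < 0).any() or (self.neighbor < 0).any():
            raise ValueError("distances must be non-negative")


def neighbor_distances(
    moa_ids,
    all_ids,
    all_profiles: np.ndarray,
    k: int | None = None,
) -> NeighborDistances:
    """Distance multisets for one MOA against the full compound library.

    ``all_ids``/``all_profiles`` list every compound profile in the library
    (one cell line); ``moa_ids`` selects the MOA's members. ``k=None`` uses
    the default k = n - 1 (n = MOA size), clipped to the library size - 1.
    """
    all_ids = list(all_ids)
    mat = np.atleast_2d(np.asarray(all_profiles, float))
    if len(all_ids) != mat.shape[0]:
        raise ValueError("all_ids and all_profiles disagree in length")
    index = {c: i for i, c in enumerate(all_ids)}
    members = [index[c] for c in moa_ids]
    n = len(members)
    m = len(all_ids)
    if n < 2:
        raise ValueError(f"MOA needs >= 2 member profiles, got {n}")
    if m < n + 1:
        raise ValueError(f"library needs >= {n + 1} compounds, got {m}")
    if k is None:
        k = min(n - 1, m - 1)
    if not 1 <= k <= m - 1:
        raise ValueError(f"k={k} out of range [1, {m - 1}]")

    member_mat = mat[members]
    within = pdist(member_mat)

    # distances from each member to every library compound
    dists = np.linalg.norm(mat[None, :, :] - member_mat[:, None, :], axis=2)
    order_ids = np.array(all_ids, dtype=object)
    neighbor = np.empty((n, k))
    for row, i in enumerate(members):
        d = dists[row].copy()
        mask = np.ones(m, dtype=bool)
        mask[i] = False  # self excluded
        cand = np.flatnonzero(mask)
        # sort by (distance, compound id) — deterministic under ties
        order = sorted(cand, key=lambda j: (d[j], str(order_ids[j])))
        neighbor[row] = d[order[:k]]
    return NeighborDistances(within=within, neighbor=neighbor.ravel())


def phenosimilarity_score(nd: NeighborDistances) -> float:
    """Overlap of within-MOA and nearest-neighbor distance distributions, in [0, 1]."""
    if nd.within.size == 0 or nd.neighbor.size == 0:
        raise ValueError("empty distance multiset")
    return 1.0 - max(0.0, ecdf_sup_difference(nd.neighbor, nd.within))


def score_all_phenosimilarity(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    min_moa_size: int = 2,
    k: int | None = None,
) -> pd.DataFrame:
    """Phenosimilarity score for every eligible (cell line, MOA) pair.

    Eligibility requires >= max(2, min_moa_size) profiled compounds in the
    cell line (pairwise distances need at least two members). The nearest-
    neighbor search runs over compound profiles only; DMSO self-profiles
    never participate. ``k=None`` uses the per-MOA default k = n - 1.
    """
    feats = feature_columns(profiles)
    moa_members = annotation.groupby(MOA)[COMPOUND].apply(list)
    rows = []
    for line, line_prof in profiles.groupby(CELL_LINE, sort=True):
        comp = line_prof.loc[line_prof[ROLE] == ROLE_COMPOUND]
        if comp.empty:
            continue
        ids = list(comp[TREATMENT])
        mat = comp[feats].to_numpy(float)
        present = set(ids)
        for moa in sorted(moa_members.index):
            members = [c for c in moa_members[moa] if c in present]
            n = len(members)
            if n < 2:
                if 0 < n < 2:
                    warnings.warn(
                        f"MOA {moa!r} has {n} compound(s) in line {line!r}; skipped"
                    )
                continue
            if n < min_moa_size or len(ids) < n + 1:
                continue
            nd = neighbor_distances(members, ids, mat, k=k)
            rows.append(
                {
                    CELL_LINE: line,
                    MOA: moa,
                    "n_compounds": n,
                    "score": phenosimilarity_score(nd),
                }
            )
    if not rows:
        raise ValueError("no eligible (cell line, MOA) pair to score")
    return pd.DataFrame(rows, columns=[CELL_LINE, MOA, "n_compounds", "score"])
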