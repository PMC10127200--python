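"""Phenoactivity: how far an MOA's compound profiles sit from the DMSO cloud.

Profiles of an MOA's compounds and of the DMSO wells are both reduced to
distances from the centroid of the DMSO point cloud in signed-KS profile
space. The phenoactivity score is the one-sided KS statistic

    score = max(0, sup_x [F_dmso(x) - F_moa(x)])

measuring how stochastically larger the MOA's centroid distances are than the
DMSO self-distances: 0 when the MOA cloud is indistinguishable from (or
closer than) the control cloud, 1 when every MOA compound lies beyond every
DMSO replicate.

A compound is called "outside the DMSO cloud" when its centroid distance
exceeds the median DMSO distance by more than one interquartile range
(linear-interpolation quartiles, strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CELL_LINE,
    MOA,
    COMPOUND,
    ROLE,
    ROLE_COMPOUND,
    ROLE_CONTROL,
    TREATMENT,
    feature_columns,
)

__all__ = [
    "DistanceSet",
    "dmso_centroid",
    "distance_set",
    "ecdf_sup_difference",
    "phenoactivity_score",
    "outside_cloud",
    "score_all_phenoactivity",
]


@dataclass
class DistanceSet:
    """Distances of MOA and DMSO profiles to the DMSO-cloud centroid."""

    reference_centroid: np.ndarray
    dmso_distances: np.ndarray
    moa_distances: np.ndarray

    def __post_init__(self):
        self.reference_centroid = np.asarray(self.reference_centroid, float)
        self.dmso_distances = np.asarray(self.dmso_distances, float)
        self.moa_distances = np.asarray(self.moa_distances, float)
        if self.dmso_distances.size < 2:
            raise ValueError("need >= 2 DMSO distances")
        if (self.dmso_distances < 0).any() or (self.moa_distances < 0).any():
            raise ValueError("distances must be non-negative")


def dmso_centroid(control_profiles: np.ndarray, method: str = "mean") -> np.ndarray:
    """Centroid of the control point cloud (coordinate-wise mean, or median)."""
    mat = np.atleast_2d(np.asarray(control_profiles, float))
    if mat.shape[0] < 2:
        raise ValueError(f"need >= 2 control profiles, got {mat.shape[0]}")
    if method == "mean":
        return mat.mean(axis=0)
    if method == "median":
        return np.median(mat, axis=0)
    raise ValueError(f"unknown centroid method {method!r}")


def _distances(mat: np.ndarray, centroid: np.ndarray, metric: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, float))
    if mat.shape[1] != centroid.size:
        raise ValueError(
            f"dimension mismatch: profiles have {mat.shape[1]} features, "
            f"centroid has {centroid.size}"
        )
    if metric == "euclidean":
        return np.linalg.norm(mat - centroid, axis=1)
    if metric == "cosine":
        num = mat @ centroid
        den = np.linalg.norm(mat, axis=1) * np.linalg.norm(centroid)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(den > 0, num / den, 1.0)
        return 1.0 - cos
    raise ValueError(f"unknown distance metric {metric!r}")


def distance_set(
    moa_profiles: np.ndarray,
    control_profiles: np.ndarray,
    centroid_method: str = "mean",
    metric: str = "euclidean",
) -> DistanceSet:
    """Distances of each MOA profile and each control profile to the DMSO centroid."""
    centroid = dmso_centroid(control_profiles, centroid_method)
    return DistanceSet(
        reference_centroid=centroid,
        dmso_distances=_distances(control_profiles, centroid, metric),
        moa_distances=_distances(moa_profiles, centroid, metric),
    )


def ecdf_sup_difference(a, b) -> float:
    """``sup_x [F_a(x) - F_b(x)]`` over the pooled sample points (one-sided KS)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample in ECDF comparison")
    a_sorted, b_sorted = np.sort(a), np.sort(b)
    grid = np.concatenate([a_sorted, b_sorted])
    f_a = np.searchsorted(a_sorted, grid, side="right") / a.size
    f_b = np.searchsorted(b_sorted, grid, side="right") / b.size
    return float((f_a - f_b).max())


def phenoactivity_score(ds: DistanceSet) -> float:
    """One-sided KS separation of MOA distances above DMSO distances, in [0, 1]."""
    if ds.moa_distances.size == 0:
        raise ValueError("MOA distance multiset is empty")
    return max(0.0, ecdf_sup_difference(ds.dmso_distances, ds.moa_distances))


def outside_cloud(ds: DistanceSet) -> tuple[float, int]:
    """IQR rule: threshold = median(DMSO) + IQR(DMSO); count MOA distances above it.

    Quartiles use linear interpolation; the comparison is strict, so with a
    constant DMSO multiset any MOA distance above that constant is outside.
    """
    q1, med, q3 = np.quantile(ds.dmso_distances, [0.25, 0.5, 0.75])
    threshold = float(med + (q3 - q1))
    n_outside = int((ds.moa_distances > threshold).sum())
    return threshold, n_outside


def score_all_phenoactivity(
    profiles: pd.DataFrame,
    annotation: pd.DataFrame,
    min_moa_size: int = 1,
    centroid_method: str = "mean",
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Phenoactivity score for every (cell line, MOA) pair.

    ``min_moa_size`` filters MOAs by the number of annotated compounds with a
    profile in that cell line (the reporting convention is >= 5; computation
    defaults to 1). Returns a score table with columns
    cell_line, moa, n_compounds, score, n_outside, threshold.
    """
    feats = feature_columns(profiles)
    moa_members = annotation.groupby(MOA)[COMPOUND].apply(list)
    rows = []
    any_overlap = False
    for line, line_prof in profiles.groupby(CELL_LINE, sort=True):
        ctrl = line_prof.loc[line_prof[ROLE] == ROLE_CONTROL]
        comp = line_prof.loc[line_prof[ROLE] == ROLE_COMPOUND]
        if len(ctrl) < 2 or comp.empty:
            continue
        centroid = dmso_centroid(ctrl[feats].to_numpy(float), centroid_method)
        dmso_d = _distances(ctrl[feats].to_numpy(float), centroid, metric)
        comp_mat = comp[feats].to_numpy(float)
        comp_index = {t: i for i, t in enumerate(comp[TREATMENT])}
        for moa in sorted(moa_members.index):
            idx = [comp_index[c] for c in moa_members[moa] if c in comp_index]
            if idx:
                any_overlap = True
            if len(idx) < max(1, min_moa_size):
                continue
            moa_d = _distances(comp_mat[idx], centroid, metric)
            ds = DistanceSet(centroid, dmso_d, moa_d)
            threshold, n_outside = outside_cloud(ds)
            rows.append(
                {
                    CELL_LINE: line,
                    MOA: moa,
                    "n_compounds": len(idx),
                    "score": phenoactivity_score(ds),
                    "n_outside": n_outside,
                    "threshold": threshold,
                }
            )
    if not any_overlap:
        raise ValueError("no overlap between annotated compounds and profiled treatments")
    return pd.DataFrame(
        rows, columns=[CELL_LINE, MOA, "n_compounds", "score", "n_outside", "threshold"]
    )
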