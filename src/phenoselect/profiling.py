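"""Signed Kolmogorov-Smirnov phenotypic profiles.

A treatment's phenotypic profile in one cell line is the vector of per-feature
signed two-sample KS statistics comparing the treated cell population with
matched DMSO control cells. The magnitude of each entry is the classical KS
statistic (sup-norm distance between the two empirical CDFs); the sign encodes
the direction of the dominant ECDF branch, positive when the treated
population is stochastically larger. Because KS is rank-based per feature, no
feature standardisation is needed before profiling.

Control matching is per-plate by default: the control population for a
treatment is every DMSO cell on the plate(s) hosting that treatment's wells.
DMSO wells get their own "self" profiles, computed leave-one-well-out against
the remaining DMSO cells on the same plate, so that the control point cloud is
non-degenerate.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    CELL_LINE,
    PLATE,
    ROLE,
    ROLE_COMPOUND,
    ROLE_CONTROL,
    TREATMENT,
    WELL,
    feature_columns,
)

__all__ = [
    "signed_ks",
    "signed_ks_profile",
    "build_profile",
    "build_control_profiles",
    "profile_screen",
]


def signed_ks(treated, control) -> float:
    """Signed two-sample KS statistic between two samples of reals.

    Let ``D+ = sup_x [F_control(x) - F_treated(x)]`` and
    ``D- = sup_x [F_treated(x) - F_control(x)]`` over the pooled sample
    points. Returns ``+D+`` when ``D+ >= D-`` (treated stochastically larger),
    else ``-D-``. ``|signed_ks|`` equals the usual two-sided KS statistic.
    """
    t = np.asarray(treated, dtype=float).ravel()
    c = np.asarray(control, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("treated sample is empty")
    if c.size == 0:
        raise ValueError("control sample is empty")
    return _signed_ks_sorted(np.sort(t), np.sort(c))


def _signed_ks_sorted(t_sorted: np.ndarray, c_sorted: np.ndarray) -> float:
    grid = np.concatenate([t_sorted, c_sorted])
    f_t = np.searchsorted(t_sorted, grid, side="right") / t_sorted.size
    f_c = np.searchsorted(c_sorted, grid, side="right") / c_sorted.size
    diff = f_c - f_t
    d_plus = diff.max()  # treated shifted up
    d_minus = -diff.min()  # treated shifted down
    return float(d_plus) if d_plus >= d_minus else -float(d_minus)


def signed_ks_profile(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Column-wise signed KS between two (cells x features) matrices."""
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if treated.shape[1] != control.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {treated.shape[1]} vs {control.shape[1]}"
        )
    if treated.shape[0] == 0:
        raise ValueError("treated sample is empty")
    if control.shape[0] == 0:
        raise ValueError("control sample is empty")
    t_sorted = np.sort(treated, axis=0)
    c_sorted = np.sort(control, axis=0)
    return np.array(
        [
            _signed_ks_sorted(t_sorted[:, j], c_sorted[:, j])
            for j in range(treated.shape[1])
        ]
    )


def _profile_row(cell_line, treatment, role, vector, feats, n_treated, n_control):
    row = {
        CELL_LINE: cell_line,
        TREATMENT: treatment,
        ROLE: role,
        "n_cells_treated": int(n_treated),
        "n_cells_control": int(n_control),
    }
    row.update(dict(zip(feats, vector)))
    return row


def build_profile(
    cells: pd.DataFrame,
    treatment: str,
    control_policy: str = "plate",
) -> pd.Series:
    """Phenotypic profile of one treatment within one cell line.

    Cells are pooled across the treatment's replicate wells; the control
    population is every DMSO cell on the same plate(s) (``control_policy =
    "plate"``) or every DMSO cell in the table (``"global"``).
    """
    lines = cells[CELL_LINE].unique()
    if len(lines) != 1:
        raise ValueError(f"build_profile expects one cell line, got {list(lines)}")
    feats = feature_columns(cells)
    treated = cells.loc[cells[TREATMENT] == treatment]
    if treated.empty:
        raise ValueError(f"no cells for treatment {treatment!r}")
    if control_policy == "plate":
        plates = treated[PLATE].unique()
        ctrl = cells.loc[(cells[ROLE] == ROLE_CONTROL) & cells[PLATE].isin(plates)]
        if ctrl.empty:
            raise ValueError(
                f"no control cells on plates {sorted(plates)} for treatment {treatment!r}"
            )
    elif control_policy == "global":
        ctrl = cells.loc[cells[ROLE] == ROLE_CONTROL]
        if ctrl.empty:
            raise ValueError("no control cells in table")
    else:
        raise ValueError(f"unknown control_policy {control_policy!r}")
    vector = signed_ks_profile(
        treated[feats].to_numpy(float), ctrl[feats].to_numpy(float)
    )
    return pd.Series(
        _profile_row(lines[0], treatment, ROLE_COMPOUND, vector, feats, len(treated), len(ctrl))
    )


def build_control_profiles(cells: pd.DataFrame) -> pd.DataFrame:
    """Leave-one-well-out DMSO self-profiles for one cell line.

    Each DMSO well is profiled against all *other* DMSO cells on its plate, so
    the control point cloud reflects well-to-well variability instead of
    collapsing to zero. Plates with a single DMSO well are skipped with a
    warning. Profile treatment identifiers are ``DMSO@<plate>/<well>``.
    """
    lines = cells[CELL_LINE].unique()
    if len(lines) != 1:
        raise ValueError(f"build_control_profiles expects one cell line, got {list(lines)}")
    feats = feature_columns(cells)
    ctrl = cells.loc[cells[ROLE] == ROLE_CONTROL]
    rows = []
    for plate, plate_ctrl in ctrl.groupby(PLATE, sort=True):
        wells = sorted(plate_ctrl[WELL].unique())
        if len(wells) < 2:
            warnings.warn(
                f"plate {plate!r} has a single DMSO well; skipped in control cloud"
            )
            continue
        mat = plate_ctrl[feats].to_numpy(float)
        well_labels = plate_ctrl[WELL].to_numpy()
        for well in wells:
            mask = well_labels == well
            vector = signed_ks_profile(mat[mask], mat[~mask])
            rows.append(
                _profile_row(
                    lines[0],
                    f"DMSO@{plate}/{well}",
                    ROLE_CONTROL,
                    vector,
                    feats,
                    int(mask.sum()),
                    int((~mask).sum()),
                )
            )
    return pd.DataFrame(rows, columns=_profile_frame_columns(feats))


def _profile_frame_columns(feats: Sequence[str]) -> list[str]:
    return [CELL_LINE, TREATMENT, ROLE, "n_cells_treated", "n_cells_control", *feats]


def profile_screen(
    cells: pd.DataFrame,
    control_policy: str = "plate",
    per_well: bool = False,
) -> pd.DataFrame:
    """Profiles for every compound treatment and every DMSO well, all cell lines.

    Replicate wells of a compound are pooled into one profile per cell line by
    default; with ``per_well=True`` each compound well yields its own profile
    named ``<treatment>@<plate>/<well>``.
    """
    feats = feature_columns(cells)
    frames = []
    for line, line_cells in cells.groupby(CELL_LINE, sort=True):
        rows = []
        comp = line_cells.loc[line_cells[ROLE] == ROLE_COMPOUND]
        if per_well:
            groups = comp.groupby([TREATMENT, PLATE, WELL], sort=True)
        else:
            groups = comp.groupby(TREATMENT, sort=True)
        for key, treated in groups:
            if per_well:
                treatment, plate, well = key
                name = f"{treatment}@{plate}/{well}"
                plates = [plate]
            else:
                treatment = name = key
                plates = treated[PLATE].unique()
            if control_policy == "plate":
                ctrl = line_cells.loc[
                    (line_cells[ROLE] == ROLE_CONTROL) & line_cells[PLATE].isin(plates)
                ]
            else:
                ctrl = line_cells.loc[line_cells[ROLE] == ROLE_CONTROL]
            if ctrl.empty:
                raise ValueError(
                    f"no control cells for treatment {treatment!r} "
                    f"(cell line {line!r}, plates {sorted(plates)})"
                )
            vector = signed_ks_profile(
                treated[feats].to_numpy(float), ctrl[feats].to_numpy(float)
            )
            rows.append(
                _profile_row(line, name, ROLE_COMPOUND, vector, feats, len(treated), len(ctrl))
            )
        frames.append(pd.DataFrame(rows, columns=_profile_frame_columns(feats)))
        frames.append(build_control_profiles(line_cells))
    out = pd.concat(frames, ignore_index=True)
    return out
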