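"""Tabular input/output and the shared domain schema.

Three kinds of delimited-text tables flow through the pipeline:

* **cell feature tables** — one row per segmented cell, metadata columns
  (cell line, plate, well, treatment, role) plus ``D`` numeric feature
  columns (77 for a Cell-Painting-style panel, but any panel works);
* **MOA annotations** — compound -> mechanism-of-action class, one row per
  (compound, MOA) pair so multi-MOA compounds appear on several rows;
* **score tables** — one row per (cell line, MOA) with the phenoactivity or
  phenosimilarity score and supporting counts.

Column names in input files are configurable through :class:`TableSchema`;
internally every table is normalised to the canonical column names below so
downstream modules never see user-specific headers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# canonical metadata column names (post-normalisation)
CELL_LINE = "cell_line"
PLATE = "plate"
WELL = "well"
TREATMENT = "treatment"
ROLE = "role"
ROLE_COMPOUND = "compound"
ROLE_CONTROL = "control"
COMPOUND = "compound"
MOA = "moa"

CELL_META_COLUMNS = (CELL_LINE, PLATE, WELL, TREATMENT, ROLE)
PROFILE_META_COLUMNS = (CELL_LINE, TREATMENT, ROLE, "n_cells_treated", "n_cells_control")
SCORE_COLUMNS = (CELL_LINE, MOA, "n_compounds", "score")


class SchemaError(ValueError):
    """A mandatory metadata column is missing or misconfigured."""


class FeatureParseError(ValueError):
    """A feature cell holds a non-numeric, non-missing value."""


@dataclass
class TableSchema:
    """Maps the columns of a user's cell feature table onto the canonical schema.

    Parameters
    ----------
    cell_line, plate, well, treatment
        Header names of the mandatory metadata columns in the input file.
    role
        Header of the compound/control role column, or ``None`` to derive the
        role from ``treatment == control_label``.
    feature_columns
        Explicit list of feature column headers; ``None`` means "every column
        that is not metadata", in file order.
    control_label
        Treatment identifier of the vehicle control (default ``"DMSO"``).
    """

    cell_line: str = CELL_LINE
    plate: str = PLATE
    well: str = WELL
    treatment: str = TREATMENT
    role: str | None = ROLE
    feature_columns: list[str] | None = None
    control_label: str = "DMSO"
    role_compound: str = ROLE_COMPOUND
    role_control: str = ROLE_CONTROL

    @classmethod
    def from_dict(cls, d: Mapping) -> "TableSchema":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**d)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a canonical cell/profile table (non-metadata columns)."""
    meta = set(CELL_META_COLUMNS) | set(PROFILE_META_COLUMNS)
    return [c for c in table.columns if c not in meta]


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """The feature block of a canonical table as a float array."""
    return table[feature_columns(table)].to_numpy(dtype=float)


def read_cell_table(path, schema: TableSchema | Mapping | None = None) -> pd.DataFrame:
    """Read and validate a per-cell feature table.

    Rows with any missing feature value are dropped (never imputed); the drop
    count is logged and stored in ``result.attrs["n_dropped"]``. Non-numeric
    feature entries raise :class:`FeatureParseError` with the offending row.

    Returns a DataFrame with canonical metadata columns followed by the
    feature columns.
    """
    if schema is None:
        schema = TableSchema()
    elif isinstance(schema, Mapping):
        schema = TableSchema.from_dict(schema)

    raw = pd.read_csv(path, dtype=str)
    mandatory = {
        CELL_LINE: schema.cell_line,
        PLATE: schema.plate,
        WELL: schema.well,
        TREATMENT: schema.treatment,
    }
    for canonical, name in mandatory.items():
        if name not in raw.columns:
            raise SchemaError(
                f"cell table {path!r} lacks mandatory column {name!r} ({canonical})"
            )
    if schema.role is not None and schema.role not in raw.columns:
        raise SchemaError(f"cell table {path!r} lacks role column {schema.role!r}")

    if schema.feature_columns is not None:
        feats = list(schema.feature_columns)
        missing = [c for c in feats if c not in raw.columns]
        if missing:
            raise SchemaError(f"feature columns absent from {path!r}: {missing}")
    else:
        meta_names = set(mandatory.values())
        if schema.role is not None:
            meta_names.add(schema.role)
        feats = [c for c in raw.columns if c not in meta_names]
    if not feats:
        raise SchemaError(f"cell table {path!r} has no feature columns")

    out = pd.DataFrame(
        {
            CELL_LINE: raw[schema.cell_line].astype(str),
            PLATE: raw[schema.plate].astype(str),
            WELL: raw[schema.well].astype(str),
            TREATMENT: raw[schema.treatment].astype(str),
        }
    )
    if schema.role is not None:
        role_map = {schema.role_compound: ROLE_COMPOUND, schema.role_control: ROLE_CONTROL}
        roles = raw[schema.role].map(role_map)
        bad = raw[schema.role][roles.isna()].unique()
        if len(bad):
            raise SchemaError(f"unrecognised role values {list(bad)} in {path!r}")
        out[ROLE] = roles
    else:
        out[ROLE] = np.where(
            out[TREATMENT] == schema.control_label, ROLE_CONTROL, ROLE_COMPOUND
        )

    for col in feats:
        cell = raw[col]
        missing_mask = cell.isna() | (cell.str.strip() == "")
        values = pd.to_numeric(cell, errors="coerce")
        bad = values.isna() & ~missing_mask
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FeatureParseError(
                f"non-numeric value {cell.iloc[row]!r} in feature column {col!r}, "
                f"data row {row}"
            )
        out[col] = values

    complete = ~out[feats].isna().any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d cell rows with missing feature values", n_dropped)
    out = out.loc[complete].reset_index(drop=True)
    out.attrs["n_dropped"] = n_dropped
    return out


def read_annotations(path) -> pd.DataFrame:
    """Read a compound -> MOA annotation table.

    The first two columns are interpreted as (compound, moa) unless columns
    named ``compound``/``moa`` exist. A compound annotated with k MOAs appears
    in k rows and contributes its profile to each MOA point cloud. Exact
    duplicate rows are dropped with a warning; empty labels are an error.
    """
    raw = pd.read_csv(path, dtype=str)
    if COMPOUND in raw.columns and MOA in raw.columns:
        ann = raw[[COMPOUND, MOA]].copy()
    else:
        if raw.shape[1] < 2:
            raise SchemaError(f"annotation table {path!r} needs two columns")
        ann = raw.iloc[:, :2].copy()
        ann.columns = [COMPOUND, MOA]
    return validate_annotations(ann, source=str(path))


def validate_annotations(ann: pd.DataFrame, source: str = "annotation table") -> pd.DataFrame:
    """Validate (compound, moa) pairs: non-empty labels, deduplicated rows."""
    ann = ann[[COMPOUND, MOA]].astype(str)
    empty = ann[MOA].str.strip().eq("") | ann[MOA].str.lower().eq("nan")
    empty |= ann[COMPOUND].str.strip().eq("") | ann[COMPOUND].str.lower().eq("nan")
    if empty.any():
        row = int(np.flatnonzero(empty.to_numpy())[0])
        raise ValueError(f"{source}: empty compound or MOA label at data row {row}")
    n_dup = int(ann.duplicated().sum())
    if n_dup:
        warnings.warn(f"{source}: dropped {n_dup} duplicate (compound, moa) rows")
        ann = ann.drop_duplicates()
    return ann.reset_index(drop=True)


def write_scores(table: pd.DataFrame, path) -> None:
    """Write a score table as CSV, deterministically ordered (cell_line, moa)."""
    cols = [c for c in (*SCORE_COLUMNS, "n_outside", "threshold") if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    out = table[cols + extra].sort_values([CELL_LINE, MOA], kind="mergesort")
    out.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={CELL_LINE: str, MOA: str})
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"score table {path!r} lacks columns {missing}")
    return table


def write_profiles(profiles: pd.DataFrame, path) -> None:
    """Write phenotypic profiles as CSV (metadata columns then feature columns)."""
    cols = list(PROFILE_META_COLUMNS) + feature_columns(profiles)
    profiles[cols].to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={CELL_LINE: str, TREATMENT: str, ROLE: str})
    missing = [c for c in PROFILE_META_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"profile table {path!r} lacks columns {missing}")
    feats = feature_columns(table)
    vec = table[feats].to_numpy(dtype=float)
    if np.abs(vec).max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError(f"profile table {path!r} has entries outside [-1, 1]")
    return table


def load_config(path) -> dict:
    """Load a YAML run configuration (paths, schema section, analysis parameters)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path!r} must be a mapping")
    return cfg
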