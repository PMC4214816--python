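"""Typed input tables and result writers.

Every analysis in this package consumes four aligned tables, all delimited
text (comma or tab) with a header row and the sampling-point identifier in
the first column:

* a community matrix (points x species; abundance counts, dry biomass in
  grams, or 0/1 presence),
* an environmental matrix (points x descriptors),
* a coordinate table (points x UTM easting/northing in metres),
* a hierarchy table mapping each point to its site, area and region.

Row order is canonicalised to the hierarchy table's point order at load
time; all downstream modules assume aligned ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Hierarchy",
    "CommunityMatrix",
    "LEVELS",
    "read_table",
    "pool_to_level",
    "presence_from_counts",
    "write_results",
    "read_delimited",
]

#: the nested scale ladder, finest to coarsest
LEVELS = ("point", "site", "area", "region", "total")

_LEVEL_COLUMN = {"site": "site_id", "area": "area_id", "region": "region_id"}


class SchemaError(ValueError):
    """Raised when an input table violates the package's schema contract."""


@dataclass(frozen=True)
class Hierarchy:
    """Nested point -> site -> area -> region labelling.

    Parameters
    ----------
    frame : pandas.DataFrame
        Indexed by unique point id, with columns ``site_id``, ``area_id``
        and ``region_id``.  The ladder must be strictly nested: a site
        belongs to exactly one area, an area to exactly one region.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in ("site_id", "area_id", "region_id") if c not in f.columns]
        if missing:
            raise SchemaError(f"hierarchy table missing columns: {missing}")
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate point ids in hierarchy: {dup}")
        # strict nesting: each child label maps to exactly one parent
        for child, parent in (("site_id", "area_id"), ("area_id", "region_id")):
            counts = f.groupby(child, observed=True)[parent].nunique()
            bad = counts[counts > 1].index.tolist()
            if bad:
                raise SchemaError(
                    f"hierarchy not nested: {child} value(s) {bad} occur under "
                    f"more than one {parent}"
                )

    @property
    def point_ids(self) -> pd.Index:
        return self.frame.index

    def labels(self, level: str) -> pd.Series:
        """Unit label of every point at ``level`` (point/site/area/region/total)."""
        if level == "point":
            return pd.Series(self.frame.index, index=self.frame.index, name="point_id")
        if level == "total":
            return pd.Series("total", index=self.frame.index, name="total")
        try:
            return self.frame[_LEVEL_COLUMN[level]]
        except KeyError:
            raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}") from None

    def units(self, level: str) -> list:
        """Ordered unique unit labels at ``level`` (first-appearance order)."""
        return list(dict.fromkeys(self.labels(level)))

    def n_units(self, level: str) -> int:
        return len(self.units(level))


@dataclass(frozen=True)
class CommunityMatrix:
    """Points x species table of non-negative values (the Y of every analysis).

    ``measure`` records what the values are: ``"abundance"`` (individuals),
    ``"biomass"`` (g dry mass) or ``"presence"`` (0/1).
    """

    data: pd.DataFrame
    measure: str = "abundance"

    def __post_init__(self) -> None:
        if self.measure not in ("abundance", "biomass", "presence"):
            raise ValueError(f"unknown measure {self.measure!r}")
        d = self.data
        if d.index.has_duplicates or d.columns.has_duplicates:
            raise SchemaError("duplicate row or column labels in community matrix")
        vals = d.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise SchemaError("non-finite values in community matrix")
        if (vals < 0).any():
            raise SchemaError("negative values in community matrix")
        if self.measure == "presence" and not np.isin(vals, (0.0, 1.0)).all():
            raise SchemaError("presence matrix must contain only 0/1")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def point_ids(self) -> pd.Index:
        return self.data.index

    @property
    def species(self) -> pd.Index:
        return self.data.columns


def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text(encoding="utf-8").splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_delimited(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with the id in the first column."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def _require_numeric(frame: pd.DataFrame, what: str) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = out.index[bad][0]
            raise SchemaError(f"non-numeric cell in {what} at row {row!r}, column {col!r}")
        if coerced.isna().any():
            row = out.index[coerced.isna()][0]
            raise SchemaError(f"missing value in {what} at row {row!r}, column {col!r}")
        out[col] = coerced.astype(float)
    return out


def read_table(path, kind: str, measure: str = "abundance"):
    """Read and validate one of the four input tables.

    Parameters
    ----------
    path : path-like
        Delimited text file, header row, point id first.
    kind : {"community", "env", "coords", "hierarchy"}
    measure : str
        For ``kind="community"``: what the values represent.

    Returns
    -------
    CommunityMatrix, pandas.DataFrame or Hierarchy depending on ``kind``.
    """
    frame = read_delimited(path)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate point ids in {kind} table: {dup}")
    if kind == "community":
        return CommunityMatrix(_require_numeric(frame, "community table"), measure=measure)
    if kind == "env":
        return _require_numeric(frame, "environmental table")
    if kind == "coords":
        frame = _require_numeric(frame, "coordinate table")
        if frame.shape[1] != 2:
            raise SchemaError(
                f"coordinate table must have exactly 2 columns, got {frame.shape[1]}"
            )
        return frame
    if kind == "hierarchy":
        return Hierarchy(frame.astype(str))
    raise ValueError(f"unknown table kind {kind!r}")


def align_to_hierarchy(table, hierarchy: Hierarchy):
    """Reorder a table's rows to the hierarchy's point order (the canonical order)."""
    ids = hierarchy.point_ids
    frame = table.data if isinstance(table, CommunityMatrix) else table
    missing = ids.difference(frame.index)
    if len(missing):
        raise SchemaError(f"points missing from table: {missing.tolist()}")
    extra = frame.index.difference(ids)
    if len(extra):
        raise SchemaError(f"points absent from hierarchy: {extra.tolist()}")
    out = frame.loc[ids]
    if isinstance(table, CommunityMatrix):
        return CommunityMatrix(out, measure=table.measure)
    return out


def pool_to_level(M: CommunityMatrix, H: Hierarchy, level: str) -> CommunityMatrix:
    """Pool a community matrix to a coarser rung of the scale ladder.

    Abundance and biomass are summed within each unit; presence is pooled by
    logical OR.  Rows of the result are the units of ``level`` in
    first-appearance order.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    if level == "point":
        return M
    labels = H.labels(level)
    aligned = align_to_hierarchy(M, H)
    grouped = aligned.data.groupby(labels.to_numpy(), sort=False).sum()
    if M.measure == "presence":
        grouped = (grouped > 0).astype(float)
    return CommunityMatrix(grouped, measure=M.measure)


def presence_from_counts(M: CommunityMatrix) -> CommunityMatrix:
    """Convert abundance or biomass to a 0/1 presence matrix."""
    if M.measure == "presence":
        raise ValueError("matrix is already a presence matrix")
    return CommunityMatrix((M.data > 0).astype(float), measure="presence")


def write_results(result, path) -> None:
    """Write any result object (or DataFrame) as tab-delimited text.

    Result objects expose ``to_frame()``; frames are written with full float
    precision so a write/read round trip is the identity.
    """
    frame = result.to_frame() if hasattr(result, "to_frame") else result
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialise {type(result).__name__}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format="%.17g")
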