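"""Reduce raw per-quadrant habitat measurements to one value per point.

Habitat structure is measured with a point-centred quarter protocol: the
sampling point is split into four quadrants and each descriptor (tree and
shrub sizes, cover percentages, litter, slope ...) is measured once per
quadrant (litter height five times; altitude and slope once per point).
Cover descriptors are recorded as ordinal classes and mapped to interval
midpoints.  Each descriptor is then reduced to a central value — the mean
when the pooled sample looks normal under a Shapiro-Wilk test, the median
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COVER_CLASSES",
    "class_midpoint",
    "basal_area_from_circumference",
    "normality_gate",
    "summarize_point",
    "summarize_env",
]

#: ordered cover classes (%) used for canopy, litter, green cover, exposed soil
COVER_CLASSES = ("0-5", "6-25", "26-50", "51-75", "76-95", "96-100")

_MIDPOINTS = {
    label: (float(label.split("-")[0]) + float(label.split("-")[1])) / 2.0
    for label in COVER_CLASSES
}
# accept en-dash variants as typed in field sheets
_MIDPOINTS.update({k.replace("-", "–"): v for k, v in list(_MIDPOINTS.items())})


def class_midpoint(label: str) -> float:
    """Midpoint (%) of an ordinal cover class such as ``"26-50"`` -> 38.0."""
    try:
        return _MIDPOINTS[str(label).strip()]
    except KeyError:
        raise ValueError(
            f"unknown cover class {label!r}; expected one of {COVER_CLASSES}"
        ) from None


def basal_area_from_circumference(circumference: float) -> float:
    """Basal area from trunk circumference, via the area of the circle.

    For circumference C the enclosed circle has area C**2 / (4*pi); units are
    the square of the circumference's unit.
    """
    c = float(circumference)
    if c < 0:
        raise ValueError(f"negative circumference: {c}")
    return c * c / (4.0 * math.pi)


def normality_gate(x, alpha: float = 0.05) -> str:
    """Choose the central-tendency statistic for a sample of measurements.

    Returns ``"mean"`` when a Shapiro-Wilk test does not reject normality at
    ``alpha``, else ``"median"``.  Constant samples and samples with fewer
    than 3 values pass as ``"mean"`` (the test is undefined; mean and median
    coincide for constants anyway).
    """
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3 or np.ptp(arr) == 0:
        return "mean"
    _, p = stats.shapiro(arr)
    return "mean" if p >= alpha else "median"


def _reduce(values: np.ndarray, statistic: str) -> float:
    return float(np.mean(values) if statistic == "mean" else np.median(values))


def summarize_point(records: pd.DataFrame, gates: dict[str, str]) -> pd.Series:
    """Reduce one point's quadrant records to a single row of descriptors.

    Parameters
    ----------
    records : DataFrame
        Long format with columns ``variable`` and ``value`` (already numeric;
        cover classes mapped through :func:`class_midpoint` beforehand).
    gates : mapping variable -> {"mean", "median"}
        The per-descriptor statistic chosen by :func:`normality_gate`.
    """
    out = {}
    for variable, grp in records.groupby("variable", sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"descriptor {variable!r} has no usable measurements")
        out[variable] = _reduce(vals, gates.get(variable, "mean"))
    return pd.Series(out)


def summarize_env(
    raw: pd.DataFrame,
    alpha: float = 0.05,
    cover_variables: tuple[str, ...] = (),
    expected: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Build the per-point environmental matrix from long-format quadrant data.

    ``raw`` has columns ``point_id, variable, quadrant, value``.  Cover-class
    variables (named in ``cover_variables``) hold class labels and are mapped
    to midpoints first.  The Shapiro-Wilk gate is applied once per descriptor
    across all points (n = 4 per point gives the test no power), then each
    point's replicates are reduced with the chosen statistic.  Descriptors
    measured once per point (altitude, land slope) pass through unchanged.
    """
    required = {"point_id", "variable", "value"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw quadrant table needs columns {sorted(required)}")
    work = raw.copy()
    in_cover = work["variable"].isin(cover_variables)
    if in_cover.any():
        work.loc[in_cover, "value"] = work.loc[in_cover, "value"].map(class_midpoint)
    work["value"] = pd.to_numeric(work["value"])

    gates = {
        var: normality_gate(grp["value"].to_numpy(dtype=float), alpha=alpha)
        for var, grp in work.groupby("variable", sort=False)
    }

    rows = {}
    for point, grp in work.groupby("point_id", sort=False):
        if expected is not None:
            present = set(grp["variable"])
            missing = [v for v in expected if v not in present]
            if missing:
                raise ValueError(f"point {point!r} missing descriptor(s): {missing}")
        rows[point] = summarize_point(grp, gates)
    env = pd.DataFrame.from_dict(rows, orient="index")
    env.index.name = "point_id"
    if env.isna().any().any():
        bad = env.columns[env.isna().any()].tolist()
        raise ValueError(f"descriptor(s) {bad} missing for some points")
    return env
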