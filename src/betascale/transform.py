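"""Hellinger transformation, linear spatial detrending and the trend test.

All ordinations in this package run on Hellinger-transformed community data
(row-wise square roots of relative abundances), which makes Euclidean
distance ecologically meaningful for species tables.  A significant linear
trend on the geographic coordinates is removed before spatial eigenfunction
analysis, otherwise broad-scale trend leaks into every spatial predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import CommunityMatrix

__all__ = ["TransformedMatrix", "hellinger", "detrend", "trend_test", "TrendTest"]


@dataclass(frozen=True)
class TransformedMatrix:
    """A points x species matrix after Hellinger transformation.

    ``detrended`` flags whether linear coordinate trend has been removed
    (after which values are residuals and may be negative).
    """

    data: pd.DataFrame
    measure: str
    detrended: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def point_ids(self) -> pd.Index:
        return self.data.index


def _hellinger_values(values: np.ndarray) -> np.ndarray:
    if (values < 0).any():
        raise ValueError("Hellinger transformation requires non-negative values")
    totals = values.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)  # all-zero rows stay all-zero
    return np.sqrt(values / safe)


def hellinger(M: CommunityMatrix) -> TransformedMatrix:
    """Hellinger-transform a community matrix: y'_ij = sqrt(y_ij / row total).

    All-zero rows (points that caught nothing) are retained as zero vectors
    so the hierarchy stays aligned; downstream modules decide their handling.
    """
    out = pd.DataFrame(
        _hellinger_values(M.values), index=M.data.index, columns=M.data.columns
    )
    return TransformedMatrix(out, measure=M.measure)


def _trend_design(coords: pd.DataFrame) -> np.ndarray:
    """Centered coordinate design matrix; errors on degenerate geometry."""
    C = coords.to_numpy(dtype=float)
    C = C - C.mean(axis=0)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("coordinates are constant or collinear; cannot detrend")
    return C


def detrend(Y: TransformedMatrix, coords: pd.DataFrame) -> TransformedMatrix:
    """Remove the linear spatial trend from every species column.

    Each column is replaced by its residual from an ordinary least-squares
    fit on centred easting and northing (with intercept).  The operation is
    the orthogonal projection off the trend space, hence idempotent.
    """
    if list(Y.data.index) != list(coords.index):
        raise ValueError("rows of Y and coords are not aligned")
    n = len(Y.data)
    if n <= 3:
        raise ValueError("detrending needs more than 3 points")
    C = _trend_design(coords)
    Q, _ = np.linalg.qr(C)
    Yc = Y.values - Y.values.mean(axis=0)
    resid = Yc - Q @ (Q.T @ Yc)
    out = pd.DataFrame(resid, index=Y.data.index, columns=Y.data.columns)
    return replace(Y, data=out, detrended=True)


@dataclass(frozen=True)
class TrendTest:
    """Permutation test of a linear coordinate trend in community data."""

    f: float
    df: int
    p: float
    nperm: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"F = {self.f:.2f}; df = {self.df}; p = {self.p:.4g} ({self.nperm} permutations)"


def trend_test(
    Y: TransformedMatrix,
    coords: pd.DataFrame,
    nperm: int = 999,
    seed: int | None = None,
) -> TrendTest:
    """Redundancy analysis of Y on the two centred coordinates.

    F = (SS_fit / 2) / (SS_res / (n - 3)); the p-value comes from ``nperm``
    row permutations of Y with the add-one convention
    p = (#{F_perm >= F_obs} + 1) / (nperm + 1).
    """
    if list(Y.data.index) != list(coords.index):
        raise ValueError("rows of Y and coords are not aligned")
    C = _trend_design(coords)
    Q, _ = np.linalg.qr(C)
    n, m = C.shape
    Yc = Y.values - Y.values.mean(axis=0)
    ss_total = float(np.sum(Yc * Yc))
    if ss_total == 0:
        raise ValueError("community matrix is constant; no trend to test")

    def f_stat(Ymat: np.ndarray) -> float:
        proj = Q.T @ Ymat
        ss_fit = float(np.sum(proj * proj))
        ss_res = max(float(np.sum(Ymat * Ymat)) - ss_fit, 0.0)
        if ss_res == 0.0:
            return np.inf
        return (ss_fit / m) / (ss_res / (n - m - 1))

    f_obs = f_stat(Yc)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        if f_stat(Yc[perm]) >= f_obs:
            hits += 1
    p = (hits + 1) / (nperm + 1)
    return TrendTest(f=f_obs, df=m, p=p, nperm=nperm)
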