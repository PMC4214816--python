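"""Staggered-block spatial eigenvectors (distance-based Moran eigenvector maps).

For a hierarchical design, spatial predictors are built separately within
each block of the design (sites, areas, or regions) by the classic PCNM /
dbMEM recipe — truncate the Euclidean distance matrix at the longest edge
of its minimum spanning tree, replace larger distances by four times the
threshold, double-centre, eigendecompose, keep the positive eigenvalues —
and the per-block eigenvectors are then assembled into one points x m
matrix with zeros everywhere outside the column's own block.  Columns of
different blocks are therefore orthogonal by construction, and each column
describes spatial variation *within* one block only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .io import Hierarchy

__all__ = ["mst_threshold", "dbmem_block", "build_staggered", "MEMSet", "SCALES"]

#: supported scales; each names the level whose variation the MEMs model
SCALES = ("site", "area", "regional")


def mst_threshold(D: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree of a distance matrix.

    This is the smallest truncation distance that keeps all points in one
    connected graph.  Ties among equal-weight edges are irrelevant to the
    threshold (every MST of a graph has the same multiset of edge weights).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] < 2:
        raise ValueError("need a square distance matrix on >= 2 points")
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    tree = minimum_spanning_tree(D)
    return float(tree.data.max())


def _pcoa_positive(D: np.ndarray, rtol: float = 1e-9):
    """Positive-eigenvalue principal coordinates of a (truncated) distance matrix."""
    n = D.shape[0]
    A = -0.5 * D * D
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = J @ A @ J
    G = (G + G.T) / 2.0
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > rtol * eigval[0]
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    # enforce exact centering (floating noise scales with the eigenvalues)
    eigvec = eigvec - eigvec.mean(axis=0)
    eigvec = eigvec / np.linalg.norm(eigvec, axis=0)
    # deterministic sign: first entry of noticeable magnitude made positive
    for k in range(eigvec.shape[1]):
        col = eigvec[:, k]
        lead = col[np.abs(col) > 1e-12]
        if lead.size and lead[0] < 0:
            eigvec[:, k] = -col
    return eigvec, eigval


def dbmem_block(coords: np.ndarray, rtol: float = 1e-9):
    """dbMEM eigenvectors for one block of points.

    Parameters
    ----------
    coords : (n, 2) array
        UTM coordinates of the block's points.

    Returns
    -------
    vectors : (n, k) array of unit-norm, centred eigenvectors
    eigenvalues : (k,) decreasing positive eigenvalues
    """
    C = np.asarray(coords, dtype=float)
    if C.ndim != 2 or C.shape[0] < 2:
        raise ValueError("a block needs at least 2 points")
    D = squareform(pdist(C))
    if D[np.triu_indices_from(D, 1)].min() == 0:
        raise ValueError("coincident points within a block")
    t = mst_threshold(D)
    Dstar = np.where(D <= t, D, 4.0 * t)
    np.fill_diagonal(Dstar, 0.0)
    return _pcoa_positive(Dstar, rtol=rtol)


@dataclass(frozen=True)
class MEMSet:
    """Points x m staggered matrix of spatial predictors for one scale.

    ``matrix`` rows follow the hierarchy's point order; entries are zero for
    points outside a column's block.  ``meta`` records, per column, the
    block it belongs to, its eigenvalue and its within-block index.
    """

    matrix: pd.DataFrame
    meta: pd.DataFrame
    scale: str

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return self.matrix


def _block_units(H: Hierarchy, scale: str):
    """(block labels per point, embedding unit labels per point) for a scale.

    site scale     -> one block per site, units are the points themselves;
    area scale     -> one block per area, units are the points;
    regional scale -> one block per region, units are the AREAS (each block
                      holds its areas' centroids, and every point inherits
                      its area's eigenvector value).
    """
    if scale == "site":
        return H.labels("site"), H.labels("point")
    if scale == "area":
        return H.labels("area"), H.labels("point")
    if scale == "regional":
        return H.labels("region"), H.labels("area")
    raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")


def build_staggered(H: Hierarchy, coords: pd.DataFrame, scale: str) -> MEMSet:
    """Build the staggered block MEM matrix for one scale.

    Blocks are the units one level above the scale's variation target; the
    regional scale embeds area centroids so that its predictors contrast
    whole areas within each region.  Columns are numbered MEM1..MEMm by
    block order then decreasing eigenvalue.
    """
    blocks, units = _block_units(H, scale)
    point_ids = H.point_ids
    C = coords.loc[point_ids].to_numpy(dtype=float)

    # centroid coordinates of each embedding unit, in first-appearance order
    unit_order = list(dict.fromkeys(units))
    unit_xy = {u: C[np.asarray(units) == u].mean(axis=0) for u in unit_order}
    unit_block = {u: blocks[np.asarray(units) == u].iloc[0] for u in unit_order}

    n = len(point_ids)
    cols, meta = [], []
    for block in dict.fromkeys(blocks):
        members = [u for u in unit_order if unit_block[u] == block]
        if len(members) < 2:
            raise ValueError(f"block {block!r} has fewer than 2 embedded units")
        vecs, vals = dbmem_block(np.vstack([unit_xy[u] for u in members]))
        # expand unit values onto point rows of this block, zeros elsewhere
        unit_row = {u: i for i, u in enumerate(members)}
        rows = np.array([unit_row.get(u, -1) for u in units])
        inside = rows >= 0
        for k in range(vecs.shape[1]):
            col = np.zeros(n)
            col[inside] = vecs[rows[inside], k]
            cols.append(col)
            meta.append({"block": block, "eigenvalue": vals[k], "within_index": k + 1})

    if not cols:
        raise ValueError("no positive spatial eigenvectors found")
    names = [f"MEM{i + 1}" for i in range(len(cols))]
    matrix = pd.DataFrame(np.column_stack(cols), index=point_ids, columns=names)
    meta_frame = pd.DataFrame(meta, index=names)
    meta_frame.index.name = "column"
    return MEMSet(matrix=matrix, meta=meta_frame, scale=scale)
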