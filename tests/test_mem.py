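import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from betascale.mem import build_staggered, dbmem_block, mst_threshold

# Frozen reference values from an independent spatial-eigenfunction
# implementation (vegan::pcnm in R 4.3.3) on the fixture produced by
# numpy's PCG64 generator, seed 42: 8 uniform points in [0, 100]^2.
VEGAN_THRESHOLD = 31.671824869488
VEGAN_EIGENVALUES = [
    17829.137718806713,
    15790.539344988329,
    12475.418023401100,
    3486.152131830249,
    267.900324012502,
]
VEGAN_V1 = [
    0.612189349319, -0.040592014189, 0.552105220857, -0.378948643376,
    -0.277547721024, -0.140222072116, -0.275295381698, -0.051688737773,
]


def _fixture_coords():
    rng = np.random.default_rng(42)
    rng.poisson(3.0, size=(12, 5))  # fixture file order: community drawn first
    rng.poisson(1.0, size=5)
    rng.normal(size=(12, 3))
    rng.normal(size=(12, 2))
    return rng.uniform(0, 100, size=(8, 2))


class TestMSTThreshold:
    def test_collinear_points(self):
        D = squareform(pdist(np.array([[0.0], [1.0], [5.0]])))
        assert mst_threshold(D) == 4.0

    def test_two_points(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert mst_threshold(D) == 3.0

    def test_exhaustive_oracle_small_instance(self):
        # brute force over all spanning trees of 6 points: the minimax
        # bottleneck edge equals the MST's longest edge
        rng = np.random.default_rng(17)
        pts = rng.uniform(0, 10, size=(6, 2))
        D = squareform(pdist(pts))
        n = len(pts)
        edges = list(itertools.combinations(range(n), 2))
        best = np.inf
        for combo in itertools.combinations(edges, n - 1):
            adj = {i: set() for i in range(n)}
            for i, j in combo:
                adj[i].add(j)
                adj[j].add(i)
            seen, stack = {0}, [0]
            while stack:
                for k in adj[stack.pop()]:
                    if k not in seen:
                        seen.add(k)
                        stack.append(k)
            if len(seen) == n:
                best = min(best, max(D[i, j] for i, j in combo))
        assert mst_threshold(D) == pytest.approx(best)

    def test_non_finite_rejected(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            mst_threshold(D)


class TestDbmemBlock:
    def test_two_points_hand_pcoa(self):
        vecs, vals = dbmem_block(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert vecs.shape == (2, 1)
        np.testing.assert_allclose(np.abs(vecs[:, 0]), 1 / np.sqrt(2))
        assert vals[0] == pytest.approx(25.0 / 2)  # d^2/2 for d = 5

    def test_centered_and_orthonormal(self):
        rng = np.random.default_rng(18)
        vecs, vals = dbmem_block(rng.uniform(0, 50, size=(9, 2)))
        assert vecs.shape[1] <= 8
        np.testing.assert_allclose(vecs.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(vecs.shape[1]), atol=1e-8)
        assert (np.diff(vals) <= 1e-12).all() and (vals > 0).all()

    def test_collinear_points_match_dense_eigendecomposition(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        vecs, vals = dbmem_block(coords)
        # independent oracle: explicit truncated matrix + dense eigh
        D = squareform(pdist(coords))
        t = 1.0
        Dstar = np.where(D <= t, D, 4.0 * t)
        np.fill_diagonal(Dstar, 0.0)
        J = np.eye(5) - np.full((5, 5), 0.2)
        G = J @ (-0.5 * Dstar**2) @ J
        w, v = np.linalg.eigh((G + G.T) / 2)
        keep = np.sort(w[w > 1e-9 * w.max()])[::-1]
        np.testing.assert_allclose(vals, keep, atol=1e-9)
        for k in range(vecs.shape[1]):
            ref = v[:, np.argmin(np.abs(w - vals[k]))]
            assert np.allclose(vecs[:, k], ref, atol=1e-8) or np.allclose(
                vecs[:, k], -ref, atol=1e-8
            )

    def test_matches_independent_reference_values(self):
        coords = _fixture_coords()
        D = squareform(pdist(coords))
        assert mst_threshold(D) == pytest.approx(VEGAN_THRESHOLD, rel=1e-10)
        vecs, vals = dbmem_block(coords)
        np.testing.assert_allclose(vals, VEGAN_EIGENVALUES, rtol=1e-9)
        np.testing.assert_allclose(vecs[:, 0], VEGAN_V1, atol=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            dbmem_block(np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestStaggered:
    def test_structural_zeros_across_blocks(self, study_data):
        ms = build_staggered(study_data.hierarchy, study_data.coords, "site")
        sites = study_data.hierarchy.labels("site")
        for col in ms.matrix.columns:
            block = ms.meta.loc[col, "block"]
            outside = ms.matrix.loc[(sites != block).to_numpy(), col]
            assert (outside == 0).all()

    def test_cross_block_columns_orthogonal(self, study_data):
        ms = build_staggered(study_data.hierarchy, study_data.coords, "site")
        gram = ms.matrix.to_numpy().T @ ms.matrix.to_numpy()
        blocks = ms.meta["block"].to_numpy()
        off = gram[blocks[:, None] != blocks[None, :]]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_within_block_columns_centered_orthogonal(self, study_data):
        ms = build_staggered(study_data.hierarchy, study_data.coords, "area")
        for block, meta in ms.meta.groupby("block"):
            sub = ms.matrix[meta.index].to_numpy()
            np.testing.assert_allclose(sub.sum(axis=0), 0.0, atol=1e-8)
            gram = sub.T @ sub
            np.testing.assert_allclose(
                gram - np.diag(np.diag(gram)), 0.0, atol=1e-8
            )

    def test_column_count_bounded_by_n_minus_blocks(self, study_data):
        for scale, n_blocks in (("site", 20), ("area", 4)):
            ms = build_staggered(study_data.hierarchy, study_data.coords, scale)
            assert ms.n_columns <= 100 - n_blocks

    def test_regional_scale_contrasts_areas(self, study_data):
        ms = build_staggered(study_data.hierarchy, study_data.coords, "regional")
        # 2 regions x 2 embedded area centroids -> one contrast per region
        assert ms.n_columns == 2
        areas = study_data.hierarchy.labels("area")
        for col in ms.matrix.columns:
            per_area = ms.matrix[col].groupby(areas.to_numpy()).nunique()
            assert (per_area == 1).all()  # constant within each area

    def test_row_permutation_equivariance(self, study_data):
        H, C = study_data.hierarchy, study_data.coords
        ms = build_staggered(H, C, "site")
        rng = np.random.default_rng(19)
        order = rng.permutation(len(H.point_ids))
        from betascale.io import Hierarchy

        H2 = Hierarchy(H.frame.iloc[order])
        ms2 = build_staggered(H2, C.iloc[order], "site")
        # align columns through their (block, within-block index) identity;
        # eigenvector sign is conventional and may flip with row order
        key = lambda meta: list(zip(meta["block"], meta["within_index"]))
        lookup = dict(zip(key(ms2.meta), ms2.meta.index))
        for col, k in zip(ms.meta.index, key(ms.meta)):
            ref = ms.matrix[col].iloc[order].to_numpy()
            new = ms2.matrix[lookup[k]].to_numpy()
            assert np.allclose(new, ref, atol=1e-9) or np.allclose(
                new, -ref, atol=1e-9
            )
            assert ms2.meta.loc[lookup[k], "eigenvalue"] == pytest.approx(
                ms.meta.loc[col, "eigenvalue"], rel=1e-12
            )

    def test_tiny_block_rejected(self, study_data):
        from betascale.io import Hierarchy

        frame = study_data.hierarchy.frame.copy()
        frame.iloc[0, 0] = "lonely_site"
        with pytest.raises(ValueError, match="fewer than 2"):
            build_staggered(Hierarchy(frame), study_data.coords, "site")
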