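import numpy as np
import pandas as pd
import pytest

from betascale.io import CommunityMatrix
from betascale.rda import (
    RDA,
    VariationPartitioning,
    adjusted_r2,
    forward_select,
    partial_rda,
    permutation_test,
    rda_fit,
    varpart_two_sets,
)
from betascale.transform import hellinger

# Frozen reference values from an independent constrained-ordination
# implementation (vegan 2.7 in R 4.3.3) on the fixture below: community
# Y ~ Poisson(3) 12x5 (row 2 redrawn at rate 1), E ~ N(0,1) 12x3,
# S ~ N(0,1) 12x2, all from numpy PCG64 seed 42, Hellinger-transformed.
VEGAN = {
    "hellinger_row0": [0.436435780472, 0.436435780472, 0.487950036474,
                       0.218217890236, 0.577350269190],
    "r2_E": 0.446021187277,
    "r2_adj_E": 0.238279132506,
    "F_E": 2.146995165561,
    "F_E_given_S": 1.582704431236,
    "pure_E": 0.166275556536,
    "shared": 0.072003575970,
    "pure_S": -0.094333493633,
    "resid": 0.856054361127,
}


@pytest.fixture(scope="module")
def fixture_case():
    rng = np.random.default_rng(42)
    Y = rng.poisson(3.0, size=(12, 5)).astype(float)
    Y[2] = rng.poisson(1.0, size=5)
    E = pd.DataFrame(rng.normal(size=(12, 3)), columns=["e1", "e2", "e3"])
    S = pd.DataFrame(rng.normal(size=(12, 2)), columns=["s1", "s2"])
    H = hellinger(CommunityMatrix(pd.DataFrame(Y)))
    return H.data, E, S


class TestRDAFit:
    def test_perfect_predictor_gives_r2_one(self):
        rng = np.random.default_rng(1)
        y = pd.DataFrame({"sp": rng.normal(size=15)})
        assert rda_fit(y, y["sp"]).r2 == pytest.approx(1.0)

    def test_orthogonal_predictor_gives_r2_zero(self):
        y = pd.DataFrame({"sp": [1.0, -1.0, 1.0, -1.0, 1.0, -1.0]})
        x = pd.DataFrame({"x": [1.0, 1.0, -1.0, -1.0, 1.0, 1.0]})
        # make x exactly orthogonal to centred y
        x["x"] -= x["x"].mean()
        x["x"] -= (x["x"] @ y["sp"]) / (y["sp"] @ y["sp"]) * y["sp"]
        assert rda_fit(y, x).r2 == pytest.approx(0.0, abs=1e-12)

    def test_projection_matrix_oracle(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 4))
        X = rng.normal(size=(20, 2))
        Yc = Y - Y.mean(axis=0)
        Xd = np.column_stack([np.ones(20), X])
        hat = Xd @ np.linalg.solve(Xd.T @ Xd, Xd.T)
        Yhat = hat @ Yc
        expected = np.trace(Yhat.T @ Yhat) / np.trace(Yc.T @ Yc)
        assert rda_fit(Y, X).r2 == pytest.approx(expected, rel=1e-12)

    def test_rank_deficient_predictors_named(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=10)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            rda_fit(rng.normal(size=(10, 2)), X)

    def test_matches_reference_implementation(self, fixture_case):
        Hm, E, S = fixture_case
        np.testing.assert_allclose(
            Hm.to_numpy()[0], VEGAN["hellinger_row0"], atol=1e-10
        )
        fit = rda_fit(Hm, E)
        assert fit.r2 == pytest.approx(VEGAN["r2_E"], rel=1e-10)
        assert fit.r2_adj == pytest.approx(VEGAN["r2_adj_E"], rel=1e-10)
        assert fit.f == pytest.approx(VEGAN["F_E"], rel=1e-10)


class TestAdjustedR2:
    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 100, 7) == pytest.approx(1.0)

    def test_zero_r2_goes_negative(self):
        assert adjusted_r2(0.0, 100, 1) == pytest.approx(-1 / 98)

    def test_direct_evaluation(self):
        assert adjusted_r2(0.10, 100, 3) == pytest.approx(0.0719, abs=5e-5)

    def test_monotone_in_r2_and_limits(self):
        grid = np.linspace(0, 1, 21)
        adj = [adjusted_r2(r, 50, 4) for r in grid]
        assert all(a < b for a, b in zip(adj, adj[1:]))
        # adjustment vanishes as n grows
        assert adjusted_r2(0.3, 10**6, 4) == pytest.approx(0.3, abs=1e-5)

    def test_undefined_when_df_exhausted(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 5, 4)


class TestPermutationTest:
    def test_exact_relationship_gives_minimum_p(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(20, 2)))
        Y = X.to_numpy() @ rng.normal(size=(2, 3))
        assert permutation_test(Y, X, nperm=99, seed=0) == pytest.approx(1 / 100)

    def test_conditioned_on_superset_nothing_left(self):
        rng = np.random.default_rng(5)
        W = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        # X inside span(W): F = 0 exactly, nothing left to explain
        X = pd.DataFrame({"x": W["a"] + W["b"]})
        Y = rng.normal(size=(25, 2))
        p = permutation_test(Y, X, W=W, nperm=99, seed=1)
        assert p == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        reps, hits = 500, 0
        for r in range(reps):
            Y = rng.normal(size=(30, 4))
            X = rng.normal(size=(30, 3))
            if permutation_test(Y, X, nperm=99, seed=3000 + r) <= 0.05:
                hits += 1
        assert 0.03 <= hits / reps <= 0.07

    def test_conditioned_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        reps, hits = 200, 0
        for r in range(reps):
            W = rng.normal(size=(30, 2))
            Y = W @ rng.normal(size=(2, 3)) + rng.normal(size=(30, 3))
            X = rng.normal(size=(30, 2))
            if permutation_test(Y, X, W=W, nperm=99, seed=4000 + r) <= 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09


class TestPartialRDA:
    def test_empty_conditioning_equals_plain_fit(self, fixture_case):
        Hm, E, _ = fixture_case
        assert partial_rda(Hm, E).r2 == pytest.approx(rda_fit(Hm, E).r2)

    def test_orthogonal_blocks_decompose(self):
        rng = np.random.default_rng(8)
        # orthonormal columns that are also centred (orthogonal to 1)
        centred = rng.normal(size=(20, 5))
        centred -= centred.mean(axis=0)
        raw = np.linalg.qr(centred)[0]
        X = pd.DataFrame(raw[:, :2], columns=["x1", "x2"])
        W = pd.DataFrame(raw[:, 2:4], columns=["w1", "w2"])
        Y = rng.normal(size=(20, 3))
        assert partial_rda(Y, X, W).r2 == pytest.approx(
            rda_fit(Y, X).r2, abs=1e-10
        )

    def test_sequential_sums_of_squares_oracle(self, fixture_case):
        Hm, E, S = fixture_case
        fit = partial_rda(Hm, E, S)
        Yc = Hm.to_numpy() - Hm.to_numpy().mean(axis=0)
        ss_total = np.sum(Yc**2)
        ss_joint = rda_fit(Hm, pd.concat([S, E], axis=1)).r2 * ss_total
        ss_w = rda_fit(Hm, S).r2 * ss_total
        assert fit.r2 * ss_total == pytest.approx(ss_joint - ss_w, rel=1e-10)
        assert fit.f == pytest.approx(VEGAN["F_E_given_S"], rel=1e-10)


class TestForwardSelection:
    def test_single_perfect_candidate_selected(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"x": rng.normal(size=30)})
        Y = pd.DataFrame({"sp": X["x"] * 2.0})
        sel = forward_select(Y, X, nperm=99, seed=0)
        assert sel.selected == ["x"]
        assert sel.trace["r2_adj_cum"].iloc[-1] == pytest.approx(1.0)

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(10)
        recovered = 0
        for r in range(20):
            X = pd.DataFrame(
                rng.normal(size=(50, 10)), columns=[f"x{j}" for j in range(10)]
            )
            signal = X[["x2", "x7"]].to_numpy() @ np.array([[1.0], [1.0]])
            Y = signal + 0.4 * rng.normal(size=(50, 1))
            sel = forward_select(Y, X, nperm=99, seed=500 + r)
            if set(sel.selected[:2]) == {"x2", "x7"}:
                recovered += 1
        assert recovered >= 18

    def test_pure_noise_fails_global_test(self):
        rng = np.random.default_rng(11)
        failures = 0
        for r in range(100):
            X = pd.DataFrame(rng.normal(size=(30, 5)))
            Y = rng.normal(size=(30, 3))
            sel = forward_select(Y, X, nperm=99, seed=900 + r)
            failures += sel.global_test_failed
        assert failures >= 85  # the global gate holds at roughly 1 - alpha


class TestVarpart:
    def test_fractions_sum_to_one(self, fixture_case):
        Hm, E, S = fixture_case
        vp = varpart_two_sets(Hm, E, S, nperm=0)
        assert vp.a + vp.b + vp.c + vp.d == pytest.approx(1.0, abs=1e-10)

    def test_matches_reference_implementation(self, fixture_case):
        Hm, E, S = fixture_case
        vp = varpart_two_sets(Hm, E, S, nperm=0)
        assert vp.a == pytest.approx(VEGAN["pure_E"], rel=1e-9)
        assert vp.b == pytest.approx(VEGAN["shared"], rel=1e-9)
        assert vp.c == pytest.approx(VEGAN["pure_S"], rel=1e-9)
        assert vp.d == pytest.approx(VEGAN["resid"], rel=1e-9)

    def test_empty_spatial_set_collapses(self, fixture_case):
        Hm, E, _ = fixture_case
        vp = varpart_two_sets(Hm, E, None, nperm=0)
        assert vp.a == pytest.approx(rda_fit(Hm, E).r2_adj)
        assert vp.b == 0.0 and vp.c == 0.0
        assert vp.d == pytest.approx(1 - rda_fit(Hm, E).r2_adj)

    def test_identical_sets_all_shared(self, fixture_case):
        Hm, E, _ = fixture_case
        E2 = E.copy()
        E2.columns = [f"{c}_dup" for c in E.columns]
        vp = varpart_two_sets(Hm, E, E2, nperm=0)
        assert vp.a == pytest.approx(0.0, abs=1e-10)
        assert vp.c == pytest.approx(0.0, abs=1e-10)
        assert vp.b == pytest.approx(rda_fit(Hm, E).r2_adj)

    def test_orthogonal_sets_share_nothing(self):
        rng = np.random.default_rng(12)
        raw = np.linalg.qr(rng.normal(size=(24, 6)))[0]
        E = pd.DataFrame(raw[:, :2] - raw[:, :2].mean(0), columns=["e1", "e2"])
        S = pd.DataFrame(raw[:, 2:4] - raw[:, 2:4].mean(0), columns=["s1", "s2"])
        Y = rng.normal(size=(24, 3))
        vp = varpart_two_sets(Y, E, S, nperm=0)
        # on the unadjusted scale the shared fraction is exactly zero;
        # adjustment introduces only a small degrees-of-freedom artefact
        assert abs(vp.b) < 0.05

    def test_table_mirrors_component_layout(self, fixture_case):
        Hm, E, S = fixture_case
        frame = varpart_two_sets(Hm, E, S, nperm=99, seed=0).to_frame()
        assert list(frame.index) == ["E [a+b]", "S [b+c]", "E|S [a]", "S|E [c]"]
        assert frame["p"].notna().all()


def test_model_front_ends(fixture_case):
    Hm, E, S = fixture_case
    fit = RDA(Hm, E, W=S).fit(nperm=99, seed=1)
    assert fit.p is not None and fit.conditioned_on == 2
    assert "Redundancy analysis" in fit.summary()
    vp = VariationPartitioning(Hm, E, S).fit(nperm=None)
    assert vp.a + vp.b + vp.c + vp.d == pytest.approx(1.0)
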