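"""Redundancy analysis, permutation tests, forward selection, varpart.

Redundancy analysis (RDA) is multivariate least squares of a (transformed,
column-centred) community matrix Y on a predictor set X; the canonical R²
is the share of Y's total sum of squares captured by the fitted values,
adjusted for the number of predictors with the Ezekiel correction

    R²_adj = 1 - (1 - R²) (n - 1) / (n - m - 1).

Significance is assessed by permutation (rows of Y for simple models;
reduced-model residual permutation for partial models).  Forward selection
uses the double stopping criterion: a candidate enters only while its
partial permutation p-value stays below alpha AND the cumulative adjusted
R² stays below the global model's.  Two-set variation partitioning reports
the classic fractions [a] (pure environment), [b] (spatially structured
environment), [c] (pure space) and [d] (unexplained) on the adjusted scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RDAFit",
    "rda_fit",
    "adjusted_r2",
    "permutation_test",
    "partial_rda",
    "forward_select",
    "ForwardSelection",
    "varpart_two_sets",
    "VarpartResult",
    "RDA",
    "VariationPartitioning",
]


def _as_matrix(X) -> np.ndarray:
    arr = X.to_numpy(dtype=float) if isinstance(X, (pd.DataFrame, pd.Series)) else np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr


def _center(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=0)


def _basis(X: np.ndarray, names=None) -> np.ndarray:
    """Orthonormal basis of the centred column space; errors on rank deficiency."""
    Xc = _center(X)
    Q, R = np.linalg.qr(Xc)
    diag = np.abs(np.diag(R))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    dependent = np.where(diag <= tol)[0]
    if dependent.size:
        labels = (
            [names[i] for i in dependent] if names is not None else dependent.tolist()
        )
        raise ValueError(f"rank-deficient predictor matrix; dependent column(s): {labels}")
    return Q


def _basis_tol(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the centred column space, dropping dependent
    columns silently (used for joint/conditional fits where predictor sets
    may overlap, e.g. nested or duplicated sets in variation partitioning)."""
    Xc = _center(X)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return U[:, s > tol]


@dataclass(frozen=True)
class RDAFit:
    """Summary of one (partial) redundancy analysis."""

    r2: float
    r2_adj: float
    m: int
    n: int
    f: float
    p: float | None = None
    conditioned_on: int = 0  # number of conditioning predictors removed

    def summary(self) -> str:
        lines = [
            "Redundancy analysis"
            + (f" (conditioned on {self.conditioned_on} predictors)" if self.conditioned_on else ""),
            f"  n = {self.n}, m = {self.m}",
            f"  R2      = {self.r2:.4f}",
            f"  R2_adj  = {self.r2_adj:.4f}",
            f"  pseudo-F = {self.f:.3f}",
        ]
        if self.p is not None:
            lines.append(f"  p (perm) = {self.p:.4g}")
        return "\n".join(lines)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel-adjusted R²; may be negative for weak models."""
    if n - m - 1 < 1:
        raise ValueError(f"adjustment undefined: n - m - 1 = {n - m - 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda_fit(Y, X) -> RDAFit:
    """Fit Y (column-centred internally) on X with intercept; no test attached."""
    Ymat, Xmat = _as_matrix(Y), _as_matrix(X)
    if Ymat.shape[0] != Xmat.shape[0]:
        raise ValueError("Y and X have different numbers of rows")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Q = _basis(Xmat, names)
    n, m = Xmat.shape
    Yc = _center(Ymat)
    ss_total = float(np.sum(Yc * Yc))
    if ss_total == 0:
        raise ValueError("Y is constant")
    proj = Q.T @ Yc
    ss_fit = float(np.sum(proj * proj))
    r2 = ss_fit / ss_total
    ss_res = ss_total - ss_fit
    f = (ss_fit / m) / (ss_res / (n - m - 1)) if ss_res > 0 else np.inf
    return RDAFit(r2=r2, r2_adj=adjusted_r2(r2, n, m), m=m, n=n, f=f)


def _partial_f(Yc: np.ndarray, Qw: np.ndarray | None, Qfull: np.ndarray, m_x: int) -> float:
    """Conditional pseudo-F of X given W from precomputed orthonormal bases.

    Residual degrees of freedom use the rank of the joint basis, so nested
    or overlapping predictor sets are handled gracefully.
    """
    n = Yc.shape[0]
    full_proj = Qfull.T @ Yc
    ss_full = float(np.sum(full_proj * full_proj))
    ss_tot = float(np.sum(Yc * Yc))
    if Qw is None:
        ss_x = ss_full
    else:
        w_proj = Qw.T @ Yc
        ss_x = ss_full - float(np.sum(w_proj * w_proj))
        if ss_x < 1e-12 * ss_tot:  # X adds nothing beyond W (numerically)
            ss_x = 0.0
    ss_res = ss_tot - ss_full
    dfe = n - Qfull.shape[1] - 1
    if ss_res <= 0 or dfe < 1:
        return np.inf
    return (ss_x / m_x) / (ss_res / dfe)


def _fit_tolerant(Y, X) -> RDAFit:
    """Like rda_fit but dropping linearly dependent predictor columns;
    m is the effective rank (the convention for joint-set fits)."""
    Ymat, Xmat = _as_matrix(Y), _as_matrix(X)
    Q = _basis_tol(Xmat)
    n, m = Xmat.shape[0], Q.shape[1]
    Yc = _center(Ymat)
    ss_total = float(np.sum(Yc * Yc))
    if ss_total == 0:
        raise ValueError("Y is constant")
    proj = Q.T @ Yc
    ss_fit = float(np.sum(proj * proj))
    r2 = ss_fit / ss_total
    ss_res = ss_total - ss_fit
    f = (ss_fit / m) / (ss_res / (n - m - 1)) if ss_res > 0 else np.inf
    return RDAFit(r2=r2, r2_adj=adjusted_r2(r2, n, m), m=m, n=n, f=f)


def permutation_test(Y, X, W=None, nperm: int = 999, seed: int | None = None) -> float:
    """Permutation p-value for the effect of X (optionally given W).

    Without conditioning, rows of Y are permuted freely.  With a
    conditioning set W, permutation follows the reduced model: residuals of
    Y on W are permuted and the fitted W part re-added before recomputing
    the partial F.  The add-one convention is used throughout.
    """
    if nperm < 99:
        raise ValueError("use at least 99 permutations")
    Ymat, Xmat = _as_matrix(Y), _as_matrix(X)
    n, m_x = Xmat.shape
    Yc = _center(Ymat)
    rng = np.random.default_rng(seed)

    if W is None or (isinstance(W, (pd.DataFrame, np.ndarray)) and _as_matrix(W).shape[1] == 0):
        Q = _basis(Xmat)
        f_obs = _partial_f(Yc, None, Q, m_x)
        hits = 0
        for _ in range(nperm):
            Yp = Yc[rng.permutation(n)]
            if _partial_f(_center(Yp), None, Q, m_x) >= f_obs:
                hits += 1
        return (hits + 1) / (nperm + 1)

    Wmat = _as_matrix(W)
    Qw = _basis(Wmat)
    Qfull = _basis_tol(np.hstack([Wmat, Xmat]))
    f_obs = _partial_f(Yc, Qw, Qfull, m_x)
    fitted_w = Qw @ (Qw.T @ Yc)
    resid_w = Yc - fitted_w
    hits = 0
    for _ in range(nperm):
        Yp = fitted_w + resid_w[rng.permutation(n)]
        if _partial_f(_center(Yp), Qw, Qfull, m_x) >= f_obs:
            hits += 1
    return (hits + 1) / (nperm + 1)


def partial_rda(Y, X, W=None) -> RDAFit:
    """Partial RDA of Y on X controlling for W.

    The semipartial adjusted fraction is reported by subtraction,
    adj(X union W) - adj(W); the F statistic uses the conditional sum of
    squares with residual degrees of freedom n - m_x - m_w - 1.
    """
    if W is None or _as_matrix(W).shape[1] == 0:
        return rda_fit(Y, X)
    Ymat, Xmat, Wmat = _as_matrix(Y), _as_matrix(X), _as_matrix(W)
    n, m_x = Xmat.shape
    m_w = Wmat.shape[1]
    Yc = _center(Ymat)
    ss_total = float(np.sum(Yc * Yc))
    Qw = _basis(Wmat)
    Qfull = _basis_tol(np.hstack([Wmat, Xmat]))
    joint = _fit_tolerant(Y, np.hstack([Wmat, Xmat]))
    wonly = rda_fit(Y, Wmat)
    w_proj = Qw.T @ Yc
    full_proj = Qfull.T @ Yc
    ss_x = max(
        float(np.sum(full_proj * full_proj)) - float(np.sum(w_proj * w_proj)), 0.0
    )
    f = _partial_f(Yc, Qw, Qfull, m_x)
    return RDAFit(
        r2=ss_x / ss_total,
        r2_adj=joint.r2_adj - wonly.r2_adj,
        m=m_x,
        n=n,
        f=f,
        conditioned_on=m_w,
    )


@dataclass(frozen=True)
class ForwardSelection:
    """Outcome of double-stopping forward selection."""

    selected: list[str]
    trace: pd.DataFrame  # one row per accepted step: candidate, p, r2_adj_cum
    global_fit: RDAFit
    global_p: float
    stopped_because: str

    @property
    def global_test_failed(self) -> bool:
        return self.stopped_because == "global test failed"


def forward_select(
    Y,
    X_candidates: pd.DataFrame,
    alpha: float = 0.05,
    nperm: int = 999,
    seed: int | None = None,
) -> ForwardSelection:
    """Forward selection of predictors with the double stopping criterion.

    Step 0 tests the global model of all candidates; if it is not
    significant at ``alpha`` the selection is empty.  Otherwise candidates
    are added greedily by added R², stopping when the incoming candidate's
    partial permutation p exceeds alpha or the cumulative adjusted R² would
    exceed the global model's adjusted R².
    """
    if X_candidates.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    rng = np.random.default_rng(seed)
    global_fit = rda_fit(Y, X_candidates)
    global_p = permutation_test(
        Y, X_candidates, nperm=nperm, seed=int(rng.integers(2**31 - 1))
    )
    empty_trace = pd.DataFrame(columns=["candidate", "p", "r2_adj_cum"])
    if global_p > alpha:
        return ForwardSelection([], empty_trace, global_fit, global_p, "global test failed")

    remaining = list(X_candidates.columns)
    selected: list[str] = []
    rows = []
    reason = "candidates exhausted"
    while remaining:
        # candidate with the largest added (equivalently joint) R²
        best, best_r2 = None, -np.inf
        for name in remaining:
            r2 = rda_fit(Y, X_candidates[selected + [name]]).r2
            if r2 > best_r2:
                best, best_r2 = name, r2
        W = X_candidates[selected] if selected else None
        p = permutation_test(
            Y,
            X_candidates[[best]],
            W=W,
            nperm=nperm,
            seed=int(rng.integers(2**31 - 1)),
        )
        if p > alpha:
            reason = f"candidate p = {p:.4g} > alpha"
            break
        r2_adj_cum = rda_fit(Y, X_candidates[selected + [best]]).r2_adj
        selected.append(best)
        remaining.remove(best)
        rows.append({"candidate": best, "p": p, "r2_adj_cum": r2_adj_cum})
        if r2_adj_cum > global_fit.r2_adj:
            # the adjusted-R2 guard: once the selection explains as much as
            # the full candidate model, further additions only overfit
            reason = "cumulative R2_adj reached the global model"
            break
    trace = pd.DataFrame(rows, columns=["candidate", "p", "r2_adj_cum"])
    return ForwardSelection(selected, trace, global_fit, global_p, reason)


@dataclass(frozen=True)
class VarpartResult:
    """Two-set variation partitioning on the adjusted-R² scale.

    Fractions: [a] pure first set (environment), [b] shared, [c] pure
    second set (space), [d] unexplained; a + b + c + d = 1 by construction
    ([b] is obtained by subtraction and may be negative).
    """

    a: float
    b: float
    c: float
    d: float
    fits: dict = field(repr=False)  # keys: E, S, ES, E|S, S|E -> RDAFit
    tests: dict = field(repr=False)  # same keys -> permutation p (or None)
    e_names: list[str] = field(default_factory=list)
    s_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.a + self.b + self.c + self.d - 1.0) > 1e-10:
            raise AssertionError("varpart fractions do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, label in (
            ("E", "E [a+b]"),
            ("S", "S [b+c]"),
            ("E|S", "E|S [a]"),
            ("S|E", "S|E [c]"),
        ):
            fit = self.fits[key]
            rows.append(
                {
                    "component": label,
                    "r2_adj_pct": 100.0 * fit.r2_adj,
                    "df": fit.m,
                    "F": fit.f,
                    "p": self.tests.get(key),
                }
            )
        return pd.DataFrame(rows).set_index("component")

    def summary(self) -> str:
        frame = self.to_frame()
        lines = ["Variation partitioning (adjusted R², %)"]
        for label, row in frame.iterrows():
            p = f"{row['p']:.4g}" if pd.notna(row["p"]) else "-"
            lines.append(
                f"  {label:<9s} {row['r2_adj_pct']:7.2f}  df={int(row['df']):3d}"
                f"  F={row['F']:6.3f}  p={p}"
            )
        lines.append(
            f"  fractions: a={100 * self.a:.2f} b={100 * self.b:.2f}"
            f" c={100 * self.c:.2f} d={100 * self.d:.2f}"
        )
        return "\n".join(lines)


def varpart_two_sets(
    Y,
    E: pd.DataFrame | None,
    S: pd.DataFrame | None,
    nperm: int = 999,
    seed: int | None = None,
) -> VarpartResult:
    """Partition Y's variation between an environmental and a spatial set.

    a = adj(E∪S) - adj(S); c = adj(E∪S) - adj(E); b = adj(E) + adj(S) -
    adj(E∪S); d = 1 - adj(E∪S).  Permutation tests are attached for E, S,
    E|S and S|E (reduced-model residual permutation for the partial tests).
    Either set may be empty/None, collapsing to a single-set fit.
    """
    rng = np.random.default_rng(seed)
    Ef = E if E is not None and E.shape[1] else None
    Sf = S if S is not None and S.shape[1] else None
    if Ef is None and Sf is None:
        raise ValueError("both predictor sets are empty")

    def seeded() -> int:
        return int(rng.integers(2**31 - 1))

    if Ef is None or Sf is None:
        X = Ef if Ef is not None else Sf
        fit = rda_fit(Y, X)
        p = permutation_test(Y, X, nperm=nperm, seed=seeded()) if nperm else None
        zero = RDAFit(r2=0.0, r2_adj=0.0, m=0, n=fit.n, f=0.0)
        if Ef is not None:
            fits = {"E": fit, "S": zero, "ES": fit, "E|S": fit, "S|E": zero}
            tests = {"E": p, "S": None, "E|S": p, "S|E": None}
            a, c = fit.r2_adj, 0.0
            e_names, s_names = list(Ef.columns), []
        else:
            fits = {"E": zero, "S": fit, "ES": fit, "E|S": zero, "S|E": fit}
            tests = {"E": None, "S": p, "E|S": None, "S|E": p}
            a, c = 0.0, fit.r2_adj
            e_names, s_names = [], list(Sf.columns)
        return VarpartResult(a, 0.0, c, 1.0 - fit.r2_adj, fits, tests, e_names, s_names)

    fit_e = rda_fit(Y, Ef)
    fit_s = rda_fit(Y, Sf)
    joint = _fit_tolerant(Y, pd.concat([Ef, Sf], axis=1))
    fit_es = partial_rda(Y, Ef, Sf)  # E | S
    fit_se = partial_rda(Y, Sf, Ef)  # S | E

    a = joint.r2_adj - fit_s.r2_adj
    c = joint.r2_adj - fit_e.r2_adj
    b = fit_e.r2_adj + fit_s.r2_adj - joint.r2_adj
    d = 1.0 - joint.r2_adj

    tests = {"E": None, "S": None, "E|S": None, "S|E": None}
    if nperm:
        tests["E"] = permutation_test(Y, Ef, nperm=nperm, seed=seeded())
        tests["S"] = permutation_test(Y, Sf, nperm=nperm, seed=seeded())
        tests["E|S"] = permutation_test(Y, Ef, W=Sf, nperm=nperm, seed=seeded())
        tests["S|E"] = permutation_test(Y, Sf, W=Ef, nperm=nperm, seed=seeded())
    fits = {"E": fit_e, "S": fit_s, "ES": joint, "E|S": fit_es, "S|E": fit_se}
    return VarpartResult(a, b, c, d, fits, tests, list(Ef.columns), list(Sf.columns))


class RDA:
    """Model-style front end for (partial) redundancy analysis.

    Parameters
    ----------
    Y : DataFrame or TransformedMatrix values
        Response (community) matrix; centred internally.
    X : DataFrame
        Constraining predictors.
    W : DataFrame, optional
        Conditioning predictors (partialled out).
    """

    def __init__(self, Y, X, W=None):
        self.Y = Y.data if hasattr(Y, "data") else Y
        self.X = X
        self.W = W

    def fit(self, nperm: int | None = 999, seed: int | None = None) -> RDAFit:
        fit = partial_rda(self.Y, self.X, self.W)
        if nperm:
            p = permutation_test(self.Y, self.X, W=self.W, nperm=nperm, seed=seed)
            fit = RDAFit(
                r2=fit.r2, r2_adj=fit.r2_adj, m=fit.m, n=fit.n, f=fit.f, p=p,
                conditioned_on=fit.conditioned_on,
            )
        return fit


class VariationPartitioning:
    """Model-style front end for two-set variation partitioning."""

    def __init__(self, Y, E, S):
        self.Y = Y.data if hasattr(Y, "data") else Y
        self.E = E
        self.S = S

    def fit(self, nperm: int | None = 999, seed: int | None = None) -> VarpartResult:
        return varpart_two_sets(self.Y, self.E, self.S, nperm=nperm or 0, seed=seed)
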