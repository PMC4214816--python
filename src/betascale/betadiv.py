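"""Total beta diversity as community-matrix variance, with SCBD and LCBD.

The total variance of the (Hellinger-transformed) community matrix is an
index of total beta diversity: with s_ij the deviation of y_ij from the
column (species) mean,

    SS_Total = sum_ij s_ij**2          BD_Total = SS_Total / (n - 1)

and the total splits exactly into Species Contributions (SCBD_j, column
shares) and Local Contributions (LCBD_i, row shares), both summing to 1.
LCBD measures the compositional uniqueness of a sampling point; its
significance is assessed by independently permuting the raw species columns
(breaking any species-site association while keeping each species' value
distribution), re-transforming, and recomputing LCBD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CommunityMatrix
from .transform import TransformedMatrix, _hellinger_values

__all__ = [
    "BetaDivResult",
    "beta_div_decompose",
    "lcbd_perm_test",
    "lcbd_correlates",
    "BetaDiversity",
]


def _decompose_values(values: np.ndarray):
    S = values - values.mean(axis=0)
    sq = S * S
    ss_total = float(sq.sum())
    if ss_total <= 0:
        raise ValueError("no beta diversity: the community matrix is constant")
    return ss_total, sq.sum(axis=0) / ss_total, sq.sum(axis=1) / ss_total


@dataclass(frozen=True)
class BetaDivResult:
    """Decomposition of total community variance into SCBD and LCBD."""

    ss_total: float
    bd_total: float
    scbd: pd.Series
    lcbd: pd.Series
    measure: str
    lcbd_p: pd.Series | None = None
    nperm: int | None = None
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.lcbd)

    @property
    def n_species(self) -> int:
        return len(self.scbd)

    def significant_points(self, alpha: float = 0.05, holm: bool = False) -> pd.Index:
        """Points whose LCBD permutation p-value falls at or below ``alpha``."""
        if self.lcbd_p is None:
            raise ValueError("run the permutation test first")
        p = self.lcbd_p
        if holm:
            order = np.argsort(p.to_numpy())
            m = len(p)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p.iloc[idx])
                adj[idx] = min(1.0, running)
            p = pd.Series(adj, index=p.index)
        return p.index[p <= alpha]

    def to_frame(self) -> pd.DataFrame:
        species = pd.DataFrame(
            {"kind": "species_scbd", "value": self.scbd, "p": np.nan}
        )
        pts = pd.DataFrame({"kind": "point_lcbd", "value": self.lcbd})
        pts["p"] = self.lcbd_p if self.lcbd_p is not None else np.nan
        out = pd.concat([species, pts])
        out.index.name = "label"
        return out

    def summary(self) -> str:
        lines = [
            f"Beta diversity decomposition ({self.measure})",
            f"  n points   : {self.n}",
            f"  n species  : {self.n_species}",
            f"  SS_Total   : {self.ss_total:.3f}",
            f"  BD_Total   : {self.bd_total:.3f}",
            f"  SCBD range : {self.scbd.min():.4f} - {self.scbd.max():.4f}"
            f" (mean {1.0 / self.n_species:.4f})",
            f"  LCBD range : {self.lcbd.min():.4f} - {self.lcbd.max():.4f}",
        ]
        if self.lcbd_p is not None:
            k = int((self.lcbd_p <= 0.05).sum())
            lines.append(
                f"  points with LCBD p <= 0.05: {k} ({self.nperm} permutations)"
            )
        return "\n".join(lines)


def beta_div_decompose(Y: TransformedMatrix | pd.DataFrame, measure: str = "") -> BetaDivResult:
    """Decompose the total variance of a (transformed) community matrix."""
    frame = Y.data if isinstance(Y, TransformedMatrix) else Y
    if not measure and isinstance(Y, TransformedMatrix):
        measure = Y.measure
    n = len(frame)
    if n < 2:
        raise ValueError("need at least 2 rows")
    ss_total, scbd, lcbd = _decompose_values(frame.to_numpy(dtype=float))
    return BetaDivResult(
        ss_total=ss_total,
        bd_total=ss_total / (n - 1),
        scbd=pd.Series(scbd, index=frame.columns, name="scbd"),
        lcbd=pd.Series(lcbd, index=frame.index, name="lcbd"),
        measure=measure,
    )


def lcbd_perm_test(
    M: CommunityMatrix, nperm: int = 999, seed: int | None = None
) -> pd.Series:
    """Permutation p-values for each point's LCBD.

    Each permutation shuffles every raw species column independently (the
    null of species placed randomly and independently across points), then
    re-applies the Hellinger transformation and recomputes LCBD.  p-values
    use the add-one convention.
    """
    if nperm < 99:
        raise ValueError("use at least 99 permutations")
    raw = M.values
    n = raw.shape[0]
    _, _, lcbd_obs = _decompose_values(_hellinger_values(raw))
    rng = np.random.default_rng(seed)
    hits = np.zeros(n, dtype=int)
    perm = raw.copy()
    for _ in range(nperm):
        for j in range(perm.shape[1]):
            rng.shuffle(perm[:, j])
        _, _, lcbd_p = _decompose_values(_hellinger_values(perm))
        hits += lcbd_p >= lcbd_obs
    return pd.Series((hits + 1) / (nperm + 1), index=M.data.index, name="lcbd_p")


def lcbd_correlates(lcbd: pd.Series, stat: pd.Series) -> tuple[float, float]:
    """Spearman correlation (rho, two-sided p) of LCBD with a point descriptor."""
    a = np.asarray(lcbd, dtype=float)
    b = np.asarray(stat, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("need two equal-length vectors with at least 4 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


class BetaDiversity:
    """Model-style front end: decompose a raw community matrix.

    Parameters
    ----------
    community : CommunityMatrix
        Raw counts, biomass or presence; Hellinger transformation is applied
        internally (on the presence matrix for composition analyses).

    ``fit(nperm=..., seed=...)`` returns a :class:`BetaDivResult` with
    permutation p-values attached when ``nperm`` is given.
    """

    def __init__(self, community: CommunityMatrix):
        self.community = community

    def fit(self, nperm: int | None = 999, seed: int | None = None) -> BetaDivResult:
        from .transform import hellinger

        res = beta_div_decompose(hellinger(self.community))
        if nperm:
            p = lcbd_perm_test(self.community, nperm=nperm, seed=seed)
            res = BetaDivResult(
                ss_total=res.ss_total,
                bd_total=res.bd_total,
                scbd=res.scbd,
                lcbd=res.lcbd,
                measure=res.measure,
                lcbd_p=p,
                nperm=nperm,
                seed=seed,
            )
        return res
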