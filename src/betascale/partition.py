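"""Additive alpha-beta-gamma partitioning over a nested sampling hierarchy.

Total (gamma) diversity splits as gamma = alpha + beta1 + beta2 + beta3,
where alpha is the mean diversity of the lowest-level units (sites by
default), beta1 is the diversity gained moving from sites to areas, beta2
from areas to regions, and beta3 from regions to the pooled whole.  Both
species richness (q = 0) and Shannon entropy in nats (q = 1, made additive
by the natural-log transform) are supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .io import CommunityMatrix, Hierarchy, pool_to_level

__all__ = [
    "shannon_entropy",
    "unit_diversities",
    "level_mean_diversity",
    "additive_partition",
    "PartitionResult",
]


def shannon_entropy(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i in nats; zero counts contribute 0."""
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("entropy undefined for an all-zero vector")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def _diversity(row: np.ndarray, measure: str) -> float:
    if measure == "richness":
        return float((row > 0).sum())
    if measure == "shannon_entropy":
        return shannon_entropy(row)
    raise ValueError(f"unknown diversity measure {measure!r}")


def unit_diversities(
    M: CommunityMatrix, H: Hierarchy, level: str, measure: str
) -> pd.Series:
    """Per-unit diversity after pooling the community matrix to ``level``."""
    if measure == "shannon_entropy" and M.measure == "presence":
        raise ValueError("Shannon entropy requires abundance (or biomass) data")
    pooled = pool_to_level(M, H, level)
    vals = {
        unit: _diversity(row.to_numpy(dtype=float), measure)
        for unit, row in pooled.data.iterrows()
    }
    return pd.Series(vals, name=f"{measure}@{level}")


def level_mean_diversity(
    M: CommunityMatrix, H: Hierarchy, level: str, measure: str
) -> float:
    """Unweighted mean diversity across the units of ``level``."""
    return float(unit_diversities(M, H, level, measure).mean())


@dataclass(frozen=True)
class PartitionResult:
    """Additive diversity partition gamma = alpha + beta1 + beta2 + beta3."""

    measure: str
    alpha: float
    beta: tuple[float, float, float]  # (beta1 sites, beta2 areas, beta3 regions)
    gamma: float
    unit_diversities: dict[str, pd.Series] = field(repr=False)
    base_level: str = "site"

    def __post_init__(self) -> None:
        total = self.alpha + sum(self.beta)
        if abs(total - self.gamma) > 1e-10 * max(1.0, abs(self.gamma)):
            raise AssertionError("partition components do not sum to gamma")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("alpha", self.alpha),
            ("beta1_sites", self.beta[0]),
            ("beta2_areas", self.beta[1]),
            ("beta3_regions", self.beta[2]),
            ("gamma", self.gamma),
        ]
        return pd.DataFrame(rows, columns=["component", self.measure]).set_index(
            "component"
        )

    def summary(self) -> str:
        lines = [f"Additive diversity partition ({self.measure}, base level: {self.base_level})"]
        for name, value in self.to_frame()[self.measure].items():
            lines.append(f"  {name:<13s} {value:8.4f}")
        return "\n".join(lines)


def additive_partition(
    M: CommunityMatrix,
    H: Hierarchy,
    measure: str = "richness",
    base_level: str = "site",
) -> PartitionResult:
    """Partition diversity additively across the nested scale ladder.

    alpha   = mean diversity at ``base_level`` (site by default; point
              available for designs where the sampling point is the unit),
    beta1   = mean area diversity   - alpha,
    beta2   = mean region diversity - mean area diversity,
    beta3   = gamma                 - mean region diversity,
    gamma   = diversity of the fully pooled assemblage.
    """
    if base_level not in ("point", "site"):
        raise ValueError("base_level must be 'point' or 'site'")
    ladder = [base_level, "area", "region", "total"]
    if base_level == "point":
        ladder = ["point", "site", "area", "region", "total"]

    per_unit = {lvl: unit_diversities(M, H, lvl, measure) for lvl in ladder}
    means = [float(per_unit[lvl].mean()) for lvl in ladder]
    gamma = means[-1]

    if all(len(per_unit[lvl]) == 1 for lvl in ladder):
        warnings.warn("degenerate hierarchy: a single unit at every level; all beta = 0")

    betas = [means[i + 1] - means[i] for i in range(len(means) - 1)]
    if base_level == "point":
        # fold the extra point->site step into beta1 so three betas are reported
        betas = [betas[0] + betas[1], betas[2], betas[3]]
    return PartitionResult(
        measure=measure,
        alpha=means[0],
        beta=tuple(betas),
        gamma=gamma,
        unit_diversities=per_unit,
        base_level=base_level,
    )
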