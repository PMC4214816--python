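"""End-to-end orchestration: transform -> detrend -> partition -> beta
diversity -> spatial eigenvectors -> forward selection -> variation
partitioning, with every statistic logged and written to delimited tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .betadiv import BetaDivResult, beta_div_decompose, lcbd_correlates, lcbd_perm_test
from .mem import SCALES, build_staggered
from .partition import additive_partition
from .rda import forward_select, varpart_two_sets
from .transform import detrend, hellinger, trend_test

__all__ = ["RunConfig", "run_pipeline", "PipelineReport"]

log = logging.getLogger("betascale")

MEASURES = ("composition", "abundance", "biomass")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run."""

    community_path: str
    env_path: str
    coords_path: str
    hierarchy_path: str
    biomass_path: str | None = None
    measures: tuple[str, ...] = ("composition", "abundance", "biomass")
    scales: tuple[str, ...] = SCALES
    nperm: int = 999
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "results"
    detrend: bool = True
    holm: bool = False
    point_level_partition: bool = False
    env_candidates: tuple[str, ...] = ()  # empty -> all env columns

    def __post_init__(self) -> None:
        if self.nperm < 99:
            raise ValueError("nperm must be >= 99")
        if not self.measures:
            raise ValueError("select at least one measure")
        bad = [m for m in self.measures if m not in MEASURES]
        if bad:
            raise ValueError(f"unknown measure(s): {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("measures", "scales", "env_candidates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineReport:
    """All tables produced by one pipeline run, keyed by measure/scale."""

    trend: dict = field(default_factory=dict)
    partition: dict = field(default_factory=dict)
    betadiv: dict = field(default_factory=dict)
    correlates: dict = field(default_factory=dict)
    mem_counts: dict = field(default_factory=dict)
    env_selected: list = field(default_factory=list)
    spatial_selected: dict = field(default_factory=dict)
    varpart: dict = field(default_factory=dict)


def _measure_matrix(measure: str, abundance, biomass):
    if measure == "abundance":
        return abundance
    if measure == "biomass":
        if biomass is None:
            raise ValueError("biomass measure requested but no biomass table given")
        return biomass
    return bio.presence_from_counts(abundance)


def run_pipeline(cfg: RunConfig) -> PipelineReport:
    """Run the complete multi-scale analysis and write all result tables."""
    rng = np.random.default_rng(cfg.seed)

    def seeded() -> int:
        return int(rng.integers(2**31 - 1))

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()

    stage = "load"
    try:
        hierarchy = bio.read_table(cfg.hierarchy_path, "hierarchy")
        abundance = bio.align_to_hierarchy(
            bio.read_table(cfg.community_path, "community", measure="abundance"),
            hierarchy,
        )
        biomass = None
        if cfg.biomass_path:
            biomass = bio.align_to_hierarchy(
                bio.read_table(cfg.biomass_path, "community", measure="biomass"),
                hierarchy,
            )
        env = bio.align_to_hierarchy(bio.read_table(cfg.env_path, "env"), hierarchy)
        coords = bio.align_to_hierarchy(bio.read_table(cfg.coords_path, "coords"), hierarchy)
        log.info("stage=load points=%d species=%d env=%d",
                 len(hierarchy.point_ids), abundance.data.shape[1], env.shape[1])

        # standardized environmental predictors (never detrended)
        env_std = (env - env.mean()) / env.std(ddof=1)
        env_std = env_std.loc[:, env_std.notna().all()]
        candidates = list(cfg.env_candidates) or list(env_std.columns)

        stage = "spatial predictors"
        mems = {scale: build_staggered(hierarchy, coords, scale) for scale in cfg.scales}
        for scale, memset in mems.items():
            report.mem_counts[scale] = memset.n_columns
            bio.write_results(memset.matrix, out / f"mem_{scale}.tsv")
            bio.write_results(memset.meta, out / f"mem_{scale}_meta.tsv")
            log.info("stage=mem scale=%s columns=%d", scale, memset.n_columns)

        stage = "diversity partition"
        base = "point" if cfg.point_level_partition else "site"
        for measure_name, part_measure in (("richness", "richness"),
                                           ("shannon_entropy", "shannon_entropy")):
            part = additive_partition(abundance, hierarchy, measure=part_measure,
                                      base_level=base)
            report.partition[measure_name] = part
            bio.write_results(part, out / f"partition_{measure_name}.tsv")
            log.info("stage=partition measure=%s alpha=%.4f beta=%s gamma=%.4f",
                     measure_name, part.alpha,
                     ",".join(f"{b:.4f}" for b in part.beta), part.gamma)

        env_selection = None
        for measure in cfg.measures:
            M = _measure_matrix(measure, abundance, biomass)
            Y = hellinger(M)

            stage = f"trend test ({measure})"
            tt = trend_test(Y, coords, nperm=cfg.nperm, seed=seeded())
            report.trend[measure] = tt
            log.info("stage=trend measure=%s stat=F=%.4f df=%d p=%.4g",
                     measure, tt.f, tt.df, tt.p)
            Yd = detrend(Y, coords) if cfg.detrend else Y

            stage = f"beta diversity ({measure})"
            bd = beta_div_decompose(Y, measure=measure)
            pvals = lcbd_perm_test(M, nperm=cfg.nperm, seed=seeded())
            bd = BetaDivResult(ss_total=bd.ss_total, bd_total=bd.bd_total,
                               scbd=bd.scbd, lcbd=bd.lcbd, measure=measure,
                               lcbd_p=pvals, nperm=cfg.nperm, seed=cfg.seed)
            report.betadiv[measure] = bd
            bio.write_results(bd, out / f"betadiv_{measure}.tsv")
            log.info("stage=betadiv measure=%s stat=SS_Total=%.4f stat=BD_Total=%.4f "
                     "significant=%d", measure, bd.ss_total, bd.bd_total,
                     len(bd.significant_points(cfg.alpha, holm=cfg.holm)))

            stage = f"LCBD correlates ({measure})"
            descriptor = {
                "composition": (abundance.data > 0).sum(axis=1).astype(float),
                "abundance": abundance.data.sum(axis=1),
                "biomass": (biomass or abundance).data.sum(axis=1),
            }[measure]
            rho, p = lcbd_correlates(bd.lcbd, descriptor)
            report.correlates[measure] = (rho, p)
            log.info("stage=correlate measure=%s stat=rho=%.4f p=%.4g", measure, rho, p)

            stage = f"forward selection, environment ({measure})"
            if env_selection is None:
                # selection run once on the full dataset, reused at all scales
                env_selection = forward_select(Yd.data, env_std[candidates],
                                               alpha=cfg.alpha, nperm=cfg.nperm,
                                               seed=seeded())
                report.env_selected = env_selection.selected
                log.info("stage=forward_select set=env selected=%s global_p=%.4g",
                         ",".join(env_selection.selected) or "-", env_selection.global_p)
            E = env_std[env_selection.selected] if env_selection.selected else None

            for scale in cfg.scales:
                stage = f"forward selection, space ({measure}, {scale})"
                memset = mems[scale]
                sel = forward_select(Yd.data, memset.matrix, alpha=cfg.alpha,
                                     nperm=cfg.nperm, seed=seeded())
                if sel.selected:
                    S = memset.matrix[sel.selected]
                else:
                    # a failed global spatial test keeps the FULL spatial model
                    # in the report (its negative adjusted R^2 is informative)
                    S = memset.matrix
                report.spatial_selected[(measure, scale)] = sel.selected
                log.info("stage=forward_select set=space measure=%s scale=%s "
                         "selected=%s global_p=%.4g", measure, scale,
                         ",".join(sel.selected) or "-", sel.global_p)

                stage = f"variation partitioning ({measure}, {scale})"
                vp = varpart_two_sets(Yd.data, E, S, nperm=cfg.nperm, seed=seeded())
                report.varpart[(measure, scale)] = vp
                bio.write_results(vp, out / f"varpart_{measure}_{scale}.tsv")
                log.info("stage=varpart measure=%s scale=%s a=%.4f b=%.4f c=%.4f "
                         "d=%.4f p_E=%s p_S=%s", measure, scale, vp.a, vp.b, vp.c,
                         vp.d, vp.tests.get("E"), vp.tests.get("S"))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return report
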