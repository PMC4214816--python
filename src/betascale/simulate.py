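"""Hierarchical metacommunity simulator with recoverable ground truth.

The generator emulates a nested mainland-island sampling design: 2 regions,
each with 2 areas, each area with 5 sites of 5 sampling points, i.e. 100
points in total, with points ~50 m apart within a site and regions tens of
kilometres apart.  Species abundances arise from one of four scenarios:

* ``sorting``   — Gaussian niche responses to an environmental gradient,
* ``dispersal`` — nested species pools (species confined to one region or
                  area regardless of environment),
* ``mixed``     — both at once,
* ``null``      — constant expectation everywhere.

Counts are negative-binomial (overdispersed; Poisson in the limit of large
dispersion) and a biomass twin is derived from the counts with
species-specific mean masses and lognormal jitter, mirroring how field
biomass is obtained by drying and weighing the individuals caught.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CommunityMatrix, Hierarchy

__all__ = ["SimConfig", "simulate_layout", "simulate_env", "simulate_community",
           "simulate_dataset", "SimulatedDataset", "study_like"]

SCENARIOS = ("sorting", "dispersal", "mixed", "null")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the hierarchical metacommunity simulation.

    Spacings are in metres and strictly decrease down the ladder; the
    defaults mirror the mainland-island study design this package targets
    (2 x 2 x 5 x 5 layout, 21 species, 20 environmental descriptors,
    total catch in the low thousands).
    """

    n_regions: int = 2
    areas_per_region: int = 2
    sites_per_area: int = 5
    points_per_site: int = 5
    spacing_region: float = 40_000.0
    spacing_area: float = 15_000.0
    spacing_site: float = 1_200.0
    spacing_point: float = 50.0
    n_species: int = 21
    n_env: int = 20
    scenario: str = "mixed"
    niche_breadth: float = 1.0
    # environmental variance components (sd on the standardized scale)
    env_trend: float = 1.0
    env_region_sd: float = 0.5
    env_area_sd: float = 0.5
    env_site_sd: float = 1.0
    env_noise_sd: float = 0.5
    # dispersal restriction: species confined to one region / one area
    n_region_exclusive: int = 10
    n_area_exclusive: int = 0
    mean_total_abundance: float = 3000.0
    nb_dispersion: float = 2.0
    biomass_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        spacings = (self.spacing_region, self.spacing_area, self.spacing_site,
                    self.spacing_point)
        if not all(a > b > 0 for a, b in zip(spacings, spacings[1:])):
            raise ValueError("spacings must be strictly decreasing and positive")
        for name in ("n_regions", "areas_per_region", "sites_per_area",
                     "points_per_site", "n_species", "n_env"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_points(self) -> int:
        return (self.n_regions * self.areas_per_region
                * self.sites_per_area * self.points_per_site)


def study_like(**overrides) -> SimConfig:
    """The packaged fixture configuration mirroring the target study design."""
    return SimConfig(**overrides)


def simulate_layout(config: SimConfig) -> tuple[Hierarchy, pd.DataFrame]:
    """Nested coordinates and hierarchy labels for the configured layout.

    Region centres sit ``spacing_region`` apart on the easting axis; areas,
    sites and points are placed around their parent centre at the configured
    spacing (points on a 50 m transect with random orientation, like a trap
    line).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    rows, xy = [], []
    for r in range(config.n_regions):
        r_id = f"R{r + 1}"
        r_center = np.array([r * config.spacing_region, 0.0])
        for a in range(config.areas_per_region):
            a_id = f"{r_id}A{a + 1}"
            angle = rng.uniform(0, 2 * np.pi)
            a_center = r_center + config.spacing_area * np.array(
                [np.cos(angle), np.sin(angle)]
            ) * (0.5 + 0.5 * a / max(1, config.areas_per_region - 1))
            for s in range(config.sites_per_area):
                s_id = f"{a_id}S{s + 1}"
                angle = rng.uniform(0, 2 * np.pi)
                radius = config.spacing_site * (0.5 + rng.uniform(0, 1.0))
                s_center = a_center + radius * np.array([np.cos(angle), np.sin(angle)])
                direction = rng.uniform(0, 2 * np.pi)
                u = np.array([np.cos(direction), np.sin(direction)])
                jitter = rng.normal(0.0, 0.05 * config.spacing_point,
                                    size=(config.points_per_site, 2))
                for p in range(config.points_per_site):
                    p_id = f"{s_id}P{p + 1}"
                    rows.append((p_id, s_id, a_id, r_id))
                    xy.append(s_center + p * config.spacing_point * u + jitter[p])
    frame = pd.DataFrame(rows, columns=["point_id", "site_id", "area_id", "region_id"])
    frame = frame.set_index("point_id")
    coords = pd.DataFrame(np.asarray(xy), index=frame.index,
                          columns=["easting", "northing"])
    return Hierarchy(frame), coords


def simulate_env(
    hierarchy: Hierarchy, coords: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Environmental descriptors = broad trend + block effects + noise.

    Returns the points x n_env matrix and a ground-truth table with the
    realized variance fraction of each component per variable.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_points
    xy = coords.to_numpy(dtype=float)
    xy_std = (xy - xy.mean(axis=0)) / np.maximum(xy.std(axis=0), 1e-12)
    labels = {lvl: hierarchy.labels(lvl) for lvl in ("region", "area", "site")}
    sds = {"region": config.env_region_sd, "area": config.env_area_sd,
           "site": config.env_site_sd}

    cols, truth_rows = {}, []
    for v in range(config.n_env):
        direction = rng.normal(size=2)
        direction /= np.linalg.norm(direction)
        trend = config.env_trend * (xy_std @ direction) * rng.uniform(0.2, 1.0)
        value = trend.copy()
        parts = {"trend": trend}
        for lvl, sd in sds.items():
            units = labels[lvl]
            effects = {u: rng.normal(0, sd) for u in dict.fromkeys(units)}
            contrib = units.map(effects).to_numpy(dtype=float)
            value += contrib
            parts[lvl] = contrib
        noise = rng.normal(0, config.env_noise_sd, size=n)
        value += noise
        parts["noise"] = noise
        name = f"env{v + 1:02d}"
        cols[name] = value
        total_var = np.var(value)
        truth_rows.append(
            {"variable": name,
             **{f"var_frac_{k}": float(np.var(p) / total_var) for k, p in parts.items()}}
        )
    env = pd.DataFrame(cols, index=hierarchy.point_ids)
    truth = pd.DataFrame(truth_rows).set_index("variable")
    return env, truth


def _species_pools(hierarchy: Hierarchy, config: SimConfig, rng) -> pd.DataFrame:
    """0/1 mask (points x species): 1 where the species' pool allows it."""
    n, s = config.n_points, config.n_species
    mask = np.ones((n, s))
    regions = hierarchy.units("region")
    areas = hierarchy.units("area")
    region_of = hierarchy.labels("region").to_numpy()
    area_of = hierarchy.labels("area").to_numpy()
    k = 0
    for j in range(min(config.n_region_exclusive, s)):
        home = regions[j % len(regions)]
        mask[region_of != home, k] = 0.0
        k += 1
    for j in range(min(config.n_area_exclusive, s - k)):
        home = areas[j % len(areas)]
        mask[area_of != home, k] = 0.0
        k += 1
    return pd.DataFrame(mask, index=hierarchy.point_ids,
                        columns=[f"sp{j + 1:02d}" for j in range(s)])


def simulate_community(
    hierarchy: Hierarchy,
    coords: pd.DataFrame,
    env: pd.DataFrame,
    config: SimConfig,
) -> tuple[CommunityMatrix, CommunityMatrix, dict]:
    """Draw the abundance matrix and its biomass twin for the scenario.

    Returns (abundance, biomass, ground_truth).  Ground truth records the
    species pool mask and, for niche scenarios, each species' optimum.
    """
    rng = np.random.default_rng(config.seed + 2)
    n, s = config.n_points, config.n_species
    species = [f"sp{j + 1:02d}" for j in range(s)]

    gradient = env.iloc[:, 0].to_numpy(dtype=float)
    gradient = (gradient - gradient.mean()) / max(gradient.std(), 1e-12)

    log_scale = rng.normal(0.0, 1.0, size=s)  # lognormal species-abundance spread
    optima = np.linspace(gradient.min(), gradient.max(), s)
    rng.shuffle(optima)

    if config.scenario in ("sorting", "mixed"):
        niche = np.exp(
            -((gradient[:, None] - optima[None, :]) ** 2)
            / (2.0 * config.niche_breadth**2)
        )
    else:
        niche = np.ones((n, s))
    lam = niche * np.exp(log_scale)[None, :]

    if config.scenario in ("dispersal", "mixed"):
        pools = _species_pools(hierarchy, config, rng)
        lam = lam * pools.to_numpy()
    else:
        pools = pd.DataFrame(np.ones((n, s)), index=hierarchy.point_ids,
                             columns=species)

    total = lam.sum()
    if total <= 0:
        raise ValueError("degenerate configuration: zero expected abundance")
    lam *= config.mean_total_abundance / total

    k = config.nb_dispersion
    p = k / (k + np.maximum(lam, 1e-12))
    counts = np.where(lam > 0, rng.negative_binomial(k, p), 0).astype(float)

    masses = np.exp(rng.normal(np.log(0.05), 1.0, size=s))  # g per individual
    jitter = np.exp(rng.normal(0.0, config.biomass_cv, size=(n, s)))
    biomass = counts * masses[None, :] * jitter

    abundance = CommunityMatrix(
        pd.DataFrame(counts, index=hierarchy.point_ids, columns=species),
        measure="abundance",
    )
    biomass_m = CommunityMatrix(
        pd.DataFrame(biomass, index=hierarchy.point_ids, columns=species),
        measure="biomass",
    )
    truth = {
        "pools": pools,
        "optima": pd.Series(optima, index=species, name="optimum"),
        "masses": pd.Series(masses, index=species, name="mean_mass_g"),
        "gradient_variable": env.columns[0],
    }
    return abundance, biomass_m, truth


@dataclass(frozen=True)
class SimulatedDataset:
    """The four input tables plus simulation ground truth."""

    config: SimConfig
    hierarchy: Hierarchy
    coords: pd.DataFrame
    env: pd.DataFrame
    abundance: CommunityMatrix
    biomass: CommunityMatrix
    truth: dict = field(repr=False)

    def write(self, directory) -> dict[str, Path]:
        """Emit the four delimited files the loaders read, plus the config."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "community": directory / "community.csv",
            "biomass": directory / "biomass.csv",
            "env": directory / "env.csv",
            "coords": directory / "coords.csv",
            "hierarchy": directory / "hierarchy.csv",
            "config": directory / "sim_config.txt",
        }
        self.abundance.data.to_csv(paths["community"], float_format="%.17g")
        self.biomass.data.to_csv(paths["biomass"], float_format="%.17g")
        self.env.to_csv(paths["env"], float_format="%.17g")
        self.coords.to_csv(paths["coords"], float_format="%.17g")
        self.hierarchy.frame.to_csv(paths["hierarchy"])
        with open(paths["config"], "w", encoding="utf-8") as fh:
            for key, value in asdict(self.config).items():
                fh.write(f"{key}={value}\n")
        return paths


def simulate_dataset(config: SimConfig | None = None, **overrides) -> SimulatedDataset:
    """One-call generator of a complete synthetic study dataset."""
    config = config or SimConfig(**overrides)
    hierarchy, coords = simulate_layout(config)
    env, env_truth = simulate_env(hierarchy, coords, config)
    abundance, biomass, truth = simulate_community(hierarchy, coords, env, config)
    truth = dict(truth)
    truth["env_variance_fractions"] = env_truth
    return SimulatedDataset(
        config=config, hierarchy=hierarchy, coords=coords, env=env,
        abundance=abundance, biomass=biomass, truth=truth,
    )
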