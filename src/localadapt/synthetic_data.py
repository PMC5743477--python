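"""Synthetic reciprocal-transplant datasets with known ground truth.

The generator draws log-normal biomass so that every simulated plant has a
strictly positive weight and the sympatry advantage acts multiplicatively —
a log-scale effect ``delta`` corresponds to a ``100 * (exp(delta) - 1)``
percent biomass advantage of local plants, the scale on which sympatric vs.
allopatric effect sizes are reported downstream.

Data-generating model, per species ``s``::

    log biomass = log(mean_s) + G[s, garden] + Q[s, ecotype]
                  + delta * 1[ecotype == garden] + eps

with garden effects ``G ~ N(0, garden_effect_sd^2)``, ecotype intrinsic
quality ``Q ~ N(0, ecotype_quality_sd^2)`` (both drawn once per species and
held fixed across replicates) and residual ``eps ~ N(0, species_sd_log^2)``
per plant.  ``delta = 0`` means no local adaptation.

:func:`study_design_config` reproduces the benchmark study layout: six
species in four regions, four of them with ecotypes from all four regions
and two with only three, twelve replicates per ecotype × garden — 22
species × garden cells and 984 plants in the full reciprocal design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_and_io import TransplantDataset

__all__ = [
    "SimulationConfig",
    "study_design_config",
    "generate_dataset",
    "ground_truth",
    "implied_standardized_sympatry_effect",
]

#: Default region vocabulary for the benchmark design (four garden regions).
DEFAULT_REGIONS = ("F", "H", "M", "T")

# Species geometric-mean biomasses (grams) used by the benchmark config.
# Chosen to span the sub-gram to ~10 g range typical of first-season
# aboveground biomass in temperate grassland perennials, so that the
# within-species standardization step has real work to do.
_DEFAULT_SPECIES_MEANS = {
    "sp1": 8.0,
    "sp2": 2.5,
    "sp3": 1.2,
    "sp4": 4.0,
    "sp5": 0.6,
    "sp6": 1.8,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic reciprocal-transplant generator.

    Attributes
    ----------
    regions
        Ordered region vocabulary (each region hosts one garden).
    species_specs
        ``(species_id, available_regions)`` pairs; a species contributes one
        ecotype per available region and is planted in the gardens of those
        same regions (full reciprocal design).
    replicates
        Plants per species × garden × ecotype cell.
    species_mean
        Geometric mean biomass in grams, per species (mapping) or shared
        scalar; enters the model as a log-scale location.
    species_sd_log
        Residual SD of log biomass (plant-to-plant noise), dimensionless.
    garden_effect_sd, ecotype_quality_sd
        SDs of the per-species garden main effects and ecotype intrinsic
        quality effects on the log scale.
    sympatry_effect
        Log-scale advantage ``delta`` of plants growing in their region of
        origin; 0 means no local adaptation.
    mortality_rate
        Probability that a plant's biomass is missing (died before harvest).
    seed
        Seed for the generator; the whole dataset is reproducible from it.
    """

    regions: tuple[str, ...] = DEFAULT_REGIONS
    species_specs: tuple[tuple[str, tuple[str, ...]], ...] = ()
    replicates: int = 12
    species_mean: Mapping[str, float] | float = 1.0
    species_sd_log: float = 0.4
    garden_effect_sd: float = 0.3
    ecotype_quality_sd: float = 0.2
    sympatry_effect: float = 0.0
    mortality_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("species_sd_log", "garden_effect_sd", "ecotype_quality_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ValueError("mortality_rate must be in [0, 1]")
        for sp, regs in self.species_specs:
            extra = set(regs) - set(self.regions)
            if extra:
                raise ValueError(f"species {sp!r} lists unknown region(s) {sorted(extra)}")

    def mean_of(self, species: str) -> float:
        if isinstance(self.species_mean, Mapping):
            return float(self.species_mean[species])
        return float(self.species_mean)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(self.species_mean, Mapping):
            d["species_mean"] = dict(self.species_mean)
        return d


def study_design_config(sympatry_effect: float = 0.0, seed: int = 0, **overrides) -> SimulationConfig:
    """Benchmark six-species, four-garden full reciprocal design.

    Four species have ecotypes from all four regions; two species (``sp5``,
    ``sp6``) have ecotypes from only three, so their gardens are likewise
    restricted.  With 12 replicates this yields 4 x 16 + 2 x 9 = 82 ecotype
    x garden combinations, 22 species x garden cells, and 984 plants.

    Extra keyword arguments override any :class:`SimulationConfig` field
    (e.g. ``replicates=48`` for a scaled-up run).
    """
    specs = (
        ("sp1", ("F", "H", "M", "T")),
        ("sp2", ("F", "H", "M", "T")),
        ("sp3", ("F", "H", "M", "T")),
        ("sp4", ("F", "H", "M", "T")),
        ("sp5", ("F", "H", "M")),
        ("sp6", ("F", "H", "T")),
    )
    kwargs = dict(
        regions=DEFAULT_REGIONS,
        species_specs=specs,
        replicates=12,
        species_mean=dict(_DEFAULT_SPECIES_MEANS),
        sympatry_effect=float(sympatry_effect),
        mortality_rate=0.0,
        seed=int(seed),
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _split_rngs(cfg: SimulationConfig):
    """Deterministic RNG streams: (effects, residuals, mortality).

    Effects are drawn on their own stream in fixed (species, region) order,
    so the realized garden/ecotype effects do not depend on replicates or
    mortality settings.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _draw_effects(cfg: SimulationConfig, rng: np.random.Generator):
    garden_effects: dict[tuple[str, str], float] = {}
    ecotype_effects: dict[tuple[str, str], float] = {}
    for sp, regs in cfg.species_specs:
        g = rng.normal(0.0, cfg.garden_effect_sd, size=len(regs))
        q = rng.normal(0.0, cfg.ecotype_quality_sd, size=len(regs))
        for r, gi, qi in zip(regs, g, q):
            garden_effects[(sp, r)] = float(gi)
            ecotype_effects[(sp, r)] = float(qi)
    return garden_effects, ecotype_effects


def generate_dataset(cfg: SimulationConfig) -> TransplantDataset:
    """Draw a complete synthetic dataset under ``cfg``.

    Returns a validated :class:`TransplantDataset` with one record per
    species × garden × ecotype × replicate; biomass values are strictly
    positive; a fraction ``mortality_rate`` of records is independently set
    missing.
    """
    if not cfg.species_specs:
        raise ValueError("species_specs is empty; nothing to generate")
    rng_eff, rng_obs, rng_mort = _split_rngs(cfg)
    G, Q = _draw_effects(cfg, rng_eff)

    frames = []
    for sp, regs in cfg.species_specs:
        log_mean = np.log(cfg.mean_of(sp))
        rows_g, rows_e, rows_r, mu = [], [], [], []
        for g in regs:
            for e in regs:
                loc = log_mean + G[(sp, g)] + Q[(sp, e)] + cfg.sympatry_effect * (e == g)
                for r in range(1, cfg.replicates + 1):
                    rows_g.append(g)
                    rows_e.append(e)
                    rows_r.append(r)
                    mu.append(loc)
        eps = rng_obs.normal(0.0, cfg.species_sd_log, size=len(mu))
        frames.append(
            pd.DataFrame(
                {
                    "species": sp,
                    "garden": rows_g,
                    "ecotype": rows_e,
                    "replicate": rows_r,
                    "biomass": np.exp(np.asarray(mu) + eps),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if cfg.mortality_rate > 0:
        dead = rng_mort.random(len(df)) < cfg.mortality_rate
        df.loc[dead, "biomass"] = np.nan
    return TransplantDataset(df, regions=cfg.regions)


def ground_truth(cfg: SimulationConfig) -> dict:
    """True parameters behind :func:`generate_dataset` for the same config.

    Returns the sympatry effect ``delta``, the per-species geometric means,
    and the realized garden and ecotype effect draws (identical to the ones
    used by :func:`generate_dataset` with this config)."""
    rng_eff, _, _ = _split_rngs(cfg)
    G, Q = _draw_effects(cfg, rng_eff)
    return {
        "sympatry_effect": cfg.sympatry_effect,
        "species_means": {sp: cfg.mean_of(sp) for sp, _ in cfg.species_specs},
        "garden_effects": G,
        "ecotype_effects": Q,
    }


def implied_standardized_sympatry_effect(cfg: SimulationConfig) -> float:
    """Population-level sympatry contrast in within-species SD units.

    This is the estimand targeted by the cross-species standardized mixed
    model: the infinite-replicate limit of its sympatry coefficient for the
    realized garden/ecotype effects of ``cfg``.  It is computed analytically
    from the log-normal moments — per cell ``(s, g, e)`` the expected
    biomass is ``mean_s * exp(G + Q + delta*1[e==g] + sd_log^2 / 2)`` — by
    standardizing the expected values within species and projecting them
    onto garden + sympatry + ecotype-within-species dummies (the
    fixed-effect limit of the random-intercept fit as group sizes grow).
    """
    truth = ground_truth(cfg)
    G, Q = truth["garden_effects"], truth["ecotype_effects"]
    s2 = cfg.species_sd_log**2

    rows = []
    for sp, regs in cfg.species_specs:
        m = cfg.mean_of(sp)
        cells = [(g, e) for g in regs for e in regs]
        ey = np.array(
            [
                m * np.exp(G[(sp, g)] + Q[(sp, e)] + cfg.sympatry_effect * (e == g) + s2 / 2)
                for g, e in cells
            ]
        )
        ey2 = np.array(
            [
                m**2 * np.exp(2 * (G[(sp, g)] + Q[(sp, e)] + cfg.sympatry_effect * (e == g)) + 2 * s2)
                for g, e in cells
            ]
        )
        mu = ey.mean()
        var = ey2.mean() - mu**2
        z = (ey - mu) / np.sqrt(var)
        for (g, e), zi in zip(cells, z):
            rows.append((sp, g, e, zi))

    cell = pd.DataFrame(rows, columns=["species", "garden", "ecotype", "z"])
    gardens = sorted(cell["garden"].unique())
    groups = list(dict.fromkeys(zip(cell["species"], cell["ecotype"])))
    n = len(cell)
    # garden dummies (drop first) + sympatry + one dummy per species:ecotype
    X = np.zeros((n, (len(gardens) - 1) + 1 + len(groups)))
    for j, g in enumerate(gardens[1:]):
        X[:, j] = (cell["garden"] == g).to_numpy(float)
    X[:, len(gardens) - 1] = (cell["garden"] == cell["ecotype"]).to_numpy(float)
    for j, (sp, e) in enumerate(groups):
        X[:, len(gardens) + j] = ((cell["species"] == sp) & (cell["ecotype"] == e)).to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, cell["z"].to_numpy(), rcond=None)
    return float(beta[len(gardens) - 1])
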