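"""Continuous-food extension of the patch model.

Instead of binary food states, each patch carries a food amount f in [0, 1]
driven by a shared, temporally autocorrelated resource (latent AR(1) mapped
into [0, 1]) plus per-patch spatial Gaussian noise, clipped to [0, 1].  Patch
production interpolates linearly between the empirical food-poor and food-rich
draws: (1 - f) * X_poor + f * X_rich, with the infected rich component scaled
by (1 - c).  The endpoints f = 0 and f = 1 reduce exactly to the binary model,
which is the property the cross-model consistency tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import (
    ReplicateResult,
    SimulationConfig,
    SporePool,
    disperse,
)
from .synthetic import INFECTED_PHENOTYPES, PHENOTYPES, ar1_series


@dataclass
class ContinuousEnvConfig:
    """Parameters of the continuous-food simulation."""

    base: SimulationConfig = field(default_factory=SimulationConfig)
    phi: float = 0.5  # lag-1 autocorrelation of the latent resource
    innovation_sd: float = 1.0
    spatial_sd: float = 0.1  # per-patch noise around the shared resource
    resource_center: float = 0.0  # latent offset; negative -> more food-poor

    def validate(self) -> None:
        if abs(self.phi) >= 1:
            raise ValueError(f"|phi| must be < 1, got {self.phi}")
        if self.innovation_sd < 0:
            raise ValueError(f"innovation_sd must be >= 0, got {self.innovation_sd}")
        if self.spatial_sd < 0:
            raise ValueError(f"spatial_sd must be >= 0, got {self.spatial_sd}")
        # the binary-model p/v_temp fields are unused here; skip their checks
        if self.base.n_patches < 1 or self.base.n_rounds < 1:
            raise ValueError("n_patches and n_rounds must be >= 1")
        if not 0 <= self.base.c <= 1:
            raise ValueError(f"c must be in [0, 1], got {self.base.c}")
        if not 0 < self.base.g <= 1:
            raise ValueError(f"g must be in (0, 1], got {self.base.g}")
        if self.base.sorus_size <= 0:
            raise ValueError(f"sorus_size must be > 0, got {self.base.sorus_size}")


def food_from_resource(
    resource_t: float,
    spatial_sd: float,
    n_patches: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-patch food amounts: clip(resource + N(0, spatial_sd), 0, 1)."""
    if not 0 <= resource_t <= 1:
        raise ValueError(f"resource_t must be in [0, 1], got {resource_t}")
    if spatial_sd == 0:
        return np.full(n_patches, resource_t)
    food = resource_t + rng.normal(0.0, spatial_sd, size=n_patches)
    return np.clip(food, 0.0, 1.0)


@dataclass
class ContinuousEnvironment:
    """Realized resource series and per-patch food amounts for one replicate."""

    resource: np.ndarray  # length n_rounds, in [0, 1]
    food: np.ndarray  # (n_rounds, n_patches), in [0, 1]


def draw_continuous_environment(config: ContinuousEnvConfig) -> ContinuousEnvironment:
    """Shared resource (logistic AR(1)) plus spatial noise, one environment seed."""
    config.validate()
    rng = np.random.default_rng(config.base.environment_seed)
    latent = ar1_series(
        config.base.n_rounds, config.phi, config.innovation_sd, rng
    )
    resource = 1.0 / (1.0 + np.exp(-(latent + config.resource_center)))
    food = np.empty((config.base.n_rounds, config.base.n_patches))
    for t in range(config.base.n_rounds):
        food[t] = food_from_resource(
            float(resource[t]), config.spatial_sd, config.base.n_patches, rng
        )
    return ContinuousEnvironment(resource=resource, food=food)


def continuous_production(
    phenotype: str,
    food: float,
    spore_pool: SporePool,
    c: float,
    rng: np.random.Generator,
) -> float:
    """One patch's production at food level f: (1-f)*X_poor + f*X_rich."""
    if not 0 <= food <= 1:
        raise ValueError(f"food must be in [0, 1], got {food}")
    x_poor = float(spore_pool.draw(phenotype, "poor", 1, rng)[0])
    x_rich = float(spore_pool.draw(phenotype, "rich", 1, rng)[0])
    if phenotype in INFECTED_PHENOTYPES:
        x_rich *= 1.0 - c
    return (1.0 - food) * x_poor + food * x_rich


def _round_total_continuous(
    phenotype: str,
    occupied: np.ndarray,
    food_row: np.ndarray,
    pool: SporePool,
    c: float,
    rng: np.random.Generator,
) -> float:
    n_occ = int(np.count_nonzero(occupied))
    if n_occ == 0:
        return 0.0
    f = food_row[occupied]
    x_poor = pool.draw(phenotype, "poor", n_occ, rng)
    x_rich = pool.draw(phenotype, "rich", n_occ, rng)
    if phenotype in INFECTED_PHENOTYPES:
        x_rich = x_rich * (1.0 - c)
    return float(np.sum((1.0 - f) * x_poor + f * x_rich))


def simulate_phenotype_continuous(
    phenotype: str,
    env: ContinuousEnvironment,
    pool: SporePool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ReplicateResult:
    """Run one phenotype through a fixed continuous-food environment.

    Same loop as the binary :func:`dictypatch.simulate.simulate_phenotype`:
    production per occupied patch, global sorus dispersal, absorbing
    extinction on a zero round.  With a food matrix containing only 0s and 1s
    this reduces exactly to the binary model.
    """
    n_rounds, n_patches = env.food.shape
    occupied = np.ones(n_patches, dtype=bool)
    totals = np.zeros(n_rounds)
    extinction_round: int | None = None
    for t in range(n_rounds):
        total = _round_total_continuous(
            phenotype, occupied, env.food[t], pool, config.c, rng
        )
        totals[t] = total
        if total == 0.0:
            extinction_round = t
            break
        if t < n_rounds - 1:
            occupied = disperse(total, config.sorus_size, n_patches, config.g, rng)
    return ReplicateResult(
        phenotype=phenotype, totals=totals, extinction_round=extinction_round
    )


def run_continuous_replicate(
    config: ContinuousEnvConfig, pool: SporePool
) -> dict[str, ReplicateResult]:
    """Continuous-food analogue of :func:`dictypatch.simulate.run_replicate`.

    Same structure: shared environment across the three phenotypes,
    independent demographic streams, absorbing extinction on a zero round.
    """
    config.validate()
    env = draw_continuous_environment(config)
    streams = np.random.SeedSequence(config.base.demographic_seed).spawn(
        len(PHENOTYPES)
    )
    return {
        phenotype: simulate_phenotype_continuous(
            phenotype, env, pool, config.base, np.random.default_rng(stream)
        )
        for phenotype, stream in zip(PHENOTYPES, streams)
    }
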