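"""Stochastic patch-colonization simulator.

The model: an environment of ``n_patches`` discrete soil patches, each food
poor with probability ``p_t`` (food rich otherwise) in round ``t``.  The mean
food-poor probability is ``p``; temporal variability enters by drawing ``p_t``
each round from a beta distribution with mean ``p`` and variance ``v_temp``
(moment-matched).  Every patch starts occupied.  Each occupied patch produces
spores drawn from the empirical plate-level distribution for its phenotype and
food state; infected hosts pay a fractional cost ``c`` in food-rich patches
(the context where carrying symbionts has been found costly).  Round totals
are converted to sori (dispersal units of ``sorus_size`` spores), each sorus
lands on a uniformly random patch and establishes with probability ``g``, and
the colonized patches form the next round's occupancy (previous occupants are
assumed dispersed away; multiply-colonized patches behave like singly
colonized ones).  A round with zero total production is extinction, which is
absorbing.

Long-run success is summarized by geometric mean (GM) and arithmetic mean (AM)
per-round total spore production: GM is the growth criterion in variable
environments because it is annihilated by any catastrophic round, and a
strategy with lower AM but higher GM than its rival is bet-hedging.

The three host phenotypes are simulated separately but share the environment
sequence within a replicate (common random numbers for the environment,
independent demographic streams per phenotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic import CONTEXTS, INFECTED_PHENOTYPES, PHENOTYPES


def geometric_mean(series) -> float:
    """exp(mean(log x)); exactly 0 if any value is 0.

    The zero-annihilation rule is the point: a lineage wiped out in one round
    has zero long-run growth no matter how good the other rounds were.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("geometric_mean needs at least one value")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("geometric_mean requires finite non-negative values")
    if np.any(x == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(x))))


def arithmetic_mean(series) -> float:
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("arithmetic_mean needs at least one value")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("arithmetic_mean requires finite non-negative values")
    return float(np.mean(x))


@dataclass(frozen=True)
class BetaSpec:
    """Beta distribution shape parameters moment-matched to (p, v_temp)."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def beta_params_from_moments(p: float, v_temp: float) -> BetaSpec:
    """Beta shape parameters with mean ``p`` and variance ``v_temp``.

    alpha = p*k, beta = (1-p)*k with k = p(1-p)/v_temp - 1.  Requires
    0 < v_temp < p(1-p); the v_temp = 0 case is handled upstream by the
    degenerate branch p_t = p.
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    limit = p * (1.0 - p)
    if v_temp <= 0:
        raise ValueError(f"v_temp must be > 0 for a beta draw, got {v_temp}")
    if v_temp >= limit:
        raise ValueError(
            f"infeasible variance: v_temp={v_temp} must be < p(1-p)={limit}"
        )
    k = limit / v_temp - 1.0
    return BetaSpec(alpha=p * k, beta=(1.0 - p) * k)


@dataclass
class SimulationConfig:
    """All parameters of the binary-food patch simulation."""

    n_patches: int = 100
    n_rounds: int = 100
    n_replicates: int = 100
    p: float = 0.5  # mean probability a patch is food poor
    v_temp: float = 0.01  # temporal variance of p_t
    c: float = 0.0  # fractional infection cost in food-rich patches
    g: float = 0.05  # per-sorus colonization probability
    sorus_size: float = 2e5  # spores per sorus (the dispersal unit)
    environment_seed: int = 0
    demographic_seed: int = 1

    def validate(self) -> None:
        if self.n_patches < 1 or self.n_rounds < 1 or self.n_replicates < 1:
            raise ValueError("n_patches, n_rounds, n_replicates must be >= 1")
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0, 1), got {self.p}")
        if self.v_temp < 0:
            raise ValueError(f"v_temp must be >= 0, got {self.v_temp}")
        if self.v_temp > 0 and self.v_temp >= self.p * (1.0 - self.p):
            raise ValueError(
                f"infeasible variance: v_temp={self.v_temp} >= p(1-p)="
                f"{self.p * (1.0 - self.p)}"
            )
        if not 0 <= self.c <= 1:
            raise ValueError(f"c must be in [0, 1], got {self.c}")
        if not 0 < self.g <= 1:
            raise ValueError(f"g must be in (0, 1], got {self.g}")
        if self.sorus_size <= 0:
            raise ValueError(f"sorus_size must be > 0, got {self.sorus_size}")

    def with_seeds(self, environment_seed: int, demographic_seed: int) -> "SimulationConfig":
        return replace(
            self,
            environment_seed=environment_seed,
            demographic_seed=demographic_seed,
        )


@dataclass
class EnvironmentSequence:
    """Realized environment for one replicate, shared across phenotypes.

    ``p_t`` has length n_rounds; ``poor`` is a (n_rounds, n_patches) boolean
    matrix, True where the patch is food poor that round.
    """

    p_t: np.ndarray
    poor: np.ndarray

    @property
    def n_rounds(self) -> int:
        return self.p_t.shape[0]

    @property
    def n_patches(self) -> int:
        return self.poor.shape[1]


def draw_environment(config: SimulationConfig) -> EnvironmentSequence:
    """Draw the per-round food-poor probabilities and patch states.

    With ``v_temp > 0`` each round's ``p_t`` is a beta draw (mean p, variance
    v_temp); with ``v_temp = 0`` the probability is constant at ``p`` and all
    variation is spatial.  Patch states are iid Bernoulli(p_t) within a round.
    Deterministic given ``environment_seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.environment_seed)
    if config.v_temp == 0:
        p_t = np.full(config.n_rounds, config.p)
    else:
        spec = beta_params_from_moments(config.p, config.v_temp)
        p_t = rng.beta(spec.alpha, spec.beta, size=config.n_rounds)
    poor = rng.random((config.n_rounds, config.n_patches)) < p_t[:, None]
    return EnvironmentSequence(p_t=p_t, poor=poor)


class SporePool:
    """Empirical spore-production values pooled by (phenotype, food context).

    The simulator draws per-patch production by resampling uniformly with
    replacement from the matching cell, so any plate-level table (synthetic or
    real) parameterizes the model without distributional assumptions.
    """

    def __init__(self, table: pd.DataFrame):
        self.cells: dict[tuple[str, str], np.ndarray] = {}
        for (phenotype, context), group in table.groupby(
            ["phenotype", "food_context"], sort=True
        ):
            values = group["spores_per_plate"].to_numpy(dtype=float)
            if np.any(values < 0) or not np.all(np.isfinite(values)):
                raise ValueError(
                    f"spores_per_plate must be finite and >= 0 in cell "
                    f"({phenotype}, {context})"
                )
            self.cells[(str(phenotype), str(context))] = values

    def values(self, phenotype: str, context: str) -> np.ndarray:
        try:
            return self.cells[(phenotype, context)]
        except KeyError:
            raise ValueError(
                f"spore pool has no records for cell ({phenotype}, {context})"
            ) from None

    def draw(
        self, phenotype: str, context: str, size: int, rng: np.random.Generator
    ) -> np.ndarray:
        values = self.values(phenotype, context)
        if size == 0:
            return np.empty(0)
        return values[rng.integers(0, values.size, size=size)]


def patch_spore_production(
    phenotype: str,
    food_state: str,
    spore_pool: SporePool,
    c: float,
    rng: np.random.Generator,
) -> float:
    """Spore output of one occupied patch.

    One value resampled from the pool's (phenotype, food_state) cell; infected
    phenotypes in food-rich patches are penalized by the factor (1 - c).
    """
    if food_state not in CONTEXTS:
        raise ValueError(f"food_state must be one of {CONTEXTS}, got {food_state!r}")
    if phenotype not in PHENOTYPES:
        raise ValueError(f"phenotype must be one of {PHENOTYPES}, got {phenotype!r}")
    value = float(spore_pool.draw(phenotype, food_state, 1, rng)[0])
    if phenotype in INFECTED_PHENOTYPES and food_state == "rich":
        value *= 1.0 - c
    return value


def _round_total(
    phenotype: str,
    occupied: np.ndarray,
    poor_row: np.ndarray,
    pool: SporePool,
    c: float,
    rng: np.random.Generator,
) -> float:
    """Total production of all occupied patches in one round (vectorized)."""
    poor_occ = int(np.count_nonzero(occupied & poor_row))
    rich_occ = int(np.count_nonzero(occupied & ~poor_row))
    total = float(pool.draw(phenotype, "poor", poor_occ, rng).sum())
    rich = float(pool.draw(phenotype, "rich", rich_occ, rng).sum())
    if phenotype in INFECTED_PHENOTYPES:
        rich *= 1.0 - c
    return total + rich


def n_sori_from_spores(
    total_spores: float, sorus_size: float, rng: np.random.Generator
) -> int:
    """Sorus count with stochastic rounding of the fractional remainder."""
    if total_spores < 0:
        raise ValueError(f"total_spores must be >= 0, got {total_spores}")
    whole, frac = divmod(total_spores / sorus_size, 1.0)
    n = int(whole)
    if frac > 0 and rng.random() < frac:
        n += 1
    return n


def disperse(
    total_spores: float,
    sorus_size: float,
    n_patches: int,
    g: float,
    rng: np.random.Generator,
    method: str = "binomial",
) -> np.ndarray:
    """Global dispersal: which empty patches get colonized next round.

    Each sorus lands on a uniformly random patch and establishes with
    probability ``g``; a patch is colonized iff at least one sorus succeeds.
    ``method='binomial'`` thins successes first (Binomial(n_sori, g)) and
    spreads them multinomially over patches — distributionally identical to
    the explicit ``method='per_sorus'`` loop, which is kept as the slow
    reference route.  Returns a boolean occupancy vector.
    """
    n_sori = n_sori_from_spores(total_spores, sorus_size, rng)
    occupied = np.zeros(n_patches, dtype=bool)
    if n_sori == 0:
        return occupied
    if method == "binomial":
        n_hit = rng.binomial(n_sori, g)
        if n_hit == 0:
            return occupied
        counts = rng.multinomial(n_hit, np.full(n_patches, 1.0 / n_patches))
        return counts > 0
    if method == "per_sorus":
        for _ in range(n_sori):
            patch = int(rng.integers(0, n_patches))
            if rng.random() < g:
                occupied[patch] = True
        return occupied
    raise ValueError(f"unknown dispersal method {method!r}")


@dataclass
class ReplicateResult:
    """One phenotype's trajectory within one replicate."""

    phenotype: str
    totals: np.ndarray  # per-round total spore production, length n_rounds
    extinction_round: int | None
    geometric_mean: float = field(init=False)
    arithmetic_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.geometric_mean = geometric_mean(self.totals)
        self.arithmetic_mean = arithmetic_mean(self.totals)

    @property
    def extinct(self) -> bool:
        return self.extinction_round is not None


def simulate_phenotype(
    phenotype: str,
    env: EnvironmentSequence,
    pool: SporePool,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> ReplicateResult:
    """Run one phenotype through a fixed environment sequence.

    All patches start occupied.  Each round: production per occupied patch
    (by that round's food states), then global sorus dispersal into fresh
    empty patches.  A zero round-total marks extinction, after which all
    later totals are 0.
    """
    n_rounds, n_patches = env.n_rounds, env.n_patches
    occupied = np.ones(n_patches, dtype=bool)
    totals = np.zeros(n_rounds)
    extinction_round: int | None = None
    for t in range(n_rounds):
        total = _round_total(phenotype, occupied, env.poor[t], pool, config.c, rng)
        totals[t] = total
        if total == 0.0:
            extinction_round = t
            break
        if t < n_rounds - 1:
            occupied = disperse(
                total, config.sorus_size, n_patches, config.g, rng
            )
    return ReplicateResult(
        phenotype=phenotype, totals=totals, extinction_round=extinction_round
    )


def run_replicate(
    config: SimulationConfig, pool: SporePool
) -> dict[str, ReplicateResult]:
    """Simulate all three phenotypes on one shared environment sequence.

    The environment stream (``environment_seed``) is common to the phenotypes;
    each phenotype gets its own demographic stream spawned deterministically
    from ``demographic_seed``.
    """
    config.validate()
    env = draw_environment(config)
    streams = np.random.SeedSequence(config.demographic_seed).spawn(len(PHENOTYPES))
    return {
        phenotype: simulate_phenotype(
            phenotype, env, pool, config, np.random.default_rng(stream)
        )
        for phenotype, stream in zip(PHENOTYPES, streams)
    }


def trajectories_frame(
    results: dict[int, dict[str, ReplicateResult]]
) -> pd.DataFrame:
    """Tidy per-round totals: columns replicate, phenotype, round, total_spores."""
    rows = []
    for replicate, by_phen in results.items():
        for phenotype, res in by_phen.items():
            for t, total in enumerate(res.totals):
                rows.append((replicate, phenotype, t, total))
    return pd.DataFrame(
        rows, columns=["replicate", "phenotype", "round", "total_spores"]
    )


def summary_frame(results: dict[int, dict[str, ReplicateResult]]) -> pd.DataFrame:
    """Per-replicate summary: columns replicate, phenotype, gm, am, extinction_round."""
    rows = []
    for replicate, by_phen in results.items():
        for phenotype, res in by_phen.items():
            rows.append(
                (
                    replicate,
                    phenotype,
                    res.geometric_mean,
                    res.arithmetic_mean,
                    res.extinction_round if res.extinct else -1,
                )
            )
    return pd.DataFrame(
        rows, columns=["replicate", "phenotype", "gm", "am", "extinction_round"]
    )


def run_replicates(
    config: SimulationConfig, pool: SporePool, master_seed: int | None = None
) -> dict[int, dict[str, ReplicateResult]]:
    """Run ``config.n_replicates`` replicates with a deterministic seed schedule.

    Each replicate gets environment and demographic seeds spawned from
    ``master_seed`` (default: the config's environment_seed).
    """
    if master_seed is None:
        master_seed = config.environment_seed
    children = np.random.SeedSequence(master_seed).spawn(config.n_replicates)
    out: dict[int, dict[str, ReplicateResult]] = {}
    for r, child in enumerate(children):
        env_seed, demo_seed = child.generate_state(2) % (2**31)
        cfg = config.with_seeds(int(env_seed), int(demo_seed))
        out[r] = run_replicate(cfg, pool)
    return out
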