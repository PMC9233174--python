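"""Synthetic plate-level data generators.

Emulates the statistical structure of the empirical inputs the simulator and
density assay consume: a spore-production table (three host phenotypes x two
food contexts, with clone- and date-level random effects and heteroscedastic
lognormal noise), microplate calibration pairs for the fluorescence->OD600
standard curve, and a temporally autocorrelated resource series for the
continuous-food model.

Host phenotypes are ``uninfected``, ``agricolaris`` (infected with
*Paraburkholderia agricolaris*) and ``hayleyella`` (infected with
*P. hayleyella*).  Food contexts are ``rich`` (edible *K. pneumoniae* supplied)
and ``poor`` (no food bacteria, so only hosts that carry food can proliferate).
Uninfected hosts on food-poor plates produce no spores; that structural zero is
enforced by the generator, not sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

PHENOTYPES = ("uninfected", "agricolaris", "hayleyella")
CONTEXTS = ("rich", "poor")
INFECTED_PHENOTYPES = ("agricolaris", "hayleyella")

#: exact column order of the spore-table TSV schema
SPORE_TABLE_COLUMNS = (
    "phenotype",
    "food_context",
    "clone_id",
    "date_id",
    "spores_per_plate",
    "symbiont_od",
)

Cell = tuple[str, str]  # (phenotype, food_context)


def _default_medians() -> dict[Cell, float]:
    # Rich-context medians are statistically indistinguishable at plate-level
    # noise (no detectable infection cost at low infection dosage), with a
    # slight edge to infected hosts: a long-run advantage for infected hosts
    # even in nearly-all-rich environments requires their rich-context output
    # not to fall below the uninfected baseline.  Infected hosts retain
    # 15-25% of their rich output on food-poor plates by carrying food
    # bacteria; uninfected hosts produce nothing there.
    return {
        ("uninfected", "rich"): 1.0e8,
        ("agricolaris", "rich"): 1.1e8,
        ("hayleyella", "rich"): 1.1e8,
        ("uninfected", "poor"): 0.0,
        ("agricolaris", "poor"): 1.65e7,
        ("hayleyella", "poor"): 2.75e7,
    }


def _default_log_sd() -> dict[Cell, float]:
    return {cell: 0.4 for cell in _default_medians()}


def _default_var_multipliers() -> dict[Cell, float]:
    # Food-poor plates are noisier (carried-food amounts vary between sori).
    return {
        (phenotype, context): (1.5 if context == "poor" else 1.0)
        for phenotype in PHENOTYPES
        for context in CONTEXTS
    }


def _default_od_medians() -> dict[Cell, float]:
    # Symbiont density left on plates after fruiting: several-fold higher in
    # the food-poor context where symbionts escape competition with food
    # bacteria; the effect is stronger for P. agricolaris.
    return {
        ("agricolaris", "rich"): 0.05,
        ("agricolaris", "poor"): 0.25,
        ("hayleyella", "rich"): 0.05,
        ("hayleyella", "poor"): 0.10,
    }


@dataclass
class SporeGenParams:
    """Parameters of the synthetic spore-production table.

    Spore counts for each (phenotype, food context) cell are lognormal with a
    configured median and log-scale SD, multiplied by lognormal clone and date
    random effects (random intercepts on the log scale) and a per-cell
    variance multiplier (heteroscedasticity between treatments).
    """

    medians: Mapping[Cell, float] = field(default_factory=_default_medians)
    log_sd: Mapping[Cell, float] = field(default_factory=_default_log_sd)
    var_multipliers: Mapping[Cell, float] = field(
        default_factory=_default_var_multipliers
    )
    clone_sd: float = 0.10
    date_sd: float = 0.10
    od_medians: Mapping[Cell, float] = field(default_factory=_default_od_medians)
    od_log_sd: float = 0.30
    n_clones: int = 4
    n_dates: int = 2
    n_plates_per_cell: int = 12
    seed: int = 0

    def validate(self) -> None:
        for name, value in (("clone_sd", self.clone_sd), ("date_sd", self.date_sd),
                            ("od_log_sd", self.od_log_sd)):
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for cell, sd in self.log_sd.items():
            _check_cell(cell)
            if sd < 0:
                raise ValueError(f"log_sd[{cell}] must be >= 0, got {sd}")
        for cell, m in self.medians.items():
            _check_cell(cell)
            if m < 0:
                raise ValueError(f"medians[{cell}] must be >= 0, got {m}")
        for cell, v in self.var_multipliers.items():
            _check_cell(cell)
            if v < 0:
                raise ValueError(f"var_multipliers[{cell}] must be >= 0, got {v}")
        if self.n_clones < 1 or self.n_dates < 1 or self.n_plates_per_cell < 1:
            raise ValueError("n_clones, n_dates and n_plates_per_cell must be >= 1")


def _check_cell(cell: Cell) -> None:
    phenotype, context = cell
    if phenotype not in PHENOTYPES:
        raise ValueError(
            f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}"
        )
    if context not in CONTEXTS:
        raise ValueError(
            f"unknown food_context {context!r}; expected one of {CONTEXTS}"
        )


def generate_spore_table(params: SporeGenParams | None = None) -> pd.DataFrame:
    """Generate a plate-level spore-production table.

    One row per plate, ``n_clones * n_dates * n_plates_per_cell`` rows per
    (phenotype, food context) cell.  Deterministic given ``params.seed``.

    Returns a DataFrame with columns ``phenotype, food_context, clone_id,
    date_id, spores_per_plate, symbiont_od``.
    """
    if params is None:
        params = SporeGenParams()
    params.validate()
    rng = np.random.default_rng(params.seed)

    # Random effects: clone multipliers nested in phenotype, date multipliers
    # shared across the whole experiment (a date is a batch).
    clone_mult = {
        (phenotype, j): float(np.exp(rng.normal(0.0, params.clone_sd)))
        for phenotype in PHENOTYPES
        for j in range(params.n_clones)
    }
    date_mult = {
        d: float(np.exp(rng.normal(0.0, params.date_sd)))
        for d in range(params.n_dates)
    }

    rows: list[tuple] = []
    for phenotype in PHENOTYPES:
        for context in CONTEXTS:
            cell = (phenotype, context)
            median = float(params.medians.get(cell, 0.0))
            sd = float(params.log_sd.get(cell, 0.0)) * float(
                params.var_multipliers.get(cell, 1.0)
            )
            od_median = float(params.od_medians.get(cell, 0.0))
            for j in range(params.n_clones):
                clone_id = f"{phenotype[:3]}{j + 1}"
                for d in range(params.n_dates):
                    date_id = f"batch{d + 1}"
                    for _ in range(params.n_plates_per_cell):
                        if phenotype == "uninfected" and context == "poor":
                            spores = 0.0
                        elif median == 0.0:
                            spores = 0.0
                        else:
                            loc = median * clone_mult[(phenotype, j)] * date_mult[d]
                            spores = float(loc * np.exp(rng.normal(0.0, sd)))
                        if phenotype == "uninfected":
                            od = 0.0
                        elif od_median == 0.0:
                            od = 0.0
                        else:
                            od = float(
                                od_median * np.exp(rng.normal(0.0, params.od_log_sd))
                            )
                        rows.append(
                            (phenotype, context, clone_id, date_id, spores, od)
                        )
    return pd.DataFrame(rows, columns=list(SPORE_TABLE_COLUMNS))


@dataclass
class CalibrationSet:
    """Fluorescence/OD600 calibration pairs with their generating truth."""

    data: pd.DataFrame  # columns: gfp_fluorescence, od600
    true_intercept: float
    true_slope: float
    noise_sd: float
    seed: int

    @property
    def gfp_fluorescence(self) -> np.ndarray:
        return self.data["gfp_fluorescence"].to_numpy(dtype=float)

    @property
    def od600(self) -> np.ndarray:
        return self.data["od600"].to_numpy(dtype=float)


def generate_calibration_data(
    true_intercept: float = 0.01,
    true_slope: float = 0.002,
    noise_sd: float = 0.005,
    n: int = 20,
    fluorescence_range: tuple[float, float] = (100.0, 5000.0),
    seed: int = 0,
) -> CalibrationSet:
    """Generate microplate calibration pairs for the standard curve.

    Fluorescence values are evenly spaced over ``fluorescence_range``;
    ``od600 = intercept + slope * fluorescence + N(0, noise_sd)`` clipped at 0.
    """
    if n < 3:
        raise ValueError(f"need at least 3 calibration points, got n={n}")
    if true_slope <= 0:
        raise ValueError(f"true_slope must be > 0, got {true_slope}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    lo, hi = fluorescence_range
    if not hi > lo:
        raise ValueError(
            f"fluorescence_range must span a positive interval, got {fluorescence_range}"
        )
    rng = np.random.default_rng(seed)
    fluorescence = np.linspace(lo, hi, n)
    od = true_intercept + true_slope * fluorescence
    if noise_sd > 0:
        od = od + rng.normal(0.0, noise_sd, size=n)
    od = np.clip(od, 0.0, None)
    data = pd.DataFrame({"gfp_fluorescence": fluorescence, "od600": od})
    return CalibrationSet(data, true_intercept, true_slope, noise_sd, seed)


def ar1_series(
    n: int, phi: float, innovation_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary zero-mean AR(1) series x_t = phi*x_{t-1} + e_t.

    The initial value is drawn from the stationary distribution
    N(0, innovation_sd^2 / (1 - phi^2)) so the whole series is stationary.
    """
    if abs(phi) >= 1:
        raise ValueError(f"AR(1) requires |phi| < 1 for stationarity, got phi={phi}")
    if innovation_sd < 0:
        raise ValueError(f"innovation_sd must be >= 0, got {innovation_sd}")
    x = np.empty(n)
    if innovation_sd == 0:
        x.fill(0.0)
        return x
    stat_sd = innovation_sd / np.sqrt(1.0 - phi * phi)
    x[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, innovation_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def generate_resource_series(
    n_rounds: int,
    phi: float,
    innovation_sd: float,
    seed: int,
    center: float = 0.0,
) -> np.ndarray:
    """Autocorrelated resource series in [0, 1].

    A stationary latent AR(1) series (lag-1 autocorrelation ``phi``) is mapped
    through a logistic transform ``1 / (1 + exp(-(x + center)))``.  ``center``
    shifts the latent mean: negative values make low-resource (food-poor)
    states more frequent.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    latent = ar1_series(n_rounds, phi, innovation_sd, rng)
    return 1.0 / (1.0 + np.exp(-(latent + center)))
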