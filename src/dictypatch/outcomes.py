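"""Outcome classification and parameter sweeps.

Each (p, v_temp, c) parameter combination is classified from its replicate
GM/AM comparisons between a focal infected phenotype and the uninfected
baseline:

- ``infected_wins`` / ``uninfected_wins``: that side has the higher geometric
  mean in at least 75% of replicates (GM ties count for neither side);
- ``bet_hedging``: infected wins AND more than half of the winning replicates
  won with strictly lower arithmetic mean (variance reduction buying long-run
  growth);
- ``mixed``: neither side reaches the 75% threshold;
- ``mixed_bet_hedging``: mixed, but at least one infected-winning replicate
  individually shows the bet-hedging signature (higher GM, lower AM);
- ``extinction``: more than half of replicates lose BOTH focal phenotypes, so
  the comparison has no survivor; this label takes precedence over the win
  rules.  A one-sided extinction is informative rather than degenerate — the
  surviving side simply wins that replicate (GM 0 vs GM > 0) — so it does not
  trigger the label; per-phenotype extinction fractions are always reported
  alongside.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ReplicateResult, SimulationConfig, SporePool, run_replicate
from .synthetic import INFECTED_PHENOTYPES

WIN_THRESHOLD = 0.75
EXTINCTION_THRESHOLD = 0.5

LABELS = (
    "infected_wins",
    "uninfected_wins",
    "bet_hedging",
    "mixed",
    "mixed_bet_hedging",
    "extinction",
)

#: color convention for rendered outcome maps
LABEL_COLORS = {
    "infected_wins": "#1f77b4",  # blue
    "uninfected_wins": "#ff7f0e",  # orange
    "bet_hedging": "#2ca02c",  # green
    "mixed": "#aaaaaa",  # gray
    "mixed_bet_hedging": "#ffd700",  # yellow
    "extinction": "#000000",
    "skipped": "#ffffff",
}


@dataclass
class ReplicateSummaries:
    """Per-replicate GM, AM and extinction flags for one phenotype."""

    gm: np.ndarray
    am: np.ndarray
    extinct: np.ndarray

    @classmethod
    def from_results(cls, results: list[ReplicateResult]) -> "ReplicateSummaries":
        return cls(
            gm=np.array([r.geometric_mean for r in results], dtype=float),
            am=np.array([r.arithmetic_mean for r in results], dtype=float),
            extinct=np.array([r.extinct for r in results], dtype=bool),
        )


@dataclass
class OutcomeCell:
    """Classified outcome of one parameter combination for one focal pair."""

    p: float
    v_temp: float
    c: float
    g: float
    focal: str  # the infected phenotype compared against uninfected
    n_replicates: int
    frac_infected_gm_wins: float
    frac_uninfected_gm_wins: float
    frac_wins_with_lower_am: float  # among infected-winning replicates
    frac_ext_infected: float
    frac_ext_uninfected: float
    label: str


def classify_cell(
    infected: ReplicateSummaries,
    uninfected: ReplicateSummaries,
    win_threshold: float = WIN_THRESHOLD,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    p: float = float("nan"),
    v_temp: float = float("nan"),
    c: float = float("nan"),
    g: float = float("nan"),
    focal: str = "infected",
) -> OutcomeCell:
    """Classify one parameter combination from its replicate summaries."""
    n = infected.gm.size
    if n == 0 or uninfected.gm.size != n:
        raise ValueError("need >= 1 replicate and equal-length summaries")
    if not (
        np.all(np.isfinite(infected.gm))
        and np.all(np.isfinite(uninfected.gm))
        and np.all(np.isfinite(infected.am))
        and np.all(np.isfinite(uninfected.am))
    ):
        raise ValueError("GM/AM values must be finite")

    inf_win = infected.gm > uninfected.gm
    unf_win = uninfected.gm > infected.gm
    frac_inf = float(np.mean(inf_win))
    frac_unf = float(np.mean(unf_win))
    frac_ext_inf = float(np.mean(infected.extinct))
    frac_ext_unf = float(np.mean(uninfected.extinct))
    lower_am = inf_win & (infected.am < uninfected.am)
    n_wins = int(inf_win.sum())
    frac_lower_am = float(lower_am.sum() / n_wins) if n_wins else 0.0

    frac_ext_both = float(np.mean(infected.extinct & uninfected.extinct))
    if frac_ext_both > extinction_threshold:
        label = "extinction"
    elif frac_inf >= win_threshold:
        label = "bet_hedging" if frac_lower_am > 0.5 else "infected_wins"
    elif frac_unf >= win_threshold:
        label = "uninfected_wins"
    else:
        label = "mixed_bet_hedging" if bool(lower_am.any()) else "mixed"

    return OutcomeCell(
        p=p,
        v_temp=v_temp,
        c=c,
        g=g,
        focal=focal,
        n_replicates=n,
        frac_infected_gm_wins=frac_inf,
        frac_uninfected_gm_wins=frac_unf,
        frac_wins_with_lower_am=frac_lower_am,
        frac_ext_infected=frac_ext_inf,
        frac_ext_uninfected=frac_ext_unf,
        label=label,
    )


@dataclass
class OutcomeGrid:
    """Classified cells over the full (p, v_temp, c) cross, per focal pair."""

    cells: list[OutcomeCell] = field(default_factory=list)
    skipped: list[tuple[float, float, float]] = field(default_factory=list)
    g: float = float("nan")
    master_seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                cell.p,
                cell.v_temp,
                cell.c,
                cell.g,
                cell.focal,
                cell.frac_infected_gm_wins,
                cell.frac_wins_with_lower_am,
                cell.frac_ext_infected,
                cell.frac_ext_uninfected,
                cell.label,
            )
            for cell in self.cells
        ]
        frame = pd.DataFrame(
            rows,
            columns=[
                "p",
                "v_temp",
                "c",
                "g",
                "focal",
                "frac_gm_wins",
                "frac_wins_lower_am",
                "frac_ext_infected",
                "frac_ext_uninfected",
                "label",
            ],
        )
        return frame.sort_values(["focal", "c", "v_temp", "p"]).reset_index(drop=True)


def sweep_grid(
    p_values,
    v_temp_values,
    c_values,
    g: float,
    base_config: SimulationConfig,
    pool: SporePool,
    master_seed: int = 0,
    focal_phenotypes=INFECTED_PHENOTYPES,
) -> OutcomeGrid:
    """Run and classify the full parameter cross.

    All three phenotypes are simulated once per replicate (shared environment)
    and both focal pairs are classified from the same runs.  The seed schedule
    is ``SeedSequence([master_seed, cell_index])`` -> per-replicate environment
    and demographic seeds, so cells are independent and the whole sweep is
    reproducible from ``master_seed``.  Infeasible cells (v_temp >= p(1-p))
    are recorded in ``skipped``, never silently dropped.
    """
    combos = list(itertools.product(p_values, v_temp_values, c_values))
    if not combos:
        raise ValueError("sweep axes must be non-empty")
    grid = OutcomeGrid(g=g, master_seed=master_seed)
    for index, (p, v_temp, c) in enumerate(combos):
        if v_temp > 0 and v_temp >= p * (1.0 - p):
            grid.skipped.append((p, v_temp, c))
            continue
        cfg = SimulationConfig(
            n_patches=base_config.n_patches,
            n_rounds=base_config.n_rounds,
            n_replicates=base_config.n_replicates,
            p=p,
            v_temp=v_temp,
            c=c,
            g=g,
            sorus_size=base_config.sorus_size,
        )
        seeds = np.random.SeedSequence([master_seed, index]).spawn(cfg.n_replicates)
        by_phen: dict[str, list[ReplicateResult]] = {}
        for child in seeds:
            env_seed, demo_seed = child.generate_state(2) % (2**31)
            rep = run_replicate(cfg.with_seeds(int(env_seed), int(demo_seed)), pool)
            for phenotype, result in rep.items():
                by_phen.setdefault(phenotype, []).append(result)
        uninfected = ReplicateSummaries.from_results(by_phen["uninfected"])
        for focal in focal_phenotypes:
            infected = ReplicateSummaries.from_results(by_phen[focal])
            grid.cells.append(
                classify_cell(
                    infected,
                    uninfected,
                    p=p,
                    v_temp=v_temp,
                    c=c,
                    g=g,
                    focal=focal,
                )
            )
    return grid


def render_grid(grid: OutcomeGrid, figsize_per_panel: tuple[float, float] = (2.6, 2.2)):
    """Render the outcome map: rows = focal phenotype, columns = cost regime.

    Within a panel, p runs along x and v_temp along y; cells are colored by
    label (skipped/infeasible cells rendered white with a hatch marker).
    Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Patch

    frame = grid.to_frame()
    if frame.empty and not grid.skipped:
        raise ValueError("cannot render an empty grid")
    focals = sorted(frame["focal"].unique()) if not frame.empty else ["(none)"]
    skipped_frame = pd.DataFrame(grid.skipped, columns=["p", "v_temp", "c"])
    c_values = sorted(
        set(frame["c"].unique()).union(skipped_frame["c"].unique())
    )
    p_values = sorted(
        set(frame["p"].unique()).union(skipped_frame["p"].unique())
    )
    v_values = sorted(
        set(frame["v_temp"].unique()).union(skipped_frame["v_temp"].unique())
    )
    nrows, ncols = len(focals), len(c_values)
    fig, axes = plt.subplots(
        nrows,
        ncols,
        figsize=(figsize_per_panel[0] * ncols, figsize_per_panel[1] * nrows),
        squeeze=False,
    )
    label_order = list(LABELS) + ["skipped"]
    to_index = {label: i for i, label in enumerate(label_order)}
    cmap = matplotlib.colors.ListedColormap(
        [LABEL_COLORS[label] for label in label_order]
    )
    for i, focal in enumerate(focals):
        for j, c in enumerate(c_values):
            ax = axes[i][j]
            img = np.full((len(v_values), len(p_values)), to_index["skipped"])
            sub = frame[(frame["focal"] == focal) & (frame["c"] == c)]
            for cell in sub.itertuples():
                img[v_values.index(cell.v_temp), p_values.index(cell.p)] = to_index[
                    cell.label
                ]
            ax.imshow(
                img,
                cmap=cmap,
                vmin=0,
                vmax=len(label_order) - 1,
                origin="lower",
                aspect="auto",
            )
            sk = skipped_frame[skipped_frame["c"] == c]
            for cell in sk.itertuples():
                ax.text(
                    p_values.index(cell.p),
                    v_values.index(cell.v_temp),
                    "x",
                    ha="center",
                    va="center",
                )
            ax.set_xticks(range(len(p_values)), [f"{p:g}" for p in p_values])
            ax.set_yticks(range(len(v_values)), [f"{v:g}" for v in v_values])
            if i == nrows - 1:
                ax.set_xlabel("p (food-poor probability)")
            if j == 0:
                ax.set_ylabel(f"{focal}\nv_temp")
            if i == 0:
                ax.set_title(f"c = {c:g}")
    handles = [
        Patch(facecolor=LABEL_COLORS[label], edgecolor="k", label=label)
        for label in label_order
    ]
    fig.legend(handles=handles, loc="upper center", ncol=4, fontsize=7)
    fig.tight_layout(rect=(0, 0, 1, 0.9))
    return fig
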