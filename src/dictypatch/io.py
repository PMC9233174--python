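"""TSV and YAML interchange.

Schemas (tab-separated, header row, exact column names):

- spore table: phenotype, food_context, clone_id, date_id, spores_per_plate,
  symbiont_od
- calibration: gfp_fluorescence, od600
- plate measurements: total_od, gfp_fluorescence (+ passthrough metadata)
- sweep grid: p, v_temp, c, g, focal, frac_gm_wins, frac_wins_lower_am,
  frac_ext_infected, frac_ext_uninfected, label
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from .continuous import ContinuousEnvConfig
from .simulate import SimulationConfig
from .synthetic import SPORE_TABLE_COLUMNS

# stable float formatting so identical runs are byte-identical on disk
_FLOAT_FORMAT = "%.10g"


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_spore_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(SPORE_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"spore table {path} is missing columns: {sorted(missing)}")
    return table


def read_calibration(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = {"gfp_fluorescence", "od600"} - set(table.columns)
    if missing:
        raise ValueError(f"calibration {path} is missing columns: {sorted(missing)}")
    return table


def load_simulation_config(path) -> SimulationConfig:
    """Read a SimulationConfig from YAML (keys mirror the field names)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return simulation_config_from_dict(raw)


def simulation_config_from_dict(raw: dict) -> SimulationConfig:
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    config = SimulationConfig(**raw)
    config.validate()
    return config


def load_continuous_config(path) -> ContinuousEnvConfig:
    """Read a ContinuousEnvConfig from YAML.

    Top-level keys are the continuous-model fields (phi, innovation_sd,
    spatial_sd, resource_center); everything else is passed to the embedded
    SimulationConfig.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cont_keys = {"phi", "innovation_sd", "spatial_sd", "resource_center"}
    cont = {k: raw.pop(k) for k in list(raw) if k in cont_keys}
    config = ContinuousEnvConfig(base=simulation_config_from_dict(raw), **cont)
    config.validate()
    return config
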