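"""Raster, table and config I/O.

Rasters live on a planar unit-spacing pixel grid, so they are written as
plain single-band TIFFs (uint8 for binary layers, float32 for real-valued
ones); tables are CSV via pandas; scenario/experiment configs are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .scenario import ScenarioConfig

__all__ = ["write_raster", "read_raster", "write_unit_table", "read_unit_table",
           "load_scenario_config", "save_scenario_config"]


def write_raster(path: str | Path, grid: np.ndarray, binary: bool = False) -> None:
    arr = np.asarray(grid)
    data = arr.astype(np.uint8) if binary else arr.astype(np.float32)
    tifffile.imwrite(str(path), data)


def read_raster(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_unit_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_unit_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_scenario_config(path: str | Path, config: ScenarioConfig) -> None:
    payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    payload = yaml.safe_load(Path(path).read_text())
    if "years" in payload:
        payload["years"] = tuple(int(y) for y in payload["years"])
    return ScenarioConfig(**payload)
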