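"""Readers/writers for the long-format gaze CSV dialect and config files."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from lookmix.simulate.config import CovariateScales, GazeSimConfig, GenerativeConfig
from lookmix.simulate.gaze import GAZE_COLUMNS


def write_gaze_csv(stream: pd.DataFrame, path: str | Path) -> None:
    stream[GAZE_COLUMNS].to_csv(path, index=False)


def read_gaze_csv(path: str | Path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a gaze table; ``column_map`` renames external columns onto the
    canonical schema (participant_id, task, sequence_id, trial, window,
    time_ms, aoi)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze table missing columns: {sorted(missing)}")
    return df[GAZE_COLUMNS]


def write_truths_csv(truths_df: pd.DataFrame, path: str | Path) -> None:
    truths_df.to_csv(path, index=False)


def config_to_dict(config) -> dict:
    d = dataclasses.asdict(config)
    return d


def save_config(config, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def load_generative_config(path: str | Path) -> GenerativeConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "covariates" in d and isinstance(d["covariates"], dict):
        d["covariates"] = CovariateScales(**d["covariates"])
    return GenerativeConfig(**d)


def load_gaze_sim_config(path: str | Path) -> GazeSimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return GazeSimConfig(**d)
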