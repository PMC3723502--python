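"""Plain-text round-tripping: CSV for sequences, YAML/JSON for configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import SubjectData
from .generative import ChangePointDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_subject",
    "read_subject",
    "load_config",
    "save_config",
]


def write_dataset(dataset: ChangePointDataset, path) -> None:
    """Write a change-point dataset as CSV (columns t, x, theta_true, cp[, noise_sd])."""
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path, family_id: str) -> ChangePointDataset:
    df = pd.read_csv(path)
    required = {"t", "x", "theta_true", "cp"}
    if not required.issubset(df.columns):
        raise ValueError(f"dataset CSV must have columns {sorted(required)}")
    return ChangePointDataset.from_frame(df, family_id)


def write_subject(subject: SubjectData, path) -> None:
    pd.DataFrame(
        {
            "t": np.arange(len(subject)),
            "x": subject.x,
            "prediction": subject.predictions,
            "noise_sd": subject.noise_sd,
        }
    ).to_csv(path, index=False)


def read_subject(path) -> SubjectData:
    df = pd.read_csv(path)
    required = {"t", "x", "prediction"}
    if not required.issubset(df.columns):
        raise ValueError(f"subject CSV must have columns {sorted(required)}")
    noise = (
        df["noise_sd"].to_numpy()
        if "noise_sd" in df.columns
        else np.full(len(df), 10.0)
    )
    return SubjectData(
        x=df["x"].to_numpy(), predictions=df["prediction"].to_numpy(), noise_sd=noise
    )


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True, default=str) + "\n")
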