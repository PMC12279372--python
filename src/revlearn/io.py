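"""Reading and writing the tabular trial formats and configs.

Schedules and trial datasets are plain delimited tables with a one-line
header; configs are JSON or YAML.  Round-tripping a generated dataset
through these functions is lossless for all analysis-relevant columns.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .task import SCHEDULE_COLUMNS, TaskConfig

DATASET_COLUMNS = SCHEDULE_COLUMNS + ["action", "modality", "confirmatory", "R"]


def write_schedule(schedule: pd.DataFrame, path, sep: str = ",") -> None:
    schedule[SCHEDULE_COLUMNS].to_csv(path, sep=sep, index=False)


def read_schedule(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file {path} missing columns: {sorted(missing)}")
    return df


def write_dataset(dataset: pd.DataFrame, path, sep: str = ",") -> None:
    cols = [c for c in DATASET_COLUMNS if c in dataset.columns]
    dataset[cols].to_csv(path, sep=sep, index=False)


def read_dataset(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    if "confirmatory" in df.columns:
        df["confirmatory"] = df["confirmatory"].astype(bool)
    return df


def load_task_config(path) -> TaskConfig:
    raw = _load_config(path)
    if "block_length_range" in raw:
        raw["block_length_range"] = tuple(raw["block_length_range"])
    if "probability_levels" in raw:
        raw["probability_levels"] = tuple(raw["probability_levels"])
    return TaskConfig(**raw)


def _load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config(obj, path) -> None:
    path = Path(path)
    data = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else dict(obj)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data))
    else:
        path.write_text(json.dumps(data, indent=2, default=list))


def write_fit_json(fit, path) -> None:
    payload = {
        "subject": str(fit.subject),
        "model": fit.model,
        "params": fit.params_dict(),
        "log_likelihood": fit.log_likelihood,
        "log_posterior": fit.log_posterior,
        "bic": fit.bic,
        "n_trials": fit.n_trials,
        "n_starts": fit.n_starts,
        "best_start_index": fit.best_start_index,
        "converged": fit.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
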