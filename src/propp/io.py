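"""Reading subject tables, writing results, run configuration.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, header mandatory; the
``z`` and ``y`` columns must be coded 0/1 and analysis columns may not
contain missing values.  Result writers embed metadata (package version,
seed, configuration hash) so a run can be traced from its output alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import SubjectTable

__all__ = ["read_subject_table", "write_results", "RunConfig", "config_hash"]

_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Schema-validated run parameters shared by the CLI commands."""

    scheme: str = "att_trial"
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    n_draws: int = 10_000
    min_draws: int | None = None
    seed: int | None = None
    covariates: list[str] | None = None
    scenario: str | None = None
    setting: object = 1
    replicates: int = 1000
    n_boot: int = 30
    extra: dict = field(default_factory=dict, repr=False)

    _KEYS = (
        "scheme", "prior_alpha", "prior_beta", "n_draws", "min_draws", "seed",
        "covariates", "scenario", "setting", "replicates", "n_boot",
    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = sorted(set(data) - set(cls._KEYS))
        if unknown:
            raise ValueError(f"unknown configuration keys: {unknown}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("extra", None)
        return d


def config_hash(config: RunConfig | dict) -> str:
    """Stable short hash of the semantic configuration fields."""
    d = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_subject_table(path, config: RunConfig | None = None) -> SubjectTable:
    """Validated :class:`SubjectTable` from a CSV file with a header row."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty file")
    covs = config.covariates if config is not None else None
    return SubjectTable(df, covariates=covs, subject_id="subject_id")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.random.SeedSequence):
        return obj.entropy
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_results(result, path, fmt: str = "json", force: bool = False,
                  config: RunConfig | None = None) -> None:
    """Serialise a results object: JSON for summaries, CSV for tables/draws.

    Refuses to overwrite an existing file unless ``force`` is set.
    """
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True (or --force) to overwrite")
    meta = {"version": _VERSION}
    if config is not None:
        meta["config_hash"] = config_hash(config)
        meta["seed"] = config.seed
    if fmt == "json":
        payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
        payload["metadata"] = {**meta, **payload.get("metadata", {})}
        path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")
    elif fmt == "csv":
        table = result.table if hasattr(result, "table") else result
        if not isinstance(table, pd.DataFrame):
            table = pd.DataFrame(table)
        table.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_weights_csv(subjects: SubjectTable, lam, weights, path, force: bool = False) -> None:
    """Per-subject λ and weight table keyed by subject id."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    pd.DataFrame(
        {
            "subject_id": subjects.subject_id,
            "z": subjects.z,
            "lambda": np.asarray(lam, dtype=float),
            "weight": np.asarray(weights, dtype=float),
        }
    ).to_csv(path, index=False)
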