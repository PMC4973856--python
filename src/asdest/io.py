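"""Configuration parsing and result serialisation.

Design configurations are JSON or YAML mappings with keys ``n1``, ``n2``,
``sigma``, ``p_S`` (a number or ``"unknown"``), and optional ``b``, ``B``
and ``seed``.  Observed summaries are JSON with ``x``, ``y``, ``s_X`` and
either ``u`` or all of ``v``, ``w``, ``s_V``.  Results serialise to JSON
(field names mirroring the dataclasses) or long-format CSV.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .estimators import EstimateSet
from .trial_model import DesignConfig, StageSummaries

__all__ = [
    "load_config",
    "load_summaries",
    "write_results",
    "RunManifest",
]

_CONFIG_KEYS = {"n1", "n2", "sigma", "p_S", "b", "B", "seed"}
_REQUIRED_KEYS = {"n1", "n2", "sigma", "p_S"}


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(data).__name__}")
    return data


def load_config(path: str | Path) -> DesignConfig:
    """Read and validate a design configuration from JSON or YAML."""
    data = _load_mapping(path)
    missing = _REQUIRED_KEYS - data.keys()
    if missing:
        raise ValueError(f"{path}: missing required config keys: {sorted(missing)}")
    unknown = data.keys() - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unrecognised config keys: {sorted(unknown)}")
    return DesignConfig(**data)


def load_summaries(path: str | Path) -> StageSummaries:
    """Read observed stage summaries from JSON or YAML."""
    data = _load_mapping(path)
    if not {"x", "y", "s_X"} <= data.keys():
        raise ValueError(f"{path}: summaries require x, y and s_X")
    allowed = {"x", "y", "s_X", "u", "v", "w", "s_V"}
    unknown = data.keys() - allowed
    if unknown:
        raise ValueError(f"{path}: unrecognised summary keys: {sorted(unknown)}")
    return StageSummaries(**data)


def write_results(result, path: str | Path, format: str = "json", precision: str = "full"):
    """Serialise an EstimateSet or a result DataFrame.

    ``format`` is ``json`` or ``csv``; DataFrames always keep their long
    column layout, EstimateSets flatten to key/value rows in CSV mode.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(result, EstimateSet):
        payload = result.to_dict(precision=precision)
        if format == "json":
            path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        elif format == "csv":
            flat = {
                k: v for k, v in payload.items() if not isinstance(v, dict)
            } | {f"prevalence_{k}": v for k, v in payload["prevalence_used"].items()}
            pd.DataFrame(
                {"field": list(flat), "value": [flat[k] for k in flat]}
            ).to_csv(path, index=False)
        else:
            raise ValueError(f"unknown format {format!r}")
        return path
    if isinstance(result, pd.DataFrame):
        if format == "csv":
            result.to_csv(path, index=False)
        elif format == "json":
            result.to_json(path, orient="records", indent=2)
        else:
            raise ValueError(f"unknown format {format!r}")
        return path
    raise TypeError(f"cannot serialise {type(result).__name__}")


@dataclass
class RunManifest:
    """Reproducibility record written next to every CLI output."""

    command: str
    config: dict
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def add_warning(self, message: str) -> None:
        if message not in self.warnings:
            self.warnings.append(message)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n")
        return path
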