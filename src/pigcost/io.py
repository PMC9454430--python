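"""Reading and writing farm configurations.

A farm lives in one structured YAML (or JSON) file. Tabular registers —
herd phases, culls, diets, health, reproduction lines, consumer goods,
labor, fuels, assets — can be written inline as lists of mappings, or
held in sidecar CSV files referenced by (relative) filename:

.. code-block:: yaml

    herd:
      sows_in_production: 1000
      ...
      phases: phases.csv        # CSV reference
    diets:                      # or inline
      - {category: dam, phase: gestation, price_per_kg: 1.4, ...}

Loading resolves every reference, applies defaults, and validates; any
error names the offending key path. Saving can emit either form, and a
load -> save -> load cycle reproduces the configuration exactly (all
numbers at full floating precision).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from pydantic import ValidationError

from .errors import ConfigError
from .models import FarmConfig
from .validation import errors as _errors, validate_config

# Sections that may be a CSV filename instead of an inline list, as
# (dotted path in the config, sidecar file suffix).
CSV_REGISTERS: tuple[str, ...] = (
    "herd.phases",
    "herd.culls",
    "repro.lines",
    "diets",
    "health",
    "consumer_goods",
    "labor",
    "fuels",
    "assets",
)


def _get_parent(data: dict[str, Any], dotted: str) -> tuple[dict[str, Any] | None, str]:
    parts = dotted.split(".")
    node: Any = data
    for part in parts[:-1]:
        if not isinstance(node, dict) or part not in node:
            return None, parts[-1]
        node = node[part]
    return (node, parts[-1]) if isinstance(node, dict) else (None, parts[-1])


def _records_from_csv(path: Path, dotted: str) -> list[dict[str, Any]]:
    if not path.exists():
        raise ConfigError(f"{dotted}: register file not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    records = df.to_dict(orient="records")
    # empty CSV cells parse as NaN; the models want them absent
    return [
        {k: v for k, v in rec.items()
         if not (isinstance(v, float) and math.isnan(v))}
        for rec in records
    ]


def load_farm_config(path: str | Path) -> FarmConfig:
    """Load, resolve and validate a farm configuration file.

    Raises :class:`~pigcost.errors.ConfigError` naming the offending
    key path on a missing file, a schema violation, or an unresolved
    (category, phase) cross-reference.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    for dotted in CSV_REGISTERS:
        parent, key = _get_parent(data, dotted)
        if parent is not None and isinstance(parent.get(key), str):
            parent[key] = _records_from_csv(path.parent / parent[key], dotted)

    try:
        cfg = FarmConfig.model_validate(data)
    except ValidationError as exc:
        msgs = [
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        ]
        raise ConfigError(
            f"{path}: schema violation: " + "; ".join(msgs)
        ) from exc

    bad = _errors(validate_config(cfg))
    if bad:
        raise ConfigError(
            f"{path}: invalid configuration: "
            + "; ".join(str(f) for f in bad)
        )
    return cfg


def save_farm_config(
    cfg: FarmConfig,
    path: str | Path,
    *,
    registers: str = "inline",
) -> Path:
    """Write a configuration to YAML.

    ``registers="inline"`` keeps everything in one file (the canonical,
    byte-stable form); ``registers="csv"`` writes each non-empty
    register to a sidecar ``<config stem>.<register>.csv`` and stores
    the filename in the YAML.
    """
    if registers not in ("inline", "csv"):
        raise ValueError(f"unknown registers mode {registers!r}")
    path = Path(path)
    data: dict[str, Any] = cfg.model_dump(mode="json")

    if registers == "csv":
        for dotted in CSV_REGISTERS:
            parent, key = _get_parent(data, dotted)
            if parent is None or not parent.get(key):
                continue
            csv_name = f"{path.stem}.{dotted.replace('.', '_')}.csv"
            # %.17g guarantees the floats survive the CSV round trip
            pd.DataFrame(parent[key]).to_csv(
                path.parent / csv_name, index=False, float_format="%.17g"
            )
            parent[key] = csv_name

    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path
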