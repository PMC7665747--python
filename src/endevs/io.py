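"""Delimited-text readers/writers for cohort tables and deviance matrices.

All tables are CSV with a header row; subject identifiers live in the first
column.  Covariate schemas (name -> continuous | categorical) are read from
YAML.  Run manifests record the seed and a hash of the configuration so
reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml


def read_matrix(path) -> pd.DataFrame:
    """Read an N x M table (deviance matrix or feature table); first column = subject id."""
    return pd.read_csv(path, index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(df).to_csv(path, index=True)


def read_schema(path) -> dict:
    """Covariate schema YAML: mapping of covariate name to kind."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise ValueError("schema YAML must be a mapping of covariate -> kind")
    return schema


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, seed: int, config: dict) -> dict:
    """Write a run manifest (seed, config, config hash) as JSON; returns it."""
    manifest = {"seed": seed, "config": config, "config_hash": config_hash(config)}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
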