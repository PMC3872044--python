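"""Delimited-text readers/writers shared by the workflow and CLI."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def write_matrix(path, values: np.ndarray, row_ids, col_ids, sep: str = "\t") -> None:
    """Write a labelled matrix as delimited text (NaN rendered as 'NA')."""
    df = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    df.to_csv(path, sep=sep, na_rep="NA", index_label="id")


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"])


def read_column_map(path) -> dict:
    """Read a column -> species-id mapping (YAML mapping or 'col: species' lines)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"column map {path} must be a flat mapping")
    return {str(k): str(v) for k, v in data.items()}


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
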