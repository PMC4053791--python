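"""TSV I/O with '#'-prefixed provenance headers.

Every pipeline output is a tab-separated table preceded by comment lines
echoing the run configuration (``# key: value``), so any result file is
self-describing.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml


def write_tsv(
    table: pd.DataFrame,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        table.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def load_run_config(path: str | Path) -> dict:
    """Run configuration as a flat YAML key-value file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a YAML mapping")
    return cfg
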