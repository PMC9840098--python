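"""CSV / JSON-lines / YAML readers and writers shared by all commands.

One fixed CSV dialect everywhere: UTF-8, comma-separated, header row,
RFC 4180 quoting, LF line endings.  All values are read back as strings —
identifier fields are text, and round-tripping must be field-identical.
Run manifests record the exact configuration and seed next to every output
directory; nothing time-dependent is written, so a rerun with the same
seed produces byte-identical files.
"""

from __future__ import annotations

import csv
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

__all__ = [
    "read_table",
    "write_table",
    "load_config",
    "write_manifest",
    "write_json",
]


def _pkg_version() -> str:
    try:
        return version("pddi")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a dataset CSV; all columns as strings, empty cells as ''."""
    return pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path,
        index=False,
        encoding="utf-8",
        quoting=csv.QUOTE_MINIMAL,
        lineterminator="\n",
    )


def load_config(path: str | Path) -> dict:
    """YAML config (JSON is a YAML subset, so either parses)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


def write_manifest(out_dir: str | Path, config: dict) -> None:
    """Machine-readable run manifest: configuration + package version."""
    write_json(
        {"tool": "pddi", "version": _pkg_version(), "config": config},
        Path(out_dir) / "manifest.json",
    )
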