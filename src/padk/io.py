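"""TSV reading/writing conventions shared by the CLI and analysis drivers.

All tables are tab-separated with a header line, '.' decimal and no index
column, matching the dialects of the emulated upstream tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def write_manifest(path: str | Path, parameters: dict) -> Path:
    """Machine-readable run manifest (parameters + package version)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"padk_version": __version__, "parameters": parameters}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    return path
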