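"""Delimited-text serialization with '#'-prefixed metadata headers.

All pipeline artifacts — traces, titrations, competition series, rate and
phi tables — are tab-separated text files whose leading comment block
carries key: value metadata (units, conventions, provenance).  Keeping
everything in plain text makes runs diffable and checksummable.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

__all__ = ["write_table", "read_table"]


def write_table(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    """Write a DataFrame as TSV with a '#'-prefixed metadata header block."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    path.write_text(buf.getvalue())


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_table`; returns (df, metadata)."""
    path = Path(path)
    metadata: dict[str, str] = {}
    lines = path.read_text().splitlines(keepends=True)
    n_header = 0
    for line in lines:
        if line.startswith("#"):
            n_header += 1
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                metadata[key.strip()] = value.strip()
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[n_header:])), sep="\t")
    return df, metadata
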