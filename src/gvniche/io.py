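"""Tab-separated I/O helpers shared by every pipeline stage.

All interchange files are UTF-8, tab-delimited, ``.`` decimal. Metadata lines
start with ``#`` followed by a space (e.g. ``# seed=42``); a ``#`` glued to the
first column name marks an eggNOG-style commented header and is tolerated on
read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["read_table", "write_table", "read_metadata"]


def _split_lines(path: str | Path) -> tuple[list[str], list[str]]:
    """Separate metadata comment lines from data lines."""
    meta: list[str] = []
    data: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##") or line.startswith("# "):
                meta.append(line.rstrip("\n"))
            else:
                data.append(line)
    return meta, data


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a pipeline TSV, skipping ``# `` metadata lines.

    A header line starting with ``#colname`` (no space, as written by
    eggNOG-mapper) has the ``#`` stripped.
    """
    meta, data = _split_lines(path)
    if not data:
        raise ValueError(f"{path}: no data rows")
    if data[0].startswith("#"):
        data[0] = data[0][1:]
    df = pd.read_csv(_io.StringIO("".join(data)), sep="\t", **kwargs)
    df.attrs["metadata"] = read_metadata(meta)
    return df


def read_metadata(meta_lines: list[str]) -> dict[str, str]:
    """Parse ``# key=value`` comment lines into a dict."""
    out: dict[str, str] = {}
    for line in meta_lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            out[key.strip()] = value.strip()
    return out


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    index: bool = False,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write a TSV with optional ``# key=value`` header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)
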