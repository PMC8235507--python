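"""Tab-separated table and provenance-header helpers.

Dialect: UTF-8, tab-separated, no quoting. Provenance lines start with
``##``; the column-header line starts with a single ``#``. Coordinates are
0-based half-open everywhere.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import __version__


def provenance_lines(seed=None, extra: Mapping | None = None) -> list[str]:
    lines = [f"## aavsnap {__version__}"]
    if seed is not None:
        lines.append(f"## seed={seed}")
    if extra:
        blob = json.dumps(extra, sort_keys=True, default=str)
        digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
        lines.append(f"## config_hash={digest}")
    return lines


def write_tsv(path, columns: Sequence[str], rows: Iterable[Sequence],
              seed=None, extra: Mapping | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in provenance_lines(seed, extra):
            fh.write(line + "\n")
        fh.write("#" + "\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` back into a DataFrame."""
    path = Path(path)
    columns = None
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##"):
                skip += 1
                continue
            if line.startswith("#"):
                columns = line[1:].rstrip("\n").split("\t")
                skip += 1
            break
    if columns is None:
        raise ValueError(f"{path}: missing '#'-prefixed header line")
    return pd.read_csv(path, sep="\t", names=columns, skiprows=skip,
                       na_values=[""], keep_default_na=False)
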