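"""Plain-text I/O helpers: labeled TSV matrices, GMT gene sets, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def write_matrix_tsv(path: str | Path, values: np.ndarray,
                     index: Sequence | None = None,
                     columns: Sequence | None = None) -> None:
    """Write a 2-D array as a TSV with row/column labels."""
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D array, got shape {arr.shape}")
    if index is None:
        index = [f"node_{i}" for i in range(arr.shape[0])]
    if columns is None:
        columns = [f"col_{j}" for j in range(arr.shape[1])]
    pd.DataFrame(arr, index=list(index), columns=list(columns)).to_csv(path, sep="\t")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_gmt(path: str | Path, sets: Mapping[str, Sequence[str]],
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT format: name <tab> description <tab> gene1 <tab> ..."""
    lines = []
    for name, genes in sets.items():
        desc = (descriptions or {}).get(name, "na")
        lines.append("\t".join([name, desc, *map(str, genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        sets[parts[0]] = parts[2:]
    return sets
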