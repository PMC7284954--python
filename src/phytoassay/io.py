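"""Plain-text I/O for square distance matrices and JSON result records."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def read_distance_matrix(path) -> tuple[list[str], np.ndarray]:
    """Square TSV with a header row and a label column -> (labels, matrix)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError("distance matrix row labels do not match column labels")
    matrix = df.to_numpy(dtype=float)
    if not np.allclose(matrix, matrix.T):
        raise ValueError("distance matrix must be symmetric")
    return labels, matrix


def write_distance_matrix(labels: Sequence[str], matrix, path) -> None:
    pd.DataFrame(np.asarray(matrix, dtype=float), index=list(labels), columns=list(labels)).to_csv(
        path, sep="\t"
    )


def write_json(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=_default) + "\n")


def _default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
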