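"""Deterministic on-disk formats for pipeline artifacts.

Everything is plain text (CSV, MatrixMarket, JSON) written with fixed float
formatting so that a rerun from the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, index=index)


def write_counts_mtx(counts: pd.DataFrame, path) -> None:
    """Counts as MatrixMarket plus row (cells) and column (genes) sidecars."""
    path = Path(path)
    spio.mmwrite(path, sparse.csr_matrix(counts.to_numpy()))
    path.with_suffix(".rows.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    path.with_suffix(".cols.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(path) -> pd.DataFrame:
    path = Path(path)
    mat = spio.mmread(path if path.exists() else path.with_suffix(".mtx")).toarray()
    rows = path.with_suffix(".rows.txt").read_text().splitlines()
    cols = path.with_suffix(".cols.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=rows, columns=cols)


def write_manifest(path, seed: int, params: dict) -> None:
    payload = {"seed": seed, "parameters": _jsonable(params)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
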