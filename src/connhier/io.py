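"""Matrix and table I/O with provenance sidecars.

Two containers are supported: tab-delimited text (a ``node_id`` index column
plus a header row of node ids for square matrices, or timepoint columns for
node x time data) and NumPy ``.npz`` as the binary container. Every write
can drop a JSON sidecar recording construction parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_matrix", "read_matrix", "write_sidecar", "read_sidecar"]


def write_sidecar(path: str | Path, params: dict) -> Path:
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(params, indent=2, default=str))
    return side


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(str(path) + ".json").read_text())


def write_matrix(
    path: str | Path,
    matrix: np.ndarray,
    node_ids: list[str],
    fmt: str = "tsv",
    params: dict | None = None,
) -> Path:
    """Write a node x node or node x time matrix; optional JSON sidecar."""
    path = Path(path)
    m = np.asarray(matrix, float)
    if m.shape[0] != len(node_ids):
        raise ValueError("matrix rows must match node_ids")
    if fmt == "tsv":
        if m.shape[0] == m.shape[1]:
            cols = list(node_ids)
        else:
            cols = [f"t{j:05d}" for j in range(m.shape[1])]
        df = pd.DataFrame(m, index=pd.Index(node_ids, name="node_id"), columns=cols)
        df.to_csv(path, sep="\t", float_format="%.12g")
    elif fmt == "npz":
        np.savez_compressed(path, matrix=m, node_ids=np.array(node_ids, dtype=object))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if params is not None:
        write_sidecar(path, params)
    return path


def read_matrix(
    path: str | Path, fmt: str = "tsv", expect_node_ids: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read a matrix back; validates the header against expected node ids."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"matrix file {path} is missing or empty")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        m = df.to_numpy(float)
        ids = [str(x) for x in df.index]
        if m.shape[0] == m.shape[1] and list(df.columns) != ids:
            raise ValueError(
                f"header/index mismatch in {path}: "
                f"rows {ids[:3]}... vs columns {list(df.columns)[:3]}..."
            )
    elif fmt == "npz":
        with np.load(path, allow_pickle=True) as z:
            m = z["matrix"]
            ids = [str(x) for x in z["node_ids"]]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if expect_node_ids is not None and ids != list(expect_node_ids):
        extra = sorted(set(ids) ^ set(expect_node_ids))
        raise ValueError(f"node ids in {path} do not match metadata; offending: {extra[:5]}")
    return m, ids
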