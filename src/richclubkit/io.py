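"""Delimited-text I/O for connectivity matrices, manifests, and result tables."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from richclubkit.core_network import ConnectivityMatrix


def read_matrix(path: str | os.PathLike, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a square whitespace- or comma-delimited matrix, with an optional
    header row of node labels. Strictly validated: square, symmetric,
    integer counts, zero diagonal; malformed cells are reported with their
    row/column coordinates."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"{path}: empty matrix file")
    sep = "," if "," in text.splitlines()[0] else None
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]

    def _tokens(line: str) -> list[str]:
        return [t for t in (line.split(sep) if sep else line.split())]

    first = _tokens(lines[0])
    has_header = not _is_number(first[0])
    labels = [t.strip() for t in first] if has_header else None
    body = lines[1:] if has_header else lines
    n = len(body)
    weights = np.zeros((n, n), dtype=np.int64)
    for i, line in enumerate(body):
        toks = _tokens(line)
        if len(toks) != n:
            raise ValueError(f"{path}: row {i} has {len(toks)} cells, expected {n}")
        for j, tok in enumerate(toks):
            try:
                val = float(tok)
            except ValueError:
                raise ValueError(f"{path}: malformed cell at row {i}, column {j}: {tok!r}") from None
            if val != int(val):
                raise ValueError(f"{path}: non-integer count at row {i}, column {j}: {tok}")
            weights[i, j] = int(val)
    if labels is None:
        labels = [f"R{i + 1:03d}" for i in range(n)]
    if subject_id is None:
        subject_id = path.stem
    return ConnectivityMatrix(tuple(labels), weights, subject_id)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_matrix(mat: ConnectivityMatrix, path: str | os.PathLike) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(mat.node_labels) + "\n")
        for row in mat.weights:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """TSV manifest with columns subject_id, path (relative to the manifest's
    directory unless absolute), and optionally group."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("subject_id", "path"):
        if col not in table.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    table["path"] = [
        p if os.path.isabs(p) else str(path.parent / p) for p in table["path"]
    ]
    return table


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike, meta: dict | None = None) -> None:
    """Write a result table as TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
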