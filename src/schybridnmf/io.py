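"""Readers and writers for the on-disk dialects.

Expression: MatrixMarket (``.mtx``) with sibling gene/cell id text
files, or dense CSV/TSV with a header row of cell ids and the first
column holding gene ids (``cells_in_rows=True`` transposes).
Locations: CSV/TSV with columns ``cell_id, x, y``.  Labels: two-column
TSV ``cell_id, cluster``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "read_expression",
    "write_expression_dense",
    "write_expression_mtx",
    "read_locations",
    "write_locations",
    "read_labels",
    "write_labels",
]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_ids(path: Path | None, n: int, prefix: str) -> list[str]:
    if path is None:
        return [f"{prefix}_{i + 1}" for i in range(n)]
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(ids) != n:
        raise ValueError(f"{path} lists {len(ids)} ids, expected {n}")
    return ids


def read_expression(
    path: str | Path,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    cells_in_rows: bool = False,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Load an expression matrix as (values genes x cells, gene_ids, cell_ids)."""
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mat = spio.mmread(path)
        values = (
            mat.toarray() if sparse.issparse(mat) else np.asarray(mat)
        ).astype(float)
        if cells_in_rows:
            values = values.T
        genes = _read_ids(genes_path, values.shape[0], "gene")
        cells = _read_ids(cells_path, values.shape[1], "cell")
        return values, genes, cells
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    if cells_in_rows:
        df = df.T
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_expression_dense(
    path: str | Path,
    values: np.ndarray,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
) -> None:
    path = Path(path)
    pd.DataFrame(values, index=list(gene_ids), columns=list(cell_ids)).to_csv(
        path, sep=_sep(path)
    )


def write_expression_mtx(
    path: str | Path,
    values: np.ndarray,
    gene_ids: Sequence[str],
    cell_ids: Sequence[str],
) -> None:
    """MatrixMarket file plus ``<stem>.genes.txt`` / ``<stem>.cells.txt``."""
    path = Path(path)
    spio.mmwrite(path, sparse.coo_matrix(np.asarray(values)))
    path.with_suffix(".genes.txt").write_text("\n".join(gene_ids) + "\n")
    path.with_suffix(".cells.txt").write_text("\n".join(cell_ids) + "\n")


def read_locations(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Load a ``cell_id, x, y`` table as (2 x n coordinates, cell_ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    cols = {c.lower(): c for c in df.columns}
    missing = {"cell_id", "x", "y"} - set(cols)
    if missing:
        raise ValueError(f"{path} lacks columns {sorted(missing)}")
    L = df[[cols["x"], cols["y"]]].to_numpy(dtype=float).T
    return L, [str(c) for c in df[cols["cell_id"]]]


def write_locations(
    path: str | Path, L: np.ndarray, cell_ids: Sequence[str]
) -> None:
    path = Path(path)
    L = np.asarray(L, dtype=float)
    pd.DataFrame(
        {"cell_id": list(cell_ids), "x": L[0], "y": L[1]}
    ).to_csv(path, sep=_sep(path), index=False)


def read_labels(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    return df["cluster"].to_numpy(dtype=int), [str(c) for c in df["cell_id"]]


def write_labels(
    path: str | Path, labels: Sequence[int], cell_ids: Sequence[str]
) -> None:
    path = Path(path)
    pd.DataFrame(
        {"cell_id": list(cell_ids), "cluster": np.asarray(labels, dtype=int)}
    ).to_csv(path, sep=_sep(path), index=False)
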