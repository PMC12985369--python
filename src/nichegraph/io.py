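"""Readers and writers for the standard on-disk formats.

Matrices travel as MatrixMarket triplets (matrix.mtx + barcodes.tsv +
features.tsv, gzip-transparent), spot coordinates as Space Ranger-style
tissue_positions CSV (headered v2 and headerless v1 dialects), derived
tables as TSV, graphs as GraphML, maps and manifests as JSON.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

POSITION_COLUMNS = [
    "barcode", "in_tissue", "array_row", "array_col",
    "pxl_row_in_fullres", "pxl_col_in_fullres",
]


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}(.gz) in {dirpath}")


def read_mtx_triplet(dirpath):
    """(sparse CSR counts units×genes, unit names, gene names) from a
    matrix.mtx/barcodes.tsv/features.tsv triplet. The matrix on disk is
    genes×units (the Cell Ranger layout) and is transposed on read."""
    dirpath = Path(dirpath)
    with _open(_find(dirpath, "matrix.mtx"), "rb") as fh:
        M = sio.mmread(fh).tocsr().T.tocsr()
    with _open(_find(dirpath, "barcodes.tsv")) as fh:
        barcodes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    with _open(_find(dirpath, "features.tsv")) as fh:
        features = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    if M.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"dimension mismatch in {dirpath}: matrix.mtx is {M.T.shape} "
            f"(genes×units) but features.tsv has {len(features)} rows and "
            f"barcodes.tsv has {len(barcodes)}"
        )
    return M, barcodes, features


def write_mtx_triplet(dirpath, X, barcodes, features) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(dirpath / "matrix.mtx", sparse.coo_matrix(X).T)
    (dirpath / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))
    (dirpath / "features.tsv").write_text("".join(f"{f}\n" for f in features))


def read_positions(path, in_tissue_only: bool = True) -> pd.DataFrame:
    """Space Ranger tissue positions CSV. Accepts the headered dialect
    (tissue_positions.csv, v2) and the headerless one
    (tissue_positions_list.csv, v1); both parse to the same frame."""
    first = pd.read_csv(path, nrows=0)
    header_cols = [c.strip() for c in first.columns]
    if "barcode" in header_cols:
        df = pd.read_csv(path)
        df.columns = [c.strip() for c in df.columns]
        missing = [c for c in POSITION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"unknown tissue-positions dialect: missing {missing}; accepted "
                f"dialects: headered {POSITION_COLUMNS} or headerless 6-column"
            )
        df = df[POSITION_COLUMNS]
    else:
        df = pd.read_csv(path, header=None)
        if df.shape[1] != len(POSITION_COLUMNS):
            raise ValueError(
                f"unknown tissue-positions dialect ({df.shape[1]} columns); "
                f"accepted dialects: headered {POSITION_COLUMNS} or "
                "headerless 6-column"
            )
        df.columns = POSITION_COLUMNS
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].tolist()
        raise ValueError(f"duplicate barcodes in positions file: {dup}")
    if in_tissue_only:
        df = df[df["in_tissue"] == 1]
    return df.set_index("barcode")


def write_positions(path, obs: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "barcode": obs.index,
            "in_tissue": 1,
            "array_row": obs["array_row"].to_numpy(),
            "array_col": obs["array_col"].to_numpy(),
            "pxl_row_in_fullres": obs["array_row"].to_numpy() * 100,
            "pxl_col_in_fullres": obs["array_col"].to_numpy() * 100,
        }
    )
    out.to_csv(path, index=False)


def write_graphml(path, G) -> None:
    nx.write_graphml(G, path)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def write_tsv(path, df: pd.DataFrame, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
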