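"""Readers and writers for the tabular artifacts the pipeline consumes.

Counts come in as MatrixMarket triplets (genes × barcodes, the 10x
convention) with side lists, or as dense CSV/TSV with spot rows; spot
positions, cell tables, abundance tables and all outputs are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .profiles import CountMatrix, GeospatialProfile, ImageProfile


def read_counts_mtx(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    """Read a genes×barcodes MatrixMarket file with gene/barcode lists."""
    m = mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, header=None, sep="\t")[0].to_numpy()
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].to_numpy()
    counts = np.asarray(m.todense() if hasattr(m, "todense") else m).T
    return CountMatrix(counts=counts.astype(np.int64), spot_ids=barcodes, gene_ids=genes)


def write_counts_mtx(counts: CountMatrix, mtx_path, genes_path, barcodes_path) -> None:
    mmwrite(str(mtx_path), csr_matrix(counts.counts.T))
    pd.Series(counts.gene_ids).to_csv(genes_path, index=False, header=False)
    pd.Series(counts.spot_ids).to_csv(barcodes_path, index=False, header=False)


def read_counts_csv(path, sep: str = ",") -> CountMatrix:
    """Dense spot×gene table; first column holds spot ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        counts=df.to_numpy(dtype=np.int64),
        spot_ids=df.index.to_numpy(),
        gene_ids=df.columns.to_numpy(),
    )


def write_counts_csv(counts: CountMatrix, path) -> None:
    pd.DataFrame(counts.counts, index=pd.Index(counts.spot_ids, name="spot_id"),
                 columns=counts.gene_ids).to_csv(path)


def read_positions(path) -> pd.DataFrame:
    """Spot positions CSV with columns spot_id, x, y (optional in_tissue)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"spot_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"positions file missing columns: {sorted(missing)}")
    df["spot_id"] = df["spot_id"].astype(str)
    if "in_tissue" in df.columns:
        df = df[df["in_tissue"].astype(bool)].reset_index(drop=True)
    return df


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return df


def read_image_profile(path) -> ImageProfile:
    """Precomputed abundance CSV: spot_id column + one column per cell type."""
    df = pd.read_csv(path)
    spot_ids = df["spot_id"].astype(str).to_numpy()
    types = [c for c in df.columns if c != "spot_id"]
    return ImageProfile(
        V=df[types].to_numpy(dtype=np.int64),
        spot_ids=spot_ids,
        cell_type_names=np.asarray(types),
    )


def write_image_profile(image: ImageProfile, path) -> None:
    df = pd.DataFrame(image.V, columns=image.cell_type_names)
    df.insert(0, "spot_id", image.spot_ids)
    df.to_csv(path, index=False)


def write_adjacency(geo: GeospatialProfile, path) -> None:
    """Sparse triplet CSV (spot_i, spot_j, 1) with i < j."""
    ii, jj = np.nonzero(np.triu(geo.G))
    pd.DataFrame({
        "spot_i": geo.spot_ids[ii],
        "spot_j": geo.spot_ids[jj],
        "value": np.ones(len(ii), dtype=int),
    }).to_csv(path, index=False)


def read_adjacency(path, spot_ids) -> np.ndarray:
    spot_ids = np.asarray([str(s) for s in spot_ids])
    index = {s: i for i, s in enumerate(spot_ids)}
    df = pd.read_csv(path)
    G = np.zeros((len(spot_ids), len(spot_ids)), dtype=np.int8)
    for a, b in zip(df["spot_i"].astype(str), df["spot_j"].astype(str)):
        i, j = index[a], index[b]
        G[i, j] = G[j, i] = 1
    return G


def write_molecular_profile(Y: np.ndarray, spot_ids, path) -> None:
    df = pd.DataFrame(Y, columns=[f"PC{j + 1}" for j in range(Y.shape[1])])
    df.insert(0, "spot_id", spot_ids)
    # 17 significant digits so doubles round-trip exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_molecular_profile(path):
    df = pd.read_csv(path, float_precision="round_trip")
    spot_ids = df["spot_id"].astype(str).to_numpy()
    cols = [c for c in df.columns if c != "spot_id"]
    return df[cols].to_numpy(dtype=float), spot_ids


def write_positions(spot_ids, T: np.ndarray, path) -> None:
    pd.DataFrame({"spot_id": spot_ids, "x": T[:, 0], "y": T[:, 1]}).to_csv(
        path, index=False, float_format="%.17g")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
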