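"""Input profiles for spatially resolved transcriptomics.

Three profiles feed the domain model:

* the **molecular profile** ``Y`` — a low-dimensional (default: top three
  principal components) representation of library-size-normalised,
  log-transformed spot-level expression;
* the **image profile** ``V`` — per-spot counts of histology-classified cell
  nuclei by type, obtained by assigning each segmented cell to the nearest
  spot centre (a Voronoi partition of the tissue, so every cell is used
  exactly once);
* the **geospatial profile** ``G`` — a binary adjacency matrix over spots on
  a square or triangular lattice.

Imaging-based single-cell platforms are handled by overlaying a square grid
and treating each non-empty grid unit as a pseudo-spot
(:func:`grid_bin_single_cell`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform


@dataclass
class CountMatrix:
    """Raw spot-by-gene (or cell-by-gene) integer counts.

    ``size_factors`` default to per-spot total counts and are used both for
    normalisation and as the negative-binomial exposure in the DE stage.
    """

    counts: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    size_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        self.spot_ids = np.asarray(self.spot_ids)
        self.gene_ids = np.asarray(self.gene_ids)
        if len(self.spot_ids) != self.counts.shape[0]:
            raise ValueError("spot_ids length does not match counts rows")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError("gene_ids length does not match counts columns")
        if len(set(map(str, self.spot_ids))) != len(self.spot_ids):
            raise ValueError("duplicate spot ids")
        if len(set(map(str, self.gene_ids))) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if self.size_factors is None:
            self.size_factors = self.counts.sum(axis=1).astype(float)
        else:
            self.size_factors = np.asarray(self.size_factors, dtype=float)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class MolecularProfile:
    """Low-dimensional expression representation (one row per spot)."""

    Y: np.ndarray
    spot_ids: np.ndarray
    method: str = "pca"

    @property
    def p_prime(self) -> int:
        return self.Y.shape[1]


@dataclass
class ImageProfile:
    """Spot-by-cell-type abundance counts from histology."""

    V: np.ndarray
    spot_ids: np.ndarray
    cell_type_names: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V)
        if np.any(self.V < 0):
            raise ValueError("cell counts must be non-negative")
        if self.V.shape[1] < 2:
            raise ValueError("at least two cell types are required")

    @property
    def totals(self) -> np.ndarray:
        """Per-spot total cell counts m_i."""
        return self.V.sum(axis=1)


@dataclass
class GeospatialProfile:
    """Spot coordinates and their binary neighbourhood graph."""

    T: np.ndarray
    spot_ids: np.ndarray
    G: np.ndarray
    lattice: str = "square"
    neighbor_threshold: float = float("nan")

    def __post_init__(self) -> None:
        G = np.asarray(self.G)
        if not np.array_equal(G, G.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(G) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.G = G

    @property
    def n_spots(self) -> int:
        return self.T.shape[0]


def normalize_counts(counts: CountMatrix, pseudocount: float = 1.0):
    """Depth-normalise and log-transform raw counts.

    Each count is divided by its spot's size factor (total counts by
    default) and shifted by ``pseudocount`` before the log, so zeros map to
    zero.  Spots with zero total counts carry no information and are
    dropped; the returned boolean mask marks the spots kept.

    Returns
    -------
    normalized : (n_kept, P) float array of ``log(c/s + pseudocount)``
    kept : (N,) boolean mask of retained spots
    """
    s = counts.size_factors
    kept = s > 0
    if not kept.all():
        warnings.warn(
            f"dropping {int((~kept).sum())} spot(s) with zero total counts",
            stacklevel=2,
        )
    c = counts.counts[kept].astype(float)
    rel = c / s[kept, None]
    return np.log(rel + pseudocount), kept


def select_hvg(normalized: np.ndarray, n_top: int = 2000) -> np.ndarray:
    """Indices of the ``n_top`` most variable genes, variance-descending.

    Ties are broken by ascending gene index so the selection is
    deterministic across platforms.
    """
    normalized = np.asarray(normalized, dtype=float)
    p = normalized.shape[1]
    if n_top > p:
        raise ValueError(f"n_top={n_top} exceeds the number of genes P={p}")
    var = normalized.var(axis=0)
    # stable sort on -var keeps index order within ties
    order = np.argsort(-var, kind="stable")
    return order[:n_top]


def reduce_dimension(
    normalized_hvg: np.ndarray, p_prime: int = 3, spot_ids=None
) -> MolecularProfile:
    """Project the normalised expression onto its top principal components.

    Scores are computed from the SVD of the column-centred matrix.  Each
    component's sign is fixed so that its largest-magnitude gene loading is
    positive, making the output independent of the linear-algebra backend.
    """
    X = np.asarray(normalized_hvg, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in the normalized matrix")
    n, p = X.shape
    if p_prime > min(n, p):
        raise ValueError(f"p_prime={p_prime} exceeds min(N, P)={min(n, p)}")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :p_prime] * S[:p_prime]
    loadings = Vt[:p_prime]
    flip = np.sign(loadings[np.arange(p_prime), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    if spot_ids is None:
        spot_ids = np.arange(n)
    return MolecularProfile(Y=scores, spot_ids=np.asarray(spot_ids), method="pca")


def build_adjacency(
    T: np.ndarray,
    lattice: str = "square",
    neighbor_threshold: float | str = "auto",
    spot_ids=None,
) -> GeospatialProfile:
    """Binary neighbourhood graph from spot coordinates.

    Two spots are neighbours when their Euclidean distance falls below the
    threshold.  ``"auto"`` sets the threshold to 1.2 times the minimal
    non-zero inter-spot distance, which links each interior spot to its 4
    (square/grid) or 6 (triangular) lattice neighbours while tolerating
    floating-point jitter in deposited coordinates.
    """
    T = np.asarray(T, dtype=float)
    if T.shape[0] < 2:
        raise ValueError("at least two spots are required")
    if lattice not in ("square", "triangular", "grid"):
        raise ValueError(f"unknown lattice type: {lattice!r}")
    d = pdist(T)
    if np.any(d == 0):
        raise ValueError("duplicate spot coordinates")
    if neighbor_threshold == "auto":
        neighbor_threshold = 1.2 * d.min()
    thr = float(neighbor_threshold)
    D = squareform(d)
    G = ((D > 0) & (D < thr)).astype(np.int8)
    if spot_ids is None:
        spot_ids = np.arange(T.shape[0])
    return GeospatialProfile(
        T=T,
        spot_ids=np.asarray(spot_ids),
        G=G,
        lattice=lattice,
        neighbor_threshold=thr,
    )


def build_image_profile(
    cells: pd.DataFrame,
    geo: GeospatialProfile,
    cell_types,
) -> ImageProfile:
    """Count classified cells per spot's expanded area.

    A spot's expanded area is its Voronoi cell: every cell nucleus is
    assigned to the nearest spot centre, so the areas tile the tissue and
    each cell contributes to exactly one spot.

    Parameters
    ----------
    cells : DataFrame with columns ``cell_id, x, y, cell_type``
    geo : spot coordinates defining the Voronoi seeds
    cell_types : ordered vocabulary of allowed cell-type labels
    """
    cell_types = np.asarray(list(cell_types))
    type_index = {t: q for q, t in enumerate(cell_types)}
    labels = cells["cell_type"].to_numpy()
    unknown = sorted(set(labels) - set(cell_types))
    if unknown:
        raise ValueError(f"cell types outside vocabulary: {unknown}")
    n, q_dim = geo.n_spots, len(cell_types)
    V = np.zeros((n, q_dim), dtype=np.int64)
    if len(cells):
        tree = cKDTree(geo.T)
        _, nearest = tree.query(cells[["x", "y"]].to_numpy(dtype=float))
        for spot, lab in zip(nearest, labels):
            V[spot, type_index[lab]] += 1
    return ImageProfile(V=V, spot_ids=geo.spot_ids, cell_type_names=cell_types)


def grid_bin_single_cell(
    cell_counts: CountMatrix,
    cells: pd.DataFrame,
    grid_size: float,
    cell_types=None,
    n_top: int | None = 2000,
    p_prime: int = 3,
):
    """Bin single-cell-resolution data onto a square pseudo-spot lattice.

    Cells are partitioned into ``grid_size``-sized square units using
    half-open ``[a, b)`` intervals on both axes (a cell on an interior grid
    line belongs to the unit on its upper-index side).  Expression is
    normalised, log-transformed and PCA-reduced at the single-cell level and
    the scores are then averaged per unit; the image profile counts cell
    types per unit directly.  Empty units are dropped, and the remaining
    units are connected rook-wise (4 neighbours).

    Returns ``(MolecularProfile, ImageProfile, GeospatialProfile, unit_of_cell)``
    where ``unit_of_cell`` maps each kept cell to its unit row.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    origin = xy.min(axis=0)
    ij = np.floor((xy - origin) / grid_size).astype(np.int64)

    norm, kept = normalize_counts(cell_counts)
    ij = ij[kept]
    cells = cells.loc[kept].reset_index(drop=True)

    units, unit_of_cell = np.unique(ij, axis=0, return_inverse=True)
    n_units = len(units)
    if n_units == 1:
        warnings.warn("grid so coarse that only one unit remains", stacklevel=2)

    if n_top is not None and n_top < norm.shape[1]:
        norm = norm[:, select_hvg(norm, n_top)]
    cell_profile = reduce_dimension(norm, p_prime=p_prime)
    Y = np.zeros((n_units, p_prime))
    np.add.at(Y, unit_of_cell, cell_profile.Y)
    counts_per_unit = np.bincount(unit_of_cell, minlength=n_units)
    Y /= counts_per_unit[:, None]

    unit_ids = np.array([f"unit_{i}_{j}" for i, j in units])
    centers = origin + (units + 0.5) * grid_size
    if n_units >= 2:
        geo = build_adjacency(centers, lattice="grid", spot_ids=unit_ids)
    else:
        geo = GeospatialProfile(
            T=centers, spot_ids=unit_ids, G=np.zeros((1, 1), dtype=np.int8),
            lattice="grid", neighbor_threshold=float("nan"),
        )

    if cell_types is None:
        cell_types = np.unique(cells["cell_type"].to_numpy())
    type_index = {t: q for q, t in enumerate(cell_types)}
    V = np.zeros((n_units, len(cell_types)), dtype=np.int64)
    for u, lab in zip(unit_of_cell, cells["cell_type"].to_numpy()):
        V[u, type_index[lab]] += 1
    image = ImageProfile(V=V, spot_ids=unit_ids, cell_type_names=np.asarray(list(cell_types)))

    molecular = MolecularProfile(Y=Y, spot_ids=unit_ids, method="pca-cell-averaged")
    return molecular, image, geo, unit_of_cell


def prepare_profiles(
    counts: CountMatrix,
    positions: pd.DataFrame,
    cells: pd.DataFrame | None = None,
    cell_types=None,
    image: ImageProfile | None = None,
    lattice: str = "square",
    n_top: int = 2000,
    p_prime: int = 3,
    neighbor_threshold: float | str = "auto",
):
    """Full spot-platform preparation: counts + positions (+ cell table) → (Y, V, G).

    Spots with zero total counts are removed from all three profiles
    jointly.  ``image`` may supply a precomputed abundance table instead of
    a cell table; zero-cell spots are retained (their multinomial
    likelihood term is one).
    """
    positions = positions.set_index("spot_id").loc[[str(s) for s in counts.spot_ids]]
    norm, kept = normalize_counts(counts)
    spot_ids = counts.spot_ids[kept]
    T = positions[["x", "y"]].to_numpy(dtype=float)[kept]

    n_top_eff = min(n_top, norm.shape[1])
    hvg = select_hvg(norm, n_top_eff)
    molecular = reduce_dimension(norm[:, hvg], p_prime=p_prime, spot_ids=spot_ids)
    geo = build_adjacency(T, lattice=lattice, neighbor_threshold=neighbor_threshold,
                          spot_ids=spot_ids)
    if image is not None:
        V = image.V[kept]
        image = ImageProfile(V=V, spot_ids=spot_ids, cell_type_names=image.cell_type_names)
    elif cells is not None:
        if cell_types is None:
            cell_types = np.unique(cells["cell_type"].to_numpy())
        image = build_image_profile(cells, geo, cell_types)
    else:
        raise ValueError("either a cell table or a precomputed image profile is required")
    return molecular, image, geo
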