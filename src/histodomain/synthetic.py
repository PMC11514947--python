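"""Synthetic spatial-transcriptomics data from the model's own generative
assumptions.

A simulated dataset consists of a lattice of spots with a spatially
coherent true partition into domains, and per spot

* a cell count ``m_i ~ Poisson`` and type counts ``v_i ~ Multi(m_i,
  omega*_{z_i})`` (plus an explicit cell table with jittered coordinates,
  so the image-profile construction can be exercised end to end);
* a low-dimensional molecular profile ``y_i ~ MN(mu*_{z_i}, Sigma*_{z_i})``;
* negative-binomial gene counts ``c_ij ~ NB(s_i * lambda_ij, psi_j)`` with
  a designated subset of genes shifted (log-fold-change) in one target
  domain, for testing the DE stage.

Defaults emulate a spot-resolution experiment with strong but not
degenerate signal: a 20 x 20 square lattice, three domains in contiguous
bands, four cell types with one dominant type per domain, 20 cells per
spot, unit-variance expression components separated by 2.5, and 200 null
plus 50 shifted genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as hio
from .mixture import _z_sweep
from .profiles import (CountMatrix, GeospatialProfile, ImageProfile,
                       MolecularProfile, build_adjacency)

__all__ = ["SimulationSpec", "SimulatedDataset", "simulate_dataset",
           "potts_partition", "lattice_coordinates", "write_dataset",
           "default_omega", "default_mu"]


def default_omega(n_domains: int, n_types: int, decay: float = 0.3) -> np.ndarray:
    """Dominated compositions with geometrically decaying minor shares.

    Domain ``k`` is dominated by cell type ``k`` (share ~0.7 at the default
    decay) and the remaining types decay geometrically around the ring
    ``(q - k) mod Q``.  Every cell type's abundance therefore differs
    across domains — the identifiability condition the reference-type
    relabelling of the mixture relies on (perfectly symmetric minor shares
    would leave the non-dominant domains unorderable).
    """
    if n_types < 2:
        raise ValueError("need at least two cell types")
    k_idx = np.arange(n_domains)[:, None]
    q_idx = np.arange(n_types)[None, :]
    omega = decay ** ((q_idx - k_idx) % n_types).astype(float)
    return omega / omega.sum(axis=1, keepdims=True)


def default_mu(n_domains: int, p_prime: int, separation: float = 2.5) -> np.ndarray:
    """Domain means placed ``separation`` apart along distinct axes."""
    mu = np.zeros((n_domains, p_prime))
    for k in range(1, n_domains):
        mu[k, (k - 1) % p_prime] = separation * ((k - 1) // p_prime + 1)
    return mu


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_rows: int = 20
    n_cols: int = 20
    lattice: str = "square"
    n_domains: int = 3
    partition: str = "blobs"          # 'blobs' (contiguous bands) or 'potts'
    potts_f: float = 1.5
    potts_sweeps: int = 50
    n_cell_types: int = 4
    p_prime: int = 3
    omega: np.ndarray | None = None   # (K, Q); defaults to dominated rows
    mu: np.ndarray | None = None      # (K, P'); defaults to separation 2.5
    sigma: float | np.ndarray = 1.0   # per-domain std (scalar or (K, P'))
    cells_per_spot_mean: float = 20.0
    n_null_genes: int = 200
    n_deg_genes: int = 50
    log_fold_change: float = 1.0
    deg_domain: int = 0
    baseline_mean: float = 10.0
    dispersion: float = 5.0           # NB size psi; var = mu + mu^2/psi
    exposure_sd: float = 0.3          # lognormal sd of per-spot exposure
    seed: int = 0

    def validate(self):
        errors = []
        if self.n_rows < 1 or self.n_cols < 1:
            errors.append("lattice shape must be positive")
        if self.lattice not in ("square", "triangular"):
            errors.append(f"unknown lattice {self.lattice!r}")
        if self.n_domains < 1:
            errors.append("n_domains must be >= 1")
        if self.partition not in ("blobs", "potts"):
            errors.append(f"unknown partition {self.partition!r}")
        if self.n_cell_types < 2:
            errors.append("n_cell_types must be >= 2")
        if self.cells_per_spot_mean < 0:
            errors.append("cells_per_spot_mean must be >= 0")
        if self.dispersion <= 0:
            errors.append("dispersion must be positive")
        if not 0 <= self.deg_domain < self.n_domains:
            errors.append("deg_domain out of range")
        if errors:
            raise ValueError("invalid simulation spec: " + "; ".join(errors))


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    molecular: MolecularProfile
    image: ImageProfile
    geo: GeospatialProfile
    z: np.ndarray
    omega: np.ndarray
    mu: np.ndarray
    deg_genes: pd.DataFrame
    cells: pd.DataFrame


def lattice_coordinates(n_rows: int, n_cols: int, lattice: str = "square"):
    """Spot centres with unit spacing; triangular rows are offset by 1/2."""
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    rows = rows.ravel().astype(float)
    cols = cols.ravel().astype(float)
    if lattice == "triangular":
        x = cols + 0.5 * (rows % 2)
        y = rows * (np.sqrt(3.0) / 2.0)
    else:
        x, y = cols, rows
    return np.column_stack([x, y])


def potts_partition(geo: GeospatialProfile, n_domains: int, f_star: float,
                    seed: int = 0, sweeps: int = 50) -> np.ndarray:
    """Gibbs-sample a Potts configuration on the spot graph.

    At ``f_star = 0`` the labels are iid uniform; larger values yield
    smoother label fields.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    from scipy.sparse import csr_matrix

    rng = np.random.default_rng(seed)
    n = geo.n_spots
    csr = csr_matrix(np.asarray(geo.G))
    indptr = csr.indptr.astype(np.int64)
    indices = csr.indices.astype(np.int64)
    z = rng.integers(n_domains, size=n).astype(np.int64)
    flat = np.zeros((n, n_domains))
    d = np.zeros(n_domains)
    for _ in range(sweeps):
        u = rng.random(n)
        z = _z_sweep(z, flat, d, f_star, indptr, indices, u)
    return z


def _bands_partition(T: np.ndarray, n_domains: int) -> np.ndarray:
    """Contiguous vertical bands with (near) equal spot counts."""
    order = np.argsort(T[:, 0], kind="stable")
    z = np.empty(len(order), dtype=np.int64)
    for k, chunk in enumerate(np.array_split(order, n_domains)):
        z[chunk] = k
    return z


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one dataset from the generative model (deterministic per seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    T = lattice_coordinates(spec.n_rows, spec.n_cols, spec.lattice)
    spot_ids = np.array([f"spot_{i}" for i in range(T.shape[0])])
    geo = build_adjacency(T, lattice=spec.lattice, spot_ids=spot_ids)
    n = geo.n_spots

    if spec.partition == "potts":
        z = potts_partition(geo, spec.n_domains, spec.potts_f,
                            seed=int(rng.integers(2 ** 31)),
                            sweeps=spec.potts_sweeps)
    else:
        z = _bands_partition(T, spec.n_domains)

    omega = (default_omega(spec.n_domains, spec.n_cell_types)
             if spec.omega is None else np.asarray(spec.omega, float))
    mu = (default_mu(spec.n_domains, spec.p_prime)
          if spec.mu is None else np.asarray(spec.mu, float))
    sigma = np.broadcast_to(np.asarray(spec.sigma, float),
                            (spec.n_domains, spec.p_prime)).copy()

    # image profile: Poisson cell totals, multinomial type counts
    m = rng.poisson(spec.cells_per_spot_mean, size=n)
    q_dim = spec.n_cell_types
    V = np.zeros((n, q_dim), dtype=np.int64)
    for i in range(n):
        if m[i] > 0:
            V[i] = rng.multinomial(m[i], omega[z[i]])
    type_names = np.array([f"type_{q}" for q in range(q_dim)])
    image = ImageProfile(V=V, spot_ids=spot_ids, cell_type_names=type_names)

    # explicit cell table: jitter keeps each cell nearest to its own spot
    cell_rows = []
    for i in range(n):
        for q in range(q_dim):
            for _ in range(V[i, q]):
                dx, dy = rng.uniform(-0.3, 0.3, size=2)
                cell_rows.append((len(cell_rows), T[i, 0] + dx, T[i, 1] + dy,
                                  type_names[q]))
    cells = pd.DataFrame(cell_rows, columns=["cell_id", "x", "y", "cell_type"])

    # molecular profile: per-domain multivariate normal (diagonal)
    Y = rng.normal(mu[z], sigma[z])
    molecular = MolecularProfile(Y=Y, spot_ids=spot_ids, method="simulated")

    # gene counts: NB with exposure and domain-shifted designated genes
    p_genes = spec.n_null_genes + spec.n_deg_genes
    gene_ids = np.array([f"gene_{j}" for j in range(p_genes)])
    is_deg = np.zeros(p_genes, dtype=bool)
    is_deg[spec.n_null_genes:] = True
    exposure = np.exp(rng.normal(0.0, spec.exposure_sd, size=n))
    lam = np.full((n, p_genes), spec.baseline_mean)
    shift = np.exp(spec.log_fold_change)
    lam[:, is_deg] *= np.where(z[:, None] == spec.deg_domain, shift, 1.0)
    mean = exposure[:, None] * lam
    gamma = rng.gamma(spec.dispersion, mean / spec.dispersion)
    counts_arr = rng.poisson(gamma)
    # the generative model is c_ij ~ NB(s_i * lambda_ij, psi_j): the true
    # exposure IS the size factor, and is recorded as such.  (Row totals,
    # the real-data default, would be dominated by the designated DE genes
    # on a panel this small — an artifact of panel size, not of the data.)
    counts = CountMatrix(counts=counts_arr, spot_ids=spot_ids,
                         gene_ids=gene_ids, size_factors=exposure)

    deg = pd.DataFrame({"gene": gene_ids, "is_deg": is_deg,
                        "domain": np.where(is_deg, spec.deg_domain, -1),
                        "log_fold_change":
                            np.where(is_deg, spec.log_fold_change, 0.0)})
    return SimulatedDataset(counts=counts, molecular=molecular, image=image,
                            geo=geo, z=z, omega=omega, mu=mu, deg_genes=deg,
                            cells=cells)


def write_dataset(ds: SimulatedDataset, out_dir) -> None:
    """Write the CSV/MTX artifacts the real-data readers consume, plus truth."""
    out = hio.ensure_dir(out_dir)
    hio.write_counts_mtx(ds.counts, out / "counts.mtx", out / "genes.tsv",
                         out / "barcodes.tsv")
    hio.write_positions(ds.geo.spot_ids, ds.geo.T, out / "positions.csv")
    ds.cells.to_csv(out / "cells.csv", index=False)
    hio.write_image_profile(ds.image, out / "image_profile.csv")
    hio.write_adjacency(ds.geo, out / "adjacency.csv")
    hio.write_molecular_profile(ds.molecular.Y, ds.molecular.spot_ids,
                                out / "molecular_profile.csv")
    pd.DataFrame({"spot_id": ds.geo.spot_ids, "domain": ds.z}).to_csv(
        out / "true_z.csv", index=False)
    pd.DataFrame({"spot_id": ds.counts.spot_ids,
                  "size_factor": ds.counts.size_factors}).to_csv(
        out / "size_factors.csv", index=False)
    pd.DataFrame(ds.omega, columns=ds.image.cell_type_names).assign(
        domain=np.arange(ds.omega.shape[0])).to_csv(out / "true_omega.csv",
                                                    index=False)
    ds.deg_genes.to_csv(out / "true_deg.csv", index=False)
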