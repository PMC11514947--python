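# histodomain

Histology-integrated Bayesian spatial domain analysis for spatially
resolved transcriptomics (SRT).

Spot-level SRT platforms (ST, 10x Visium) measure expression on a lattice
of capture spots, while the matching H&E image carries single-cell
morphology that standard expression-only clustering ignores. `histodomain`
integrates three views of a tissue section — a low-dimensional **molecular
profile** `Y` (expression PCs per spot), an **image profile** `V` (counts
of AI-classified cell nuclei by type per spot, from any nuclei
segmentation/classification tool), and a **geospatial profile** `G` (the
spot neighbourhood graph) — to identify *histology-based spatial domains*,
quantify their cell-type composition with full posterior uncertainty, and
then test genes for domain-specific differential expression. Imaging-based
single-cell platforms (e.g. STARmap) are supported by binning cells onto a
square pseudo-spot grid.

It is aimed at computational biologists analysing SRT sections with paired
histology, and at methodologists who want a transparent, fully seeded
Gibbs-sampler implementation of the model.

## The model

**Stage I — domain detection.** Spot `i` carries `y_i ∈ R^{P'}` (top `P'`
expression PCs, default 3) and cell-type counts `v_i ∈ N^Q` with total
`m_i`. Each domain `k = 1..K` has parameters `(μ_k, Σ_k, ω_k)` and the
mixture component is

```
f_k(y_i, v_i) = MN(y_i; μ_k, Σ_k) · Multi(v_i; m_i, ω_k)^w ,
```

where `w ∈ [0, 1]` balances histology against expression (`w = 0` ignores
the image entirely; 0.05 is the default for spot platforms, 0.5 for
grid-binned single-cell data). The labels `z` get a Potts /
Markov-random-field prior

```
π(z_i = k | z_-i) ∝ exp(d_k + f Σ_{i'} g_{ii'} I(z_{i'} = k)) ,
```

encouraging neighbouring spots to share a domain (`f = 1` by default).
Conjugate priors (normal–inverse-Wishart for `(μ_k, Σ_k)`, or independent
normal–inverse-gamma per PC in the default diagonal variant; Dirichlet for
`ω_k`) give closed-form full conditionals, so inference is plain Gibbs
sampling. Label switching is resolved by reordering domains on the
abundance of a reference cell type at every stored draw. The fit reports:

* mode labels `ẑ_i = argmax_k π(z_i = k | ·)` with marginal probabilities;
* **boundary spots** (`max_k π(z_i = k | ·) < 0.9`) and their connected
  components, the **interactive zones**;
* posterior means and credible intervals for each domain's cell-type
  composition `ω_k` — the quantity that lets a domain be named after the
  cell type dominating it;
* the integrated completed likelihood
  `ICL(K) = −2 log L(Y, V, ẑ | plug-in params) + d log N` with
  `d = 2KP' + K(Q−1)`, for choosing `K` when it is unknown.

**Stage II — spaDEGs.** For a target domain `k`, each gene `j` is tested
with a negative-binomial regression `c_ij ~ NB(s_i λ_ij, ψ_j)` on the
indicator `x_ik = I(ẑ_i = k)` (log link, size-factor offset), Wald test of
`β_jk = 0`, Benjamini–Hochberg adjustment across genes; discoveries at
adjusted p < 0.05 are the domain-specific differentially expressed genes.
Per-spot expression richness and per-gene Moran's I diagnostics are
included.

A fully seeded synthetic-data generator draws lattices, spatially coherent
partitions (contiguous bands or Potts fields), cell tables, molecular
profiles and NB counts from these same generative assumptions, so the
entire pipeline is testable without external downloads.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from histodomain import (SimulationSpec, simulate_dataset,
                         SpatialDomainModel, DomainDEG)

ds = simulate_dataset(SimulationSpec(seed=1))          # 20x20 lattice, K=3
model = SpatialDomainModel(n_domains=3, w=0.05, f=1.0, seed=1)
model.fit(ds.molecular.Y, ds.image.V, ds.geo.G)

print("ARI vs truth:", round(adjusted_rand_score(ds.z, model.labels_), 3))
print("domain sizes:", np.bincount(model.labels_))
print("boundary spots:", int(model.boundary_mask_.sum()),
      "| interactive zones:", len(model.interactive_zones_))
for k in range(3):
    top = int(np.argmax(model.omega_mean_[k]))
    lo, hi = model.omega_ci_low_[k, top], model.omega_ci_high_[k, top]
    print(f"domain {k}: dominant cell type {top} "
          f"omega = {model.omega_mean_[k, top]:.3f} (95% CI {lo:.3f}-{hi:.3f})")

deg = DomainDEG(domain=0).fit(ds.counts, model.labels_)
print("spaDEGs in domain 0:", deg.n_discoveries_, "of", len(deg.results_))
```

Output:

```
ARI vs truth: 0.978
domain sizes: [131 135 134]
boundary spots: 16 | interactive zones: 3
domain 0: dominant cell type 2 omega = 0.699 (95% CI 0.622-0.774)
domain 1: dominant cell type 1 omega = 0.694 (95% CI 0.608-0.764)
domain 2: dominant cell type 0 omega = 0.675 (95% CI 0.595-0.756)
spaDEGs in domain 0: 54 of 250
```

The fitted partition matches the simulated truth almost perfectly
(ARI 0.978); the 16 low-confidence spots trace the borders between the
three bands and form three interactive zones; each domain's composition
credible interval covers the truth (the simulated dominant share is ~0.71);
and the DE stage recovers the 50 genes simulated with a log-fold-change of
1 in domain 0 (plus a handful of borderline false calls at the BH 0.05
level).

The same pipeline is available from the shell:

```bash
histodomain simulate --seed 1 --out sim/
histodomain fit --profiles sim/ -k 3 --seed 1 --out fit/
histodomain select-k --profiles sim/ --k-min 2 --k-max 6 --out selk/
histodomain spadeg --counts-mtx sim/counts.mtx --genes sim/genes.tsv \
    --barcodes sim/barcodes.tsv --domains fit/domains.csv --domain 0 --out deg/
```

For real data, `histodomain prepare` builds the three profiles from a
counts matrix (MTX or CSV), a spot-position CSV and either a cell table
(`cell_id, x, y, cell_type`) or a precomputed spot-by-cell-type abundance
CSV; every command writes a `manifest.json` recording its effective
configuration and seed.

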