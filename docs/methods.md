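# Methods

## Input profiles

`histodomain` works from three per-spot views of a tissue section.

**Molecular profile `Y` (N × P').** Raw counts `c_ij` are depth-normalised
to relative levels `c̃_ij = c_ij / s_i` with `s_i = Σ_j c_ij` (spots with
`s_i = 0` are dropped from all profiles jointly), shifted by a pseudocount
of 1 and log-transformed — the +1 keeps zeros finite and is the standard
convention. The top `n_top = 2000` most variable genes (variance of the
normalised values, index-order tie-break) are reduced by PCA to `P' = 3`
scores. Three components keep the normal sub-component low-dimensional
while retaining most clustering-relevant variance; the model accepts any
`P'`. PCA signs are fixed by making each component's largest-magnitude
loading positive, so results do not depend on the linear-algebra backend.

**Image profile `V` (N × Q).** Any nuclei segmentation/classification tool
that emits `(cell_id, x, y, cell_type)` can feed the model. Because spots
cover only part of the tissue, each cell is assigned to the *expanded
area* of its nearest spot centre — i.e. the Voronoi cell of the spot —
which tiles the section so every cell is counted exactly once and no cell
is counted twice. Zero-cell spots are retained; their multinomial
likelihood term is 1.

**Geospatial profile `G` (N × N).** Binary adjacency: spots closer than a
threshold are neighbours. The automatic threshold is 1.2 × the minimal
non-zero inter-spot distance, which yields the expected 4 neighbours per
interior spot on square lattices and 6 on triangular (Visium-style)
lattices while tolerating floating-point jitter in deposited coordinates.

**Single-cell platforms.** For imaging-based data at cellular resolution,
a square grid of side `grid_size` is laid over the section; cells are
binned into units by half-open `[a, b)` intervals on both axes (a cell on
an interior grid line belongs to exactly one unit), expression is
normalised/log-transformed/PCA-reduced *per cell* and then averaged per
unit, cell types are counted per unit, empty units are dropped, and units
are connected rook-wise.

## Stage I: the normal-multinomial mixture with an MRF prior

Per domain `k`: `y_i | z_i = k ~ MN(μ_k, Σ_k)` and
`v_i | z_i = k ~ Multi(m_i, ω_k)`, combined as
`MN(y_i; μ_k, Σ_k) · Multi(v_i; m_i, ω_k)^w`. The tempering weight
`w ∈ [0, 1]` controls how much histology influences clustering relative to
expression; defaults are 0.05 for spot-resolution platforms (where `V` is
a noisy, coarse summary) and 0.5 for grid-binned single-cell data (where
cell typing is direct). The labels carry the Potts prior
`π(z_i = k | z_-i) ∝ exp(d_k + f Σ_{i'} g_{ii'} I(z_{i'} = k))` with
`d_k = 1` and `f = 1` by default; very large `f` risks the usual Potts
phase transition (all spots collapse into one domain), so `f` is not
auto-tuned.

**Priors.** `μ_k | Σ_k ~ MN(ν_0, Σ_k/τ_0)`, `Σ_k ~ IW(η_0, Φ_0)` with
`ν_0` = empirical mean of `Y` (≈ 0 after PCA centring), `τ_0 = 0.01`
(weak), `η_0 = P' + 1`, `Φ_0 = I`. When the reduction is PCA the scores
are orthogonal, so the default restricts `Σ_k` to a diagonal matrix and
uses an independent normal–inverse-gamma pair per coordinate,
`σ²_kp ~ IG(0.1, 0.1)` (stored as shape/scale 0.2/0.2 halved in the
update); `covariance="full"` enables the full NIW variant.
`ω_k ~ Dir(α_0)` with `α_0q = 1/2`.

**Gibbs sweep.** Parameters are initialised with one conditional draw
given k-means labels (on standardised `Y`, concatenated with standardised
cell-type proportions when `w > 0`; `init="random"` is available). Each
sweep then updates every `z_i` in index order from its full conditional
(computed in log space with max-subtraction), followed by conjugate draws
of `(μ_k, Σ_k)` and `ω_k` for every `k`. Defaults: 2000 sweeps, 1000
burn-in. All randomness flows through one `numpy` generator seeded by
`seed`, with the label sweep consuming pre-drawn uniforms, so chains are
bit-reproducible; the sweep inner loop is JIT-compiled with numba.

**Tempered ω update.** With the multinomial raised to `w`, the coherent
Dirichlet conditional is `ω_k ~ Dir(α_0 + w Σ_{i: z_i=k} v_i)` (prior
untempered, likelihood tempered); at `w = 1` it reduces to the classical
`α_0 + Σ v_i` update, which is also available directly via
`temper_dirichlet_update=False`.

**Label switching and identifiability.** Every stored draw is relabelled
so the abundance of a reference cell type `q_ref` is strictly decreasing
in the domain index (stable sort; `q_ref` defaults to the globally most
abundant cell type). This device identifies the domains only when every
domain has a *distinct* abundance of `q_ref`; with exactly equal
abundances the non-dominant domains are unorderable and relabelling would
artificially mix their draws. The synthetic generator's default
compositions are chosen to satisfy this condition (below).

**Inference.** Marginal probabilities are label frequencies over stored
draws; `ẑ` is the row-wise argmax (ties go to the lowest index and are
flagged — a tied spot has max probability ≤ 0.5 and is boundary anyway).
Spots with `max_k π(z_i = k | ·) < 0.9` are boundary spots; their
connected components under `G` are the interactive zones, with singleton
components reported separately rather than discarded silently. Composition
estimates are posterior means with equal-tailed sample-quantile credible
intervals; arbitrary posterior probabilities (e.g.
`π(ω_kq > ω_k'q | ·)`) are draw-wise indicator averages.

**Choosing K.** `ICL(K) = −2 log L(Y, V, ẑ | μ̂, Σ̂, ω̂) + d log N`, where
the complete-data likelihood is the product of the mixture components at
the called labels with posterior-mean plug-ins, and `d = 2KP' + K(Q−1)`.
The recommended `K` minimises ICL over a user-supplied range. Overfitted
`K` leaves near-empty domains whose plug-in parameters are prior-dominated,
which inflates ICL sharply — the criterion is decisive on clean data.

## Stage II: domain-specific differential expression

`c_ij ~ NB(s_i λ_ij, ψ_j)` with mean model on the binary indicator
`x_ik = I(ẑ_i = k)`. Because the predictor is binary, the additive mean
model `λ = α + βx` and the log-link model `log λ = α' + β'x` describe the
same two group means and share the null `β = 0`; the log link guarantees
positivity and matches standard NB GLM practice, so it is the default
(`link="identity"` reproduces the additive parameterisation, with the
dispersion fixed from a first-pass log-link ML fit). `ψ_j` is estimated
per gene by maximum likelihood (NB2), `log s_i` enters as the offset, the
default test is Wald on the domain coefficient (`test="lrt"` switches to
the likelihood-ratio statistic). All-zero and non-converged genes are
flagged and excluded from the Benjamini–Hochberg family; discoveries at
adjusted p < `level` (default 0.05) are the spaDEGs. Size factors default
to per-spot totals, matching the Stage-I normalisation.

Diagnostics: per-spot richness (fraction of genes with a non-zero count,
useful for comparing interactive zones to domain interiors) and per-gene
Moran's I with binary weights,
`I = (N/W) Σ_{ii'} g_{ii'}(x_i − x̄)(x_{i'} − x̄) / Σ_i (x_i − x̄)²`;
a constant vector returns NaN with a warning since the statistic is
undefined.

## The synthetic generator

`SimulationSpec` defaults define the reference study conditions: a 20 × 20
square lattice (N = 400), K = 3 domains as contiguous vertical bands
(`partition="potts"` instead samples a Potts field at strength `potts_f`),
Q = 4 cell types, Poisson(20) cells per spot with `v_i ~ Multi(m_i,
ω*_{z_i})` and an explicit jittered cell table, `y_i ~ MN(μ*_{z_i}, I)`
with domain means separated by 2.5 along distinct PC axes, and NB counts
for 200 null plus 50 shifted genes (log-fold-change 1.0 in domain 0,
baseline mean 10, dispersion ψ = 5, log-normal exposures with σ = 0.3).
These values give strong but not degenerate signal — per-spot Bayes error
from the molecular profile alone is ~10% per pairwise comparison, so
spatial smoothing and the image profile both contribute measurably — and
the full fixture fits in about a second.

Two deliberate choices:

* **Compositions.** Default `ω*` rows are dominated (≈ 0.71 on the
  domain's own type) with the remaining mass decaying geometrically around
  the type ring, so every cell type's abundance differs across domains.
  Perfectly symmetric minor shares would violate the identifiability
  condition of the reference-type relabelling (two domains with identical
  `ω_{k,q_ref}` cannot be ordered), which is a limitation of the ordering
  device, not of the sampler.
* **Size factors.** The generative model is `c_ij ~ NB(s_i λ_ij, ψ_j)`
  with explicit exposures, and the generator records those true `s_i` in
  its `CountMatrix` (and in `size_factors.csv`). On a 250-gene panel,
  estimating `s_i` from row totals would be confounded by the 50 shifted
  genes themselves — a panel-size artifact that a genome-wide count matrix
  does not suffer. Real-data readers always default to row totals.

What the generator does *not* emulate: histology images or segmentation
error (cell typing is exact), platform-specific spatial artifacts,
zero-inflation, or between-gene correlation. Passing tests on this
fixture therefore demonstrate correctness of the inference machinery
under the model's own assumptions, not robustness to real-tissue
misspecification.

## Numerical and design notes

* Label conditionals are normalised in log space after max-subtraction;
  a spot whose K terms are all `−inf` raises instead of silently
  renormalising.
* The multinomial coefficient is omitted in the per-sweep likelihood
  matrix (it cancels in the label conditional) but included in the
  component likelihood used for ICL.
* Empty domains fall back to prior draws in every conjugate update.
* `w = 0` makes the chain draw-for-draw identical to a mixture that never
  sees `V` (same seed, same `q_ref`), which is tested bit-exactly.
* Sampler-level exchangeability under spot permutation cannot hold
  bit-wise for a fixed-order sequential sweep; equivariance is instead
  guaranteed (and tested) at the inference level: permuting the stored
  chain and the adjacency permutes labels, boundary calls and zones
  accordingly.
* Problem sizes in the test-suite and acceptance runs (400-spot fixtures,
  2000 sweeps, 10-seed selection studies, 10–50 coverage replicates,
  1000-gene calibration panels) were chosen so each study gives stable
  Monte-Carlo estimates while the whole suite runs in a few minutes on a
  single core.

## Known limitations

* The MRF coupling `f` is fixed, not inferred; the phase-transition regime
  is the user's responsibility.
* The reference-type relabelling fails when domains share the reference
  type's abundance (see above); choosing `q_ref` explicitly is advisable
  on real data.
* ICL uses plug-in posterior means; it is a model-selection heuristic, not
  a marginal likelihood.
* Stage II treats `ẑ` as known, ignoring Stage-I uncertainty; boundary
  spots could be excluded by the caller if that matters.
* The DE model assumes NB counts with a single dispersion per gene and no
  shrinkage across genes.
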