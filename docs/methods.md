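# Methods

This note documents the models implemented in traitprop, the defaults and
why they are set where they are, the synthetic data used to validate the
package, and the numerical choices made where the design was genuinely open.

## Model overview

traitprop estimates, for every cell of an scATAC-seq experiment, the
relevance of that cell to a genetic trait with fine-mapped causal variants.
The estimate has two stages: a *local* colocalization statistic computed
independently per cell, and a *global* smoothing step that shares evidence
across similar cells through a graph diffusion. The central assumption is
that trait relevance is a property of cell state, and that cell state is
well captured by the global accessibility profile even when any individual
locus is unreliable: absence of signal at a variant-bearing peak in one cell
is weak evidence, but a neighborhood of cells jointly depleted for such
signal is strong evidence.

### Bias-corrected deviation Z

Per-peak weights are the sum of posterior probabilities (PP) of the variants
falling inside the peak (1-based variant positions, 0-based half-open BED
peaks). Summation (rather than max) treats PPs within a credible set as
additive evidence that the peak contains a causal variant. Variants are
pre-filtered at PP > 0.001 (strict).

For cell j, observed weighted accessibility o_j = Σ_i w_i x_ij is compared
with the expectation e_j = Σ_i w_i · (row_i · col_j / total) under the
rank-1 margin model, giving the raw deviation d_j = (o_j − e_j)/e_j, which
is invariant to rescaling the weights. Raw deviations confound trait signal
with per-peak technical structure (mean accessibility, GC content, PCR
effects), so each weighted peak is matched to its 100 nearest peaks in
z-scored covariate space (mean accessibility, plus GC fraction when the BED
file provides one; GC is optional so no genome FASTA is ever needed) and 50
background weight vectors are drawn by transplanting the weights onto
sampled neighbors. The bias-corrected Z is the real deviation standardized
by the mean and SD of the background deviations. Cells with zero totals,
zero expectation, or zero background spread get NaN rather than an
exception, and are excluded from seed selection.

Defaults: 50 background sets, neighborhood K = 100, both standard for this
family of statistics; larger values change Z by noise only.

### Seed cells

Z is converted to a one-tailed normal P = 1 − Φ(Z); cells with P < 0.05 are
seeds, truncated to the ceil(0.05 N) highest-Z cells when more pass. The 5%
cap keeps the restart distribution concentrated on high-confidence cells
regardless of how diffuse the Z distribution is. If no cell passes, the
package falls back to the top max(10, ceil(0.01 N)) cells by Z with a loud
warning (configurable to a hard error): an empty restart vector is
undefined, and a silent failure would be worse than a clearly flagged
low-confidence run.

### Cell graph

The binarized matrix is TF-IDF weighted: tf_ij is the cell-normalized
binarized value (each cell's entries sum to 1) and idf_i = log(1 + N/df_i)
with the natural logarithm. Cell-frequency tf matches common scATAC LSI
practice; a raw binarized tf is available via `tf_mode="binary"`. The
weighted matrix is decomposed by truncated SVD and cells are embedded at
V·Σ using the d = 30 leading components, all retained (no
depth-component dropping). Small matrices (min dimension ≤ 200) use an
exact dense SVD with a deterministic sign convention; larger ones the
seeded ARPACK solver.

The graph connects cells that are mutually within each other's k = 30
nearest neighbors (Euclidean distance in LSI space). Mutuality bounds the
degree by k and suppresses hub cells. Neighbor lists come from an
exhaustive blockwise distance computation with a stable sort, so ties at
equal distance resolve to the lower cell index and the construction is
bit-reproducible and matches a brute-force oracle exactly. A cell with no
mutual neighbor is attached to its single nearest neighbor (recorded as a
fallback edge), which guarantees degree ≥ 1 but *not* a single connected
component; the component count is reported, cells in seed-free components
receive propagation score exactly 0, and `bridge_components=True`
optionally joins components through their closest inter-component pair.

### Random walk with restart

With adjacency A and degree matrix D, the transition matrix is the
column-stochastic M = A D⁻¹ (each cell splits its mass equally among its
neighbors), which conserves Σv = 1 exactly; the iteration is
v ← (1 − γ) M v + γ v₀ with v₀ uniform over the seeds and restart
probability γ = 0.05. Convergence is declared when the L1 change falls
below α = 1e-5 — L1 is the scale-natural norm for probability vectors, so
the tolerance means the same thing at any cell count. Mass conservation is
asserted at 1e-10 every iteration, γ = 0 is rejected (a pure walk on a
near-bipartite graph can oscillate), and a safety cap of 10,000 iterations
returns a flagged non-converged result (at γ = 0.05 convergence typically
takes tens of iterations). On graphs of ≤ 200 nodes the iterate agrees
with the direct solve v = γ(I − (1−γ)M)⁻¹v₀ to L∞ ≤ 1e-6 (tested).

### Trait relevance score

NP scores scale as 1/N and are not comparable across datasets. The TRS
ceilings NP at its 99th percentile (linear-interpolation percentile, the
numpy default; configurable), min-max scales the *ceiled* values to [0, 1]
(ceiling first, then min-max), and multiplies by a scaling factor: the mean
bias-corrected Z of the ceil(0.01 N) highest-Z cells, which anchors the
TRS to the enrichment level of the dataset's strongest cells. An
alternative factor — the mean NP of those same cells — is available via
`scaling_mode="mean_np"`. If all NP values coincide the scaled vector is
defined as all zeros; a non-positive factor is passed through with a
warning, leaving interpretation to the caller.

### Degree-matched permutation test

NP vectors all sum to 1, so scores from different seed sets are directly
comparable; the null distribution of each cell's NP is built by re-running
the walk from B = 1000 permuted seed sets that preserve the real seeds'
degree multiset: a seed with m neighbors is replaced by a uniform draw
(without replacement within a permutation) from cells with exactly m
neighbors. When an exact-degree pool is exhausted the draw falls back to
the nearest available degree (ties toward smaller |Δdegree|, then the lower
degree) — the construction the test needs when a degree class is smaller
than its seed count; fallback draws are counted and logged. Real seeds are
eligible pool members, and permuted sets may coincide with the real set
(logged). The empirical P is (1 + #{NP ≤ NP_null}) / (1 + B): ties count
toward the null, P ∈ [1/(B+1), 1], and the test is conservative. A cell is
*enriched* iff P < 0.05; depletion is simply "not enriched" (a symmetric
lower-tail call is deliberately not the default). Null walks stream as
per-cell exceedance counters when the real NP vector is supplied, keeping
memory O(cells) at any B.

Calibration: when the "real" seed set is itself drawn uniformly, real and
permuted sets are exchangeable conditional on the degree multiset, so P is
uniform on its grid and the expected enriched fraction at α is
floor(α(B+1))/(B+1) (0.0498 at B = 200); the test suite verifies the
observed fraction over 20 × 500 cells stays within 3 binomial SE of 0.05.

## The simulator and what it does (not) capture

Counts are Binomial(2, p_it) per peak with
p_it = (n/2)((1 − q) r_it + q/k): a diploid-like two-trial model blending
the bulk ratio vector r with a uniform noise floor q, scaled so the
expected total per cell is exactly n fragments whenever no p_it caps at 1
(capped peaks are counted and logged). At q = 1 the counts are independent
of the bulk profile. The binomial size 2 is fixed. Note the published form
of this model omits the depth factor on the bulk term, which would make
the expected total depend on q (1 fragment at q = 0, n at q = 1); the
implementation uses the dimensionally consistent form above and keeps the
uncorrected one behind `printed_formula=True` for comparison.

Synthetic bulk profiles give each cell type a disjoint block of marker
peaks carrying a `specificity` fraction of its read mass, the remainder
uniform over shared peaks; synthetic trait variants are placed uniformly
inside the target type's marker peaks with PP ~ U(pp_range). These
fixtures emulate the *structure* of FACS-sorted bulk ATAC data — marker
enrichment, shared background, variant concentration in open chromatin of
the relevant type — but not its texture: no correlated fragment lengths,
no doublets, no batch effects, no LD structure among variants, and uniform
rather than heavy-tailed PP. Tests passing on these fixtures therefore
demonstrate algorithmic correctness and the qualitative rescue effect of
propagation, not performance figures transferable to real atlases.

## Reference study conditions

The recovery benchmark (`traitprop.benchmark.recovery_benchmark`) fixes,
once: 50,000 peaks (≈10× scale-down of a real bulk peak set), two cell
types with 5,000 marker peaks each at specificity 0.3 (≈3× marker
enrichment), 20 variants with PP ~ U(0.1, 0.9) in the target's markers,
n = 10,000 fragments, q = 0.3, 500 cells per type. In this regime the raw
Z ranking classifies ~96–98% of cells and the NP ranking reaches ~100%,
with the improvement reproducing across seeds. The calibration benchmark
uses 500 cells, 25 seeds, B = 200 and 20 replicates. The simulator-moment
checks use k = 5,000 peaks with a uniform bulk at n = 10,000 (mean totals),
and a skewed bulk at n = 2,000 for the full-noise homogeneity test, a
regime where the counts are genuinely stochastic.

## Known limitations

- The per-stage RNG fan-out (`blake2s(master_seed:stage)`) makes streams
  independent but means a stage's stream cannot be reproduced from the
  master seed without the package.
- Exhaustive kNN is O(N²) in time; fine to ~10⁵ cells on one core, beyond
  which an approximate index would be needed (at the cost of exactness
  guarantees).
- Components with no seed cell receive NP = 0 rather than being excluded;
  their empirical P is 1 by construction, which is conservative.
- Zero-count cells and zero-count peaks are dropped once at pipeline start
  (recorded in the manifest); library functions called directly on such
  data return NaN scores instead.
- No multiple-testing correction is applied across cells, and no lower-tail
  depletion test is run by default.
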