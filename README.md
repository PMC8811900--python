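# traitprop

**traitprop** maps fine-mapped GWAS variants to the single cells they are most
relevant to, using single-cell chromatin accessibility (scATAC-seq) and
network propagation.

## The problem

Colocalizing trait-associated variants with accessible chromatin identifies
the cell types in which a trait's causal variation acts — but scATAC-seq
matrices are extremely sparse (a typical peak is silent in most cells), so a
per-cell colocalization score is reliable only for a handful of cells and
uninformative for the rest. traitprop treats those few confident cells as
*seeds* and lets their identity diffuse over a cell-to-cell similarity graph,
assigning every cell a probability of relevance that pools evidence across
its neighborhood.

## The method

Given a peak-by-cell count matrix `X`, a fine-mapped variant table
(posterior probabilities PP, filtered at PP > 0.001), and per-peak
covariates:

1. **Per-cell enrichment Z.** Per-peak weights `w_i = Σ PP` over contained
   variants; per cell `j`, observed `o_j = Σ_i w_i x_ij` vs expected
   `e_j = Σ_i w_i · row_i col_j / total`, raw deviation `(o_j − e_j)/e_j`,
   standardized against 50 background peak sets matched on mean accessibility
   (and GC content when provided) — a bias-corrected deviation Z.
2. **Seed cells.** Cells with one-tailed `P = 1 − Φ(Z) < 0.05`, capped at the
   top 5% of cells by Z.
3. **Cell graph.** Binarize `X`, weight by TF-IDF
   (`w_ij = tf_ij · log(1 + N/df_i)`), embed cells with a truncated SVD
   (LSI, d = 30), and connect cells that are mutually within each other's
   k = 30 nearest neighbors (isolated cells fall back to their single nearest
   neighbor).
4. **Random walk with restart.** Iterate
   `v ← (1 − γ) M v + γ v₀` with column-stochastic `M = A D⁻¹`, restart
   probability γ = 0.05 and uniform mass on the seeds, to the stationary
   network propagation score (NP; sums to 1, L1 tolerance 1e-5).
5. **Trait relevance score (TRS).** Ceiling NP at its 99th percentile,
   min-max scale to [0, 1], multiply by the mean Z of the top 1% of cells.
6. **Cell states.** Re-propagate B = 1000 seed sets permuted under a
   degree-matched scheme; empirical `P = (1 + #{NP ≤ NP_null}) / (1 + B)`;
   a cell is *enriched* iff P < 0.05, else *depleted*.

A binomial simulator (`counts ~ Binomial(2, p_it)` with
`p_it = (n/2)((1−q) r_it + q/k)` blending bulk read ratios `r` with uniform
noise `q`) generates labeled synthetic cells from bulk profiles, so the whole
pipeline is testable without external data.

## Worked example

`examples/03_propagate.py` simulates 300 monocyte-like and 300 NK-like cells
at shallow depth (600 fragments over 5,000 peaks, noise q = 0.3), places 20
fine-mapped variants in the monocyte marker peaks, and runs the full chain:

```
seed cells: 30 | graph components: 4 | RWR iterations: 31
accuracy ranking by raw Z:  0.927
accuracy ranking by NP:     1.000
TRS scaling factor (mean Z of top 1% cells): 4.530
```

Ranking cells by the raw enrichment Z classifies 92.7% of cells into the
correct type; ranking by the propagated NP score classifies all of them —
propagation rescues target cells whose own variant-peak signal dropped out.
The other examples cover simulation and sparsity (`01`), bias-corrected
scoring (`02`), and permutation-based state calls (`04`); each prints a short
readout with a comment on what the numbers mean.

The same workflow is available from the shell:

```sh
traitprop simulate --bulk synthetic --celltypes mono,nk --out sim/
traitprop run --matrix sim/matrix.mtx --peaks sim/peaks.bed \
    --barcodes sim/barcodes.txt --variants variants.tsv \
    --permutations --out-dir results/
```

which writes a per-cell TSV (`barcode, zscore, seed, np_score, trs,
empirical_p, state`) plus a JSON run manifest capturing the full
configuration, seeds and convergence diagnostics.

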