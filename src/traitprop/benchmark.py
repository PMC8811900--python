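"""Self-contained benchmark routines on synthetic data.

These encode the package's reference study conditions once, so tests,
examples and the reproduction script all run the same experiments:

* ``recovery_benchmark`` — the two-cell-type discovery benchmark: 500 + 500
  synthetic cells at n=10,000 fragments and noise q=0.3 over a 50,000-peak
  genome (a ~10x scale-down of a real bulk ATAC peak set), with 5,000 marker
  peaks per type at specificity 0.3 (~3x marker enrichment) and 20
  fine-mapped variants (PP ~ U(0.1, 0.9)) inside the target type's markers.
  It reports how accurately cells are classified into target / other when
  ranked by the raw bias-corrected Z versus by the network propagation score.

* ``calibration_benchmark`` — the permutation-test null calibration: seeds
  are themselves a uniform random draw of cells, so conditionally on their
  degree multiset the real and permuted seed sets are exchangeable and the
  empirical P values are uniform on their achievable grid; the fraction of
  cells called enriched at alpha should match alpha.
"""
from __future__ import annotations

import numpy as np

from ._utils import stage_seed
from .graph import build_mknn_graph, lsi_embed, tfidf_transform
from .propagation import SeedSet, random_walk, select_seeds
from .scoring import deviation_zscores, sample_background_peaks
from .significance import classify_states, degree_matched_permutations, empirical_pvalues
from .simulate import SimulationSpec, simulate_mixture, synth_bulk_profiles, synth_trait_weights


def recovery_benchmark(rng_seed: int, n_peaks: int = 50000, cells_per_type: int = 500,
                       n_fragments: int = 10000, noise: float = 0.3,
                       specificity: float = 0.3, n_variants: int = 20,
                       d: int = 30, k: int = 30) -> dict:
    """One replicate of the two-cell-type recovery benchmark.

    Returns classification accuracies when ranking cells by raw Z and by the
    propagated NP score (top half predicted as the target type), plus the
    seed-cell count.  Accuracy is the fraction of correctly classified cells.
    """
    celltypes = ["target", "other"]
    bulk = synth_bulk_profiles(n_peaks, celltypes, specificity=specificity,
                               rng_seed=stage_seed(rng_seed, "bulk"),
                               markers_per_type=n_peaks // 10)
    spec = SimulationSpec(n_fragments=n_fragments, noise=noise,
                          cells_per_type=cells_per_type,
                          rng_seed=stage_seed(rng_seed, "cells"))
    m, labels = simulate_mixture(bulk, celltypes, spec)
    _, weights = synth_trait_weights(bulk, "target", n_variants=n_variants,
                                     rng_seed=stage_seed(rng_seed, "variants"))
    bg = sample_background_peaks(m, weights.nonzero_peaks,
                                 rng_seed=stage_seed(rng_seed, "background"))
    scores = deviation_zscores(m, weights, bg)

    embedding = lsi_embed(tfidf_transform(m), d=d, svd_seed=stage_seed(rng_seed, "svd"))
    graph = build_mknn_graph(embedding, k=k)
    seeds = select_seeds(scores)
    result = random_walk(graph, seeds)

    is_target = (labels.to_numpy() == "target")
    n_target = int(is_target.sum())

    def accuracy(ranking_score: np.ndarray) -> float:
        order = np.argsort(-ranking_score, kind="stable")
        predicted = np.zeros(ranking_score.size, dtype=bool)
        predicted[order[:n_target]] = True
        return float((predicted == is_target).mean())

    return {
        "zscore_accuracy": accuracy(np.nan_to_num(scores.zscore, nan=-np.inf)),
        "np_accuracy": accuracy(result.np_score),
        "n_seeds": len(seeds),
        "n_cells": m.n_cells,
        "graph_components": graph.n_components,
    }


def calibration_benchmark(rng_seed: int, n_cells: int = 500, n_seeds: int = 25,
                          B: int = 200, n_replicates: int = 20, k: int = 30,
                          alpha: float = 0.05) -> dict:
    """Null calibration of the degree-matched permutation test.

    Each replicate builds an M-kNN graph over a fresh Gaussian point cloud
    (a stand-in LSI embedding), draws 5% of the cells uniformly as the
    "real" seed set, and compares its NP scores against B degree-matched
    permutations.  Under this null the expected enriched fraction at alpha
    is the largest achievable P below alpha, i.e.
    floor(alpha * (B + 1)) / (B + 1).
    """
    rng = np.random.default_rng(rng_seed)
    fractions = []
    for rep in range(n_replicates):
        coords = rng.standard_normal((n_cells, 10))
        from .graph import LSIEmbedding
        emb = LSIEmbedding(coords=coords, singular_values=np.ones(10))
        graph = build_mknn_graph(emb, k=k)
        seed_idx = np.sort(rng.choice(n_cells, size=n_seeds, replace=False))
        seeds = SeedSet(indices=seed_idx, zscores=np.zeros(n_seeds))
        real = random_walk(graph, seeds)
        null = degree_matched_permutations(
            graph, seeds, B=B, rng_seed=int(rng.integers(2**31)),
            real_np=real.np_score)
        pvals = empirical_pvalues(real.np_score, null)
        fractions.append(float(classify_states(pvals, alpha=alpha).enriched.mean()))
    fractions = np.asarray(fractions)
    n_total = n_cells * n_replicates
    expected = np.floor(alpha * (B + 1)) / (B + 1)
    return {
        "enriched_fraction": float(fractions.mean()),
        "per_replicate": fractions,
        "expected": float(expected),
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / n_total)),
        "n_total": n_total,
    }
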