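"""Propagate seed cells over the mutual-kNN graph and compare rankings.

Raw per-cell Z scores are noisy: sparsity leaves many truly relevant cells
unremarkable.  Selecting only the strongest cells as seeds and diffusing
their identity over the cell-to-cell graph (random walk with restart)
recovers the rest of the population.  The comparison printed here is the
package's benchmark readout: classification accuracy when ranking cells by
raw Z versus by the propagated NP score.
"""
import numpy as np

import traitprop as tp

bulk = tp.synth_bulk_profiles(n_peaks=5000, celltypes=["mono", "nk"],
                              specificity=0.3, rng_seed=0)
# shallow sequencing (600 fragments over 5,000 peaks) so the per-cell signal
# is genuinely noisy -- the regime propagation is designed for
spec = tp.SimulationSpec(n_fragments=600, noise=0.3, cells_per_type=300, rng_seed=0)
matrix, labels = tp.simulate_mixture(bulk, ["mono", "nk"], spec)
variants, _ = tp.synth_trait_weights(bulk, target="mono", n_variants=20, rng_seed=1)

weights = tp.variant_peak_weights(variants, matrix)
background = tp.sample_background_peaks(matrix, weights.nonzero_peaks, rng_seed=2)
scores = tp.deviation_zscores(matrix, weights, background)

embedding = tp.lsi_embed(tp.tfidf_transform(matrix), d=30, svd_seed=0)
graph = tp.build_mknn_graph(embedding, k=30)
seeds = tp.select_seeds(scores)  # P < 0.05, capped at 5% of cells
result = tp.random_walk(graph, seeds, gamma=0.05)
trs, factor = tp.compute_trs(result.np_score, scores.zscore)

is_target = labels.to_numpy() == "mono"
n_target = int(is_target.sum())

def accuracy(score):
    order = np.argsort(-score, kind="stable")
    hit = np.zeros(score.size, bool)
    hit[order[:n_target]] = True
    return (hit == is_target).mean()

print(f"seed cells: {len(seeds)} | graph components: {graph.n_components} "
      f"| RWR iterations: {result.iterations}")
print(f"accuracy ranking by raw Z:  {accuracy(np.nan_to_num(scores.zscore, nan=-np.inf)):.3f}")
print(f"accuracy ranking by NP:     {accuracy(result.np_score):.3f}")
print(f"TRS scaling factor (mean Z of top 1% cells): {factor:.3f}")
# NP-based ranking should match or beat the raw Z ranking: propagation pools
# evidence across similar cells, rescuing cells whose own signal dropped out.
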