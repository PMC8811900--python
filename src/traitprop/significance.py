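"""Degree-matched permutation null, empirical P values, and cell state calls.

Because the NP vector of every walk sums to 1, NP scores from different seed
sets are directly comparable; the null distribution of a cell's NP is
therefore built by rerunning the walk from permuted seed sets that preserve
the real seeds' node-degree multiset (a seed with m neighbors may only be
replaced by a cell with m neighbors, falling back to the nearest available
degree when a pool runs dry).  The per-cell empirical P value counts how
often the permuted score meets or exceeds the real one, with the +1 / (B+1)
correction, so P is always in [1/(B+1), 1] and ties count toward the null.
A cell is called trait-enriched when P < alpha (default 0.05) and depleted
otherwise (binary classification).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import CellGraph
from .propagation import SeedSet, _rwr, transition_matrix

log = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """Null NP scores from B degree-matched seed permutations.

    When ``real_np`` was supplied at construction the null is streamed: only
    the per-cell exceedance counters (# permutations with NP >= real NP) are
    kept, so memory stays O(cells).  Otherwise the full (B, n_cells) score
    matrix is stored.
    """

    B: int
    rng_seed: int
    seed_sets: np.ndarray  # (B, n_seeds) permuted seed indices
    exceed_counts: np.ndarray | None = None
    scores: np.ndarray | None = None  # (B, n_cells) when stored
    n_fallback_draws: int = 0

    def degree_multisets(self, g: CellGraph) -> np.ndarray:
        """Sorted degree multiset of every permuted seed set, one row each."""
        return np.sort(g.degrees[self.seed_sets], axis=1)


@dataclass
class StateCalls:
    """Per-cell empirical P and the binary enriched/depleted call."""

    pvalues: np.ndarray
    enriched: np.ndarray  # bool, True iff P < alpha
    alpha: float

    @property
    def state(self) -> np.ndarray:
        return np.where(self.enriched, "enriched", "depleted")


def _draw_degree_matched(rng: np.random.Generator, degrees: np.ndarray,
                         seed_degrees: np.ndarray,
                         pools: dict[int, np.ndarray]) -> tuple[np.ndarray, int]:
    """One permuted seed set with the same degree multiset as the real seeds.

    Draws are without replacement within the permutation.  If the pool for a
    degree is exhausted, the remaining draws come from the nearest available
    degree (ties toward the smaller |delta|, then the lower degree).
    """
    used = np.zeros(degrees.size, dtype=bool)
    chosen: list[int] = []
    deficits: list[int] = []
    uniq, counts = np.unique(seed_degrees, return_counts=True)
    for deg, cnt in zip(uniq.tolist(), counts.tolist()):
        pool = pools[deg]
        avail = pool[~used[pool]]
        take = min(cnt, avail.size)
        if take:
            pick = rng.choice(avail, size=take, replace=False)
            used[pick] = True
            chosen.extend(pick.tolist())
        deficits.extend([deg] * (cnt - take))
    n_fallback = len(deficits)
    for deg in deficits:
        all_degs = sorted(pools, key=lambda d: (abs(d - deg), d))
        pick = None
        for d in all_degs:
            avail = pools[d][~used[pools[d]]]
            if avail.size:
                pick = int(rng.choice(avail))
                break
        if pick is None:
            raise ValueError("more seeds than cells; cannot permute without replacement")
        used[pick] = True
        chosen.append(pick)
    return np.sort(np.array(chosen, dtype=int)), n_fallback


def degree_matched_permutations(g: CellGraph, seeds: SeedSet, B: int = 1000,
                                rng_seed: int = 0, gamma: float = 0.05,
                                alpha: float = 1e-5, max_iter: int = 10000,
                                real_np: np.ndarray | None = None,
                                batch: int = 256) -> PermutationNull:
    """Propagate B degree-matched permuted seed sets and collect their NP scores.

    The walks share the transition matrix and iterate in batches of seed
    columns to the same tolerance as the real walk.  Passing ``real_np``
    switches to streaming exceedance counters (memory O(cells)); otherwise
    the (B, n_cells) score matrix is retained.  Fully reproducible given
    ``rng_seed``; fallback (nearest-degree) draws are counted and logged.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        log.warning("B=%d permutations gives coarse empirical P resolution (min P = %.3g)",
                    B, 1.0 / (B + 1))
    rng = np.random.default_rng(rng_seed)
    degrees = g.degrees
    pools = {int(d): np.nonzero(degrees == d)[0] for d in np.unique(degrees)}
    seed_degrees = degrees[seeds.indices]
    n = g.n_cells
    M = transition_matrix(g)

    seed_sets = np.empty((B, len(seeds)), dtype=int)
    n_fallback = 0
    for b in range(B):
        seed_sets[b], fb = _draw_degree_matched(rng, degrees, seed_degrees, pools)
        n_fallback += fb
    if n_fallback:
        log.info("%d nearest-degree fallback draws across %d permutations", n_fallback, B)
    coincide = int((np.sort(seed_sets, axis=1) == np.sort(seeds.indices)).all(axis=1).sum())
    if coincide:
        log.info("%d permuted seed set(s) coincide with the real seed set", coincide)

    stream = real_np is not None
    exceed = np.zeros(n, dtype=np.int64) if stream else None
    stored = None if stream else np.empty((B, n))
    inv = 1.0 / len(seeds)
    for start in range(0, B, batch):
        stop = min(start + batch, B)
        v0 = np.zeros((n, stop - start))
        for j in range(start, stop):
            v0[seed_sets[j], j - start] = inv
        v, _, converged = _rwr(M, v0, gamma, alpha, max_iter)
        if not converged:
            log.warning("permutation walks %d-%d did not all converge", start, stop - 1)
        if stream:
            exceed += (v >= np.asarray(real_np)[:, None]).sum(axis=1)
        else:
            stored[start:stop] = v.T
    return PermutationNull(B=B, rng_seed=rng_seed, seed_sets=seed_sets,
                           exceed_counts=exceed, scores=stored,
                           n_fallback_draws=n_fallback)


def empirical_pvalues(real_np: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Tie-inclusive empirical P per cell: (1 + #{b : NP_c <= NP_c^(b)}) / (1 + B)."""
    real_np = np.asarray(real_np, dtype=float)
    if null.exceed_counts is not None:
        counts = null.exceed_counts
    else:
        if null.scores.shape[1] != real_np.size:
            raise ValueError("null scores and real NP cover different numbers of cells")
        counts = (null.scores >= real_np[None, :]).sum(axis=0)
    return (1.0 + counts) / (1.0 + null.B)


def classify_states(pvalues: np.ndarray, alpha: float = 0.05) -> StateCalls:
    """Binary call: enriched iff empirical P < alpha (strict), else depleted."""
    pvalues = np.asarray(pvalues, dtype=float)
    return StateCalls(pvalues=pvalues, enriched=pvalues < alpha, alpha=alpha)
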