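"""Seed selection, random walk with restart, and the trait relevance score.

Seed cells are the cells whose bias-corrected Z converts to a one-tailed
normal P below 0.05, capped at the top 5% of cells by Z.  Information starts
uniformly distributed over the seeds and spreads over the cell graph by the
random walk with restart (RWR) iteration

    v_{s+1} = (1 - gamma) M v_s + gamma v_0,

with M = A D^{-1} column-stochastic (each cell splits its mass equally among
its neighbors) and restart probability gamma (default 0.05).  The iteration
is run to the stationary distribution (L1 change < alpha, default 1e-5); the
result, the network propagation (NP) score, sums to 1 over cells at every
step.  The trait relevance score (TRS) rescales NP — 99th-percentile ceiling,
min-max to [0, 1], then multiplication by a scaling factor anchored to the
enrichment level of the top 1% of cells — so that scores are comparable
across datasets and traits.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import norm

from .graph import CellGraph
from .scoring import TraitScores

log = logging.getLogger(__name__)


@dataclass
class SeedSet:
    """Indices of the seed cells that initialize propagation."""

    indices: np.ndarray
    zscores: np.ndarray
    p_threshold: float = 0.05
    max_fraction: float = 0.05
    fallback_used: bool = False

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.zscores = np.asarray(self.zscores, dtype=float)
        if self.indices.size == 0:
            raise ValueError("seed set is empty")

    def __len__(self) -> int:
        return self.indices.size


@dataclass
class PropagationResult:
    """Stationary NP scores with convergence diagnostics, plus optional TRS."""

    np_score: np.ndarray
    iterations: int
    converged: bool
    gamma: float
    alpha: float
    trs: np.ndarray | None = None
    scaling_factor: float | None = None


def select_seeds(scores: TraitScores, p_threshold: float = 0.05,
                 max_fraction: float = 0.05, on_empty: str = "fallback") -> SeedSet:
    """Pick seed cells from bias-corrected Z scores.

    P_j = 1 - Phi(Z_j) (upper tail); seeds are cells with P < ``p_threshold``,
    truncated to the ceil(max_fraction * N) cells with the highest Z when more
    pass.  Ties at the cutoff resolve to the lower cell index.  If no cell
    passes, either fall back to the top max(10, ceil(0.01 N)) cells by Z with
    a prominent warning (default) or raise (``on_empty="error"``).
    """
    z = np.asarray(scores.zscore, dtype=float)
    n = z.size
    defined = np.isfinite(z)
    if not defined.any():
        raise ValueError("no cell has a defined Z score")
    pvals = np.full(n, np.nan)
    pvals[defined] = norm.sf(z[defined])
    passing = np.nonzero(defined & (pvals < p_threshold))[0]
    fallback_used = False
    if passing.size == 0:
        if on_empty == "error":
            raise ValueError(f"no cell passes P < {p_threshold}")
        n_fb = max(10, math.ceil(0.01 * n))
        n_fb = min(n_fb, int(defined.sum()))
        log.warning("NO cell passes P < %g; falling back to the top %d cells by Z",
                    p_threshold, n_fb)
        passing = np.nonzero(defined)[0]
        fallback_used = True
        cap = n_fb
    else:
        cap = math.ceil(max_fraction * n)
    if passing.size > cap:
        # highest Z first; ties broken toward the lower cell index
        order = np.lexsort((passing, -z[passing]))
        passing = np.sort(passing[order[:cap]])
    else:
        passing = np.sort(passing)
    log.info("selected %d seed cells (cap %d of %d cells)", passing.size, cap, n)
    return SeedSet(indices=passing, zscores=z[passing], p_threshold=p_threshold,
                   max_fraction=max_fraction, fallback_used=fallback_used)


def transition_matrix(g: CellGraph) -> sp.csr_matrix:
    """Column-stochastic M = A D^{-1}: column j distributes 1/deg_j to each neighbor."""
    deg = g.degrees
    if (deg == 0).any():
        raise ValueError("graph has isolated nodes; every node needs degree >= 1")
    return sp.csr_matrix(g.adjacency.astype(float) @ sp.diags(1.0 / deg))


def _rwr(M: sp.csr_matrix, v0: np.ndarray, gamma: float, alpha: float,
         max_iter: int) -> tuple[np.ndarray, int, bool]:
    """Iterate v <- (1-gamma) M v + gamma v0 on one or many seed columns.

    ``v0`` may be (n,) or (n, b); convergence requires every column's L1
    change below ``alpha``.  Mass conservation (each column sums to 1) is
    checked at 1e-10 every iteration.
    """
    v = v0.astype(float).copy()
    restart = gamma * v0
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        v_next = (1.0 - gamma) * (M @ v) + restart
        drift = np.abs(np.asarray(v_next.sum(axis=0)) - 1.0).max()
        if drift > 1e-10:
            raise RuntimeError(f"propagation mass drifted by {drift:.3e} (> 1e-10)")
        change = np.abs(v_next - v).sum(axis=0).max()
        v = v_next
        if change < alpha:
            converged = True
            break
    return v, it, converged


def random_walk(g: CellGraph, seeds: SeedSet, gamma: float = 0.05,
                alpha: float = 1e-5, max_iter: int = 10000) -> PropagationResult:
    """Run RWR from the seed set to the stationary NP score.

    v_0 puts 1/|seeds| on each seed cell.  gamma=1 reduces to the restart
    state itself; gamma=0 is rejected (a pure walk may fail to mix).  Cells in
    components containing no seed end with NP exactly 0.
    """
    if not (0 < gamma <= 1):
        raise ValueError("restart probability gamma must be in (0, 1]")
    n = g.n_cells
    if seeds.indices.min() < 0 or seeds.indices.max() >= n:
        raise ValueError("seed index outside graph")
    M = transition_matrix(g)
    v0 = np.zeros(n)
    v0[seeds.indices] = 1.0 / len(seeds)
    seed_components = set(g.component_labels[seeds.indices].tolist())
    orphan = ~np.isin(g.component_labels, list(seed_components))
    if orphan.any():
        log.warning("%d cells live in components without any seed; their NP is 0",
                    int(orphan.sum()))
    v, iterations, converged = _rwr(M, v0, gamma, alpha, max_iter)
    if not converged:
        log.warning("RWR did not converge within %d iterations", max_iter)
    return PropagationResult(np_score=v, iterations=iterations, converged=converged,
                             gamma=gamma, alpha=alpha)


def compute_trs(np_scores: np.ndarray, zscores: np.ndarray, percentile: float = 0.99,
                top_fraction: float = 0.01, scaling_mode: str = "mean_z",
                ) -> tuple[np.ndarray, float]:
    """Normalize NP scores to the trait relevance score.

    Ceiling at the ``percentile`` quantile of NP (linear interpolation
    between order statistics), min-max scale the ceiled values to [0, 1],
    then multiply by a scaling factor computed over the ceil(top_fraction * N)
    cells with the highest Z: their mean Z (default) or, with
    ``scaling_mode="mean_np"``, their mean NP.  If all NP values coincide the
    scaled vector is all zeros (degenerate min-max) with a warning.
    """
    np_scores = np.asarray(np_scores, dtype=float)
    z = np.asarray(zscores, dtype=float)
    if np_scores.shape != z.shape:
        raise ValueError("NP and Z vectors must be aligned over the same cells")
    n = np_scores.size
    ceiling = float(np.percentile(np_scores, percentile * 100))
    ceiled = np.minimum(np_scores, ceiling)
    lo, hi = ceiled.min(), ceiled.max()
    if hi == lo:
        log.warning("all NP scores equal after ceiling; TRS set to zero")
        scaled = np.zeros(n)
    else:
        scaled = (ceiled - lo) / (hi - lo)
    m_top = max(1, math.ceil(top_fraction * n))
    defined = np.nonzero(np.isfinite(z))[0]
    order = np.lexsort((defined, -z[defined]))
    top = defined[order[:m_top]]
    if scaling_mode == "mean_z":
        factor = float(z[top].mean())
    elif scaling_mode == "mean_np":
        factor = float(np_scores[top].mean())
    else:
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")
    if factor <= 0:
        log.warning("scaling factor %.4g <= 0; TRS will be non-positive", factor)
    return scaled * factor, factor


def solve_stationary(g: CellGraph, seeds: SeedSet, gamma: float = 0.05) -> np.ndarray:
    """Direct linear solve of the stationary state v = gamma (I - (1-gamma) M)^{-1} v0.

    Exact (up to solver tolerance) reference for the iterated walk; intended
    for small graphs and cross-checks.
    """
    n = g.n_cells
    M = transition_matrix(g).toarray()
    v0 = np.zeros(n)
    v0[seeds.indices] = 1.0 / len(seeds)
    return gamma * np.linalg.solve(np.eye(n) - (1.0 - gamma) * M, v0)
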