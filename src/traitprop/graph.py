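"""Cell-to-cell similarity graph: TF-IDF weighting, LSI embedding, mutual kNN.

The binarized peak-by-cell matrix is weighted as
``w_ij = tf_ij * log(1 + N / df_i)`` where ``tf_ij`` is the per-cell term
frequency of the binarized entry (a cell's entries sum to 1), ``df_i`` the
number of cells in which feature i appears and ``N`` the number of cells.
Truncated SVD of the weighted matrix gives the latent semantic indexing (LSI)
embedding; cells are placed at ``V @ diag(sigma)`` (right singular vectors
scaled by singular values).  The propagation substrate is then the mutual
k-nearest-neighbor (M-kNN) graph under Euclidean distance in LSI space: an
edge exists only when two cells are each within the other's k nearest
neighbors, which caps the degree at k and suppresses hub nodes.  A cell with
no mutual neighbor is attached to its single nearest neighbor so that no node
is isolated (the graph may still have several connected components).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import TruncatedSVD

from .io import PeakCellMatrix

log = logging.getLogger(__name__)

_DENSE_SVD_MAX = 200  # below this many cells/peaks a dense SVD is exact and cheap


@dataclass
class LSIEmbedding:
    """Cell coordinates in LSI space with the associated singular values."""

    coords: np.ndarray  # (n_cells, d)
    singular_values: np.ndarray  # non-increasing, >= 0

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class CellGraph:
    """Undirected simple graph over cells (binary symmetric adjacency)."""

    adjacency: sp.csr_matrix
    k: int
    fallback_edges: list[tuple[int, int]] = field(default_factory=list)
    component_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        if self.component_labels is None:
            _, self.component_labels = connected_components(self.adjacency, directed=False)

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1


def tfidf_transform(m: PeakCellMatrix | sp.spmatrix, tf_mode: str = "frequency") -> sp.csr_matrix:
    """TF-IDF weight the binarized feature-by-cell matrix.

    ``tf_mode="frequency"`` (default) normalizes each cell's binarized column
    to sum to 1; ``"binary"`` leaves the binarized values as-is.  The IDF
    term uses the natural logarithm.  Features present in no cell keep weight
    0; cells with no features are kept as all-zero columns with a warning
    (drop them upstream to keep the graph meaningful).
    """
    counts = m.counts if isinstance(m, PeakCellMatrix) else m
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("empty matrix")
    b = counts.tocsc().astype(float)
    b.data = (b.data != 0).astype(float)
    b.eliminate_zeros()
    n_cells = b.shape[1]
    df = np.asarray((b != 0).sum(axis=1)).ravel()
    feats_per_cell = np.asarray(b.sum(axis=0)).ravel()
    if (feats_per_cell == 0).any():
        log.warning("%d cells have no nonzero features after binarization",
                    int((feats_per_cell == 0).sum()))
    if tf_mode == "frequency":
        with np.errstate(divide="ignore"):
            inv = np.where(feats_per_cell > 0, 1.0 / feats_per_cell, 0.0)
        tf = b @ sp.diags(inv)
    elif tf_mode == "binary":
        tf = b
    else:
        raise ValueError(f"unknown tf_mode {tf_mode!r}")
    with np.errstate(divide="ignore"):
        idf = np.where(df > 0, np.log1p(n_cells / np.maximum(df, 1)), 0.0)
    return sp.csr_matrix(sp.diags(idf) @ tf)


def lsi_embed(weighted: sp.spmatrix, d: int = 30, svd_seed: int = 0) -> LSIEmbedding:
    """Truncated SVD of the weighted feature-by-cell matrix.

    Cells (columns) are embedded at ``V_{:, :d} @ diag(sigma_{:d})``.  Small
    matrices use an exact dense SVD; larger ones the ARPACK solver, seeded so
    the pipeline is deterministic.  Components come back in non-increasing
    singular-value order; trailing zero singular values are kept (the matching
    embedding columns are then zero).
    """
    n_feat, n_cells = weighted.shape
    if d < 2:
        raise ValueError("d must be >= 2")
    if d > min(n_feat, n_cells) - 1:
        raise ValueError(f"d={d} too large for a {n_feat}x{n_cells} matrix (need d <= min-1)")
    if min(n_feat, n_cells) <= _DENSE_SVD_MAX:
        dense = np.asarray(weighted.todense() if sp.issparse(weighted) else weighted, float)
        _, s, vt = np.linalg.svd(dense, full_matrices=False)
        v = vt[:d].T  # (n_cells, d)
        # deterministic sign: the largest-|.| entry of each component is positive,
        # so permuting cells permutes embedding rows without sign flips
        for j in range(d):
            i_star = int(np.argmax(np.abs(v[:, j])))
            if v[i_star, j] < 0:
                v[:, j] = -v[:, j]
        coords = v * s[:d]
        sigma = s[:d].copy()
    else:
        svd = TruncatedSVD(n_components=d, algorithm="arpack", random_state=svd_seed)
        coords = svd.fit_transform(sp.csr_matrix(weighted).T)
        sigma = svd.singular_values_.copy()
    order = np.argsort(-sigma, kind="stable")
    coords, sigma = coords[:, order], sigma[order]
    if sigma[-1] == 0:
        log.warning("rank-deficient input: trailing zero singular values retained")
    return LSIEmbedding(coords=np.ascontiguousarray(coords), singular_values=sigma)


def _knn_indices(coords: np.ndarray, k: int, block: int = 1024) -> np.ndarray:
    """Indices of each point's k nearest neighbors (self excluded).

    Exhaustive blockwise Euclidean distances with a stable sort, so ties at
    equal distance resolve to the lower cell index — the graph is then fully
    deterministic and matches a brute-force oracle exactly.
    """
    n = coords.shape[0]
    sq = np.einsum("ij,ij->i", coords, coords)
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (coords[start:stop] @ coords.T)
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(stop - start), np.arange(start, stop)] = -1.0  # self sorts first
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, 1 : k + 1]
    return out


def build_mknn_graph(e: LSIEmbedding, k: int = 30,
                     bridge_components: bool = False) -> CellGraph:
    """Mutual k-nearest-neighbor graph over the LSI embedding.

    Edge (u, v) exists iff u and v are each in the other's kNN list.  Any
    node left without a mutual edge gains one recorded fallback edge to its
    single nearest neighbor, guaranteeing degree >= 1 but not a single
    connected component.  With ``bridge_components=True`` the components are
    additionally joined through their closest inter-component cell pairs.
    """
    n = e.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nbrs = _knn_indices(e.coords, k)
    rows = np.repeat(np.arange(n), k)
    directed = sp.csr_matrix(
        (np.ones(n * k, dtype=np.int8), (rows, nbrs.ravel())), shape=(n, n)
    )
    mutual = directed.multiply(directed.T)
    adj = sp.lil_matrix(mutual)
    fallback: list[tuple[int, int]] = []
    isolated = np.nonzero(np.asarray(mutual.sum(axis=1)).ravel() == 0)[0]
    for u in isolated:
        v = int(nbrs[u, 0])
        adj[u, v] = 1
        adj[v, u] = 1
        fallback.append((int(u), v))
    adj = sp.csr_matrix(adj)
    adj.setdiag(0)
    adj.eliminate_zeros()
    n_comp, labels = connected_components(adj, directed=False)
    if bridge_components and n_comp > 1:
        adj = sp.lil_matrix(adj)
        while n_comp > 1:
            # join the two closest cells that lie in different components
            best = None
            for u in range(n):
                d2 = np.einsum("ij,ij->i", e.coords - e.coords[u], e.coords - e.coords[u])
                d2[labels == labels[u]] = np.inf
                v = int(np.argmin(d2))
                if best is None or d2[v] < best[0]:
                    best = (d2[v], u, v)
            _, u, v = best
            adj[u, v] = 1
            adj[v, u] = 1
            fallback.append((u, v))
            n_comp, labels = connected_components(sp.csr_matrix(adj), directed=False)
        adj = sp.csr_matrix(adj)
    if n_comp > 1:
        log.info("M-kNN graph has %d connected components", n_comp)
    if fallback:
        log.info("%d fallback edge(s) added for cells without mutual neighbors", len(fallback))
    return CellGraph(adjacency=adj, k=k, fallback_edges=fallback, component_labels=labels)
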