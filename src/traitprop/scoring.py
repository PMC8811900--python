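"""Per-cell trait enrichment: variant-weighted, bias-corrected deviation Z scores.

Fine-mapped variants are folded into per-peak weights (sum of causal posterior
probabilities of the variants falling inside each peak).  Each cell's weighted
accessibility is compared against its expectation under the rank-1 margin
model (row total x column total / grand total), and the raw deviation is
standardised against deviations computed with the same weights mapped onto
covariate-matched background peaks.  The background matching corrects for
technical confounders (mean accessibility and, when available, GC content),
in the spirit of the chromVAR family of statistics.  The same machinery scores
any non-negative per-peak annotation, e.g. TF motif hit vectors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree
from sklearn.neighbors import NearestNeighbors

from .io import PeakCellMatrix, VariantSet

log = logging.getLogger(__name__)


@dataclass
class AnnotationWeights:
    """Non-negative per-peak weights for one annotation (e.g. one trait)."""

    weights: np.ndarray
    name: str = "annotation"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")

    @property
    def nonzero_peaks(self) -> np.ndarray:
        return np.nonzero(self.weights)[0]


@dataclass
class BackgroundSets:
    """Covariate-matched background peaks for a set of weighted peaks.

    ``peak_indices[i, b]`` is the background peak standing in for weighted
    peak ``weighted_peaks[i]`` in background set ``b``.  Backgrounds are drawn
    uniformly from each weighted peak's ``k_neighbors`` nearest peaks in
    standardized covariate space; self-matches are allowed.
    """

    weighted_peaks: np.ndarray
    peak_indices: np.ndarray  # (n_weighted, n_background)
    rng_seed: int
    k_neighbors: int

    @property
    def n_background(self) -> int:
        return self.peak_indices.shape[1]


@dataclass
class TraitScores:
    """Per-cell raw deviation and bias-corrected Z for one annotation.

    Cells with undefined scores (zero total counts, zero expectation, or zero
    background spread) carry NaN.
    """

    deviation: np.ndarray
    zscore: np.ndarray
    trait: str
    n_background: int
    rng_seed: int


def variant_peak_weights(variants: VariantSet, m: PeakCellMatrix,
                         name: str | None = None) -> AnnotationWeights:
    """Sum variant posterior probabilities over the peaks that contain them.

    Variant positions are 1-based and peaks half-open 0-based, so a variant at
    1-based position p lands in peak [start, end) iff start <= p-1 < end.
    Peaks with no overlapping variant get weight 0.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, group in m.peaks.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, i) for i, s, e in zip(group.index, group["start"], group["end"])
        )
    w = np.zeros(m.n_peaks)
    tab = variants.table
    for chrom, pos, pp in zip(tab["chrom"], tab["pos"], tab["pp"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree[int(pos) - 1]:
            w[iv.data] += float(pp)
    if w.sum() == 0:
        raise ValueError("no variant overlaps any peak")
    if name is None:
        traits = tab["trait"].unique()
        name = traits[0] if len(traits) == 1 else "+".join(map(str, traits))
    log.info("weights: %d/%d peaks carry variant mass (total %.4g)",
             int((w > 0).sum()), m.n_peaks, w.sum())
    return AnnotationWeights(weights=w, name=str(name))


def sample_background_peaks(m: PeakCellMatrix, weighted_peaks: np.ndarray,
                            n_background: int = 50, rng_seed: int = 0,
                            k_neighbors: int = 100) -> BackgroundSets:
    """Draw covariate-matched background peaks for each weighted peak.

    Covariate space is z-scored mean accessibility plus z-scored GC fraction
    when the peak table provides one.  Each background draw is uniform over a
    weighted peak's ``k_neighbors`` nearest peaks (self included).  When every
    peak has identical covariates the draws degenerate to uniform sampling
    over all peaks.
    """
    weighted_peaks = np.asarray(weighted_peaks, dtype=int)
    rng = np.random.default_rng(rng_seed)
    cols = [m.mean_accessibility()]
    if "gc_fraction" in m.peaks.columns:
        cols.append(m.peaks["gc_fraction"].to_numpy(float))
    cov = np.column_stack(cols)
    sd = cov.std(axis=0)
    informative = sd > 0
    if not informative.any():
        log.info("all peaks share identical covariates; background is uniform over peaks")
        draws = rng.integers(0, m.n_peaks, size=(len(weighted_peaks), n_background))
        return BackgroundSets(weighted_peaks=weighted_peaks, peak_indices=draws,
                              rng_seed=rng_seed, k_neighbors=m.n_peaks)
    cov = (cov[:, informative] - cov[:, informative].mean(axis=0)) / sd[informative]
    k = k_neighbors
    if k > m.n_peaks:
        k = m.n_peaks - 1
        log.warning("fewer peaks than background neighborhood size; using K=%d", k)
    nn = NearestNeighbors(n_neighbors=k).fit(cov)
    _, neighbors = nn.kneighbors(cov[weighted_peaks])
    choice = rng.integers(0, k, size=(len(weighted_peaks), n_background))
    draws = neighbors[np.arange(len(weighted_peaks))[:, None], choice]
    return BackgroundSets(weighted_peaks=weighted_peaks, peak_indices=draws,
                          rng_seed=rng_seed, k_neighbors=k)


def deviation_zscores(m: PeakCellMatrix, w: AnnotationWeights,
                      bg: BackgroundSets) -> TraitScores:
    """Bias-corrected deviation Z score per cell.

    Per cell j with weights w over peaks: observed o_j = sum_i w_i x_ij,
    expected e_j = sum_i w_i * row_sum_i * col_sum_j / total, raw deviation
    d_j = (o_j - e_j) / e_j.  The same deviation is computed for every
    background set (weights transplanted onto the matched background peaks)
    and z_j = (d_j - mean_b d_j^(b)) / sd_b d_j^(b).

    Raw deviations are invariant to scaling all weights by a positive
    constant.  Cells with zero expectation and backgrounds with zero spread
    yield NaN (with a warning), never an exception.
    """
    if not w.nonzero_peaks.size:
        raise ValueError("all weights are zero; deviations undefined")
    X = m.counts.astype(float)
    row_sum = np.asarray(X.sum(axis=1)).ravel()
    col_sum = np.asarray(X.sum(axis=0)).ravel()
    total = row_sum.sum()
    if total == 0:
        raise ValueError("count matrix is all zero")
    if (col_sum == 0).any():
        log.warning("%d cells have zero total counts; their scores are NaN",
                    int((col_sum == 0).sum()))

    def _deviation(weight_rows: sp.csr_matrix) -> np.ndarray:
        obs = (weight_rows @ X).toarray() if sp.issparse(weight_rows @ X) else weight_rows @ X
        obs = np.asarray(obs)
        exp = np.outer(weight_rows @ row_sum, col_sum) / total
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(exp > 0, (obs - exp) / exp, np.nan)

    w_real = sp.csr_matrix(w.weights[None, :])
    d = _deviation(w_real).ravel()

    n_w, n_b = bg.peak_indices.shape
    w_active = w.weights[bg.weighted_peaks]
    rows = np.repeat(np.arange(n_b), n_w)
    cols = bg.peak_indices.T.ravel()
    data = np.tile(w_active, n_b)
    w_bg = sp.csr_matrix((data, (rows, cols)), shape=(n_b, m.n_peaks))
    d_bg = _deviation(w_bg)  # (n_background, n_cells)

    mean_bg = d_bg.mean(axis=0)
    sd_bg = d_bg.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (d - mean_bg) / sd_bg
    z[~np.isfinite(z)] = np.nan
    if np.isnan(z).any():
        log.warning("%d cells have undefined Z (zero expectation or zero background spread)",
                    int(np.isnan(z).sum()))
    return TraitScores(deviation=d, zscore=z, trait=w.name,
                       n_background=n_b, rng_seed=bg.rng_seed)
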