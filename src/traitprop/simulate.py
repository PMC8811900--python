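"""Binomial single-cell simulator and self-contained synthetic fixtures.

Synthetic scATAC-seq cells are drawn by downsampling bulk peak profiles: the
count of peak i in a cell of type t is Binomial(2, p_it) with

    p_it = (n/2) * ((1 - q) * r_it + q / k),

where r_it is the bulk read ratio of peak i in cell type t (columns sum
to 1), k the number of peaks, n the target number of fragments per cell and
q in [0, 1] the noise level: q=0 reproduces the bulk profile, q=1 scatters n
fragments uniformly over the k peaks.  The expected total count per cell is
exactly n whenever no p_it needs capping at 1.  (A variant where the bulk
term is not scaled by n is available as ``printed_formula=True``; it yields
an expected total of 1 fragment at q=0 and is kept only for comparison.)

The module also fabricates multi-cell-type bulk profiles (disjoint
marker-peak blocks on a shared background) and trait variant sets
concentrated in one cell type's marker peaks, so the whole pipeline is
testable without any external data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import PeakCellMatrix, VariantSet
from .scoring import AnnotationWeights

log = logging.getLogger(__name__)


@dataclass
class BulkProfiles:
    """Peak x cell-type bulk read-ratio matrix; every column sums to 1."""

    ratios: np.ndarray  # (n_peaks, n_celltypes)
    celltypes: list[str]
    peaks: pd.DataFrame
    marker_blocks: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.ndim != 2 or self.ratios.shape[1] != len(self.celltypes):
            raise ValueError("ratios must be peaks x celltypes")
        if (self.ratios < 0).any():
            raise ValueError("bulk ratios must be non-negative")
        colsums = self.ratios.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-9:
            raise ValueError("every cell type's ratios must sum to 1")

    @property
    def n_peaks(self) -> int:
        return self.ratios.shape[0]

    def column(self, celltype: str) -> np.ndarray:
        return self.ratios[:, self.celltypes.index(celltype)]


@dataclass
class SimulationSpec:
    """Per-cell-type simulation settings: depth, noise, cell count, seed."""

    n_fragments: int = 10000
    noise: float = 0.3
    cells_per_type: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        if not (0.0 <= self.noise <= 1.0):
            raise ValueError("noise level q must lie in [0, 1]")
        if self.cells_per_type < 1:
            raise ValueError("cells_per_type must be >= 1")


def binomial_probabilities(bulk: BulkProfiles, celltype: str, n_fragments: int,
                           noise: float, printed_formula: bool = False) -> np.ndarray:
    """Per-peak success probability p_it of the Binomial(2, p_it) count model."""
    r = bulk.column(celltype)
    k = bulk.n_peaks
    if printed_formula:
        p = (1.0 - noise) * r / 2.0 + noise * n_fragments / (2.0 * k)
    else:
        p = (n_fragments / 2.0) * ((1.0 - noise) * r + noise / k)
    capped = int((p > 1.0).sum())
    if capped:
        log.warning("%d/%d peaks have p_it capped at 1 (n too large for this profile)",
                    capped, k)
    return np.clip(p, 0.0, 1.0)


def simulate_cells(bulk: BulkProfiles, celltype: str, spec: SimulationSpec,
                   printed_formula: bool = False) -> PeakCellMatrix:
    """Simulate one cell type's cells; barcodes are '<celltype>_<i>'."""
    if celltype not in bulk.celltypes:
        raise ValueError(f"unknown cell type {celltype!r}")
    p = binomial_probabilities(bulk, celltype, spec.n_fragments, spec.noise,
                               printed_formula=printed_formula)
    rng = np.random.default_rng(spec.rng_seed)
    counts = rng.binomial(2, p[:, None],
                          size=(bulk.n_peaks, spec.cells_per_type)).astype(np.int32)
    barcodes = [f"{celltype}_{i}" for i in range(spec.cells_per_type)]
    return PeakCellMatrix(counts=sp.csr_matrix(counts), peaks=bulk.peaks.copy(),
                          barcodes=barcodes)


def simulate_mixture(bulk: BulkProfiles, celltypes: list[str], spec: SimulationSpec,
                     printed_formula: bool = False) -> tuple[PeakCellMatrix, pd.Series]:
    """Simulate several cell types side by side; returns the matrix and true labels.

    Each cell type gets an independent RNG stream derived from
    ``spec.rng_seed`` so the mixture is reproducible regardless of order of
    materialization.
    """
    blocks, labels, barcodes = [], [], []
    for t, celltype in enumerate(celltypes):
        sub = SimulationSpec(n_fragments=spec.n_fragments, noise=spec.noise,
                             cells_per_type=spec.cells_per_type,
                             rng_seed=spec.rng_seed + 7919 * t)
        part = simulate_cells(bulk, celltype, sub, printed_formula=printed_formula)
        blocks.append(part.counts)
        labels.extend([celltype] * part.n_cells)
        barcodes.extend(part.barcodes)
    counts = sp.hstack(blocks, format="csr")
    m = PeakCellMatrix(counts=counts, peaks=bulk.peaks.copy(), barcodes=barcodes)
    return m, pd.Series(labels, index=barcodes, name="celltype")


def synth_bulk_profiles(n_peaks: int, celltypes: list[str], specificity: float = 0.3,
                        rng_seed: int = 0, markers_per_type: int | None = None,
                        ) -> BulkProfiles:
    """Fabricate bulk profiles with disjoint marker-peak blocks per cell type.

    A fraction ``specificity`` of each type's read mass sits uniformly on its
    own block of marker peaks; the rest is spread uniformly over the shared
    (non-marker) peaks.  ``specificity=0`` gives one uniform profile shared
    by all types; ``specificity=1`` gives fully disjoint supports.  Marker
    blocks default to ~n_peaks/(5 * n_types) peaks each.  Peak positions are
    synthetic 1 kb-spaced intervals; block membership is randomized with
    ``rng_seed``.
    """
    n_types = len(celltypes)
    if n_peaks < 10 * n_types:
        raise ValueError("need at least 10 peaks per cell type")
    if not (0.0 <= specificity <= 1.0):
        raise ValueError("specificity must lie in [0, 1]")
    if markers_per_type is None:
        markers_per_type = max(1, n_peaks // (5 * n_types))
    n_shared = n_peaks - markers_per_type * n_types
    if n_shared < 0 or (n_shared == 0 and specificity < 1.0):
        raise ValueError("marker blocks leave no shared peaks; shrink markers_per_type")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n_peaks)
    blocks = {
        t: np.sort(perm[i * markers_per_type:(i + 1) * markers_per_type])
        for i, t in enumerate(celltypes)
    }
    ratios = np.zeros((n_peaks, n_types))
    if specificity == 0.0:
        ratios[:] = 1.0 / n_peaks  # all types share one uniform profile
    else:
        shared = np.sort(perm[markers_per_type * n_types:])
        for i, t in enumerate(celltypes):
            ratios[blocks[t], i] = specificity / markers_per_type
            if n_shared:
                ratios[shared, i] = (1.0 - specificity) / n_shared
    starts = np.arange(n_peaks, dtype=int) * 1000
    peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500})
    return BulkProfiles(ratios=ratios, celltypes=list(celltypes), peaks=peaks,
                        marker_blocks=blocks)


def synth_trait_weights(bulk: BulkProfiles, target: str, n_variants: int = 20,
                        pp_range: tuple[float, float] = (0.1, 0.9), rng_seed: int = 0,
                        max_per_peak: int = 5, trait: str = "synthetic_trait",
                        ) -> tuple[VariantSet, AnnotationWeights]:
    """Place fine-mapped variants inside the target type's marker peaks.

    Variant positions are uniform within the chosen peaks, posterior
    probabilities uniform over ``pp_range``; at most ``max_per_peak``
    variants land in any one peak.  Returns both the variant table (for
    end-to-end I/O tests) and the implied per-peak weight vector (PP sums).
    """
    if bulk.marker_blocks is None or target not in bulk.marker_blocks:
        raise ValueError(f"no marker block recorded for cell type {target!r}")
    markers = bulk.marker_blocks[target]
    if n_variants > markers.size * max_per_peak:
        raise ValueError("n_variants exceeds marker-peak capacity")
    rng = np.random.default_rng(rng_seed)
    pool = np.repeat(markers, max_per_peak)
    peak_idx = np.sort(rng.choice(pool, size=n_variants, replace=False))
    starts = bulk.peaks["start"].to_numpy()[peak_idx]
    ends = bulk.peaks["end"].to_numpy()[peak_idx]
    # 1-based positions inside the half-open peak: start+1 .. end
    pos = rng.integers(starts + 1, ends + 1)
    lo, hi = pp_range
    pp = rng.uniform(lo, hi, size=n_variants) if hi > lo else np.full(n_variants, float(lo))
    table = pd.DataFrame({
        "chrom": bulk.peaks["chrom"].to_numpy()[peak_idx],
        "pos": pos,
        "id": [f"snp_{i:05d}" for i in range(n_variants)],
        "pp": pp,
        "trait": trait,
    })
    weights = np.zeros(bulk.n_peaks)
    np.add.at(weights, peak_idx, pp)
    return VariantSet(table=table), AnnotationWeights(weights=weights, name=trait)
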