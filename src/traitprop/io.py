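"""Readers/writers for the standard inputs and outputs, plus the sparsity report.

Formats handled here:

* peak-by-cell fragment counts: Matrix Market coordinate file (1-based on
  disk, 0-based in memory) together with a BED peak file (0-based half-open
  intervals) and a plain-text barcode list, one barcode per line;
* fine-mapped variant tables: TSV with columns ``chrom, pos, id, pp, trait``
  (positions 1-based, VCF convention);
* per-cell result tables: TSV, one row per barcode.

Peaks are unstranded and barcodes are opaque strings.  Optional BED columns 4
and 5 are interpreted as per-peak GC fraction and precomputed mean
accessibility, respectively.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ("chrom", "pos", "id", "pp", "trait")


@dataclass
class PeakCellMatrix:
    """Sparse fragment counts over peaks x cells with peak intervals and barcodes.

    ``counts`` has one row per peak and one column per cell/barcode.  ``peaks``
    is a DataFrame with at least ``chrom`` (str), ``start`` and ``end``
    (0-based half-open ints) and optionally ``gc_fraction`` and
    ``mean_accessibility`` covariate columns.
    """

    counts: sp.csr_matrix
    peaks: pd.DataFrame
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.peaks = self.peaks.reset_index(drop=True)
        self.barcodes = list(self.barcodes)
        n_peaks, n_cells = self.counts.shape
        if len(self.peaks) != n_peaks:
            raise ValueError(
                f"peak table has {len(self.peaks)} rows but counts matrix has {n_peaks}"
            )
        if len(self.barcodes) != n_cells:
            raise ValueError(
                f"barcode list has {len(self.barcodes)} entries but counts matrix has {n_cells} columns"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            dupes = pd.Index(self.barcodes)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate barcode(s): {dupes[:5]}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative count in matrix")
        starts = self.peaks["start"].to_numpy()
        ends = self.peaks["end"].to_numpy()
        bad = np.nonzero(starts >= ends)[0]
        if bad.size:
            raise ValueError(f"peak {bad[0]} has start >= end ({starts[bad[0]]} >= {ends[bad[0]]})")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def mean_accessibility(self) -> np.ndarray:
        """Per-peak mean count across cells (precomputed covariate if present)."""
        if "mean_accessibility" in self.peaks.columns:
            return self.peaks["mean_accessibility"].to_numpy(float)
        return np.asarray(self.counts.mean(axis=1)).ravel()


@dataclass
class VariantSet:
    """Fine-mapped variants: (chrom, pos [1-based], id, pp, trait) records."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"variant table missing column(s): {missing}")
        self.table = self.table.reset_index(drop=True)
        pp = self.table["pp"].to_numpy(float)
        if len(pp) and (np.nanmin(pp) < 0 or np.nanmax(pp) > 1):
            bad = int(np.nonzero((pp < 0) | (pp > 1))[0][0])
            raise ValueError(f"posterior probability outside [0, 1] at row {bad + 1}")
        key = self.table[["chrom", "pos", "id", "trait"]]
        if key.duplicated().any():
            bad = int(np.nonzero(key.duplicated().to_numpy())[0][0])
            raise ValueError(f"duplicate variant record at row {bad + 1}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SparsityReport:
    """Per-peak and per-cell fractions of zero entries.

    ``peak_sparsity[i]`` is the proportion of cells with no signal at peak i;
    ``cell_sparsity[j]`` the proportion of peaks with no signal in cell j.
    """

    peak_sparsity: np.ndarray
    cell_sparsity: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": ["peaks", "cells"],
                "mean_sparsity": [self.peak_sparsity.mean(), self.cell_sparsity.mean()],
                "median_sparsity": [
                    float(np.median(self.peak_sparsity)),
                    float(np.median(self.cell_sparsity)),
                ],
            }
        )


def _read_bed(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno} in {path}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno} in {path}: {exc}") from exc
            row = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) >= 4:
                try:
                    row["gc_fraction"] = float(fields[3])
                except ValueError:
                    pass  # conventional name column; covariates absent
            if len(fields) >= 5:
                try:
                    row["mean_accessibility"] = float(fields[4])
                except ValueError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)


def read_peak_cell_matrix(matrix_path, peaks_path, barcodes_path) -> PeakCellMatrix:
    """Load a Matrix Market + BED + barcode triplet into a :class:`PeakCellMatrix`.

    The three files must agree on dimensions: matrix rows == BED lines,
    matrix columns == barcode lines.
    """
    counts = sp.csr_matrix(mmread(matrix_path))
    if counts.nnz and counts.data.min() < 0:
        raise ValueError(f"negative count in {matrix_path}")
    peaks = _read_bed(Path(peaks_path))
    with open(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if counts.shape[0] != len(peaks):
        raise ValueError(
            f"dimension mismatch: {matrix_path} has {counts.shape[0]} rows "
            f"but {peaks_path} has {len(peaks)} peaks"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"dimension mismatch: {matrix_path} has {counts.shape[1]} columns "
            f"but {barcodes_path} has {len(barcodes)} barcodes"
        )
    m = PeakCellMatrix(counts=counts, peaks=peaks, barcodes=barcodes)
    log.info("read %d peaks x %d cells (%d nonzeros)", m.n_peaks, m.n_cells, m.counts.nnz)
    return m


def write_peak_cell_matrix(m: PeakCellMatrix, matrix_path, peaks_path, barcodes_path) -> None:
    """Write the MTX/BED/barcode triplet (inverse of :func:`read_peak_cell_matrix`)."""
    mmwrite(str(matrix_path), sp.coo_matrix(m.counts), field="integer")
    cols = ["chrom", "start", "end"]
    for extra in ("gc_fraction", "mean_accessibility"):
        if extra in m.peaks.columns:
            cols.append(extra)
    m.peaks[cols].to_csv(peaks_path, sep="\t", header=False, index=False)
    Path(barcodes_path).write_text("".join(b + "\n" for b in m.barcodes))


def read_variants(path, pp_threshold: float = 0.001) -> VariantSet:
    """Read a fine-mapped variant TSV, keeping records with pp strictly > threshold.

    The default threshold 0.001 retains variants with non-negligible causal
    posterior probability; the inequality is strict, so pp == threshold is
    dropped.
    """
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"variant table {path} missing column(s): {missing}")
    pp = pd.to_numeric(table["pp"], errors="coerce").to_numpy()
    bad = np.nonzero(np.isnan(pp) | (pp < 0) | (pp > 1))[0]
    if bad.size:
        raise ValueError(
            f"posterior probability outside [0, 1] at data row {bad[0] + 1} of {path}"
        )
    kept = table.loc[pp > pp_threshold].reset_index(drop=True)
    log.info("variants: %d read, %d retained at pp > %g", len(table), len(kept), pp_threshold)
    if kept.empty:
        log.warning("no variants pass pp > %g; returning empty set", pp_threshold)
    return VariantSet(table=kept)


def sparsity_report(m: PeakCellMatrix) -> SparsityReport:
    """Fraction of zero entries per peak and per cell.

    For an all-zero matrix both vectors are identically 1; both means equal
    the overall zero fraction of the matrix.
    """
    if m.n_peaks == 0 or m.n_cells == 0:
        raise ValueError("empty matrix")
    nz = m.counts.copy()
    nz.data = (nz.data != 0).astype(np.int64)
    nz_per_peak = np.asarray(nz.sum(axis=1)).ravel()
    nz_per_cell = np.asarray(nz.sum(axis=0)).ravel()
    return SparsityReport(
        peak_sparsity=1.0 - nz_per_peak / m.n_cells,
        cell_sparsity=1.0 - nz_per_cell / m.n_peaks,
    )


RESULT_COLUMNS = ("barcode", "zscore", "seed", "np_score", "trs", "empirical_p", "state")


def write_cell_results(scores: pd.DataFrame, path, n_cells: int | None = None) -> None:
    """Write the per-cell results table as TSV.

    ``scores`` must contain a ``barcode`` column; optional columns absent from
    the frame are simply omitted from the file.  Floats keep 8 significant
    digits so a read-back is lossless to at least 6.
    """
    if "barcode" not in scores.columns:
        raise ValueError("results table must have a 'barcode' column")
    if n_cells is not None and len(scores) != n_cells:
        raise ValueError(f"results table has {len(scores)} rows but matrix has {n_cells} barcodes")
    cols = [c for c in RESULT_COLUMNS if c in scores.columns]
    cols += [c for c in scores.columns if c not in cols]
    scores[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")
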