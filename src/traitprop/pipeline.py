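"""End-to-end orchestration: read -> score -> embed -> graph -> propagate -> call states.

``run_pipeline`` executes the full workflow from the three matrix files and a
variant table, writes a per-cell results TSV, a JSON run manifest (config,
versions, seeds, filtering and convergence diagnostics) and a log file, and
returns the results table.  Zero-count cells and zero-df peaks are dropped
once, up front, and recorded in the manifest; all downstream indices refer to
the filtered matrix.  Identical config + inputs reproduce byte-identical
outputs.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import __version__
from ._utils import stage_seed
from .config import RunConfig, validate_config
from .graph import build_mknn_graph, lsi_embed, tfidf_transform
from .io import (PeakCellMatrix, read_peak_cell_matrix, read_variants,
                 sparsity_report, write_cell_results)
from .propagation import compute_trs, random_walk, select_seeds
from .scoring import deviation_zscores, sample_background_peaks, variant_peak_weights
from .significance import classify_states, degree_matched_permutations, empirical_pvalues

log = logging.getLogger(__name__)


def filter_matrix(m: PeakCellMatrix) -> tuple[PeakCellMatrix, dict]:
    """Drop zero-count cells and zero-count peaks once, up front."""
    cell_tot = np.asarray(m.counts.sum(axis=0)).ravel()
    peak_tot = np.asarray(m.counts.sum(axis=1)).ravel()
    keep_cells = np.nonzero(cell_tot > 0)[0]
    keep_peaks = np.nonzero(peak_tot > 0)[0]
    info = {
        "cells_in": m.n_cells, "peaks_in": m.n_peaks,
        "cells_dropped": int(m.n_cells - keep_cells.size),
        "peaks_dropped": int(m.n_peaks - keep_peaks.size),
    }
    if info["cells_dropped"] or info["peaks_dropped"]:
        log.warning("dropped %d zero-count cells and %d zero-count peaks",
                    info["cells_dropped"], info["peaks_dropped"])
        m = PeakCellMatrix(
            counts=sp.csr_matrix(m.counts[keep_peaks][:, keep_cells]),
            peaks=m.peaks.iloc[keep_peaks],
            barcodes=[m.barcodes[j] for j in keep_cells],
        )
    return m, info


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full workflow described by ``config``; see module docstring."""
    validate_config(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("traitprop")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "read"
    try:
        m = read_peak_cell_matrix(config.matrix, config.peaks, config.barcodes)
        variants = read_variants(config.variants, pp_threshold=config.pp_threshold)
        m, filter_info = filter_matrix(m)
        validate_config(config, n_cells=m.n_cells, n_peaks=m.n_peaks)
        sparsity = sparsity_report(m)

        stage = "score"
        weights = variant_peak_weights(variants, m)
        bg = sample_background_peaks(m, weights.nonzero_peaks,
                                     n_background=config.n_background,
                                     rng_seed=stage_seed(config.seed, "background"),
                                     k_neighbors=config.bg_neighbors)
        scores = deviation_zscores(m, weights, bg)

        stage = "embed"
        weighted = tfidf_transform(m, tf_mode=config.tf_mode)
        embedding = lsi_embed(weighted, d=config.d,
                              svd_seed=stage_seed(config.seed, "svd"))
        stage = "graph"
        graph = build_mknn_graph(embedding, k=config.k,
                                 bridge_components=config.bridge_components)

        stage = "propagate"
        seeds = select_seeds(scores, p_threshold=config.p_threshold,
                             max_fraction=config.max_seed_fraction)
        result = random_walk(graph, seeds, gamma=config.gamma, alpha=config.alpha,
                             max_iter=config.max_iter)
        trs, factor = compute_trs(result.np_score, scores.zscore,
                                  percentile=config.percentile,
                                  top_fraction=config.top_fraction_for_scaling,
                                  scaling_mode=config.scaling_mode)

        is_seed = np.zeros(m.n_cells, dtype=int)
        is_seed[seeds.indices] = 1
        table = pd.DataFrame({
            "barcode": m.barcodes,
            "zscore": scores.zscore,
            "seed": is_seed,
            "np_score": result.np_score,
            "trs": trs,
        })

        perm_info: dict = {}
        if config.permutations:
            stage = "permutation"
            null = degree_matched_permutations(
                graph, seeds, B=config.B,
                rng_seed=stage_seed(config.seed, "permutation"),
                gamma=config.gamma, alpha=config.alpha, max_iter=config.max_iter,
                real_np=result.np_score)
            pvals = empirical_pvalues(result.np_score, null)
            calls = classify_states(pvals, alpha=config.state_alpha)
            table["empirical_p"] = pvals
            table["state"] = calls.state
            perm_info = {
                "B": config.B,
                "fallback_draws": null.n_fallback_draws,
                "enriched_cells": int(calls.enriched.sum()),
            }

        stage = "write"
        results_path = out_dir / "cell_results.tsv"
        written.append(results_path)
        write_cell_results(table, results_path, n_cells=m.n_cells)
        manifest = {
            "tool": "traitprop",
            "version": __version__,
            "config": config.to_dict(),
            "stage_seeds": {s: stage_seed(config.seed, s)
                            for s in ("background", "svd", "permutation")},
            "filtering": filter_info,
            "mean_peak_sparsity": float(sparsity.peak_sparsity.mean()),
            "mean_cell_sparsity": float(sparsity.cell_sparsity.mean()),
            "n_variants": len(variants),
            "n_weighted_peaks": int(weights.nonzero_peaks.size),
            "n_seed_cells": len(seeds),
            "seed_fallback_used": seeds.fallback_used,
            "graph": {
                "n_components": graph.n_components,
                "fallback_edges": len(graph.fallback_edges),
                "max_degree": int(graph.degrees.max()),
            },
            "propagation": {
                "iterations": result.iterations,
                "converged": result.converged,
                "scaling_factor": factor,
            },
            "permutation": perm_info,
        }
        manifest_path = out_dir / "manifest.json"
        written.append(manifest_path)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return table
    except Exception as exc:
        for path in written:  # remove partial outputs
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
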