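import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import traitprop as tp


@pytest.fixture(scope="session")
def two_type_dataset():
    """Small two-cell-type synthetic dataset shared across unit tests.

    2,000 peaks, 100 cells per type at 1,000 fragments and noise 0.3; trait
    variants sit in the target type's marker peaks.
    """
    bulk = tp.synth_bulk_profiles(2000, ["target", "other"], specificity=0.3, rng_seed=11)
    spec = tp.SimulationSpec(n_fragments=1000, noise=0.3, cells_per_type=100, rng_seed=11)
    m, labels = tp.simulate_mixture(bulk, ["target", "other"], spec)
    variants, weights = tp.synth_trait_weights(bulk, "target", n_variants=20, rng_seed=12)
    return {"bulk": bulk, "matrix": m, "labels": labels,
            "variants": variants, "weights": weights}


@pytest.fixture()
def tiny_matrix():
    """3 peaks x 2 cells with two nonzero entries; hand-checkable."""
    counts = sp.csr_matrix(np.array([[2, 0], [0, 0], [0, 1]]))
    peaks = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                          "start": [100, 300, 50], "end": [200, 400, 150]})
    return tp.PeakCellMatrix(counts=counts, peaks=peaks, barcodes=["cellA", "cellB"])


def write_matrix_files(m, tmp_path):
    paths = (tmp_path / "matrix.mtx", tmp_path / "peaks.bed", tmp_path / "barcodes.txt")
    tp.write_peak_cell_matrix(m, *paths)
    return paths


def random_embedding(n, d, seed):
    rng = np.random.default_rng(seed)
    return tp.LSIEmbedding(coords=rng.standard_normal((n, d)),
                           singular_values=np.linspace(d, 1, d, dtype=float))
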