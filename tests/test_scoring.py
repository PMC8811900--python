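"""Variant-to-peak weights, background matching and bias-corrected deviations."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import traitprop as tp


def _matrix(counts, starts=None, ends=None):
    counts = sp.csr_matrix(np.asarray(counts))
    n = counts.shape[0]
    if starts is None:
        starts = np.arange(n) * 1000
        ends = starts + 500
    peaks = pd.DataFrame({"chrom": "chr1", "start": starts, "end": ends})
    return tp.PeakCellMatrix(counts=counts, peaks=peaks,
                             barcodes=[f"c{j}" for j in range(counts.shape[1])])


def _variants(rows):
    return tp.VariantSet(table=pd.DataFrame(rows, columns=["chrom", "pos", "id", "pp", "trait"]))


class TestVariantPeakWeights:
    def test_variant_inside_half_open_peak(self):
        m = _matrix(np.ones((1, 2)), starts=[100], ends=[200])
        vs = _variants([("chr1", 150, "v1", 0.8, "t")])
        assert tp.variant_peak_weights(vs, m).weights.tolist() == [0.8]

    def test_position_at_peak_end_does_not_overlap(self):
        """1-based pos 200 is 0-based 199... no: 0-based 199 is inside [100,200).
        The boundary case is 1-based 201 -> 0-based 200, outside; and 1-based
        200 -> 0-based 199, the last covered base.  A peak [100, 200) therefore
        excludes a variant whose 0-based coordinate is 200."""
        m = _matrix(np.ones((1, 2)), starts=[100], ends=[200])
        inside = _variants([("chr1", 200, "v1", 0.5, "t")])  # 0-based 199
        assert tp.variant_peak_weights(inside, m).weights.tolist() == [0.5]
        outside = _variants([("chr1", 201, "v2", 0.5, "t")])  # 0-based 200
        with pytest.raises(ValueError, match="no variant overlaps"):
            tp.variant_peak_weights(outside, m)

    def test_multiple_variants_sum_their_pp(self):
        m = _matrix(np.ones((2, 2)), starts=[100, 300], ends=[200, 400])
        vs = _variants([("chr1", 120, "v1", 0.6, "t"), ("chr1", 180, "v2", 0.3, "t")])
        np.testing.assert_allclose(tp.variant_peak_weights(vs, m).weights, [0.9, 0.0])


class TestBackgroundPeaks:
    def test_identical_covariates_give_uniform_draws(self):
        m = _matrix(np.ones((300, 3)))
        bg = tp.sample_background_peaks(m, np.array([0]), n_background=2000, rng_seed=0)
        drawn = np.unique(bg.peak_indices)
        assert drawn.size > 250  # essentially uniform over all 300 peaks

    def test_fixed_seed_is_deterministic(self, two_type_dataset):
        m, w = two_type_dataset["matrix"], two_type_dataset["weights"]
        a = tp.sample_background_peaks(m, w.nonzero_peaks, rng_seed=42)
        b = tp.sample_background_peaks(m, w.nonzero_peaks, rng_seed=42)
        assert (a.peak_indices == b.peak_indices).all()

    def test_draws_come_from_covariate_nearest_neighbors(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.poisson(2.0, size=(400, 10)))
        # continuous precomputed accessibility covariate, tie-free, one extreme peak
        acc = rng.normal(2.0, 0.3, size=400)
        acc[0] = 50.0
        m.peaks["mean_accessibility"] = acc
        bg = tp.sample_background_peaks(m, np.array([0]), n_background=500, rng_seed=1)
        expected = set(np.argsort(np.abs(acc - acc[0]))[:100].tolist())
        assert set(bg.peak_indices.ravel().tolist()) <= expected

    def test_small_peak_set_shrinks_neighborhood(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.poisson(2.0, size=(20, 5)))
        bg = tp.sample_background_peaks(m, np.array([3]), k_neighbors=100, rng_seed=0)
        assert bg.k_neighbors == 19


class TestDeviationZscores:
    def _bg(self, m, w, seed=0, n_background=50):
        return tp.sample_background_peaks(m, w.nonzero_peaks, rng_seed=seed,
                                          n_background=n_background)

    def test_average_profile_has_zero_deviation(self):
        """When every cell matches the average profile, obs == exp exactly."""
        profile = np.array([3, 1, 2, 5], dtype=float)
        m = _matrix(np.tile(profile[:, None], (1, 6)))
        w = tp.AnnotationWeights(weights=np.array([1.0, 0.5, 0.0, 2.0]))
        scores = tp.deviation_zscores(m, w, self._bg(m, w))
        np.testing.assert_allclose(scores.deviation, 0.0, atol=1e-12)

    def test_two_by_two_hand_computation(self):
        """X=[[2,0],[0,2]], weight on peak 0: o=(2,0), e=(1,1), d=(1,-1)."""
        m = _matrix(np.array([[2, 0], [0, 2]]))
        w = tp.AnnotationWeights(weights=np.array([1.0, 0.0]))
        scores = tp.deviation_zscores(m, w, self._bg(m, w))
        np.testing.assert_allclose(scores.deviation, [1.0, -1.0])
        assert scores.deviation[0] > 0 > scores.deviation[1]

    def test_deviation_invariant_to_weight_scale(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.poisson(1.0, size=(50, 20)))
        w1 = tp.AnnotationWeights(weights=rng.uniform(0, 1, 50))
        w3 = tp.AnnotationWeights(weights=3.0 * w1.weights)
        bg = self._bg(m, w1)
        d1 = tp.deviation_zscores(m, w1, bg).deviation
        d3 = tp.deviation_zscores(m, w3, bg).deviation
        np.testing.assert_allclose(d1, d3, rtol=1e-12)

    def test_background_deviations_center_near_zero_on_exchangeable_data(self):
        rng = np.random.default_rng(7)
        m = _matrix(rng.poisson(2.0, size=(500, 40)))
        w = tp.AnnotationWeights(weights=(rng.uniform(size=500) < 0.05).astype(float))
        scores = tp.deviation_zscores(m, w, self._bg(m, w, n_background=100))
        # corrected z should be modest everywhere on null data
        assert np.nanmean(np.abs(scores.zscore)) < 2.0

    def test_recovers_target_cell_type(self, two_type_dataset):
        m, w = two_type_dataset["matrix"], two_type_dataset["weights"]
        labels = two_type_dataset["labels"].to_numpy()
        scores = tp.deviation_zscores(m, w, self._bg(m, w))
        assert (np.nanmean(scores.zscore[labels == "target"])
                > np.nanmean(scores.zscore[labels == "other"]))
        top_decile = np.argsort(-np.nan_to_num(scores.zscore, nan=-np.inf))[:m.n_cells // 10]
        assert (labels[top_decile] == "target").mean() > 0.8

    def test_determinism_bitwise(self, two_type_dataset):
        m, w = two_type_dataset["matrix"], two_type_dataset["weights"]
        s1 = tp.deviation_zscores(m, w, self._bg(m, w, seed=9))
        s2 = tp.deviation_zscores(m, w, self._bg(m, w, seed=9))
        assert np.array_equal(s1.zscore, s2.zscore)
        assert np.array_equal(s1.deviation, s2.deviation)

    def test_all_zero_weights_rejected(self):
        m = _matrix(np.ones((3, 3)))
        with pytest.raises(ValueError, match="non-negative|zero"):
            tp.deviation_zscores(
                m, tp.AnnotationWeights(weights=np.zeros(3)),
                tp.BackgroundSets(weighted_peaks=np.array([], dtype=int),
                                  peak_indices=np.empty((0, 5), dtype=int),
                                  rng_seed=0, k_neighbors=5))

    def test_zero_count_cell_gets_nan(self):
        counts = np.array([[2, 0], [1, 0]])
        m = _matrix(counts)
        w = tp.AnnotationWeights(weights=np.array([1.0, 0.0]))
        scores = tp.deviation_zscores(m, w, self._bg(m, w))
        assert np.isnan(scores.deviation[1]) and np.isnan(scores.zscore[1])
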