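"""Activation-map construction against brute-force Pearson oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from connfusion.connectome import (ConnectivityVector, ROITimeSeries,
                                   compute_connectivity_vector,
                                   compute_fingerprint,
                                   connectivity_matrix_from_vector,
                                   extract_roi_timeseries, n_pair_features,
                                   pearson)
from connfusion.dataio import ParcellationAtlas, Volume4D
from connfusion.errors import GeometryError, ValidationError


def brute_pearson(x, y):
    """Independent oracle: direct evaluation of the product-moment formula."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    return 0.0 if denom == 0 else float((xm * ym).sum() / denom)


class TestPearson:
    @pytest.mark.parametrize("x, y, expected", [
        ([1, 2, 3], [1, 2, 3], 1.0),            # self-correlation
        ([1, 2, 3], [3, 2, 1], -1.0),           # perfect anticorrelation
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),      # hand-computed value
        ([2, 2, 2], [1, 5, 9], 0.0),            # zero-variance convention
    ])
    def test_reference_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_contract_violations(self):
        with pytest.raises(ValidationError):
            pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            pearson([1], [2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.floats(0.01, 5.0), st.floats(-10, 10))
    def test_affine_invariance(self, xs, scale, shift):
        """Positive rescaling and constant shifts leave r unchanged."""
        rng = np.random.default_rng(42)
        y = rng.normal(size=len(xs))
        base = pearson(xs, y)
        assert pearson(np.asarray(xs) * scale + shift, y) == pytest.approx(
            base, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 20))
    def test_matches_brute_force(self, seed, length):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, length))
        assert pearson(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-12)


class TestROITimeSeries:
    def _atlas(self, labels):
        return ParcellationAtlas(labels=np.asarray(labels, dtype=np.int32))

    def test_constant_region_mean(self):
        vol = Volume4D(data=np.full((2, 1, 1, 4), 5.0))
        atlas = self._atlas([[[1]], [[2]]])
        roits = extract_roi_timeseries(vol, atlas)
        np.testing.assert_array_equal(roits.series[0], [5, 5, 5, 5])

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1, 2))
        data[0, 0, 0] = [1, 2]
        data[1, 0, 0] = [3, 4]
        # region 1 = both voxels, region 2 required elsewhere for validity
        data = np.concatenate([data, np.zeros((1, 1, 1, 2))], axis=0)
        atlas = self._atlas([[[1]], [[1]], [[2]]])
        roits = extract_roi_timeseries(Volume4D(data=data), atlas)
        np.testing.assert_allclose(roits.series[0], [2.0, 3.0])

    def test_single_voxel_region_identity(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 1, 1, 6))
        vol = Volume4D(data=data)
        roits = extract_roi_timeseries(vol, self._atlas([[[1]], [[2]]]))
        np.testing.assert_allclose(roits.series[1], data[1, 0, 0])

    def test_grid_mismatch_and_empty_region(self):
        vol = Volume4D(data=np.zeros((2, 2, 2, 3)))
        atlas = self._atlas(np.arange(1, 9).reshape(2, 2, 2))
        bad_vol = Volume4D(data=np.zeros((2, 2, 3, 3)))
        with pytest.raises(GeometryError):
            extract_roi_timeseries(bad_vol, atlas)


class TestFingerprint:
    def test_toy_volume_matches_exhaustive_oracle(self):
        """Every fingerprint entry equals a per-voxel brute-force Pearson."""
        rng = np.random.default_rng(1)
        data = rng.normal(size=(2, 1, 1, 5))
        vol = Volume4D(data=data)
        atlas = ParcellationAtlas(
            labels=np.array([[[1]], [[2]]], dtype=np.int32))
        roits = extract_roi_timeseries(vol, atlas)
        fp = compute_fingerprint(vol, roits)
        assert fp.corr.shape == (2, 1, 1, 2)
        for v in range(2):
            for n in range(2):
                expected = brute_pearson(data[v, 0, 0], roits.series[n])
                assert fp.corr[v, 0, 0, n] == pytest.approx(expected, abs=1e-6)

    def test_voxel_equal_to_roi_series_gives_unit_correlation(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(2, 1, 1, 8))
        vol = Volume4D(data=data)
        atlas = ParcellationAtlas(
            labels=np.array([[[1]], [[2]]], dtype=np.int32))
        roits = extract_roi_timeseries(vol, atlas)
        fp = compute_fingerprint(vol, roits)
        assert fp.corr[0, 0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert fp.corr[1, 0, 0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_refold_between_matrix_and_grid_preserves_values(self):
        rng = np.random.default_rng(3)
        vol = Volume4D(data=rng.normal(size=(3, 4, 2, 6)))
        labels = np.ones((3, 4, 2), dtype=np.int32)
        labels[2:] = 2
        roits = extract_roi_timeseries(vol, ParcellationAtlas(labels=labels))
        fp = compute_fingerprint(vol, roits)
        np.testing.assert_array_equal(
            fp.as_matrix().reshape(fp.corr.shape), fp.corr)

    def test_noise_free_parcellation_limit(self):
        """Voxels identical to their region mean correlate 1 with it."""
        rng = np.random.default_rng(4)
        latent = rng.normal(size=(2, 10))
        data = np.empty((4, 1, 1, 10))
        data[:2] = latent[0]
        data[2:] = latent[1]
        labels = np.array([[[1]], [[1]], [[2]], [[2]]], dtype=np.int32)
        vol = Volume4D(data=data)
        roits = extract_roi_timeseries(vol, ParcellationAtlas(labels=labels))
        fp = compute_fingerprint(vol, roits)
        region_of = [0, 0, 1, 1]
        for v in range(4):
            assert fp.corr[v, 0, 0, region_of[v]] == pytest.approx(1.0, abs=1e-6)

    def test_frame_mismatch(self):
        vol = Volume4D(data=np.zeros((2, 1, 1, 5)))
        roits = ROITimeSeries(series=np.random.default_rng(0).normal(size=(2, 4)),
                              region_ids=[1, 2])
        with pytest.raises(ValidationError):
            compute_fingerprint(vol, roits)


class TestConnectivityVector:
    def test_full_scale_feature_count(self):
        assert n_pair_features(116) == 6670

    def test_three_region_ordering(self):
        rng = np.random.default_rng(5)
        roits = ROITimeSeries(series=rng.normal(size=(3, 7)),
                              region_ids=[1, 2, 3])
        vec = compute_connectivity_vector(roits)
        assert len(vec) == 3
        expected = [brute_pearson(roits.series[i], roits.series[j])
                    for i, j in [(0, 1), (0, 2), (1, 2)]]
        np.testing.assert_allclose(vec.values, expected, atol=1e-12)

    def test_requires_two_regions(self):
        roits = ROITimeSeries(series=np.random.default_rng(0).normal(size=(2, 5)),
                              region_ids=[1, 2])
        with pytest.raises(ValidationError):
            compute_connectivity_vector(
                ROITimeSeries(series=roits.series[:1], region_ids=[1]))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 8), st.integers(3, 15))
    def test_reconstructed_matrix_matches_pairwise_oracle(self, seed, n, t):
        """Vector + unit diagonal rebuilds a symmetric matrix equal to the
        exhaustive pairwise-Pearson matrix to 1e-10."""
        rng = np.random.default_rng(seed)
        roits = ROITimeSeries(series=rng.normal(size=(n, t)),
                              region_ids=list(range(1, n + 1)))
        vec = compute_connectivity_vector(roits)
        assert len(vec) == n_pair_features(n)
        mat = connectivity_matrix_from_vector(vec, n)
        np.testing.assert_array_equal(mat, mat.T)
        oracle = np.array([[brute_pearson(roits.series[i], roits.series[j])
                            for j in range(n)] for i in range(n)])
        np.fill_diagonal(oracle, 1.0)
        assert np.abs(mat - oracle).max() <= 1e-10
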