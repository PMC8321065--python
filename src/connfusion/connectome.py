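"""Construction of the two connectomic activation maps.

From a 4D BOLD volume and a parcellation atlas this module derives

* the ROI mean time series (one averaged BOLD trace per region),
* the voxel-to-ROI connectivity *fingerprint* — for every voxel, its
  Pearson correlation with each region's mean trace, stored re-folded to
  the spatial grid as an (H, W, D, N) volume so a 3D network can consume
  it with the N regions as input channels, and
* the ROI-to-ROI *connectivity vector* — the strict upper triangle of the
  N x N inter-regional correlation matrix, row-major over pairs (i, j)
  with i < j in ascending-label order, length N(N-1)/2 (6670 for the
  116-region AAL atlas).

Correlations are raw Pearson coefficients (no Fisher z-transform).  A
series with zero variance (e.g. background voxels) correlates 0 with
everything by convention, never NaN, so downstream networks stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ParcellationAtlas, Volume4D
from .errors import GeometryError, ValidationError


@dataclass
class ROITimeSeries:
    """(N regions x T frames) matrix of region-averaged BOLD signals."""

    series: np.ndarray
    region_ids: list[int]

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=np.float64)
        if self.series.ndim != 2:
            raise ValidationError("ROITimeSeries requires a 2D (N,T) matrix")
        if self.series.shape[0] != len(self.region_ids):
            raise ValidationError("one series row per region id required")
        if not np.isfinite(self.series).all():
            raise ValidationError("ROITimeSeries contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_frames(self) -> int:
        return self.series.shape[1]


@dataclass
class FingerprintMap:
    """(H, W, D, N) voxel-by-region correlation volume."""

    corr: np.ndarray
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.corr = np.asarray(self.corr)
        if self.corr.ndim != 4:
            raise ValidationError("FingerprintMap requires 4 axes (H,W,D,N)")
        if np.abs(self.corr).max(initial=0.0) > 1.0 + 1e-6:
            raise ValidationError("correlations must lie in [-1, 1]")

    def as_matrix(self) -> np.ndarray:
        """Flatten to the (H*W*D, N) layout (C-order voxel linearisation)."""
        return self.corr.reshape(-1, self.corr.shape[3])


@dataclass
class ConnectivityVector:
    """Strict upper triangle of the ROI correlation matrix, row-major."""

    values: np.ndarray
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValidationError("ConnectivityVector must be 1D")
        if self.values.size and np.abs(self.values).max() > 1.0 + 1e-6:
            raise ValidationError("correlations must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.values.size


def n_pair_features(n_regions: int) -> int:
    """Number of unordered region pairs, N(N-1)/2."""
    return n_regions * (n_regions - 1) // 2


def extract_roi_timeseries(volume: Volume4D, atlas: ParcellationAtlas) -> ROITimeSeries:
    """Average the BOLD signal over each region's voxels, per frame."""
    if tuple(volume.grid) != tuple(atlas.grid):
        raise GeometryError(
            f"volume grid {volume.grid} != atlas grid {atlas.grid}"
        )
    flat_labels = atlas.labels.reshape(-1)
    flat = volume.data.reshape(-1, volume.n_frames)
    rows = np.empty((atlas.n_regions, volume.n_frames), dtype=np.float64)
    for i, rid in enumerate(atlas.region_ids):
        mask = flat_labels == rid
        if not mask.any():
            raise ValidationError(f"region {rid} has zero voxels")
        rows[i] = flat[mask].mean(axis=0)
    return ROITimeSeries(series=rows, region_ids=list(atlas.region_ids))


def _standardize(rows: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; zero-variance rows become all-zero,
    which makes their correlation with anything exactly 0."""
    rows = np.asarray(rows, dtype=np.float64)
    centered = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    return centered / safe


def pearson(x, y) -> float:
    """Product-moment correlation with the zero-variance-maps-to-0 rule."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1:
        raise ValidationError("pearson expects 1D series")
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise ValidationError("pearson requires series of length >= 2")
    zx = _standardize(x[None, :])[0]
    zy = _standardize(y[None, :])[0]
    r = float(np.dot(zx, zy))
    return float(np.clip(r, -1.0, 1.0))


def compute_fingerprint(volume: Volume4D, roits: ROITimeSeries) -> FingerprintMap:
    """Correlate every voxel's series with every region's mean series.

    Internally works on the (H*W*D, T) unfold of the scan (C-order voxel
    linearisation); the result is returned folded back to (H, W, D, N).
    """
    if volume.n_frames != roits.n_frames:
        raise ValidationError(
            f"frame count mismatch: volume T={volume.n_frames}, "
            f"series T={roits.n_frames}"
        )
    H, W, D = volume.grid
    vox = _standardize(volume.data.reshape(-1, volume.n_frames))
    roi = _standardize(roits.series)
    corr = np.clip(vox @ roi.T, -1.0, 1.0)
    return FingerprintMap(
        corr=corr.reshape(H, W, D, roits.n_regions),
        region_ids=list(roits.region_ids),
    )


def compute_connectivity_vector(roits: ROITimeSeries) -> ConnectivityVector:
    """Upper-triangle (i < j, row-major) inter-regional Pearson correlations."""
    n = roits.n_regions
    if n < 2:
        raise ValidationError("connectivity vector requires >= 2 regions")
    z = _standardize(roits.series)
    full = np.clip(z @ z.T, -1.0, 1.0)
    iu = np.triu_indices(n, k=1)
    return ConnectivityVector(values=full[iu], region_ids=list(roits.region_ids))


def connectivity_matrix_from_vector(vec: ConnectivityVector, n_regions: int) -> np.ndarray:
    """Rebuild the symmetric N x N correlation matrix (unit diagonal)."""
    expected = n_pair_features(n_regions)
    if len(vec) != expected:
        raise ValidationError(
            f"vector length {len(vec)} != N(N-1)/2 = {expected} for N={n_regions}"
        )
    mat = np.eye(n_regions)
    iu = np.triu_indices(n_regions, k=1)
    mat[iu] = vec.values
    mat[(iu[1], iu[0])] = vec.values
    return mat
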