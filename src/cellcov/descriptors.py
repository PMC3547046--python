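"""Per-pixel feature mappings and region (normalised) covariance descriptors.

A feature mapping Phi assigns each pixel of the averaged image a
d-dimensional attribute vector; the descriptor of a subwindow R with n
pixels is the sample covariance of those vectors,

    C_R = 1/(n-1) * sum_k (z_k - mu_R)(z_k - mu_R)^T,

a symmetric positive semidefinite d x d matrix.  Four mappings are
provided:

* ``F1``/``F2``/``F3`` (d = 15): intensity, the six level-2 complex wavelet
  magnitudes, and the eight directional score planes using the median, max
  and mean aggregator respectively;
* ``F4`` (d = 5): the classical mapping — intensity and the absolute first
  and second central-difference derivatives along each axis.

Pixel coordinates are deliberately not part of any mapping: subwindows are
drawn from arbitrary positions, so absolute position carries no class
information here.

The normalised variant divides each off-diagonal entry by the product of
the corresponding standard deviations (a correlation), which removes
per-feature scale — e.g. global contrast changes — while the diagonal
keeps the raw variances so that the variance-only ablation remains
meaningful.  For the SVM, descriptors are flattened to their upper
triangle, d(d+1)/2 values (120 for d = 15, 15 for d = 5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate1d

from .io import ContractError, DegenerateInputError, ValidationError
from .dtcwt import AverageImage, MagnitudeStack
from .directional import DirectionalScoreStack
from .sampling import Subwindow

__all__ = [
    "MAPPINGS",
    "FeatureMap",
    "CovarianceDescriptor",
    "DescriptorVector",
    "build_feature_map",
    "sample_covariance",
    "region_covariance",
    "normalize_covariance",
    "vectorize_descriptor",
    "matrix_from_vector",
    "diagonal_only",
]

MAPPINGS = ("F1", "F2", "F3", "F4")

_VARIANCE_EPS = 1e-12


@dataclass(frozen=True)
class FeatureMap:
    """d feature planes aligned on the averaged-image grid."""

    planes: np.ndarray              # (d, H, W)
    mapping_id: str

    @property
    def d(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


@dataclass(frozen=True)
class CovarianceDescriptor:
    matrix: np.ndarray              # (d, d) symmetric
    normalized: bool
    window: Subwindow | None = None

    @property
    def d(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class DescriptorVector:
    values: np.ndarray              # d(d+1)/2 or d (diagonal-only)
    mapping_id: str
    normalized: bool


def build_feature_map(
    avg,
    mags: MagnitudeStack | None = None,
    scores_median: DirectionalScoreStack | None = None,
    scores_max: DirectionalScoreStack | None = None,
    scores_mean: DirectionalScoreStack | None = None,
    mapping: str = "F1",
) -> FeatureMap:
    """Assemble the per-pixel feature planes for one mapping.

    Plane order is fixed: ``[intensity, |w_15..w_-15|, S_0..S_315]`` for
    F1-F3 (scores from the median/max/mean stack respectively), and
    ``[intensity, |dI/dcol|, |dI/drow|, |d2I/dcol2|, |d2I/drow2|]`` for F4.
    """
    if mapping not in MAPPINGS:
        raise ValidationError(f"unknown mapping {mapping!r}")
    x = avg.pixels if isinstance(avg, AverageImage) else np.asarray(avg, dtype=float)

    if mapping == "F4":
        d1 = np.array([0.5, 0.0, -0.5])    # central difference
        d2 = np.array([1.0, -2.0, 1.0])
        planes = np.stack([
            x,
            np.abs(correlate1d(x, d1, axis=1, mode="reflect")),
            np.abs(correlate1d(x, d1, axis=0, mode="reflect")),
            np.abs(correlate1d(x, d2, axis=1, mode="reflect")),
            np.abs(correlate1d(x, d2, axis=0, mode="reflect")),
        ])
        return FeatureMap(planes, "F4")

    scores = {"F1": scores_median, "F2": scores_max, "F3": scores_mean}[mapping]
    if mags is None or scores is None:
        raise ValidationError(f"mapping {mapping} needs magnitudes and a score stack")
    if mags.shape != x.shape or scores.shape != x.shape:
        raise ValidationError(
            f"misaligned feature planes: avg {x.shape}, magnitudes {mags.shape}, "
            f"scores {scores.shape}"
        )
    planes = np.concatenate([x[None], mags.magnitudes, scores.scores])
    return FeatureMap(planes, mapping)


def sample_covariance(vectors: np.ndarray) -> np.ndarray:
    """Sample covariance (divisor n-1) of column vectors, shape (d, n)."""
    z = np.asarray(vectors, dtype=float)
    n = z.shape[1]
    if n < 2:
        raise DegenerateInputError("covariance needs at least 2 samples")
    zc = z - z.mean(axis=1, keepdims=True)
    C = (zc @ zc.T) / (n - 1)
    return 0.5 * (C + C.T)                             # kill rounding asymmetry


def region_covariance(fm: FeatureMap, window: Subwindow) -> CovarianceDescriptor:
    """Covariance descriptor of the feature vectors inside one subwindow."""
    H, W = fm.shape
    if window.row0 < 0 or window.col0 < 0 or \
            window.row0 + window.size > H or window.col0 + window.size > W:
        raise ValidationError(f"window {window} outside feature map {H}x{W}")
    rs, cs = window.slices()
    z = fm.planes[:, rs, cs].reshape(fm.d, window.size * window.size)
    return CovarianceDescriptor(sample_covariance(z), normalized=False, window=window)


def normalize_covariance(cd: CovarianceDescriptor) -> CovarianceDescriptor:
    """Correlation-normalise the off-diagonal; keep raw variances on the diagonal.

    Entries whose row or column variance is below 1e-12 are set to 0 rather
    than divided — a feature that is constant in the window carries no
    correlation information.
    """
    if cd.normalized:
        raise ValidationError("descriptor is already normalised")
    C = cd.matrix
    v = np.diag(C).copy()
    s = np.sqrt(np.where(v > _VARIANCE_EPS, v, 1.0))
    M = C / np.outer(s, s)
    bad = v <= _VARIANCE_EPS
    M[bad, :] = 0.0
    M[:, bad] = 0.0
    np.fill_diagonal(M, v)
    return CovarianceDescriptor(M, normalized=True, window=cd.window)


def vectorize_descriptor(cd: CovarianceDescriptor) -> DescriptorVector:
    """Upper triangle (diagonal included) in row-major order: d(d+1)/2 values."""
    M = cd.matrix
    if not np.allclose(M, M.T, atol=1e-9):
        raise ContractError("descriptor matrix is not symmetric")
    iu = np.triu_indices(cd.d)
    return DescriptorVector(M[iu].copy(), mapping_id="", normalized=cd.normalized)


def matrix_from_vector(values: np.ndarray, d: int) -> np.ndarray:
    """Inverse of :func:`vectorize_descriptor` (round-trip helper)."""
    values = np.asarray(values, dtype=float)
    if len(values) != d * (d + 1) // 2:
        raise ContractError(f"expected {d*(d+1)//2} values for d={d}, got {len(values)}")
    M = np.zeros((d, d))
    iu = np.triu_indices(d)
    M[iu] = values
    M = M + np.triu(M, 1).T
    return M


def diagonal_only(cd: CovarianceDescriptor) -> DescriptorVector:
    """The d variances alone — the ablation that drops all cross-feature terms."""
    return DescriptorVector(np.diag(cd.matrix).copy(), mapping_id="", normalized=cd.normalized)
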