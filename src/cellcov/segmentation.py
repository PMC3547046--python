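"""Foreground/background separation.

Brightfield cell-line images have a bright, nearly uniform background and
textured cellular foreground whose intensities scatter both above and
below the background level, so a single threshold cannot separate them.
Instead the pixel-intensity histogram is modelled as a two-component
Gaussian mixture fitted by EM; the component with the larger variance is
the foreground.  The resulting binary mask is cleaned with a morphological
closing followed by a median filter, and kernel sizes can be picked
automatically by an intra-region uniformity / inter-region contrast score.

The EM here is the plain one-dimensional two-component algorithm, written
out so the per-iteration log-likelihood trajectory is available to callers
(monotonicity is an advertised contract).  Initialisation is deterministic
— a split at the intensity median with equal weights — so a seed only
matters when very large images are subsampled for fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.morphology import closing as _morph_closing

from .io import ConfigError, DegenerateInputError, GrayImage, ValidationError

__all__ = [
    "GMMParams",
    "ForegroundMask",
    "fit_two_gaussian_em",
    "segment_foreground",
    "refine_mask",
    "select_kernels",
    "downsample_mask",
]

_VAR_FLOOR = 1e-8
_SUBSAMPLE_LIMIT = 1_000_000


@dataclass(frozen=True)
class GMMParams:
    """Two-component Gaussian mixture over pixel intensities."""

    weights: np.ndarray      # (2,), sums to 1
    means: np.ndarray        # (2,)
    variances: np.ndarray    # (2,), floored at 1e-8
    log_likelihood: float
    n_iterations: int
    trajectory: tuple[float, ...] = ()   # log-likelihood after each iteration


@dataclass(frozen=True)
class ForegroundMask:
    mask: np.ndarray         # 2-D bool

    @property
    def foreground_fraction(self) -> float:
        return float(self.mask.mean())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)


def _log_gauss(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mu) ** 2 / var)


def fit_two_gaussian_em(
    img,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> GMMParams:
    """Fit the two-Gaussian intensity mixture by EM.

    Initialised by splitting the sample at its median (equal weights);
    images above 10^6 pixels are subsampled to 10^6 pixels for fitting,
    which is the only use of ``seed``.  Iterates until the log-likelihood
    improves by less than ``tol`` (per sample point) or ``max_iter``.
    """
    x = _pixels(img).ravel()
    if np.unique(x).size < 2:
        raise DegenerateInputError("image has fewer than 2 distinct intensities")
    if x.size > _SUBSAMPLE_LIMIT:
        rng = np.random.default_rng(seed)
        x = rng.choice(x, size=_SUBSAMPLE_LIMIT, replace=False)

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:       # median equals max: fall back to a strict split
        lo, hi = x[x < med], x[x >= med]
    means = np.array([lo.mean(), hi.mean()])
    variances = np.maximum(np.array([lo.var(), hi.var()]), _VAR_FLOOR)
    weights = np.array([0.5, 0.5])

    n = x.size
    ll_prev = -np.inf
    traj: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # E step (log-domain responsibilities)
        logp = np.stack([
            np.log(weights[0]) + _log_gauss(x, means[0], variances[0]),
            np.log(weights[1]) + _log_gauss(x, means[1], variances[1]),
        ])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum() / n)
        resp = np.exp(logp - lse)
        # M step
        nk = resp.sum(axis=1)
        weights = nk / n
        means = (resp @ x) / nk
        variances = np.maximum(
            (resp @ (x * x)) / nk - means ** 2, _VAR_FLOOR
        )
        traj.append(ll)
        if ll - ll_prev < tol and it > 1:
            break
        ll_prev = ll
    return GMMParams(weights, means, variances, traj[-1], it, tuple(traj))


def segment_foreground(img, gmm: GMMParams) -> ForegroundMask:
    """Assign each pixel to its maximum-posterior component; the
    larger-variance component is the foreground (ties: component 0 is
    background).  Swapping the component order leaves the mask unchanged."""
    x = _pixels(img)
    logp0 = np.log(gmm.weights[0]) + _log_gauss(x, gmm.means[0], gmm.variances[0])
    logp1 = np.log(gmm.weights[1]) + _log_gauss(x, gmm.means[1], gmm.variances[1])
    comp1 = logp1 > logp0
    fg_comp = 1 if gmm.variances[1] >= gmm.variances[0] else 0
    mask = comp1 if fg_comp == 1 else ~comp1
    return ForegroundMask(mask)


def refine_mask(mask: ForegroundMask, closing_k: int = 5, median_k: int = 9) -> ForegroundMask:
    """Binary closing (square element) then median filtering.

    Closing bridges sub-kernel gaps between cell fragments; the median
    filter removes isolated speckle in both classes.  Kernels must be odd.
    """
    for name, k in (("closing_k", closing_k), ("median_k", median_k)):
        if k < 1 or k % 2 == 0:
            raise ConfigError(f"{name} must be an odd integer >= 1, got {k}")
    m = np.asarray(mask.mask, dtype=bool)
    if closing_k > 1:
        m = _morph_closing(m, footprint=np.ones((closing_k, closing_k), dtype=bool))
    if median_k > 1:
        m = median_filter(m.astype(np.uint8), size=median_k, mode="reflect") > 0
    return ForegroundMask(m)


def _segmentation_score(img: np.ndarray, mask: np.ndarray, lam: float = 1.0) -> float:
    """Inter-region contrast minus intra-region non-uniformity.

    contrast = |mean_fg - mean_bg| / pooled std;
    penalty  = pixel-weighted within-region variance / total variance.
    Larger is better.  Requires both regions non-empty.
    """
    fg, bg = img[mask], img[~mask]
    n_fg, n_bg = fg.size, bg.size
    v_fg, v_bg = fg.var(), bg.var()
    pooled = np.sqrt((n_fg * v_fg + n_bg * v_bg) / (n_fg + n_bg))
    contrast = abs(fg.mean() - bg.mean()) / max(pooled, 1e-12)
    total_var = img.var()
    penalty = (n_fg * v_fg + n_bg * v_bg) / ((n_fg + n_bg) * max(total_var, 1e-12))
    return contrast - lam * penalty


def select_kernels(
    img,
    candidates: list[tuple[int, int]],
    gmm: GMMParams | None = None,
) -> tuple[int, int]:
    """Pick (closing_k, median_k) maximising the segmentation score.

    Each candidate refines the raw EM mask and is scored on the full-
    resolution image; candidates yielding an empty foreground or
    background are skipped.  Ties keep the earliest candidate.
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    x = _pixels(img)
    if gmm is None:
        gmm = fit_two_gaussian_em(x)
    raw = segment_foreground(x, gmm)
    best: tuple[int, int] | None = None
    best_score = -np.inf
    for ck, mk in candidates:
        m = refine_mask(raw, ck, mk).mask
        if not m.any() or m.all():
            continue
        score = _segmentation_score(x, m)
        if score > best_score:
            best, best_score = (ck, mk), score
    if best is None:
        raise ValidationError("every candidate produced an empty region")
    return best


def downsample_mask(mask: ForegroundMask, factor: int = 4) -> np.ndarray:
    """Reduce a full-resolution mask to the averaged-image grid by a >= 50%
    vote over each factor x factor block (trailing partial blocks dropped)."""
    m = np.asarray(mask.mask, dtype=float)
    H, W = (m.shape[0] // factor) * factor, (m.shape[1] // factor) * factor
    blocks = m[:H, :W].reshape(H // factor, factor, W // factor, factor)
    return blocks.mean(axis=(1, 3)) >= 0.5
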