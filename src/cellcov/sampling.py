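"""Constrained random subwindow selection.

Cell-line micrographs are mostly background, so descriptor windows are
drawn at random but kept only if they are (a) mostly foreground — more
than 50% of their pixels inside the segmentation mask — and (b) textured —
their intensity variance exceeds the variance of the whole image they come
from.  Both constraints are evaluated on the quarter-resolution averaged
image, which is the raster actually being classified.

Proposals are uniform over all admissible top-left corners; windows may
overlap.  Rejection sampling with a seeded generator makes the draw
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SamplingExhaustedError, ValidationError
from .dtcwt import AverageImage

__all__ = ["Subwindow", "SubwindowSet", "propose_topleft", "sample_subwindows"]

_PROPOSAL_BATCH = 512


@dataclass(frozen=True)
class Subwindow:
    """Half-open square window [row0, row0+size) x [col0, col0+size) on the
    averaged-image grid."""

    row0: int
    col0: int
    size: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.size),
                slice(self.col0, self.col0 + self.size))


@dataclass(frozen=True)
class SubwindowSet:
    windows: tuple[Subwindow, ...]
    image_id: str
    seed: int


def propose_topleft(rng: np.random.Generator, n: int, H: int, W: int, M: int):
    """Uniform top-left proposals for M x M windows on an H x W grid."""
    return rng.integers(0, H - M + 1, size=n), rng.integers(0, W - M + 1, size=n)


def sample_subwindows(
    avg,
    mask: np.ndarray,
    M: int,
    N: int,
    seed: int,
    max_attempts: int | None = None,
    image_id: str = "",
) -> SubwindowSet:
    """Draw N admissible M x M subwindows by rejection sampling.

    Parameters
    ----------
    avg
        ``AverageImage`` (or bare 2-D array): the raster whose variance
        defines the texture threshold.
    mask
        Boolean foreground mask on the same grid.
    M, N
        Window side and number of windows.
    seed
        Seeds the proposal stream; identical seeds give identical windows.
    max_attempts
        Proposal budget before giving up (default ``10_000 * N``).

    Raises
    ------
    SamplingExhaustedError
        If fewer than N windows are accepted within the budget; the error
        carries the observed acceptance rate.
    """
    x = avg.pixels if isinstance(avg, AverageImage) else np.asarray(avg, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValidationError(f"mask shape {mask.shape} != image shape {x.shape}")
    H, W = x.shape
    if M > min(H, W):
        raise ValidationError(f"window size {M} exceeds grid {H}x{W}")
    if N < 1:
        raise ValidationError("N must be >= 1")
    if max_attempts is None:
        max_attempts = 10_000 * N

    var_threshold = float(np.var(x))
    area = float(M * M)

    # integral images make each proposal O(1)
    isum = np.zeros((H + 1, W + 1))
    isum[1:, 1:] = np.cumsum(np.cumsum(x, 0), 1)
    isum2 = np.zeros((H + 1, W + 1))
    isum2[1:, 1:] = np.cumsum(np.cumsum(x * x, 0), 1)
    msum = np.zeros((H + 1, W + 1))
    msum[1:, 1:] = np.cumsum(np.cumsum(mask.astype(float), 0), 1)

    def boxsum(tab, r, c):
        return tab[r + M, c + M] - tab[r, c + M] - tab[r + M, c] + tab[r, c]

    rng = np.random.default_rng(seed)
    accepted: list[Subwindow] = []
    attempts = 0
    while len(accepted) < N and attempts < max_attempts:
        n_prop = min(_PROPOSAL_BATCH, max_attempts - attempts)
        rows, cols = propose_topleft(rng, n_prop, H, W, M)
        attempts += n_prop
        for r, c in zip(rows, cols):
            fg_frac = boxsum(msum, r, c) / area
            if fg_frac <= 0.5:
                continue
            s1 = boxsum(isum, r, c)
            s2 = boxsum(isum2, r, c)
            win_var = s2 / area - (s1 / area) ** 2
            if win_var <= var_threshold:
                continue
            accepted.append(Subwindow(int(r), int(c), M))
            if len(accepted) == N:
                break
    if len(accepted) < N:
        rate = len(accepted) / max(attempts, 1)
        raise SamplingExhaustedError(
            f"accepted only {len(accepted)}/{N} windows after {attempts} proposals "
            f"(acceptance rate {rate:.2e}) on image {image_id!r}",
            acceptance_rate=rate,
        )
    return SubwindowSet(tuple(accepted), image_id, seed)
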