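"""Synthetic oriented-texture micrograph generator.

Produces class-separable images that emulate the structure the pipeline is
built for: a bright, nearly flat background; darker cellular foreground
blobs (round "epithelioid" discs or elongated "fibroblastoid" bars); and
oriented texture inside the foreground.  Orientation is the primary class
signal by design — it exercises exactly the discriminative mechanism the
oriented wavelet magnitudes and directional scores are meant to capture.

Each class's texture combines a high-frequency component (tuned to the
level-2 wavelet bands of the full-resolution image) and a low-frequency
component (which survives the 4x averaging and drives the directional
scores).  Three texture styles exist:

* ``single`` — every blob carries texture at the class orientation;
* ``plaid``  — half the blobs (chosen per blob) carry both the class
  orientation and its orthogonal complement superimposed, the other half
  are smooth (low-contrast cells);
* ``mixed``  — every blob carries exactly one of the two orthogonal
  orientations, chosen at random per blob;
* ``isotropic`` — ring-spectrum noise with no preferred orientation (for
  control datasets whose classes differ only in texture frequency).

The plaid and mixed styles at the same orientation are moment-matched by
construction: each of the two oriented components is "on" in half the
blobs at the same per-component amplitude in both styles, so every
per-feature variance has the same distribution — but the two components
co-occur in plaid blobs and exclude each other in mixed blobs, flipping
the sign of the spatial correlation between the corresponding wavelet
magnitudes.  Separating such a pair requires the covariance structure,
which is the premise of the variance-only ablation experiment.

Per-image nuisance variation — texture amplitude and frequency jitter —
emulates illumination/contrast and focus variability between micrographs
of one cell line.

Everything is deterministic given the seeds; ``generate_dataset`` writes
16-bit PNGs, ground-truth masks and a manifest CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (CellcovError, DatasetManifest, GrayImage, ManifestEntry,
                 ValidationError, save_image, save_manifest)
from .segmentation import ForegroundMask

__all__ = [
    "GenerationError",
    "ClassDef",
    "SyntheticSpec",
    "default_spec",
    "control_spec",
    "generate_image",
    "generate_dataset",
]

TEXTURE_STYLES = ("single", "plaid", "mixed", "isotropic")
MORPHOLOGIES = ("round", "elongated")

#: Ratio between the high-frequency carrier and the low-frequency component.
_F_LOW_RATIO = 4.5
#: Per-image nuisance jitter ranges (multiplicative): global illumination /
#: contrast drift between micrographs, and focus drift of the carrier.
_AMP_JITTER = (0.85, 1.15)
_FREQ_JITTER = (0.92, 1.08)
#: Per-blob texture contrast jitter: cells in one image differ in density
#: and focal depth, so local texture contrast varies patch to patch.  This
#: is the variation that correlation normalisation is designed to absorb —
#: raw per-feature variances fluctuate with it, correlations do not.
_BLOB_AMP_JITTER = (0.60, 1.35)
#: Target foreground coverage.
_COVERAGE = 0.55
_MAX_BLOBS = 600


class GenerationError(CellcovError):
    """Blob placement failed to reach the requested coverage."""


@dataclass(frozen=True)
class ClassDef:
    """One synthetic cell-line class."""

    label: str
    orientation: float           # degrees, stripe orientation of the texture
    frequency: float             # cycles/pixel of the high-frequency carrier
    morphology: str = "round"    # blob shape
    texture: str = "single"      # texture style
    fg_mean: float = 0.50
    bg_mean: float = 0.85
    noise_sd: float = 0.04
    amp_high: float = 0.10       # per-component carrier amplitude
    amp_low: float = 0.055       # per-component low-frequency amplitude

    def __post_init__(self):
        if self.morphology not in MORPHOLOGIES:
            raise ValidationError(f"unknown morphology {self.morphology!r}")
        if self.texture not in TEXTURE_STYLES:
            raise ValidationError(f"unknown texture style {self.texture!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """A synthetic dataset: classes, image geometry, counts and seed.

    Classes must be pairwise distinguishable by construction: two classes
    may share an orientation only if their texture styles differ; otherwise
    orientations must be at least 20 degrees apart (mod 180).  The
    foreground/background mean gap must exceed 3x the noise s.d. so the
    two-Gaussian segmentation stage is solvable.
    """

    class_defs: tuple[ClassDef, ...]
    image_size: int = 256
    n_images: int = 10
    seed: int = 0

    def __post_init__(self):
        labels = [c.label for c in self.class_defs]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate class labels")
        for c in self.class_defs:
            if abs(c.fg_mean - c.bg_mean) < 3.0 * c.noise_sd:
                raise ValidationError(
                    f"class {c.label!r}: fg/bg mean gap must be >= 3x noise sd"
                )
        defs = self.class_defs
        for i in range(len(defs)):
            for j in range(i + 1, len(defs)):
                a, b = defs[i], defs[j]
                sep = abs(a.orientation - b.orientation) % 180.0
                sep = min(sep, 180.0 - sep)
                if sep < 20.0 and a.texture == b.texture:
                    raise ValidationError(
                        f"classes {a.label!r} and {b.label!r} are not "
                        f"distinguishable: orientations {sep:.0f} deg apart "
                        f"with the same texture style"
                    )

    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.class_defs)

    def class_def(self, label: str) -> ClassDef:
        for c in self.class_defs:
            if c.label == label:
                return c
        raise ValidationError(f"unknown class label {label!r}")


def default_spec(n_images: int = 10, image_size: int = 512, seed: int = 0) -> SyntheticSpec:
    """The default 4-class oriented benchmark.

    Two single-orientation "epithelioid" classes (round blobs) at +30 and
    -30 degrees — a mirror pair that axis-aligned absolute-derivative
    statistics cannot tell apart — and the moment-matched plaid/mixed pair
    of "fibroblastoid" classes at 45/135 degrees (elongated blobs) that
    per-feature variances cannot separate (see the module docstring).
    """
    defs = (
        ClassDef("lineA-epi30", 30.0, 0.18, "round", "single"),
        ClassDef("lineB-fib45p", 45.0, 0.18, "elongated", "plaid"),
        ClassDef("lineC-epi150", 150.0, 0.18, "round", "single"),
        ClassDef("lineD-fib45m", 45.0, 0.18, "elongated", "mixed"),
    )
    return SyntheticSpec(defs, image_size=image_size, n_images=n_images, seed=seed)


def control_spec(n_images: int = 10, image_size: int = 512, seed: int = 0) -> SyntheticSpec:
    """Orientation-free control: two isotropic-texture classes that differ
    only in texture frequency, so the classical derivative mapping suffices
    while oriented features carry no extra information.  Frequencies are
    low enough to survive the 4x averaging that precedes feature
    extraction."""
    defs = (
        ClassDef("ctrl-coarse", 0.0, 0.02, "round", "isotropic"),
        ClassDef("ctrl-fine", 90.0, 0.08, "round", "isotropic"),
    )
    return SyntheticSpec(defs, image_size=image_size, n_images=n_images, seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: Per-pixel texture state painted by :func:`_paint_blobs`.
_SMOOTH, _PRIMARY, _SECONDARY, _BOTH = 0, 1, 2, 3


def _blob_state(texture: str, axis_secondary: bool, rng: np.random.Generator) -> int:
    if texture == "plaid":
        return _BOTH if rng.random() < 0.5 else _SMOOTH
    if texture == "mixed":
        # spindle texture runs along the cell axis
        return _SECONDARY if axis_secondary else _PRIMARY
    return _PRIMARY


def _paint_blobs(cdef: ClassDef, S: int, rng: np.random.Generator):
    """Place blobs until coverage is reached.

    Returns ``(mask, state map, amplitude map)``: the state map records
    which texture component(s) each foreground pixel carries, the
    amplitude map each blob's contrast factor.  Blob sizes are in absolute
    pixels — larger images contain more cells, as micrographs do — so a
    fixed-size analysis window always straddles several blobs.
    """
    mask = np.zeros((S, S), dtype=bool)
    state = np.zeros((S, S), dtype=np.int8)
    amp = np.zeros((S, S))
    rr, cc = np.mgrid[0:S, 0:S].astype(float)
    target = _COVERAGE * S * S
    for i in range(_MAX_BLOBS):
        if mask.sum() >= target:
            return mask, state, amp
        r0, c0 = rng.uniform(0, S, size=2)
        # elongated cell axes split evenly between the two orientations in
        # every style, so blob-edge orientation energy is class-neutral
        axis_secondary = bool(rng.random() < 0.5)
        st = _blob_state(cdef.texture, axis_secondary, rng)
        if cdef.morphology == "round":
            rad = rng.uniform(18.0, 34.0)
            blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad ** 2
        else:
            a = rng.uniform(30.0, 45.0)     # semi-major
            b = rng.uniform(8.0, 13.0)      # semi-minor
            th = np.deg2rad(cdef.orientation
                            + (90.0 if axis_secondary else 0.0)
                            + rng.normal(0.0, 10.0))
            # image rows grow downward: the axis along a +th visual stripe
            u = (cc - c0) * np.cos(th) - (rr - r0) * np.sin(th)
            v = (cc - c0) * np.sin(th) + (rr - r0) * np.cos(th)
            blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        mask |= blob
        state[blob] = st
        amp[blob] = rng.uniform(*_BLOB_AMP_JITTER)
    if mask.sum() < target:
        raise GenerationError(
            f"coverage {mask.mean():.2f} below target {_COVERAGE} "
            f"after {_MAX_BLOBS} blobs"
        )
    return mask, state, amp


def _grating(S: int, freq: float, theta_deg: float, phase: float) -> np.ndarray:
    """Unit-amplitude sinusoid whose stripes run at +theta degrees
    (counter-clockwise from horizontal on the displayed image)."""
    th = np.deg2rad(theta_deg)
    rr, cc = np.mgrid[0:S, 0:S].astype(float)
    return np.sin(2.0 * np.pi * freq * (rr * np.cos(th) + cc * np.sin(th)) + phase)


def _isotropic_noise(S: int, freq: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a ring power spectrum centred at ``freq``."""
    f = np.fft.fftfreq(S)
    fr = np.sqrt(f[:, None] ** 2 + f[None, :] ** 2)
    band = np.exp(-0.5 * ((fr - freq) / (0.15 * freq)) ** 2)
    spec = band * np.exp(2j * np.pi * rng.random((S, S)))
    x = np.fft.ifft2(spec).real
    return x / max(x.std(), 1e-12)


def _texture_field(cdef: ClassDef, S: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Primary- and secondary-orientation texture fields (full amplitude)."""
    amp_scale = rng.uniform(*_AMP_JITTER)
    freq_scale = rng.uniform(*_FREQ_JITTER)
    ah = cdef.amp_high * amp_scale
    al = cdef.amp_low * amp_scale
    f_hi = cdef.frequency * freq_scale
    f_lo = f_hi / _F_LOW_RATIO
    if cdef.texture == "isotropic":
        rms = np.sqrt(ah ** 2 + al ** 2) / np.sqrt(2.0)
        t = rms * _isotropic_noise(S, f_hi, rng)
        return t, t
    fields = []
    for extra in (0.0, 90.0):
        th = cdef.orientation + extra
        t = (ah * _grating(S, f_hi, th, rng.uniform(0, 2 * np.pi))
             + al * _grating(S, f_lo, th, rng.uniform(0, 2 * np.pi)))
        fields.append(t)
    return fields[0], fields[1]


def generate_image(spec: SyntheticSpec, class_label: str, seed: int) -> tuple[GrayImage, ForegroundMask]:
    """Render one image of a class plus its ground-truth foreground mask.

    Bit-identical for identical ``(spec, class_label, seed)``.  With
    ``noise_sd = 0`` the background is exactly the class background mean.
    """
    cdef = spec.class_def(class_label)
    S = spec.image_size
    rng = np.random.default_rng(seed)

    mask, state, amp = _paint_blobs(cdef, S, rng)
    t_primary, t_secondary = _texture_field(cdef, S, rng)

    img = np.full((S, S), cdef.bg_mean)
    on1 = (state == _PRIMARY) | (state == _BOTH)
    on2 = (state == _SECONDARY) | (state == _BOTH)
    tex = on1 * t_primary + on2 * t_secondary
    img[mask] = cdef.fg_mean + (amp * tex)[mask]
    if cdef.noise_sd > 0:
        img = img + rng.normal(0.0, cdef.noise_sd, size=(S, S))
    img = np.clip(img, 0.0, 1.0)
    return GrayImage(img), ForegroundMask(mask)


def generate_dataset(
    spec: SyntheticSpec,
    out_dir: str | Path,
    magnification: str = "20x",
    write_masks: bool = True,
) -> DatasetManifest:
    """Write a balanced PNG dataset with manifest and ground-truth masks.

    Files are ``<label>_<i>.png`` (16-bit grayscale), masks are
    ``<label>_<i>_mask.png``, and the manifest is ``manifest.csv`` in the
    same directory.  Per-image seeds derive from ``spec.seed``, so the same
    spec regenerates byte-identical files.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for ci, cdef in enumerate(spec.class_defs):
        for i in range(spec.n_images):
            img_seed = (spec.seed + 7919 * ci + i) % (2 ** 31)
            img, truth = generate_image(spec, cdef.label, img_seed)
            name = f"{cdef.label}_{i:02d}.png"
            try:
                save_image(img, out / name)
                if write_masks:
                    iio.imwrite(out / f"{cdef.label}_{i:02d}_mask.png",
                                truth.mask.astype(np.uint8) * 255)
            except OSError as exc:
                raise CellcovError(f"failed to write {out / name}: {exc}") from exc
            entries.append(ManifestEntry(str(out / name), cdef.label, magnification))
    manifest = DatasetManifest(tuple(entries))
    save_manifest(manifest, out / "manifest.csv")
    return manifest
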