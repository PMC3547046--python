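"""Image and manifest I/O, run configuration, and model persistence.

Everything downstream works on intensity rasters scaled to ``[0, 1]``:
normalising at load time makes variance thresholds and the Gaussian-mixture
segmentation scale-free, so the same configuration works for 8-bit and
16-bit acquisitions alike.  Colour inputs are reduced to luma; brightfield
cell-line micrographs are effectively grayscale anyway.

Coordinates are 0-based ``(row, col)`` throughout, and windows are half-open
``[r, r+M) x [c, c+M)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

__all__ = [
    "CellcovError",
    "InputError",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "DecompositionError",
    "DegenerateInputError",
    "SamplingExhaustedError",
    "ContractError",
    "OutOfBoundsError",
    "GrayImage",
    "ManifestEntry",
    "DatasetManifest",
    "RunConfig",
    "load_image",
    "save_image",
    "load_manifest",
    "save_manifest",
    "load_config",
    "save_config",
    "save_model",
    "load_model",
]

MIN_IMAGE_SIDE = 64
MAGNIFICATIONS = ("10x", "20x", "40x")

#: BT.601 luma weights used for colour -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class CellcovError(Exception):
    """Base class for all package errors."""


class InputError(CellcovError):
    """A file could not be read or decoded."""


class FormatError(CellcovError):
    """A structured input (manifest, config) is malformed."""


class ValidationError(CellcovError):
    """An input violates a documented invariant."""


class ConfigError(CellcovError):
    """A configuration value is out of range or unknown."""


class DecompositionError(CellcovError):
    """The wavelet decomposition cannot be applied to this input."""


class DegenerateInputError(CellcovError):
    """An estimator received an input with no usable variation."""


class SamplingExhaustedError(CellcovError):
    """Rejection sampling failed to find enough admissible subwindows."""

    def __init__(self, msg: str, acceptance_rate: float = 0.0):
        super().__init__(msg)
        self.acceptance_rate = acceptance_rate


class ContractError(CellcovError):
    """An internal contract between pipeline stages was violated."""


class OutOfBoundsError(CellcovError):
    """A requested sample point lies outside the image."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrayImage:
    """A 2-D intensity raster in ``[0, 1]``, at least 64 x 64 pixels.

    The size floor exists because the pipeline decimates twice and then
    samples square subwindows on the quarter-resolution grid; anything
    smaller has no room for a meaningful window.
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D raster, got ndim={px.ndim}")
        if min(px.shape) < MIN_IMAGE_SIDE:
            raise ValidationError(
                f"image of shape {px.shape} is smaller than the "
                f"{MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE} minimum"
            )
        if not np.isfinite(px).all():
            raise ValidationError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValidationError("image intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    label: str
    magnification: str


@dataclass(frozen=True)
class DatasetManifest:
    """Labelled image inventory: one row per image.

    Every class must have at least two images so that
    leave-one-image-per-class cross-validation is well defined.
    """

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self):
        entries = tuple(self.entries)
        if not entries:
            raise FormatError("manifest has no entries")
        paths = [e.path for e in entries]
        if len(set(paths)) != len(paths):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ValidationError(f"duplicate image paths in manifest: {dupes}")
        for e in entries:
            if e.magnification not in MAGNIFICATIONS:
                raise ValidationError(
                    f"unknown magnification {e.magnification!r} for {e.path!r}; "
                    f"expected one of {MAGNIFICATIONS}"
                )
        counts: dict[str, int] = {}
        for e in entries:
            counts[e.label] = counts.get(e.label, 0) + 1
        thin = [lab for lab, n in counts.items() if n < 2]
        if thin:
            raise ValidationError(
                f"classes with fewer than 2 images cannot be cross-validated: {sorted(thin)}"
            )
        object.__setattr__(self, "entries", entries)

    @property
    def class_count(self) -> int:
        return len({e.label for e in self.entries})

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted({e.label for e in self.entries}))

    def by_class(self) -> dict[str, list[ManifestEntry]]:
        """Entries grouped by label, preserving manifest order within a class."""
        out: dict[str, list[ManifestEntry]] = {}
        for e in self.entries:
            out.setdefault(e.label, []).append(e)
        return out

    def filter_magnification(self, magnification: str) -> "DatasetManifest":
        kept = tuple(e for e in self.entries if e.magnification == magnification)
        return DatasetManifest(kept)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, in one flat record.

    ``window_size`` and both SVM kernel parameters are configuration rather
    than constants: they are dataset-scale dependent, and every report
    written by the package embeds the values used.  ``window_size`` counts
    pixels on the quarter-resolution averaged-image grid (32 there spans
    roughly 128 pixels of the original image).
    """

    levels: int = 2                    # decomposition depth
    radius_L: int = 5                  # largest concentric-ring radius, px
    n_angles_diff: int = 8             # directional-score orientations
    window_size: int = 32              # subwindow side, averaged-image px
    n_subwindows: int = 20             # windows per image (votes per image)
    mapping: str = "F1"                # one of F1..F4
    normalized: bool = True            # correlation-normalised descriptors
    diagonal_only: bool = False        # variance-only ablation
    svm_C: float = 10.0
    svm_gamma: float | str = "auto"    # "auto" = 1/n_features
    seed: int = 0
    filter_set: str = "bior97_qshift14"
    closing_k: int = 5                 # mask closing kernel (odd)
    median_k: int = 9                  # mask median-filter kernel (odd)

    def __post_init__(self):
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        if self.radius_L < 1:
            raise ConfigError("radius_L must be >= 1")
        if self.mapping not in ("F1", "F2", "F3", "F4"):
            raise ConfigError(f"unknown feature mapping {self.mapping!r}")
        if self.svm_C <= 0:
            raise ConfigError("svm_C must be positive")
        if isinstance(self.svm_gamma, str):
            if self.svm_gamma not in ("auto", "scale"):
                raise ConfigError(f"svm_gamma must be positive or 'auto'/'scale', got {self.svm_gamma!r}")
        elif self.svm_gamma <= 0:
            raise ConfigError("svm_gamma must be positive")
        if self.window_size < 2 or self.n_subwindows < 1:
            raise ConfigError("window_size >= 2 and n_subwindows >= 1 required")
        for name in ("closing_k", "median_k"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ConfigError(f"{name} must be an odd integer >= 1, got {k}")


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> GrayImage:
    """Read a PNG/JPG/TIFF file as a ``[0, 1]`` grayscale raster.

    Colour inputs are converted with the BT.601 luma weights
    ``0.299 R + 0.587 G + 0.114 B``; integer sample ranges are rescaled by
    the dtype full scale, so a constant-255 8-bit file maps to constant 1.
    """
    import imageio.v3 as iio

    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise InputError(f"image file not found: {path}") from None
    except Exception as exc:  # decoder errors vary by plugin
        raise InputError(f"could not decode image {path}: {exc}") from exc

    arr = np.asarray(raw)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ np.asarray(LUMA_WEIGHTS)
        scale = float(np.iinfo(raw.dtype).max) if np.issubdtype(raw.dtype, np.integer) else 1.0
    elif arr.ndim == 2:
        scale = float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else 1.0
        arr = arr.astype(float)
    else:
        raise InputError(f"unsupported image dimensionality {arr.ndim} in {path}")
    arr = np.clip(arr / scale, 0.0, 1.0)

    if min(arr.shape) < MIN_IMAGE_SIDE:
        raise ValidationError(
            f"image {path} is {arr.shape[0]}x{arr.shape[1]}; "
            f"the pipeline requires at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}"
        )
    return GrayImage(arr)


def save_image(img: GrayImage | np.ndarray, path: str | Path) -> None:
    """Write a ``[0, 1]`` raster as a 16-bit grayscale PNG (lossless to ~1.5e-5)."""
    import imageio.v3 as iio

    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, float)
    iio.imwrite(Path(path), np.round(px * 65535.0).astype(np.uint16))


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a ``path,label,magnification`` CSV into a validated manifest."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"manifest file not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"manifest {path} is empty") from None
    missing = {"path", "label", "magnification"} - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} is missing columns: {sorted(missing)}")
    entries = tuple(
        ManifestEntry(str(r["path"]), str(r["label"]), str(r["magnification"]))
        for _, r in df.iterrows()
    )
    return DatasetManifest(entries)


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.path, e.label, e.magnification) for e in manifest.entries],
        columns=["path", "label", "magnification"],
    )
    df.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# flat key-value config files
# ---------------------------------------------------------------------------

_BOOL_FIELDS = {"normalized", "diagonal_only"}
_STR_FIELDS = {"mapping", "filter_set"}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` file (``#`` comments) into a RunConfig."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
        if key in _BOOL_FIELDS:
            if val.lower() not in ("true", "false"):
                raise FormatError(f"{path}:{lineno}: {key} must be true/false")
            kwargs[key] = val.lower() == "true"
        elif key in _STR_FIELDS:
            kwargs[key] = val
        elif key == "svm_gamma":
            kwargs[key] = val if val in ("auto", "scale") else float(val)
        elif key in ("svm_C",):
            kwargs[key] = float(val)
        else:
            kwargs[key] = int(val)
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    lines = [f"{f.name} = {getattr(cfg, f.name)}" for f in dataclasses.fields(RunConfig)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model, cfg: RunConfig, path: str | Path) -> None:
    """Persist a trained classifier together with the config that built it."""
    joblib.dump({"model": model, "config": cfg}, Path(path))


def load_model(path: str | Path):
    """Return ``(model, config)`` written by :func:`save_model`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"model file not found: {path}")
    blob = joblib.load(path)
    try:
        return blob["model"], blob["config"]
    except (TypeError, KeyError):
        raise FormatError(f"{path} is not a cellcov model file") from None
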