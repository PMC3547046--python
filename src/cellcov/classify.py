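"""RBF-SVM classification with per-image majority voting and
leave-one-image-per-class cross-validation.

An image's signature is the set of N descriptor vectors from N admissible
random subwindows.  A multiclass SVM (RBF kernel, one-vs-one) classifies
each vector independently; the image receives the modal label of its N
votes, with ties broken by the largest summed decision margin and then
lexicographically.  Descriptor vectors are z-scored per dimension with
statistics from the training set only — RBF kernels on mixed-scale
features (intensities ~1e-1, score variances ~1e-4) need it.

Cross-validation follows the leave-one-image-per-class protocol: with K
images per class there are K folds, fold i testing simultaneously on the
i-th image (manifest order) of every class.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import (DatasetManifest, GrayImage, RunConfig, ValidationError,
                 ContractError, load_image)
from .dtcwt import (average_intensity, forward_dtcwt2d, load_filter_bank,
                    subband_magnitudes, FilterBank)
from .directional import directional_score_stack
from .descriptors import (DescriptorVector, build_feature_map, diagonal_only,
                          normalize_covariance, region_covariance,
                          vectorize_descriptor)
from .segmentation import (downsample_mask, fit_two_gaussian_em, refine_mask,
                           segment_foreground)
from .sampling import sample_subwindows

__all__ = [
    "SVMModel",
    "PredictionResult",
    "CVFoldPlan",
    "CVReport",
    "extract_image_signature",
    "train_svm",
    "predict_image",
    "make_fold_plan",
    "cross_validate",
]


# ---------------------------------------------------------------------------
# signature extraction (the full per-image pipeline)
# ---------------------------------------------------------------------------

def _image_seed(base_seed: int, image_id: str) -> int:
    """Stable per-image sampling seed below 2**31."""
    return (base_seed + zlib.crc32(image_id.encode())) % (2 ** 31)


def extract_image_signature(
    img: GrayImage,
    cfg: RunConfig,
    image_id: str = "",
    filter_bank: FilterBank | None = None,
) -> list[DescriptorVector]:
    """Run the whole per-image pipeline and return N descriptor vectors.

    Stages: EM foreground segmentation and mask refinement (full
    resolution, then a block vote down to the quarter grid); two-level
    dual-tree decomposition giving the level-2 magnitudes and the averaged
    image; directional scores; constrained subwindow sampling; one
    (optionally correlation-normalised) covariance descriptor per window,
    vectorised (or reduced to its diagonal for the ablation).

    The image is cropped at the bottom/right to a multiple of 4 so the
    averaged grid is exactly shape/4.  Deterministic given
    ``(img, cfg.seed, image_id)``.
    """
    if cfg.levels < 2:
        raise ValidationError("the signature pipeline needs a depth-2 decomposition")
    fb = filter_bank or load_filter_bank(cfg.filter_set)
    px = img.pixels
    H, W = (px.shape[0] // 4) * 4, (px.shape[1] // 4) * 4
    px = px[:H, :W]
    seed = _image_seed(cfg.seed, image_id)

    gmm = fit_two_gaussian_em(px, seed=seed)
    mask_full = refine_mask(segment_foreground(px, gmm), cfg.closing_k, cfg.median_k)
    mask4 = downsample_mask(mask_full, 4)

    pyr = forward_dtcwt2d(px, cfg.levels, fb)
    mags = subband_magnitudes(pyr, level=2)
    avg = average_intensity(px, fb)

    if cfg.mapping == "F4":
        fm = build_feature_map(avg, mapping="F4")
    else:
        agg = {"F1": "median", "F2": "max", "F3": "mean"}[cfg.mapping]
        stack = directional_score_stack(avg, L=cfg.radius_L, aggregator=agg)
        kw = {"F1": "scores_median", "F2": "scores_max", "F3": "scores_mean"}[cfg.mapping]
        fm = build_feature_map(avg, mags, **{kw: stack}, mapping=cfg.mapping)

    wins = sample_subwindows(avg, mask4, cfg.window_size, cfg.n_subwindows,
                             seed=seed, image_id=image_id)
    vectors = []
    for w in wins.windows:
        cd = region_covariance(fm, w)
        if cfg.normalized:
            cd = normalize_covariance(cd)
        vec = diagonal_only(cd) if cfg.diagonal_only else vectorize_descriptor(cd)
        vectors.append(dataclasses.replace(vec, mapping_id=cfg.mapping))
    return vectors


# ---------------------------------------------------------------------------
# SVM model
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    """Trained classifier: standardisation statistics + RBF SVC state."""

    scaler: StandardScaler
    svc: SVC

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.svc.classes_)

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(vectors))

    def class_scores(self, vectors: np.ndarray) -> np.ndarray:
        """Per-class decision scores, shape (n_samples, n_classes)."""
        df = self.svc.decision_function(self.scaler.transform(vectors))
        if df.ndim == 1:  # binary: positive margin favours classes_[1]
            df = np.column_stack([-df, df])
        return df


def train_svm(
    vectors: np.ndarray,
    labels: np.ndarray,
    C: float = 10.0,
    gamma: float | str = "auto",
) -> SVMModel:
    """Fit the standardiser and the one-vs-one RBF SVM on training vectors."""
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("vectors must be (n_samples, d) matching labels")
    if not np.isfinite(X).all():
        raise ValidationError("descriptor vectors contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValidationError("training needs at least 2 classes")
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovr")
    svc.fit(scaler.transform(X), y)
    return SVMModel(scaler, svc)


@dataclass(frozen=True)
class PredictionResult:
    image_id: str
    subwindow_labels: tuple[str, ...]
    voted_label: str
    vote_histogram: dict[str, int]


def predict_image(model: SVMModel, signature: list[DescriptorVector],
                  image_id: str = "") -> PredictionResult:
    """Classify each signature vector and majority-vote the image label.

    Ties are broken by the larger per-class decision score summed over the
    image's vectors, then lexicographically.
    """
    if not signature:
        raise ContractError("empty signature")
    X = np.stack([v.values for v in signature])
    labels = model.predict(X)
    hist: dict[str, int] = {}
    for lab in labels:
        hist[lab] = hist.get(lab, 0) + 1
    top = max(hist.values())
    tied = sorted(lab for lab, n in hist.items() if n == top)
    if len(tied) > 1:
        scores = model.class_scores(X).sum(axis=0)
        by_class = {c: scores[i] for i, c in enumerate(model.classes)}
        tied.sort(key=lambda lab: (-by_class[lab], lab))
    voted = tied[0]
    return PredictionResult(image_id, tuple(labels), voted, hist)


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVFoldPlan:
    """K folds; fold i tests on the i-th image of every class."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (test, train) paths

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass(frozen=True)
class CVReport:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float
    confusion: np.ndarray              # (n_classes, n_classes), rows = truth
    class_labels: tuple[str, ...]
    config: RunConfig
    predictions: tuple[PredictionResult, ...] = ()

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "fold_accuracies": list(self.fold_accuracies),
            "class_labels": list(self.class_labels),
            "confusion": self.confusion.tolist(),
            "config": dataclasses.asdict(self.config),
        }


def make_fold_plan(manifest: DatasetManifest) -> CVFoldPlan:
    """Leave-one-image-per-class folds in manifest order.

    Requires a balanced manifest (equal image count K per class); produces
    K folds whose test sets partition the manifest.
    """
    groups = manifest.by_class()
    counts = {lab: len(es) for lab, es in groups.items()}
    if len(set(counts.values())) != 1:
        raise ValidationError(f"unbalanced classes, cannot build fold plan: {counts}")
    K = next(iter(counts.values()))
    folds = []
    for i in range(K):
        test = tuple(groups[lab][i].path for lab in sorted(groups))
        train = tuple(e.path for lab in sorted(groups) for j, e in enumerate(groups[lab]) if j != i)
        folds.append((test, train))
    return CVFoldPlan(tuple(folds))


def cross_validate(
    manifest: DatasetManifest,
    cfg: RunConfig,
    image_loader=None,
    magnification: str | None = None,
    filter_bank: FilterBank | None = None,
) -> CVReport:
    """Run the full leave-one-image-per-class experiment.

    Signatures are extracted once per image; each fold then standardises
    and trains on the training images' vectors only and votes on the test
    images.  ``image_loader(path) -> GrayImage`` may replace file loading
    (used for in-memory datasets).
    """
    if magnification is not None:
        manifest = manifest.filter_magnification(magnification)
    loader = image_loader or load_image
    plan = make_fold_plan(manifest)
    label_of = {e.path: e.label for e in manifest.entries}
    fb = filter_bank or load_filter_bank(cfg.filter_set)

    signatures = {
        e.path: extract_image_signature(loader(e.path), cfg, image_id=e.path,
                                        filter_bank=fb)
        for e in manifest.entries
    }

    labels = manifest.labels
    idx = {lab: i for i, lab in enumerate(labels)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    fold_acc = []
    predictions = []
    for test_paths, train_paths in plan.folds:
        X = np.vstack([np.stack([v.values for v in signatures[p]]) for p in train_paths])
        y = np.concatenate([[label_of[p]] * len(signatures[p]) for p in train_paths])
        model = train_svm(X, y, C=cfg.svm_C, gamma=cfg.svm_gamma)
        correct = 0
        for p in test_paths:
            pred = predict_image(model, signatures[p], image_id=p)
            predictions.append(pred)
            confusion[idx[label_of[p]], idx[pred.voted_label]] += 1
            correct += int(pred.voted_label == label_of[p])
        fold_acc.append(correct / len(test_paths))
    mean_acc = float(np.mean(fold_acc))
    return CVReport(tuple(fold_acc), mean_acc, confusion, labels,
                    dataclasses.replace(cfg), tuple(predictions))
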