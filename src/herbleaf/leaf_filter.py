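"""Intact-leaf filtering from binary silhouettes.

A candidate component may be a single intact leaf, a union of overlapping
leaves, a partial blade, or a leaf with a stem attached.  The discrimination
is purely a matter of outline shape, so each candidate is reduced to a
normalized binary silhouette (padded square, inverse-Otsu binarized,
hole-filled, resized to the classifier input resolution) before
classification.  Color and texture never reach the classifier.

The default backbone is a deterministic shape-descriptor classifier: Hu
moment invariants plus the standard leaf-shape ratios (solidity, extent,
circularity, aspect ratio, ...) and two convexity-deficiency summaries, fed
to a logistic regression.  These descriptors are rotation/flip/shift
invariant, which is why single blades, bilobed overlap unions, clipped
blades and stem-attached blobs separate cleanly.  An alternative ``mlp``
backbone (a small multilayer perceptron over downsampled silhouette pixels,
trained with flip/rotation/shift augmentation) is available behind the same
interface for experiments where learned pixel features are wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.measure import regionprops
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from herbleaf.components import LeafCandidate
from herbleaf.postprocess import fill_holes, otsu_threshold
from herbleaf.synthetic import ClassifierDataset

__all__ = [
    "SilhouetteImage",
    "ClassifierModel",
    "preprocess_candidate",
    "train_single_leaf_classifier",
    "filter_individual_leaves",
]

_INPUT_RESOLUTION = 300
_MLP_RESOLUTION = 48


@dataclass
class SilhouetteImage:
    """Square binary silhouette at classifier input resolution."""

    pixels: np.ndarray
    provenance: int | None = None


@dataclass
class ClassifierModel:
    """A fitted single-leaf classifier plus its training record."""

    backbone: str
    estimator: Pipeline
    decision_threshold: float = 0.5
    metadata: dict = field(default_factory=dict)
    holdout_metrics: dict = field(default_factory=dict)
    fitted: bool = False

    def predict_scores(self, silhouettes: Sequence[np.ndarray]) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("classifier has not been trained")
        if len(silhouettes) == 0:
            return np.empty(0)
        feats = np.stack([_featurize(s, self.backbone) for s in silhouettes])
        return self.estimator.predict_proba(feats)[:, 1]


# ---------------------------------------------------------------------------
# silhouette normalization


def preprocess_candidate(
    cand: LeafCandidate, resolution: int = _INPUT_RESOLUTION
) -> SilhouetteImage:
    """Normalize a candidate crop into a square binary silhouette.

    Steps: pad the white-background crop to a square (content centered, white
    padding so aspect ratio survives the resize), convert to grayscale,
    inverse-Otsu binarize (the leaf is the dark class), fill interior holes,
    and resize to ``resolution``.  Raises on empty crops.
    """
    crop = np.asarray(cand.image_crop)
    if crop.size == 0:
        raise ValueError("candidate has an empty image crop")
    h, w = crop.shape[:2]
    side = max(h, w)
    square = np.full((side, side, 3), 255, dtype=crop.dtype)
    oy, ox = (side - h) // 2, (side - w) // 2
    square[oy : oy + h, ox : ox + w] = crop

    gray = rgb2gray(square.astype(float) / 255.0)
    binary = otsu_threshold(gray, invert=True)
    if not binary.any():
        raise ValueError("candidate silhouette is empty after binarization")
    binary = fill_holes(binary)
    small = resize(binary.astype(float), (resolution, resolution), order=1,
                   anti_aliasing=False)
    return SilhouetteImage(pixels=(small >= 0.5).astype(np.uint8), provenance=cand.id)


# ---------------------------------------------------------------------------
# features

_STRUCT_8 = np.ones((3, 3), dtype=bool)


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_STRUCT_8)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def _shape_descriptors(silhouette: np.ndarray) -> np.ndarray:
    """19 rotation/flip/shift-invariant descriptors of a binary silhouette."""
    mask = _largest_component(np.asarray(silhouette) > 0)
    filled = ndimage.binary_fill_holes(mask)
    p = regionprops(filled.astype(np.uint8))[0]
    area = float(p.area)
    per = float(p.perimeter_crofton)
    major = max(float(p.axis_major_length), 1e-6)
    minor = max(float(p.axis_minor_length), 1e-6)
    feret = float(p.feret_diameter_max)
    convex_area = float(p.area_convex)

    # convexity-deficiency summaries: bilobed overlap unions and bitten
    # margins leave large connected pockets between the hull and the blade
    deficiency = p.image_convex & ~p.image_filled
    dlab, dn = ndimage.label(deficiency, structure=_STRUCT_8)
    if dn:
        dsizes = ndimage.sum_labels(deficiency, dlab, index=range(1, dn + 1))
        n_large = int((dsizes > 0.01 * convex_area).sum())
        max_pocket = float(dsizes.max()) / convex_area
    else:
        n_large, max_pocket = 0, 0.0

    hu = p.moments_hu
    hu_log = np.sign(hu) * np.log10(np.abs(hu) + 1e-30)

    base = np.array(
        [
            float(p.solidity),
            float(p.extent),
            float(p.eccentricity),
            4.0 * np.pi * area / per**2 if per > 0 else 0.0,
            major / minor,
            feret / major,
            per / feret if feret > 0 else 0.0,
            per / major,
            per / (major + minor),
            area / (major * minor),
            float(n_large),
            max_pocket,
        ]
    )
    return np.concatenate([base, hu_log])


def _pixel_features(silhouette: np.ndarray) -> np.ndarray:
    small = resize(np.asarray(silhouette).astype(float), (_MLP_RESOLUTION, _MLP_RESOLUTION),
                   order=1, anti_aliasing=True)
    return small.ravel()


def _featurize(silhouette: np.ndarray, backbone: str) -> np.ndarray:
    if backbone == "shape":
        return _shape_descriptors(silhouette)
    if backbone == "mlp":
        return _pixel_features(silhouette)
    raise ValueError(f"unknown backbone {backbone!r}")


def _augment(images: list[np.ndarray], labels: np.ndarray, rng: np.random.Generator):
    """Flip / 90-degree-rotate / shift copies for the pixel-based backbone."""
    out_imgs, out_labels = list(images), list(labels)
    for img, lab in zip(images, labels):
        aug = img[:, ::-1] if rng.uniform() < 0.5 else img[::-1, :]
        aug = np.rot90(aug, k=int(rng.integers(0, 4)))
        shift = rng.integers(-12, 13, size=2)
        aug = np.roll(aug, shift=tuple(shift), axis=(0, 1))
        out_imgs.append(aug)
        out_labels.append(lab)
    return out_imgs, np.asarray(out_labels)


# ---------------------------------------------------------------------------
# training and filtering


def train_single_leaf_classifier(
    dataset: ClassifierDataset,
    backbone: str = "shape",
    decision_threshold: float = 0.5,
    test_size: float = 0.3,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the intact-leaf classifier and report held-out metrics.

    The dataset is split (stratified) into train/held-out parts; accuracy,
    precision, recall and the confusion counts on the held-out part are
    stored on the returned model.  Training is deterministic for a fixed
    seed.  Raises if the dataset does not contain both classes.
    """
    if not 0.0 < decision_threshold < 1.0:
        raise ValueError("decision_threshold must lie in (0, 1)")
    labels = np.asarray(dataset.labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires both positive and negative silhouettes")
    for img in dataset.images:
        if img.ndim != 2 or img.shape[0] != img.shape[1]:
            raise ValueError("all training silhouettes must be square binary images")

    idx_train, idx_test = train_test_split(
        np.arange(len(labels)), test_size=test_size, stratify=labels, random_state=seed
    )
    train_imgs = [dataset.images[i] for i in idx_train]
    train_labels = labels[idx_train]
    if backbone == "mlp":
        rng = np.random.default_rng(seed)
        train_imgs, train_labels = _augment(train_imgs, train_labels, rng)
        clf = MLPClassifier(hidden_layer_sizes=(128,), batch_size=32, max_iter=300,
                            random_state=seed)
    else:
        clf = LogisticRegression(max_iter=2000, C=10.0)
    est = Pipeline([("scale", StandardScaler()), ("clf", clf)])

    x_train = np.stack([_featurize(s, backbone) for s in train_imgs])
    x_test = np.stack([_featurize(dataset.images[i], backbone) for i in idx_test])
    y_test = labels[idx_test]
    est.fit(x_train, train_labels)

    scores = est.predict_proba(x_test)[:, 1]
    pred = scores >= decision_threshold
    tp = int(((pred == 1) & (y_test == 1)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    metrics = {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "accuracy": (tp + tn) / len(y_test),
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
    }
    return ClassifierModel(
        backbone=backbone,
        estimator=est,
        decision_threshold=decision_threshold,
        metadata={"seed": seed, "n_train": len(train_labels), "n_test": len(y_test),
                  "test_size": test_size},
        holdout_metrics=metrics,
        fitted=True,
    )


def filter_individual_leaves(
    cands: Sequence[LeafCandidate], model: ClassifierModel
) -> list[LeafCandidate]:
    """Keep exactly the candidates whose silhouette scores >= the threshold.

    Ties at the threshold are kept: a spurious extra crop is cheaper for
    downstream trait analysis than a silently dropped leaf.  Order preserved.
    """
    if not model.fitted:
        raise RuntimeError("classifier has not been trained")
    if not cands:
        return []
    silhouettes = [preprocess_candidate(c).pixels for c in cands]
    scores = model.predict_scores(silhouettes)
    return [c for c, s in zip(cands, scores) if s >= model.decision_threshold]
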