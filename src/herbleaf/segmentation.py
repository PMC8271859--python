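"""Phase-1 segmentation backends.

Downstream stages consume only a :class:`SegmentationResult` (a per-pixel
foreground-score map at its own working resolution), so any segmenter can
stand behind this interface.  Two backends are provided:

* :func:`reference_chroma_segmenter` — a deterministic color-model segmenter
  that scores each pixel by its RGB distance to a leaf color reference.  It
  is intended for synthetic sheets and controlled fixtures, where leaf color
  is distinct from the sheet background and the non-plant distractors.
* :func:`load_external_mask` — loads a mask produced by any trained model
  (e.g. an encoder–decoder network run elsewhere) from a single-channel
  raster file.  Values are normalized to [0, 1]; no resizing happens here —
  the post-processing stage owns resizing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

__all__ = ["SegmentationResult", "ChromaParams", "reference_chroma_segmenter", "load_external_mask"]


@dataclass(frozen=True)
class SegmentationResult:
    """Per-pixel foreground score map in [0, 1] at its own resolution."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.size == 0:
            raise ValueError(f"scores must be a non-empty 2-D array, got shape {s.shape}")
        if s.min() < 0.0 or s.max() > 1.0:
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "scores", s)

    @property
    def resolution(self) -> tuple[int, int]:
        return self.scores.shape  # (h, w)


@dataclass(frozen=True)
class ChromaParams:
    """Color model for the reference segmenter.

    The model lives in green-opponent chroma coordinates (G - R, G - B),
    which separate foliage from achromatic content (paper, labels, barcodes)
    that a plain RGB distance confuses with green at equal Euclidean
    distance.  leaf_color is the RGB reference defining the opponent center;
    sigma the score decay scale in opponent units.  Segmentation runs at
    working_resolution (square), matching the reduced working size a learned
    model would use.
    """

    leaf_color: tuple[float, float, float] = (70.0, 115.0, 60.0)
    sigma: float = 45.0
    working_resolution: int = 512


def _opponent(rgb: np.ndarray) -> np.ndarray:
    """Green-opponent chroma coordinates (G - R, G - B)."""
    return np.stack([rgb[..., 1] - rgb[..., 0], rgb[..., 1] - rgb[..., 2]], axis=-1)


def reference_chroma_segmenter(
    image: np.ndarray, params: ChromaParams | None = None
) -> SegmentationResult:
    """Score leaf-likeness of each pixel against a leaf color model.

    The image is downsampled (bilinear) to the square working resolution and
    each pixel gets score ``exp(-(d / sigma)^2)`` where ``d`` is its distance
    to the leaf reference in green-opponent chroma coordinates.
    Deterministic.
    """
    if params is None:
        params = ChromaParams()
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    r = params.working_resolution
    small = resize(image.astype(float), (r, r), order=1, anti_aliasing=True)
    ref = _opponent(np.asarray(params.leaf_color, dtype=float))
    d2 = ((_opponent(small) - ref) ** 2).sum(axis=-1)
    scores = np.exp(-d2 / params.sigma**2)
    return SegmentationResult(scores=scores)


def load_external_mask(path: str | Path) -> SegmentationResult:
    """Load an externally produced mask from a single-channel raster file.

    Integer rasters are normalized by their dtype maximum (an 8-bit {0, 255}
    mask becomes {0.0, 1.0}).  Multi-channel files are rejected: a model mask
    is a score map, and silently collapsing color channels would hide an
    upstream export mistake.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    if arr.ndim != 2:
        raise OSError(
            f"mask file {path} has {arr.ndim} dimensions; expected a single-channel raster"
        )
    if np.issubdtype(arr.dtype, np.integer):
        scores = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        scores = arr.astype(float)
    return SegmentationResult(scores=np.clip(scores, 0.0, 1.0))
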