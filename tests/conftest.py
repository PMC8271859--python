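"""Shared fixtures: expensive resources built once per session."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import resize

from herbleaf import (
    make_classifier_dataset,
    render_sheet,
    train_single_leaf_classifier,
)
from herbleaf.pipeline import PipelineConfig, process_sheet
from herbleaf.segmentation import SegmentationResult
from herbleaf.synthetic import SheetSpec, _rasterize_outline, sample_leaf_shape

N_EVAL_SHEETS = 20
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size silhouette training set (881 positives / 1015 negatives)."""
    return make_classifier_dataset(881, 1015, rng_seed=0)


@pytest.fixture(scope="session")
def default_model(default_dataset):
    return train_single_leaf_classifier(default_dataset, seed=0)


@pytest.fixture(scope="session")
def eval_sheets():
    """Seeded synthetic sheets (default layout: 3 intact, 1 pair, 1 damaged)."""
    return [render_sheet(SheetSpec(seed=s)) for s in range(N_EVAL_SHEETS)]


@pytest.fixture(scope="session")
def eval_pipeline_results(default_model, eval_sheets):
    """Full-pipeline results for each evaluation sheet."""
    config = PipelineConfig(model=default_model)
    return [process_sheet(img, config) for img, _, _ in eval_sheets]


def make_two_leaf_fixture(seed: int, gap: int = 8, shape: tuple[int, int] = (768, 1024)):
    """A sheet with two intact leaves ``gap`` px apart and a deliberately
    merged low-resolution mask covering both as a single component.

    Emulates the under-segmentation failure of a coarse segmenter on closely
    placed leaves; the post-processing stage is expected to split the blob.
    Returns ``(image, merged_seg_result)``.
    """
    rng = np.random.default_rng(seed)
    len_a, len_b = rng.uniform(200, 280, size=2)
    blade_a = sample_leaf_shape(len_a, len_a / rng.uniform(1.5, 2.5), rng)
    blade_b = sample_leaf_shape(len_b, len_b / rng.uniform(1.5, 2.5), rng)
    cy = shape[0] // 2
    cx_a = shape[1] // 2 - int(len_a / 2) - gap // 2
    cx_b = shape[1] // 2 + int(len_b / 2) + (gap - gap // 2)
    mask_a = _rasterize_outline(blade_a.outline, 0.0, (cx_a, cy), shape)
    mask_b = _rasterize_outline(blade_b.outline, 0.0, (cx_b, cy), shape)

    image = np.empty(shape + (3,), dtype=float)
    image[:] = (235.0, 228.0, 210.0)
    image += rng.normal(0.0, 3.0, size=image.shape)
    image[mask_a] = (70, 115, 60)
    image[mask_b] = (72, 118, 58)
    image = np.clip(image, 0, 255).astype(np.uint8)

    small = resize((mask_a | mask_b).astype(float), (512, 512), order=0) > 0.5
    merged = small
    for size in (3, 5, 7, 9, 11, 13):
        merged = ndimage.maximum_filter(small.astype(np.uint8), size=size) > 0
        _, n = ndimage.label(merged, structure=_STRUCT_8)
        if n == 1:
            break
    assert n == 1, "fixture failed to merge the two leaves into one component"
    return image, SegmentationResult(scores=merged.astype(float))
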