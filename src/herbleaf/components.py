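"""Connected-component candidate extraction.

Each sufficiently large 8-connected component of the clean mask becomes a
:class:`LeafCandidate`: the component's tight bounding box cropped from both
the mask and the sheet image, with every pixel outside a slightly dilated
component mask painted white.  The dilation (default radius 10 px) exists
only to shield the masking step: it keeps the component's own margin pixels
while still erasing any *other* leaf that happens to fall inside the same
bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["LeafCandidate", "label_components", "extract_components"]

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class LeafCandidate:
    """A background-cleaned candidate component cropped from a sheet.

    bbox is [x0, y0, x1, y1], 0-based half-open, in sheet pixel coordinates
    (x = column, y = row); area is the component's pre-dilation pixel count.
    """

    id: int
    bbox: tuple[int, int, int, int]
    image_crop: np.ndarray
    mask_crop: np.ndarray
    area: int


def label_components(mask: np.ndarray, connectivity: int = 8):
    """Label connected foreground components of a binary mask.

    Returns ``(labels, areas, bboxes)`` where ``labels`` assigns each maximal
    connected region a positive integer (background 0), ``areas[i]`` is the
    pixel count of label ``i + 1``, and ``bboxes[i]`` its [x0, y0, x1, y1]
    half-open tight box.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask) > 0
    structure = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    labels, n = ndimage.label(mask, structure=structure)
    areas = ndimage.sum_labels(mask, labels, index=range(1, n + 1)).astype(int)
    slices = ndimage.find_objects(labels)
    bboxes = [(sl[1].start, sl[0].start, sl[1].stop, sl[0].stop) for sl in slices]
    return labels, areas, bboxes


def extract_components(
    image: np.ndarray,
    clean_mask: np.ndarray,
    min_area: int = 1000,
    component_dilation: int = 10,
    dilation_mode: str = "radius",
) -> list[LeafCandidate]:
    """Extract every component with area strictly greater than ``min_area``.

    For each retained component, a single-component mask is dilated by
    ``component_dilation`` pixels, the sheet image is masked with it (outside
    pixels set to white), and both mask and masked image are cropped to the
    *un-dilated* component's tight bounding box.

    ``dilation_mode`` selects how "dilate by d pixels" is read: ``"radius"``
    (default) uses one pass of a (2d+1) x (2d+1) square element;
    ``"iterative"`` uses d passes of a 3 x 3 element (identical reach for
    square elements, kept for parity with implementations that iterate).
    """
    image = np.asarray(image)
    clean_mask = np.asarray(clean_mask) > 0
    if image.shape[:2] != clean_mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {clean_mask.shape} dimensions differ"
        )
    if dilation_mode not in ("radius", "iterative"):
        raise ValueError(f"dilation_mode must be 'radius' or 'iterative', got {dilation_mode!r}")

    labels, areas, bboxes = label_components(clean_mask, connectivity=8)
    h, w = clean_mask.shape
    d = int(component_dilation)
    candidates: list[LeafCandidate] = []
    for idx, (area, bbox) in enumerate(zip(areas, bboxes)):
        if area <= min_area:
            continue
        label = idx + 1
        x0, y0, x1, y1 = bbox
        # The dilated component only reaches d px beyond the tight box, and
        # everything is cropped back to the tight box, so all morphology can
        # run on a d-padded window instead of the full sheet.
        py0, py1 = max(0, y0 - d), min(h, y1 + d)
        px0, px1 = max(0, x0 - d), min(w, x1 + d)
        comp = labels[py0:py1, px0:px1] == label
        if d > 0:
            if dilation_mode == "radius":
                shield = ndimage.maximum_filter(comp.astype(np.uint8), size=2 * d + 1,
                                                mode="constant") > 0
            else:
                shield = ndimage.binary_dilation(comp, structure=np.ones((3, 3), bool),
                                                 iterations=d)
        else:
            shield = comp
        window = image[py0:py1, px0:px1].copy()
        window[~shield] = 255
        ly0, lx0 = y0 - py0, x0 - px0
        image_crop = window[ly0 : ly0 + (y1 - y0), lx0 : lx0 + (x1 - x0)]
        mask_crop = comp[ly0 : ly0 + (y1 - y0), lx0 : lx0 + (x1 - x0)]
        candidates.append(
            LeafCandidate(
                id=label,
                bbox=(x0, y0, x1, y1),
                image_crop=image_crop,
                mask_crop=mask_crop,
                area=int(area),
            )
        )
    return candidates
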