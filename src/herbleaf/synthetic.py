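"""Seeded synthetic herbarium sheets with per-leaf ground truth.

A rendered sheet emulates the content of a digitized herbarium specimen: a
light paper background, several leaf blades (well-separated intact ones,
mutually overlapping pairs, and damaged blades with bitten margins), thin
brown stems, and the non-plant objects found on real sheets (a color chart,
a barcode, a specimen label) placed in reserved margin bands off the
specimen.  Every sheet comes with a pixel-exact ground-truth mask (union of
all leaf rasters, distractors and stems excluded) and a per-leaf inventory
whose trait vectors are computed from the leaf's own raster by
:func:`herbleaf.traits.compute_traits`, so the generator and the measurement
code can never drift apart.

Blades are superellipse profiles — two mirrored smooth arcs meeting at apex
and base — with random aspect ratio, boundary-exponent and rotation plus a
small smooth margin wobble.  This spans the shape range needed to separate
"single intact leaf" from "overlap union / partial blade / stem-attached
blob" without modelling real taxa; see the classifier dataset builder.

Everything is driven by a single integer seed: identical specs give
bit-identical images, masks and inventories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours

from herbleaf.traits import compute_traits

__all__ = [
    "LayoutError",
    "LeafShape",
    "SheetSpec",
    "InventoryLeaf",
    "LeafInventory",
    "ClassifierDataset",
    "sample_leaf_shape",
    "render_sheet",
    "make_classifier_dataset",
]

_VALID_DISTRACTORS = frozenset({"color_chart", "barcode", "label", "ruler"})


class LayoutError(RuntimeError):
    """Requested leaves could not be placed on the sheet within the retry budget."""


@dataclass
class LeafShape:
    """A single leaf blade as a closed polygon in sheet pixel coordinates.

    outline is an (N, 2) array of (x, y) vertices; category is one of
    ``intact``, ``overlapping``, ``damaged``; damage_holes holds interior
    hole polygons (margin bites instead reshape the outline itself).
    """

    outline: np.ndarray
    category: str = "intact"
    petiole: np.ndarray | None = None
    damage_holes: list[np.ndarray] = field(default_factory=list)


@dataclass(frozen=True)
class SheetSpec:
    """Layout recipe for one synthetic sheet.

    Counts are leaves by category (each overlap pair contributes two
    ``overlapping`` leaves); min_gap is the minimum pixel distance enforced
    between distinct specimen items (intact leaves, pair unions, damaged
    leaves, stems).  The default canvas, 1536 x 2048, keeps the
    high-resolution-sheet / low-resolution-segmenter asymmetry of real
    digitization workflows while staying fast to render.
    """

    width: int = 1536
    height: int = 2048
    n_intact: int = 3
    n_overlap_pairs: int = 1
    n_damaged: int = 1
    n_stems: int = 2
    min_gap: int = 25
    distractors: tuple[str, ...] = ("color_chart", "barcode", "label")
    leaf_color: tuple[float, float, float] = (70.0, 115.0, 60.0)
    background_color: tuple[float, float, float] = (235.0, 228.0, 210.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("sheet dimensions must be positive")
        for name in ("n_intact", "n_overlap_pairs", "n_damaged", "n_stems", "min_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.distractors) - _VALID_DISTRACTORS
        if unknown:
            raise ValueError(f"unknown distractors: {sorted(unknown)}")


@dataclass
class InventoryLeaf:
    """Ground truth for one rendered leaf."""

    id: int
    category: str
    bbox: tuple[int, int, int, int]  # [x0, y0, x1, y1], half-open
    mask_crop: np.ndarray
    traits: dict[str, float]


@dataclass
class LeafInventory:
    leaves: list[InventoryLeaf]

    @property
    def n_intact_expected(self) -> int:
        return sum(1 for leaf in self.leaves if leaf.category == "intact")


@dataclass
class ClassifierDataset:
    """Labelled binary square silhouettes; label 1 = single intact leaf."""

    images: list[np.ndarray]
    labels: np.ndarray


# ---------------------------------------------------------------------------
# blade geometry


def sample_leaf_shape(
    length: float,
    width: float,
    rng_seed: int | np.random.Generator = 0,
    n_points: int = 200,
) -> LeafShape:
    """Sample a smooth closed blade outline with the given axis extents.

    The blade is a superellipse ``|2x/L|^e + |2y/W|^e = 1`` with exponent
    drawn from [1.6, 3.0], modulated by a low-order smooth radial wobble
    (< 3%) so margins are not perfectly analytic.  The outline is centered at
    the origin, unrotated, with axis-aligned extents equal to ``length`` and
    ``width``.  Identical seeds give bit-identical polygons.
    """
    if length <= 0 or width <= 0:
        raise ValueError(f"blade length and width must be positive, got {length} x {width}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    e = rng.uniform(1.6, 3.0)
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    cx = np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / e)
    cy = np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / e)
    # low-frequency margin wobble, zero-mean so extents stay honest
    k = rng.integers(3, 6)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    wobble = 1.0 + 0.025 * np.cos(k * t + phase)
    x = 0.5 * length * cx * wobble
    y = 0.5 * width * cy * wobble
    # renormalize so the axis-aligned extents match the request exactly
    x *= 0.5 * length / max(x.max(), -x.min())
    y *= 0.5 * width / max(y.max(), -y.min())
    return LeafShape(outline=np.column_stack([x, y]))


def _rasterize_outline(
    outline: np.ndarray, angle: float, center: tuple[float, float], shape: tuple[int, int]
) -> np.ndarray:
    """Rotate, translate and rasterize a blade outline onto a canvas."""
    c, s = np.cos(angle), np.sin(angle)
    rot = outline @ np.array([[c, s], [-s, c]])
    xs = rot[:, 0] + center[0]
    ys = rot[:, 1] + center[1]
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(ys, xs, shape=shape)
    mask[rr, cc] = True
    return mask


def _bite_margin(mask: np.ndarray, rng: np.random.Generator, n_bites: int) -> np.ndarray:
    """Remove disk-shaped bites centered on the blade margin.

    Emulates herbivory/mounting damage that destroys the outer margin.  Keeps
    the blade connected and at least half its original area; a bite that
    would disconnect it is re-drawn.
    """
    area0 = mask.sum()
    out = mask.copy()
    for _ in range(n_bites):
        for _attempt in range(20):
            boundary = out & ~ndimage.binary_erosion(out)
            by, bx = np.nonzero(boundary)
            if by.size == 0:
                return out
            i = rng.integers(by.size)
            # bite radius scales with blade size; deep enough to destroy the
            # local margin, shallow enough to keep the blade connected
            r = rng.uniform(0.10, 0.18) * np.sqrt(area0)
            trial = out.copy()
            rr, cc = draw_disk((by[i], bx[i]), r, shape=out.shape)
            trial[rr, cc] = False
            _, n = ndimage.label(trial, structure=np.ones((3, 3), bool))
            if n == 1 and trial.sum() >= 0.5 * area0:
                out = trial
                break
    return out


def _outline_from_mask(mask: np.ndarray) -> np.ndarray:
    """Largest closed contour of a mask as an (N, 2) (x, y) polygon."""
    contours = find_contours(mask.astype(float), 0.5)
    longest = max(contours, key=len)
    return np.column_stack([longest[:, 1], longest[:, 0]])


# ---------------------------------------------------------------------------
# sheet rendering

_MARGIN_TOP = 200
_MARGIN_BOTTOM = 260
_MAX_TRIES = 300


def _local_dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return mask
    return ndimage.maximum_filter(mask.astype(np.uint8), size=2 * radius + 1,
                                  mode="constant") > 0


class _Placer:
    """Rejection-samples item placements subject to the min-gap constraint."""

    def __init__(self, spec: SheetSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.shape = (spec.height, spec.width)
        self.blocked = np.zeros(self.shape, dtype=bool)
        self.y_range = (_MARGIN_TOP + spec.min_gap,
                        spec.height - _MARGIN_BOTTOM - spec.min_gap)
        self.x_range = (40 + spec.min_gap, spec.width - 40 - spec.min_gap)

    def _fits(self, mask: np.ndarray) -> bool:
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            return False
        if ys.min() < self.y_range[0] or ys.max() >= self.y_range[1]:
            return False
        if xs.min() < self.x_range[0] or xs.max() >= self.x_range[1]:
            return False
        return not (mask & self.blocked).any()

    def commit(self, mask: np.ndarray) -> None:
        ys, xs = np.nonzero(mask)
        g = self.spec.min_gap
        y0, y1 = max(0, ys.min() - g), min(self.shape[0], ys.max() + g + 1)
        x0, x1 = max(0, xs.min() - g), min(self.shape[1], xs.max() + g + 1)
        window = _local_dilate(mask[y0:y1, x0:x1], g)
        self.blocked[y0:y1, x0:x1] |= window

    def _random_blade(self) -> tuple[np.ndarray, tuple[float, float], float]:
        rng = self.rng
        length = rng.uniform(260.0, 420.0)
        aspect = rng.uniform(1.5, 4.0)
        shape = sample_leaf_shape(length, length / aspect, rng)
        angle = rng.uniform(0.0, np.pi)
        cy = rng.uniform(*self.y_range)
        cx = rng.uniform(*self.x_range)
        mask = _rasterize_outline(shape.outline, angle, (cx, cy), self.shape)
        return mask, (cx, cy), length

    def place_single(self) -> np.ndarray:
        for _ in range(_MAX_TRIES):
            mask, _, _ = self._random_blade()
            if self._fits(mask):
                return mask
        raise LayoutError("could not place a leaf; reduce counts or min_gap")

    def place_pair(self) -> tuple[np.ndarray, np.ndarray]:
        for _ in range(_MAX_TRIES):
            a, (cx, cy), length = self._random_blade()
            if not self._fits(a):
                continue
            theta = self.rng.uniform(0.0, 2.0 * np.pi)
            off = self.rng.uniform(0.30, 0.45) * length
            length_b = self.rng.uniform(260.0, 420.0)
            aspect_b = self.rng.uniform(1.5, 4.0)
            shape_b = sample_leaf_shape(length_b, length_b / aspect_b, self.rng)
            angle_b = self.rng.uniform(0.0, np.pi)
            center_b = (cx + off * np.cos(theta), cy + off * np.sin(theta))
            b = _rasterize_outline(shape_b.outline, angle_b, center_b, self.shape)
            if self._fits(b) and (a & b).any():
                return a, b
        raise LayoutError("could not place an overlapping pair")

    def place_damaged(self) -> np.ndarray:
        for _ in range(_MAX_TRIES):
            mask, _, _ = self._random_blade()
            if not self._fits(mask):
                continue
            bitten = _bite_margin(mask, self.rng, n_bites=int(self.rng.integers(2, 4)))
            if self._fits(bitten):
                return bitten
        raise LayoutError("could not place a damaged leaf")

    def place_stem(self) -> np.ndarray:
        for _ in range(_MAX_TRIES):
            length = self.rng.uniform(300.0, 550.0)
            width = self.rng.uniform(8.0, 14.0)
            half = np.array(
                [[-length / 2, -width / 2], [length / 2, -width / 2],
                 [length / 2, width / 2], [-length / 2, width / 2]]
            )
            angle = self.rng.uniform(0.0, np.pi)
            cy = self.rng.uniform(*self.y_range)
            cx = self.rng.uniform(*self.x_range)
            mask = _rasterize_outline(half, angle, (cx, cy), self.shape)
            if self._fits(mask):
                return mask
        raise LayoutError("could not place a stem")


def _draw_distractors(image: np.ndarray, spec: SheetSpec, rng: np.random.Generator) -> None:
    """Paint the non-plant sheet objects into the reserved margin bands."""
    h, w = spec.height, spec.width
    if "barcode" in spec.distractors:
        y0, x0 = 40, w - 360
        image[y0 : y0 + 110, x0 : x0 + 300] = (250, 250, 250)
        for i in range(28):
            bw = int(rng.integers(2, 8))
            x = x0 + 12 + i * 10
            if x + bw < x0 + 290:
                image[y0 + 15 : y0 + 95, x : x + bw] = (15, 15, 15)
    if "label" in spec.distractors:
        y0, x0 = h - 220, w - 520
        image[y0 : y0 + 180, x0 : x0 + 470] = (252, 250, 245)
        for i in range(6):
            y = y0 + 30 + i * 25
            line_w = int(rng.integers(220, 430))
            image[y : y + 6, x0 + 20 : x0 + 20 + line_w] = (40, 40, 45)
    if "color_chart" in spec.distractors:
        # saturated patches, deliberately excluding leaf-like greens
        palette = [
            (200, 40, 40), (40, 60, 200), (230, 200, 50), (200, 50, 180),
            (60, 190, 210), (245, 140, 30), (120, 70, 30), (230, 230, 230),
            (30, 30, 30), (150, 150, 150), (240, 120, 150), (90, 40, 120),
        ]
        y0, x0 = h - 220, 60
        for i, color in enumerate(palette):
            r, c = divmod(i, 6)
            yy, xx = y0 + 20 + r * 85, x0 + 20 + c * 85
            image[yy : yy + 75, xx : xx + 75] = color
    if "ruler" in spec.distractors:
        y0, x0 = 40, 60
        image[y0 : y0 + 70, x0 : x0 + 600] = (248, 246, 240)
        for i in range(60):
            tick_h = 40 if i % 10 == 0 else 22
            image[y0 + 5 : y0 + 5 + tick_h, x0 + 10 + i * 10 : x0 + 12 + i * 10] = (20, 20, 20)


def render_sheet(spec: SheetSpec) -> tuple[np.ndarray, np.ndarray, LeafInventory]:
    """Render a sheet and its ground truth.

    Returns ``(image, gt_mask, inventory)``: a uint8 RGB image, a boolean
    mask that is the union of all leaf rasters (stems and distractors
    excluded), and the per-leaf inventory.  Deterministic in ``spec``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    placer = _Placer(spec, rng)

    leaves: list[tuple[str, np.ndarray]] = []
    for _ in range(spec.n_intact):
        leaves.append(("intact", placer.place_single()))
        placer.commit(leaves[-1][1])
    for _ in range(spec.n_overlap_pairs):
        a, b = placer.place_pair()
        leaves.append(("overlapping", a))
        leaves.append(("overlapping", b))
        placer.commit(a | b)
    for _ in range(spec.n_damaged):
        leaves.append(("damaged", placer.place_damaged()))
        placer.commit(leaves[-1][1])
    stems = []
    for _ in range(spec.n_stems):
        stems.append(placer.place_stem())
        placer.commit(stems[-1])

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = spec.background_color
    image += rng.normal(0.0, 3.0, size=image.shape)

    stem_color = np.array([135.0, 70.0, 35.0])
    for stem in stems:
        image[stem] = stem_color + rng.normal(0.0, 2.0, 3)

    gt_mask = np.zeros((h, w), dtype=bool)
    records: list[InventoryLeaf] = []
    for leaf_id, (category, mask) in enumerate(leaves):
        # dried leaves vary mostly in lightness, far less in hue: scale the
        # whole color, then add a small independent per-channel jitter
        color = np.asarray(spec.leaf_color) * rng.uniform(0.85, 1.15) + rng.normal(0.0, 4.0, 3)
        image[mask] = color
        image[mask] += rng.normal(0.0, 2.5, size=(int(mask.sum()), 3))
        gt_mask |= mask
        ys, xs = np.nonzero(mask)
        bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        crop = mask[bbox[1] : bbox[3], bbox[0] : bbox[2]].copy()
        records.append(
            InventoryLeaf(
                id=leaf_id,
                category=category,
                bbox=bbox,
                mask_crop=crop,
                traits=compute_traits(crop),
            )
        )

    image_u8 = np.clip(image, 0, 255).astype(np.uint8)
    _draw_distractors(image_u8, spec, rng)
    return image_u8, gt_mask, LeafInventory(leaves=records)


# ---------------------------------------------------------------------------
# classifier training data

_SIL_SIZE = 300


def _canvas_blade(rng: np.random.Generator, size: int, scale: tuple[float, float] = (0.45, 0.85)):
    length = rng.uniform(*scale) * size
    aspect = rng.uniform(1.5, 4.0)
    shape = sample_leaf_shape(length, length / aspect, rng)
    angle = rng.uniform(0.0, np.pi)
    cx = rng.uniform(0.35, 0.65) * size
    cy = rng.uniform(0.35, 0.65) * size
    return _rasterize_outline(shape.outline, angle, (cx, cy), (size, size)), (cx, cy), length, angle


def _positive_silhouette(rng: np.random.Generator, size: int) -> np.ndarray:
    """Single intact blade; interior damage is irrelevant after hole filling."""
    mask, _, _, _ = _canvas_blade(rng, size)
    if rng.uniform() < 0.3:
        # punch interior holes, then fill them — the classifier sees filled
        # silhouettes, so damaged-but-recognizable-margin leaves are positives
        for _ in range(int(rng.integers(1, 3))):
            ys, xs = np.nonzero(ndimage.binary_erosion(mask, iterations=8))
            if ys.size:
                i = rng.integers(ys.size)
                rr, cc = draw_disk((ys[i], xs[i]), rng.uniform(5, 15), shape=mask.shape)
                mask[rr, cc] = False
        mask = ndimage.binary_fill_holes(mask)
    return mask


def _negative_overlap(rng: np.random.Generator, size: int) -> np.ndarray:
    for _ in range(50):
        a, (cx, cy), length, angle_a = _canvas_blade(rng, size, scale=(0.35, 0.6))
        theta = rng.uniform(0.0, 2.0 * np.pi)
        off = rng.uniform(0.3, 0.5) * length
        length_b = rng.uniform(0.35, 0.6) * size
        shape_b = sample_leaf_shape(length_b, length_b / rng.uniform(1.5, 4.0), rng)
        angle_b = angle_a + rng.uniform(0.35, np.pi / 2) * rng.choice([-1.0, 1.0])
        b = _rasterize_outline(
            shape_b.outline, angle_b, (cx + off * np.cos(theta), cy + off * np.sin(theta)),
            (size, size),
        )
        union = a | b
        if (a & b).any() and not _touches_border(union):
            return union
    return a | b  # pragma: no cover - fallback after exhausted retries


def _negative_partial(rng: np.random.Generator, size: int) -> np.ndarray:
    """A blade whose margin is destroyed: straight clip or deep bites."""
    mask, _, _, _ = _canvas_blade(rng, size)
    if rng.uniform() < 0.5:
        # straight clip removing 25-45% of the blade, as if cut off at an
        # image border or hidden under mounting tape
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        theta = rng.uniform(0.0, 2.0 * np.pi)
        n = np.array([np.cos(theta), np.sin(theta)])
        proj = (ys - cy) * n[0] + (xs - cx) * n[1]
        cut = np.quantile(proj, rng.uniform(0.55, 0.75))
        keep = np.zeros_like(mask)
        keep[ys[proj <= cut], xs[proj <= cut]] = True
        lab, nlab = ndimage.label(keep, structure=np.ones((3, 3), bool))
        if nlab > 1:
            sizes = ndimage.sum_labels(keep, lab, index=range(1, nlab + 1))
            keep = lab == (1 + int(np.argmax(sizes)))
        return keep
    return _bite_margin(mask, rng, n_bites=int(rng.integers(2, 4)))


def _negative_stem(rng: np.random.Generator, size: int) -> np.ndarray:
    """A blade with a stem attached — or, occasionally, a bare stem sliver,
    as produced when segmentation picks up a stem fragment on its own."""
    mask, (cx, cy), length, angle = _canvas_blade(rng, size, scale=(0.35, 0.6))
    stem_len = rng.uniform(0.8, 1.4) * length
    stem_w = rng.uniform(4.0, 8.0)
    rect = np.array(
        [[0, -stem_w / 2], [stem_len, -stem_w / 2], [stem_len, stem_w / 2], [0, stem_w / 2]]
    )
    stem = _rasterize_outline(rect, angle + rng.normal(0.0, 0.2), (cx, cy), (size, size))
    if rng.uniform() < 0.25:
        return stem
    return mask | stem


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def make_classifier_dataset(
    n_pos: int, n_neg: int, rng_seed: int = 0, size: int = _SIL_SIZE
) -> ClassifierDataset:
    """Build a labelled set of binary square silhouettes for filter training.

    Positives are single intact blades (damaged-but-recognizable-margin cases
    reduce to these once interior holes are filled).  Negatives cycle through
    the three failure modes the filter must reject: unions of two overlapping
    blades, partial blades with a destroyed margin, and stem-attached blobs.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("class counts must be >= 0")
    rng = np.random.default_rng(rng_seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    for _ in range(n_pos):
        images.append(_positive_silhouette(rng, size).astype(np.uint8))
        labels.append(1)
    neg_makers = (_negative_overlap, _negative_partial, _negative_stem)
    for i in range(n_neg):
        images.append(neg_makers[i % 3](rng, size).astype(np.uint8))
        labels.append(0)
    return ClassifierDataset(images=images, labels=np.asarray(labels, dtype=int))
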