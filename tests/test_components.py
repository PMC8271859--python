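"""Connected-component labelling and candidate extraction."""

from collections import deque

import numpy as np
import pytest

from herbleaf import extract_components, label_components
from herbleaf.synthetic import _rasterize_outline, sample_leaf_shape


def bfs_label_oracle(mask: np.ndarray, connectivity: int = 8):
    """Independent breadth-first-search labelling for cross-checking."""
    mask = mask > 0
    h, w = mask.shape
    if connectivity == 8:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((h, w), dtype=int)
    areas = []
    next_label = 0
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or labels[y, x]:
                continue
            next_label += 1
            queue = deque([(y, x)])
            labels[y, x] = next_label
            area = 0
            while queue:
                cy, cx = queue.popleft()
                area += 1
                for dy, dx in steps:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not labels[ny, nx]:
                        labels[ny, nx] = next_label
                        queue.append((ny, nx))
            areas.append(area)
    return next_label, sorted(areas)


class TestLabelComponents:
    def test_two_disjoint_blocks(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        _, areas, bboxes = label_components(mask)
        assert sorted(areas.tolist()) == [9, 9]
        assert (1, 1, 4, 4) in bboxes and (6, 6, 9, 9) in bboxes

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, connectivity=8)[1]) == 1
        assert len(label_components(mask, connectivity=4)[1]) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_agrees_with_bfs_oracle(self, connectivity):
        rng = np.random.default_rng(0)
        for _ in range(30):
            mask = rng.uniform(size=(20, 20)) < 0.4
            _, areas, _ = label_components(mask, connectivity=connectivity)
            n_oracle, areas_oracle = bfs_label_oracle(mask, connectivity)
            assert len(areas) == n_oracle
            assert sorted(areas.tolist()) == areas_oracle

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError):
            label_components(np.zeros((3, 3), dtype=bool), connectivity=6)


def _block_mask(shape, y0, x0, h, w):
    mask = np.zeros(shape, dtype=bool)
    mask[y0 : y0 + h, x0 : x0 + w] = True
    return mask


class TestExtractComponents:
    def test_area_gate_is_strict(self):
        """A component of exactly min_area is excluded; min_area + 1 kept."""
        shape = (200, 200)
        mask = _block_mask(shape, 10, 10, 25, 40)  # area 1000 -> excluded
        mask |= _block_mask(shape, 100, 10, 13, 77)  # area 1001 -> kept
        image = np.zeros(shape + (3,), dtype=np.uint8)
        cands = extract_components(image, mask, min_area=1000)
        assert len(cands) == 1
        assert cands[0].area == 1001

    def test_all_zero_mask_gives_no_candidates(self):
        image = np.zeros((100, 100, 3), dtype=np.uint8)
        assert extract_components(image, np.zeros((100, 100), dtype=bool)) == []

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_components(
                np.zeros((50, 50, 3), dtype=np.uint8), np.zeros((60, 60), dtype=bool)
            )

    def test_nearby_leaf_erased_from_crop(self):
        """Two diagonal blades with overlapping bounding boxes but rasters
        >= 25 px apart: each crop must contain no pixel of the other."""
        shape = (600, 600)
        blade = sample_leaf_shape(300, 80, rng_seed=1)
        mask_a = _rasterize_outline(blade.outline, np.pi / 4, (220, 280), shape)
        mask_b = _rasterize_outline(blade.outline, np.pi / 4, (380, 280), shape)
        assert not (mask_a & mask_b).any()
        # bounding boxes overlap even though the rasters are well separated
        ya, xa = np.nonzero(mask_a)
        yb, xb = np.nonzero(mask_b)
        assert xa.max() > xb.min() and ya.max() > yb.min()
        image = np.full(shape + (3,), 255, dtype=np.uint8)
        image[mask_a] = (60, 110, 50)
        image[mask_b] = (60, 110, 50)
        cands = extract_components(image, mask_a | mask_b, min_area=1000,
                                   component_dilation=10)
        assert len(cands) == 2
        for cand, other in zip(cands, [mask_b, mask_a]):
            x0, y0, x1, y1 = cand.bbox
            non_white = (cand.image_crop != 255).any(axis=2)
            assert not (non_white & other[y0:y1, x0:x1]).any()

    def test_candidates_disjoint_and_cover_large_components(self):
        rng = np.random.default_rng(7)
        mask = rng.uniform(size=(120, 120)) < 0.46
        image = np.zeros((120, 120, 3), dtype=np.uint8)
        cands = extract_components(image, mask, min_area=30, component_dilation=3)
        union = np.zeros_like(mask)
        covered = 0
        for cand in cands:
            x0, y0, x1, y1 = cand.bbox
            assert not (union[y0:y1, x0:x1] & cand.mask_crop).any()
            union[y0:y1, x0:x1] |= cand.mask_crop
            covered += cand.area
        _, areas, _ = label_components(mask)
        assert covered == sum(a for a in areas if a > 30)
        assert union.sum() == covered

    @pytest.mark.parametrize("mode", ["radius", "iterative"])
    def test_dilation_modes_agree_for_square_elements(self, mode):
        shape = (80, 80)
        mask = _block_mask(shape, 30, 30, 20, 20)
        image = np.full(shape + (3,), 255, dtype=np.uint8)
        image[mask] = (0, 128, 0)
        cands = extract_components(image, mask, min_area=100, component_dilation=5,
                                   dilation_mode=mode)
        assert len(cands) == 1
        assert cands[0].bbox == (30, 30, 50, 50)
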