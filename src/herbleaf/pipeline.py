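"""End-to-end orchestration: segment -> clean mask -> extract -> filter -> traits.

The pipeline is a pure composition of the stage functions; running the
stages by hand with the same configuration gives identical results.  Sheets
in a batch are isolated: a failure on one sheet is recorded in its report
entry and the rest of the batch continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from imageio.v3 import imread, imwrite

from herbleaf.components import extract_components
from herbleaf.leaf_filter import ClassifierModel, filter_individual_leaves
from herbleaf.postprocess import PostprocessParams, postprocess_mask
from herbleaf.segmentation import (
    ChromaParams,
    SegmentationResult,
    load_external_mask,
    reference_chroma_segmenter,
)
from herbleaf.traits import TRAIT_NAMES, compute_traits

__all__ = ["PipelineConfig", "SheetResult", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    backend is ``"chroma"`` (built-in color segmenter) or ``"file"`` (load a
    per-sheet mask produced by an external model; supply ``mask_paths``
    aligned with the image list).  All remaining fields mirror the stage
    parameters.  Inference is deterministic; ``seed`` is recorded for
    provenance and used only by seeded stages (e.g. classifier training done
    elsewhere).
    """

    backend: str = "chroma"
    chroma: ChromaParams = field(default_factory=ChromaParams)
    postprocess: PostprocessParams = field(default_factory=PostprocessParams)
    min_area: int = 1000
    component_dilation: int = 10
    dilation_mode: str = "radius"
    model: ClassifierModel | None = None
    mask_paths: list[str | Path] | None = None
    seed: int = 0

    def describe(self) -> dict:
        return {
            "backend": self.backend,
            "working_resolution": self.chroma.working_resolution,
            "dilation_kernel": self.postprocess.dilation_kernel,
            "min_area": self.min_area,
            "component_dilation": self.component_dilation,
            "dilation_mode": self.dilation_mode,
            "decision_threshold": self.model.decision_threshold if self.model else None,
            "seed": self.seed,
        }


@dataclass
class SheetResult:
    name: str
    ok: bool
    n_candidates: int = 0
    n_kept: int = 0
    candidates: list = field(default_factory=list)
    kept: list = field(default_factory=list)
    traits: pd.DataFrame | None = None
    clean_mask: np.ndarray | None = None
    error: str | None = None


@dataclass
class PipelineReport:
    sheets: list[SheetResult]
    config: dict

    @property
    def n_failed(self) -> int:
        return sum(1 for s in self.sheets if not s.ok)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "sheets": [
                {
                    "name": s.name,
                    "ok": s.ok,
                    "n_candidates": s.n_candidates,
                    "n_kept": s.n_kept,
                    "kept_ids": [c.id for c in s.kept],
                    "error": s.error,
                }
                for s in self.sheets
            ],
        }


def _segment(image: np.ndarray, config: PipelineConfig, index: int) -> SegmentationResult:
    if config.backend == "chroma":
        return reference_chroma_segmenter(image, config.chroma)
    if config.backend == "file":
        if config.mask_paths is None or index >= len(config.mask_paths):
            raise ValueError("file backend requires mask_paths aligned with images")
        return load_external_mask(config.mask_paths[index])
    raise ValueError(f"unknown backend {config.backend!r}")


def process_sheet(
    image: np.ndarray, config: PipelineConfig, name: str = "sheet", index: int = 0
) -> SheetResult:
    """Run all three phases on one sheet image."""
    if config.model is None:
        raise ValueError("pipeline requires a trained classifier model")
    seg = _segment(image, config, index)
    clean = postprocess_mask(image, seg, config.postprocess)
    cands = extract_components(
        image, clean,
        min_area=config.min_area,
        component_dilation=config.component_dilation,
        dilation_mode=config.dilation_mode,
    )
    kept = filter_individual_leaves(cands, config.model)
    rows = {c.id: compute_traits(c.mask_crop) for c in kept}
    traits = pd.DataFrame.from_dict(rows, orient="index", columns=list(TRAIT_NAMES))
    traits.index.name = "leaf_id"
    return SheetResult(
        name=name, ok=True,
        n_candidates=len(cands), n_kept=len(kept),
        candidates=cands, kept=kept, traits=traits, clean_mask=clean,
    )


def run_pipeline(
    images: list[np.ndarray | str | Path],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Process a batch of sheets; per-sheet failures do not abort the batch.

    ``images`` may mix in-memory RGB arrays and file paths.  When ``out_dir``
    is given, each sheet gets a sub-directory with ``clean_mask.png``,
    ``cand_<id>.png`` / ``cand_<id>_mask.png``, ``kept.json`` and
    ``traits.csv``, plus a batch-level ``report.json``.
    """
    results: list[SheetResult] = []
    for i, item in enumerate(images):
        if isinstance(item, (str, Path)):
            name = Path(item).stem
            try:
                image = imread(item)
            except Exception as exc:  # noqa: BLE001 - per-sheet isolation
                results.append(SheetResult(name=name, ok=False, error=str(exc)))
                continue
        else:
            name, image = f"sheet_{i:03d}", np.asarray(item)
        try:
            results.append(process_sheet(image, config, name=name, index=i))
        except Exception as exc:  # noqa: BLE001 - per-sheet isolation
            results.append(SheetResult(name=name, ok=False, error=str(exc)))

    report = PipelineReport(sheets=results, config=config.describe())
    if out_dir is not None:
        _write_outputs(report, Path(out_dir))
    return report


def _write_outputs(report: PipelineReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for sheet in report.sheets:
        if not sheet.ok:
            continue
        sdir = out_dir / sheet.name
        sdir.mkdir(parents=True, exist_ok=True)
        imwrite(sdir / "clean_mask.png", (sheet.clean_mask.astype(np.uint8) * 255))
        for cand in sheet.candidates:
            imwrite(sdir / f"cand_{cand.id}.png", cand.image_crop)
            imwrite(sdir / f"cand_{cand.id}_mask.png", cand.mask_crop.astype(np.uint8) * 255)
        with open(sdir / "kept.json", "w") as fh:
            json.dump(
                [
                    {"id": c.id, "bbox": list(c.bbox), "area": c.area}
                    for c in sheet.kept
                ],
                fh, indent=2,
            )
        sheet.traits.to_csv(sdir / "traits.csv")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
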