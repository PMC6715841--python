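"""Virtual labeling: classifier predictions painted onto the image.

A classifier trained on isolated populations is applied to each cell of
an extracted mixed-population catalog, and the predicted class of every
cell is rendered as a color over the cell's region on a maximum-
intensity projection of the reflection stack — tag-free annotation of
intact cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

from .catalog import HyperspectrumCatalog
from .classify import ClassifierModel
from .segmentation import LabelMap, match_regions_to_truth, max_intensity_projection

# class 0 blue, class 1 red (the conventional two-species palette), then extras
DEFAULT_PALETTE = (
    (60, 80, 255),
    (255, 60, 60),
    (60, 200, 80),
    (240, 200, 40),
    (200, 80, 220),
    (80, 220, 220),
)


@dataclass
class AnnotationResult:
    cell_ids: list[int]
    centroids: list[tuple[float, ...]]
    predicted: list[str]
    scores: np.ndarray  # (n, K) per-class decision scores
    classes: list[str]
    overlay: np.ndarray | None = None  # (y, x, 3) uint8
    palette: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def as_table(self) -> list[dict]:
        return [
            {"cell_id": cid, "centroid": c, "predicted": p}
            for cid, c, p in zip(self.cell_ids, self.centroids, self.predicted)
        ]


def _overlay_image(
    reflection, labelmap: LabelMap, predictions: dict[int, str],
    palette: dict[str, tuple[int, int, int]], alpha: float = 0.55,
) -> np.ndarray:
    mip = max_intensity_projection(reflection)
    lo, hi = mip.min(), mip.max()
    gray = np.zeros_like(mip) if hi == lo else (mip - lo) / (hi - lo)
    rgb = np.repeat((gray * 255.0)[:, :, None], 3, axis=2)
    labels2d = labelmap.labels if labelmap.labels.ndim == 2 else labelmap.labels.max(axis=0)
    for cell_id, cls in predictions.items():
        mask = labels2d == cell_id
        color = np.array(palette[cls], dtype=float)
        rgb[mask] = (1.0 - alpha) * rgb[mask] + alpha * color
    return np.clip(rgb, 0, 255).astype(np.uint8)


def annotate_population(
    model: ClassifierModel,
    catalog: HyperspectrumCatalog,
    labelmap: LabelMap | None = None,
    reflection=None,
    palette=DEFAULT_PALETTE,
) -> AnnotationResult:
    """Predict a class for every cell and (optionally) render the overlay.

    The model's feature settings travel with it, so the catalog must
    have been extracted compatibly; every catalog cell receives exactly
    one predicted class.  With a label map and reflection stack, an RGB
    overlay is rendered: each labeled region recolored by its class
    over the reflection MIP.
    """
    predicted = model.predict(catalog)
    scores = model.predict_scores(catalog)
    class_palette = {cls: tuple(palette[i % len(palette)]) for i, cls in enumerate(model.classes)}
    overlay = None
    if labelmap is not None and reflection is not None:
        id_to_pred = {e.cell_id: p for e, p in zip(catalog.entries, predicted)}
        overlay = _overlay_image(reflection, labelmap, id_to_pred, class_palette)
    return AnnotationResult(
        [e.cell_id for e in catalog.entries],
        [e.centroid for e in catalog.entries],
        list(predicted), np.asarray(scores), list(model.classes),
        overlay, class_palette,
    )


def save_overlay(result: AnnotationResult, path) -> None:
    if result.overlay is None:
        raise ValueError("annotation result has no rendered overlay")
    iio.imwrite(path, result.overlay)


def annotation_accuracy(
    result: AnnotationResult,
    truth,
    labelmap: LabelMap,
    tol_px: float = 3.0,
    config=None,
) -> tuple[float, int]:
    """Fraction of truth-matched cells annotated with their true class.

    Detected regions are greedily matched one-to-one to true cell
    centers within ``tol_px``; unmatched (missed) cells are excluded
    from the denominator and their count is returned alongside.
    """
    mapping = match_regions_to_truth(labelmap, truth, tol_px, config)
    if not mapping:
        raise ValueError("no detected cells matched the ground truth")
    true_class = {c.cell_id: c.class_name for c in truth.cells}
    pred_by_id = dict(zip(result.cell_ids, result.predicted))
    correct = 0
    matched = 0
    for det_id, true_id in mapping.items():
        if det_id not in pred_by_id:
            continue
        matched += 1
        if pred_by_id[det_id] == true_class[true_id]:
            correct += 1
    if matched == 0:
        raise ValueError("matched regions carry no predictions")
    n_missed = len(truth.cells) - matched
    return correct / matched, n_missed
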