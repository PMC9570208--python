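"""Per-image RBC segmentation with debris and aggregate filtering.

Default mode is unsupervised: Otsu threshold on the summed channels,
hole filling, 8-connected labelling, then per-object filters on projected
area and solidity that reject debris (too small), aggregates (too large or
ragged) and optionally border-touching objects. Every rejection is logged
per object. An opt-in supervised mode replaces the Otsu foreground with a
random-forest pixel classifier trained on sparse user labels over
multi-scale Gaussian intensity and gradient-magnitude features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from sklearn.ensemble import RandomForestClassifier

from .io import DualChannelImage

logger = logging.getLogger("laurdangp")

__all__ = ["CellMaskSet", "segment_cells", "train_pixel_classifier", "PixelClassifier"]

#: classifier label conventions for sparse training rasters
CLASS_CELL, CLASS_BACKGROUND, CLASS_DEBRIS = 1, 2, 3


@dataclass
class CellMaskSet:
    """Labelled RBC regions for one image after filtering.

    ``labels`` uses contiguous positive integers 1..``n_cells`` with 0 as
    background. ``filter_log`` records one row per candidate object with
    its measurements and, for rejected objects, the reason.
    """

    labels: np.ndarray
    n_cells: int
    filter_log: pd.DataFrame

    def __post_init__(self) -> None:
        present = np.unique(self.labels[self.labels > 0])
        expected = np.arange(1, self.n_cells + 1)
        if not np.array_equal(present, expected):
            raise ValueError("labels must be contiguous 1..n_cells")


def segment_cells(
    image: DualChannelImage,
    min_area_um2: float = 20.0,
    max_area_um2: float = 120.0,
    min_solidity: float = 0.85,
    exclude_border: bool = False,
    classifier: "PixelClassifier | None" = None,
) -> CellMaskSet:
    """Segment RBC from a dual-channel image.

    Foreground comes from Otsu on blue+green (or from ``classifier`` when
    given); objects failing the area window or solidity floor are rejected
    as debris/aggregates and logged. A blank image yields an empty mask
    with a warning, not an error.
    """
    total = image.blue + image.green
    if classifier is not None:
        fg = classifier.predict(image) == CLASS_CELL
    else:
        if np.ptp(total) == 0:
            logger.warning("blank image (no intensity variation): empty cell mask")
            return CellMaskSet(
                labels=np.zeros(total.shape, dtype=np.int32),
                n_cells=0,
                filter_log=_empty_log(),
            )
        fg = total > threshold_otsu(total)
    fg = ndi.binary_fill_holes(fg)
    raw_labels, n_raw = ndi.label(fg, structure=ndi.generate_binary_structure(2, 2))
    if n_raw == 0:
        logger.warning("no foreground objects found: empty cell mask")
        return CellMaskSet(
            labels=np.zeros(total.shape, dtype=np.int32), n_cells=0, filter_log=_empty_log()
        )
    px_area = image.pixel_size_um**2
    rows = []
    keep: list[int] = []
    h, w = total.shape
    for prop in regionprops(raw_labels):
        area_um2 = prop.area * px_area
        reason = ""
        if area_um2 < min_area_um2:
            reason = "below min_area"
        elif area_um2 > max_area_um2:
            reason = "above max_area"
        elif prop.solidity < min_solidity:
            reason = "low solidity"
        elif exclude_border:
            minr, minc, maxr, maxc = prop.bbox
            if minr == 0 or minc == 0 or maxr == h or maxc == w:
                reason = "touches border"
        rows.append(
            {
                "object_id": prop.label,
                "centroid_y": prop.centroid[0],
                "centroid_x": prop.centroid[1],
                "area_um2": area_um2,
                "solidity": prop.solidity,
                "kept": reason == "",
                "reason": reason,
            }
        )
        if reason == "":
            keep.append(prop.label)
    relabel = np.zeros(n_raw + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        relabel[old] = new
    labels = relabel[raw_labels]
    log = pd.DataFrame(rows)
    n_rej = int((~log["kept"]).sum())
    if n_rej:
        logger.info("segment_cells: rejected %d object(s): %s",
                    n_rej, log.loc[~log["kept"], "reason"].value_counts().to_dict())
    return CellMaskSet(labels=labels, n_cells=len(keep), filter_log=log)


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["object_id", "centroid_y", "centroid_x", "area_um2", "solidity", "kept", "reason"]
    )


def _features(image: DualChannelImage, sigmas: Sequence[float] = (1.0, 2.0, 4.0)) -> np.ndarray:
    """Per-pixel feature stack: smoothed intensity + gradient magnitude per scale."""
    total = image.blue + image.green
    feats = []
    for s in sigmas:
        sm = ndi.gaussian_filter(total, s)
        feats.append(sm)
        feats.append(ndi.gaussian_gradient_magnitude(total, s))
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifier:
    """Random-forest pixel classifier over multi-scale features (opt-in mode)."""

    forest: RandomForestClassifier
    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0)

    def predict(self, image: DualChannelImage) -> np.ndarray:
        feats = _features(image, self.sigmas)
        pred = self.forest.predict(feats.reshape(-1, feats.shape[-1]))
        return pred.reshape(image.shape).astype(np.int32)


def train_pixel_classifier(
    labeled_examples: Sequence[tuple[DualChannelImage, np.ndarray]],
    sigmas: Sequence[float] = (1.0, 2.0, 4.0),
    n_estimators: int = 50,
    random_state: int = 0,
) -> PixelClassifier:
    """Fit the supervised pixel classifier from sparse label rasters.

    Each example pairs an image with a raster where 0 = unlabeled,
    1 = cell, 2 = background, 3 = debris. At least two distinct classes
    must be labeled.
    """
    X_parts, y_parts = [], []
    for image, labels in labeled_examples:
        labels = np.asarray(labels)
        if labels.shape != image.shape:
            raise ValueError("label raster shape must match image shape")
        sel = labels > 0
        if sel.any():
            feats = _features(image, sigmas)
            X_parts.append(feats[sel])
            y_parts.append(labels[sel])
    if not X_parts:
        raise ValueError("no labeled pixels provided")
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    if len(np.unique(y)) < 2:
        raise ValueError("need labeled pixels from at least 2 classes")
    forest = RandomForestClassifier(
        n_estimators=n_estimators, random_state=random_state, n_jobs=1
    )
    forest.fit(X, y)
    return PixelClassifier(forest=forest, sigmas=tuple(sigmas))
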