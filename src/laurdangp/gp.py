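"""Per-pixel generalized polarization (GP) maps and their aggregation.

GP is the ratiometric index

    GP = (I_blue - G * I_green) / (I_blue + G * I_green)

with I_blue/I_green the two emission-channel intensities and G an
instrument calibration factor applied to the green channel. GP lies in
[-1, 1] for any non-negative intensities and positive G; higher GP means a
more ordered, less fluid membrane environment. Pixels whose denominator
does not exceed a floor are left undefined rather than assigned a
noise-dominated value, and undefined pixels are excluded from every
downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .io import DualChannelImage

__all__ = ["GPMap", "SubjectSummary", "compute_gp", "calibrate_g", "subject_gp_summary"]


@dataclass
class GPMap:
    """Per-pixel GP raster with an undefined-pixel mask.

    ``gp`` is NaN where ``defined`` is False. ``G`` records the calibration
    factor used; ``pixel_size_um`` and ``meta`` are carried over from the
    source image.
    """

    gp: np.ndarray
    defined: np.ndarray
    G: float
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.gp[self.defined]
        if vals.size and (np.abs(vals) > 1.0 + 1e-12).any():
            raise ValueError("defined GP values must lie in [-1, 1]")


def compute_gp(image: DualChannelImage, G: float = 1.0, denom_floor: float = 1.0) -> GPMap:
    """Apply the GP formula pixelwise.

    Pixels with ``blue + G*green <= denom_floor`` are flagged undefined.
    Negative intensities indicate upstream corruption and raise.
    """
    if not (G > 0):
        raise ValueError("G must be positive")
    blue, green = image.blue, image.green
    if (blue < 0).any() or (green < 0).any():
        raise ValueError("negative intensities in input image")
    denom = blue + G * green
    defined = denom > denom_floor
    gp = np.full(blue.shape, np.nan)
    np.divide(blue - G * green, denom, out=gp, where=defined)
    return GPMap(
        gp=gp,
        defined=defined,
        G=G,
        pixel_size_um=image.pixel_size_um,
        meta=dict(image.meta),
    )


def calibrate_g(
    ref_image: DualChannelImage,
    gp_ref: float,
    mask: np.ndarray | None = None,
) -> float:
    """Calibration factor G from a reference of known GP.

    Solves GP(reference) = ``gp_ref`` for G over the reference ``mask``
    (default: pixels with positive intensity in both channels):

        G = (mean I_blue / mean I_green) * (1 - gp_ref) / (1 + gp_ref)
    """
    if not (abs(gp_ref) < 1):
        raise ValueError("gp_ref = +/-1 is degenerate; need |gp_ref| < 1")
    if mask is None:
        mask = (ref_image.blue > 0) & (ref_image.green > 0)
    if not mask.any():
        raise ValueError("empty reference mask")
    mean_blue = float(ref_image.blue[mask].mean())
    mean_green = float(ref_image.green[mask].mean())
    if mean_green <= 0 or mean_blue <= 0:
        raise ValueError("reference pixels must have positive mean intensities")
    return (mean_blue / mean_green) * (1.0 - gp_ref) / (1.0 + gp_ref)


@dataclass
class SubjectSummary:
    """Per-subject GP aggregate (the study's per-patient fluidity index).

    ``mean_gp``/``sd_gp`` pool all defined pixels inside cell masks across
    the subject's images; ``mean_gp_cellwise`` averages per-cell means
    instead (both aggregations are reported because the choice is a
    genuine analysis degree of freedom).
    """

    subject_id: str
    group: str
    mean_gp: float
    sd_gp: float
    n_cells: int
    n_pixels: int
    mean_gp_cellwise: float
    cell_means: pd.DataFrame  # columns: image_index, cell_id, mean_gp, n_pixels

    def __post_init__(self) -> None:
        if not (-1.0 <= self.mean_gp <= 1.0):
            raise ValueError("mean_gp out of [-1, 1]")
        if self.n_cells < 1:
            raise ValueError(f"subject {self.subject_id}: no cells to summarize")


def subject_gp_summary(
    gp_maps: Sequence[GPMap],
    masks: Sequence["np.ndarray | Any"],
    subject_id: str = "",
    group: str = "",
) -> SubjectSummary:
    """Pool GP over all defined pixels inside cell masks for one subject.

    ``masks`` may be label rasters or objects with a ``labels`` attribute
    (:class:`~laurdangp.segmentation.CellMaskSet`), aligned with
    ``gp_maps`` image by image.
    """
    if len(gp_maps) != len(masks):
        raise ValueError("gp_maps and masks must align image by image")
    pooled: list[np.ndarray] = []
    rows: list[dict[str, Any]] = []
    for i, (gpm, m) in enumerate(zip(gp_maps, masks)):
        labels = getattr(m, "labels", m)
        sel = gpm.defined & (labels > 0)
        pooled.append(gpm.gp[sel])
        for lab in np.unique(labels[labels > 0]):
            cell_sel = gpm.defined & (labels == lab)
            n = int(cell_sel.sum())
            if n == 0:
                continue
            rows.append(
                {
                    "image_index": i,
                    "cell_id": int(lab),
                    "mean_gp": float(gpm.gp[cell_sel].mean()),
                    "n_pixels": n,
                }
            )
    values = np.concatenate(pooled) if pooled else np.array([])
    if values.size == 0:
        raise ValueError(f"subject {subject_id!r}: zero defined pixels inside cell masks")
    cell_means = pd.DataFrame(rows, columns=["image_index", "cell_id", "mean_gp", "n_pixels"])
    return SubjectSummary(
        subject_id=subject_id,
        group=group,
        mean_gp=float(values.mean()),
        sd_gp=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        n_cells=len(cell_means),
        n_pixels=int(values.size),
        mean_gp_cellwise=float(cell_means["mean_gp"].mean()),
        cell_means=cell_means,
    )
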