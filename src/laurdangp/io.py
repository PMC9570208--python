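"""Raster and table I/O plus run configuration.

The pipeline's on-disk layout is deliberately plain: multi-channel 16-bit
TIFF for the dual-channel intensity images, single-channel TIFF for label
rasters, 32-bit float TIFF for GP maps, UTF-8 CSV for every table, and
YAML/JSON for configuration. The canonical study layout is::

    <root>/subjects.csv           # subject_id, group, optional covariates
    <root>/<subject_id>/<i>.tif   # dual-channel image i of that subject

All rasters are row-major with 0-based pixel indexing; lengths are kept in
pixels internally and converted to micrometres only when a measurement is
reported.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("laurdangp")

__all__ = [
    "DualChannelImage",
    "RunConfig",
    "read_dual_tiff",
    "write_dual_tiff",
    "read_label_tiff",
    "write_label_tiff",
    "write_gp_tiff",
    "write_table",
    "read_table",
]


@dataclass
class DualChannelImage:
    """Registered blue/green emission rasters for one field of view.

    Parameters
    ----------
    blue, green
        Intensity rasters in detector units (photons for synthetic data).
        Must share a shape and be finite and non-negative.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    meta
        Free-form metadata (subject id, group, image index, ...).
    """

    blue: np.ndarray
    green: np.ndarray
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.blue.shape != self.green.shape:
            raise ValueError(
                f"channel shapes differ: blue {self.blue.shape} vs green {self.green.shape}"
            )
        if self.blue.ndim != 2:
            raise ValueError("channels must be 2-D rasters")
        for name, arr in (("blue", self.blue), ("green", self.green)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} channel contains non-finite values")
            if (arr < 0).any():
                raise ValueError(f"{name} channel contains negative intensities")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


@dataclass
class RunConfig:
    """Pipeline configuration with the defaults used throughout.

    ``lc_percentile`` is the reference-stack percentile defining the
    liquid-crystalline threshold (the highest quartile, i.e. 75).
    ``G`` is the channel calibration factor of the GP formula.
    """

    G: float = 1.0
    lc_percentile: float = 75.0
    min_domain_px: int = 2
    connectivity: int = 8
    reference_group: str = "DM"
    reference_n_cells: int = 20
    pixel_size_um: float = 0.05
    denom_floor: float = 1.0
    min_area_um2: float = 20.0
    max_area_um2: float = 120.0
    min_solidity: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lc_percentile < 100):
            raise ValueError("lc_percentile must be in (0, 100)")
        if not (self.G > 0):
            raise ValueError("G must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Pixel size in µm from TIFF resolution tags, if present and sane."""
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" in tags and "ResolutionUnit" in tags:
        num, den = tags["XResolution"].value
        if num == 0:
            return None
        unit = tags["ResolutionUnit"].value  # 2 = inch, 3 = cm
        px_per_unit = num / den
        unit_um = {2: 25_400.0, 3: 10_000.0}.get(int(unit))
        if unit_um is None:
            return None
        return unit_um / px_per_unit
    return None


def read_dual_tiff(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    pixel_size_um: float | None = None,
    meta: Mapping[str, Any] | None = None,
) -> DualChannelImage:
    """Read a multi-channel TIFF into a :class:`DualChannelImage`.

    ``channel_map`` selects which planes are blue/green (default
    ``{"blue": 0, "green": 1}``). Pixel size is taken from the TIFF
    resolution tags when present, else from ``pixel_size_um``.
    """
    path = Path(path)
    if channel_map is None:
        channel_map = {"blue": 0, "green": 1}
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if data.ndim == 2:
        raise ValueError(f"{path}: single-channel file, need at least 2 channels")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a (channel, y, x) stack, got shape {data.shape}")
    # channel axis is the smallest one; tifffile yields (C, Y, X) for our writer
    n_chan = data.shape[0]
    for name in ("blue", "green"):
        if channel_map[name] >= n_chan:
            raise ValueError(
                f"{path}: channel_map asks for plane {channel_map[name]} "
                f"but file has {n_chan} channels"
            )
    px = tag_px if tag_px is not None else pixel_size_um
    if px is None:
        raise ValueError(f"{path}: no resolution tags and no pixel_size_um given")
    return DualChannelImage(
        blue=data[channel_map["blue"]],
        green=data[channel_map["green"]],
        pixel_size_um=float(px),
        meta=dict(meta or {}),
    )


def write_dual_tiff(path: str | Path, image: DualChannelImage) -> None:
    """Write a dual-channel 16-bit TIFF with µm resolution tags.

    Intensities are rounded and clipped to the uint16 range.
    """
    stack = np.stack([image.blue, image.green]).round().clip(0, 65535).astype(np.uint16)
    px_per_cm = 10_000.0 / image.pixel_size_um
    tifffile.imwrite(
        Path(path),
        stack,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"axes": "CYX"},
    )


def read_label_tiff(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(Path(path))
    if labels.ndim != 2:
        raise ValueError(f"{path}: label raster must be single-channel 2-D")
    return labels.astype(np.int32)


def write_label_tiff(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.int32))


def write_gp_tiff(path: str | Path, gp: np.ndarray, defined: np.ndarray) -> None:
    """GP map as 32-bit float TIFF plus an 8-bit defined-mask sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(gp, dtype=np.float32))
    mask_path = path.with_name(path.stem + "_defined" + path.suffix)
    tifffile.imwrite(mask_path, np.asarray(defined, dtype=np.uint8) * 255)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """CSV writer used for every pipeline table (UTF-8, header row, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(Path(path), index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), encoding="utf-8")
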