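"""Synthetic dual-channel Laurdan-like RBC images with known ground truth.

The generator emulates the study design of a ratiometric membrane-fluidity
experiment: each subject contributes five confocal fields of view with on
the order of a hundred red blood cells in total, each cell carrying a
two-phase generalized-polarization (GP) field — a disordered fluid
background phase and high-GP liquid-crystalline (LC) elliptical domains —
rendered into blue/green emission channels through the inverse of the GP
formula and degraded with per-channel Poisson photon noise.

Two properties of the construction matter downstream:

* Exact inversion: in the noise-free case, applying the GP formula with the
  true calibration factor recovers the planted GP field to machine
  precision on every stained pixel.
* Exact subject means: the fluid-phase GP of each cell is solved from the
  realized LC area fraction so that the cell's noise-free mean GP equals
  the group target plus the subject's offset. Group-level recovery error is
  therefore dominated by between-subject sampling, not rendering detail.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Sequence

import logging

import numpy as np
from scipy import ndimage as ndi

from .io import DualChannelImage

logger = logging.getLogger("laurdangp")

__all__ = [
    "GroupPreset",
    "GroundTruth",
    "group_presets",
    "make_cell_geometry",
    "make_domain_field",
    "render_dual_channel",
    "simulate_subject",
]

#: GP of the ordered (liquid-crystalline) phase, common to all groups.
GP_LC = 0.70
#: Background (unstained) photon level per channel.
DARK_LEVEL = 5.0
#: Default expected photons per stained pixel (blue + green, G = 1).
TOTAL_INTENSITY = 10_000.0
#: Default lateral sampling, µm per pixel. Sub-Nyquist sampling for a
#: 60x/1.4NA confocal (lateral resolution ~0.16 µm) so that the smallest
#: reported domains (~0.18 µm Feret) span several pixels.
PIXEL_SIZE_UM = 0.05


@dataclass(frozen=True)
class GroupPreset:
    """Simulation truth for one study group.

    ``mean_gp`` is the target per-subject mean GP; ``subject_sd_gp`` the
    between-subject SD of that mean. ``n_domains_per_cell`` is the Poisson
    mean of planted LC domains per cell; each domain is an ellipse with
    major axis ``domain_feret_um`` and axis ratio ``domain_elongation``.
    ``lc_area_fraction`` is the design LC area fraction implied by the
    domain load and cell size; together with ``mean_gp`` and ``mean_gp_lc``
    it fixes the nominal fluid-phase GP ``mean_gp_fluid``.
    """

    group_name: str
    mean_gp: float
    n_domains_per_cell: float
    domain_feret_um: float
    domain_elongation: float
    subject_sd_gp: float
    cell_radius_um: tuple[float, float]
    lc_area_fraction: float
    mean_gp_lc: float = GP_LC
    domain_circularity: float | None = None  # informational target

    def __post_init__(self) -> None:
        if not (-1.0 <= self.mean_gp <= 1.0 and -1.0 <= self.mean_gp_lc <= 1.0):
            raise ValueError("GP parameters must lie in [-1, 1]")
        if self.n_domains_per_cell < 0:
            raise ValueError("n_domains_per_cell must be >= 0")
        if self.domain_elongation < 1:
            raise ValueError("domain_elongation is major/minor, must be >= 1")
        if not (0 <= self.lc_area_fraction < 1):
            raise ValueError("lc_area_fraction must be in [0, 1)")
        if self.mean_gp_lc <= self.mean_gp_fluid:
            raise ValueError("mean_gp_lc must exceed mean_gp_fluid (LC is the high-GP phase)")

    @property
    def mean_gp_fluid(self) -> float:
        """Nominal fluid-phase GP solving the two-phase mixture for ``mean_gp``."""
        f = self.lc_area_fraction
        return (self.mean_gp - f * self.mean_gp_lc) / (1.0 - f)


@dataclass
class GroundTruth:
    """Planted truth for one rendered field of view."""

    cell_labels: np.ndarray
    domain_labels: np.ndarray
    true_gp_field: np.ndarray  # NaN outside cells
    preset: GroupPreset
    seed: int
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        inside = self.cell_labels > 0
        if (self.domain_labels > 0)[~inside].any():
            raise ValueError("domain labels extend outside cell labels")
        defined = np.isfinite(self.true_gp_field)
        if not np.array_equal(defined, inside):
            raise ValueError("true_gp_field must be finite exactly where cell_labels > 0")


def group_presets() -> dict[str, GroupPreset]:
    """Presets for the three study groups (CTRL, DM, DM_PAD).

    The group targets are the study's printed group means: subject mean GP
    0.534/0.519/0.501 with between-subject SD 0.018/0.007/0.026, LC-domain
    counts per cell 20.2/95.4/100.1, Feret diameters 1.028/0.245/0.183 µm
    and circularities 0.643/0.846/0.903. Domain elongations invert the
    analytic ellipse circularity against those circularity targets. Cell
    radii are set so the DM LC area fraction (~0.265) exceeds the upper
    quartile — a structural requirement for the 75th-percentile reference
    threshold to fall inside the ordered phase — while CTRL's large
    elongated domains remain packable without overlap.
    """
    return {
        "CTRL": GroupPreset(
            group_name="CTRL",
            mean_gp=0.534,
            n_domains_per_cell=20.2,
            domain_feret_um=1.028,
            domain_elongation=3.0,
            subject_sd_gp=0.018,
            cell_radius_um=(2.80, 2.90),
            lc_area_fraction=0.22,
            domain_circularity=0.643,
        ),
        "DM": GroupPreset(
            group_name="DM",
            mean_gp=0.519,
            n_domains_per_cell=95.4,
            domain_feret_um=0.245,
            domain_elongation=2.0,
            subject_sd_gp=0.007,
            cell_radius_um=(1.60, 1.67),
            lc_area_fraction=0.262,
            domain_circularity=0.846,
        ),
        "DM_PAD": GroupPreset(
            group_name="DM_PAD",
            mean_gp=0.501,
            n_domains_per_cell=100.1,
            domain_feret_um=0.183,
            domain_elongation=1.7,
            subject_sd_gp=0.026,
            cell_radius_um=(1.60, 1.67),
            lc_area_fraction=0.185,
            domain_circularity=0.903,
        ),
    }


def make_cell_geometry(
    n_cells: int,
    image_shape: tuple[int, int],
    radius_um: tuple[float, float],
    pixel_size_um: float = PIXEL_SIZE_UM,
    seed: int | np.random.Generator = 0,
    annulus_width_um: float | None = None,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Place ``n_cells`` non-overlapping discs, labelled 1..n_cells.

    Cells are filled discs by default; ``annulus_width_um`` switches to
    annular rims mimicking membrane-only staining. Positions are rejection
    sampled with a 2-px clearance; exhausting ``max_tries`` raises.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    r_lo, r_hi = (radius_um[0] / pixel_size_um, radius_um[1] / pixel_size_um)
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("radius range must be positive and ordered")
    h, w = image_shape
    if 2 * r_hi + 2 > min(h, w) and n_cells > 0:
        raise ValueError(f"cannot place cells of radius {r_hi:.1f} px in a {h}x{w} frame")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = np.zeros(image_shape, dtype=np.int32)
    centers: list[tuple[float, float, float]] = []  # (y, x, r)
    yy, xx = np.mgrid[0:h, 0:w]
    tries = 0
    for lab in range(1, n_cells + 1):
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"cannot place {n_cells} cells in a {h}x{w} frame "
                    f"(placed {lab - 1} after {max_tries} tries)"
                )
            r = rng.uniform(r_lo, r_hi)
            cy = rng.uniform(r + 1, h - r - 1)
            cx = rng.uniform(r + 1, w - r - 1)
            if all((cy - y0) ** 2 + (cx - x0) ** 2 > (r + r0 + 2.0) ** 2 for y0, x0, r0 in centers):
                break
        centers.append((cy, cx, r))
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= r * r
        if annulus_width_um is not None:
            rim = annulus_width_um / pixel_size_um
            disc &= d2 >= (r - rim) ** 2
        labels[disc] = lab
    return labels


def _raster_ellipse(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    """Boolean raster of an ellipse (pixel-centre inclusion, >= 2 px)."""
    h, w = shape
    r = int(np.ceil(a)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - cx) * ct + (yy - cy) * st
    yr = -(xx - cx) * st + (yy - cy) * ct
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    if mask.sum() < 2:
        # sub-resolution domain: appears at the two-pixel scale along its major axis
        iy, ix = int(round(cy)), int(round(cx))
        jy = int(round(cy + st)) if abs(st) >= abs(ct) else iy
        jx = int(round(cx + ct)) if abs(ct) > abs(st) else ix
        if (jy, jx) == (iy, ix):
            jx = min(w - 1, ix + 1)
        for py, px in ((iy, ix), (jy, jx)):
            if 0 <= py < h and 0 <= px < w:
                mask[py, px] = True
    return mask


def make_domain_field(
    cell_labels: np.ndarray,
    preset: GroupPreset,
    pixel_size_um: float = PIXEL_SIZE_UM,
    seed: int | np.random.Generator = 0,
    max_tries_per_domain: int = 200,
) -> np.ndarray:
    """Plant elliptical LC domains inside each cell.

    Per cell the domain count is Poisson(``n_domains_per_cell``); each
    domain is an ellipse with major axis ``domain_feret_um`` and axis ratio
    ``domain_elongation`` at uniform random orientation. Centres are drawn
    from the cell interior (clearance one semi-major axis, so domains are
    rarely clipped). Placements are rejection sampled to keep planted
    domains separated by at least one background pixel — otherwise
    adjacent domains would fuse under 8-connectivity and the realized
    per-cell count could not track the preset; a domain whose placement
    still fails after ``max_tries_per_domain`` tries is dropped with a log
    message (overlapping or touching survivors, if any, merge in the
    final connected-component labelling).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = preset.domain_feret_um / pixel_size_um / 2.0
    b = a / preset.domain_elongation
    occupied = np.zeros_like(cell_labels, dtype=bool)
    blocked = np.zeros_like(cell_labels, dtype=bool)  # occupied, dilated by 1 px
    structure = ndi.generate_binary_structure(2, 2)
    n_dropped = 0
    for lab in range(1, int(cell_labels.max()) + 1):
        cell = cell_labels == lab
        if not cell.any():
            continue
        interior = ndi.distance_transform_edt(cell) > (a + 0.5)
        cand_y, cand_x = np.nonzero(interior if interior.any() else cell)
        n_domains = rng.poisson(preset.n_domains_per_cell)
        for _ in range(n_domains):
            placed = None
            for _try in range(max_tries_per_domain):
                i = rng.integers(len(cand_y))
                cy = cand_y[i] + rng.uniform(-0.5, 0.5)
                cx = cand_x[i] + rng.uniform(-0.5, 0.5)
                theta = rng.uniform(0, np.pi)
                mask = _raster_ellipse(cell_labels.shape, cy, cx, a, b, theta) & cell
                if mask.sum() < 2:
                    continue
                if not (mask & blocked).any():
                    placed = mask
                    break
            if placed is None:
                n_dropped += 1
                continue
            occupied |= placed
            blocked |= ndi.binary_dilation(placed, structure)
    if n_dropped:
        logger.debug("make_domain_field: dropped %d unplaceable domain(s)", n_dropped)
    domain_labels, _ = ndi.label(occupied, structure=structure)
    return domain_labels.astype(np.int32)


def render_dual_channel(
    truth: GroundTruth,
    total_intensity: float = TOTAL_INTENSITY,
    noise: bool = True,
    G_true: float = 1.0,
    background: float = DARK_LEVEL,
    blur_sigma_px: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> DualChannelImage:
    """Render a ground-truth GP field into blue/green photon rasters.

    On stained pixels the expected intensities invert the GP formula,

        blue  = I (1 + GP) / 2,      green = I (1 - GP) / (2 G_true),

    so that GP = (blue - G green)/(blue + G green) with G = G_true recovers
    the planted field exactly in the noise-free case. Background pixels get
    a low dark level in both channels; independent Poisson noise per
    channel is applied when ``noise`` is set.
    """
    if total_intensity <= 0:
        raise ValueError("total_intensity must be positive")
    gp = truth.true_gp_field
    inside = truth.cell_labels > 0
    if inside.any() and np.nanmax(np.abs(gp[inside])) > 1.0:
        raise ValueError("|GP| > 1 in the ground-truth field")
    blue = np.full(gp.shape, background, dtype=float)
    green = np.full(gp.shape, background, dtype=float)
    blue[inside] = total_intensity * (1.0 + gp[inside]) / 2.0
    green[inside] = total_intensity * (1.0 - gp[inside]) / (2.0 * G_true)
    if blur_sigma_px > 0:
        blue = ndi.gaussian_filter(blue, blur_sigma_px)
        green = ndi.gaussian_filter(green, blur_sigma_px)
    if noise:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        blue = rng.poisson(blue).astype(float)
        green = rng.poisson(green).astype(float)
    meta = dict(truth.meta)
    meta.update(group=truth.preset.group_name, G_true=G_true)
    return DualChannelImage(
        blue=blue, green=green, pixel_size_um=meta.get("pixel_size_um", PIXEL_SIZE_UM), meta=meta
    )


def _solve_fluid_gp(target_mean: float, lc_fraction: float, gp_lc: float) -> float:
    """Fluid-phase GP making the two-phase cell mean equal ``target_mean``."""
    g = (target_mean - lc_fraction * gp_lc) / (1.0 - lc_fraction)
    return float(np.clip(g, -1.0, 1.0))


def build_ground_truth(
    preset: GroupPreset,
    image_shape: tuple[int, int] = (512, 512),
    n_cells: int = 20,
    pixel_size_um: float = PIXEL_SIZE_UM,
    seed: int | np.random.Generator = 0,
    subject_offset: float = 0.0,
    meta: dict[str, Any] | None = None,
) -> GroundTruth:
    """Cells + domains + exact GP field for one field of view.

    The fluid-phase GP is solved per cell from the realized LC area
    fraction so the noise-free cell mean equals
    ``preset.mean_gp + subject_offset`` exactly.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cells = make_cell_geometry(
        n_cells, image_shape, preset.cell_radius_um, pixel_size_um, seed=rng
    )
    domains = make_domain_field(cells, preset, pixel_size_um, seed=rng)
    gp = np.full(image_shape, np.nan)
    target = preset.mean_gp + subject_offset
    for lab in range(1, n_cells + 1):
        cell = cells == lab
        n_px = int(cell.sum())
        if n_px == 0:
            continue
        f = float((domains[cell] > 0).sum()) / n_px
        fluid = _solve_fluid_gp(target, f, preset.mean_gp_lc)
        gp[cell] = fluid
        gp[cell & (domains > 0)] = preset.mean_gp_lc
    m = dict(meta or {})
    m.setdefault("pixel_size_um", pixel_size_um)
    m["subject_offset"] = subject_offset
    return GroundTruth(
        cell_labels=cells,
        domain_labels=domains,
        true_gp_field=gp,
        preset=preset,
        seed=int(rng.integers(2**31)),
        meta=m,
    )


def simulate_subject(
    preset: GroupPreset,
    n_images: int = 5,
    seed: int = 0,
    cells_per_image: int = 20,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = PIXEL_SIZE_UM,
    total_intensity: float = TOTAL_INTENSITY,
    noise: bool = True,
    G_true: float = 1.0,
    subject_id: str = "S0",
) -> list[tuple[DualChannelImage, GroundTruth]]:
    """Simulate one subject: ``n_images`` fields of view sharing one GP offset.

    The subject-level offset is drawn once from Normal(0, ``subject_sd_gp``)
    and enters every cell's target mean, emulating between-patient
    variability of the per-patient GP index. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    offset = float(rng.normal(0.0, preset.subject_sd_gp)) if preset.subject_sd_gp > 0 else 0.0
    out: list[tuple[DualChannelImage, GroundTruth]] = []
    for i in range(n_images):
        truth = build_ground_truth(
            preset,
            image_shape=image_shape,
            n_cells=cells_per_image,
            pixel_size_um=pixel_size_um,
            seed=rng,
            subject_offset=offset,
            meta={"subject_id": subject_id, "image_index": i},
        )
        img = render_dual_channel(
            truth,
            total_intensity=total_intensity,
            noise=noise,
            G_true=G_true,
            seed=rng,
        )
        img.meta.update(subject_id=subject_id, image_index=i)
        out.append((img, truth))
    return out
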