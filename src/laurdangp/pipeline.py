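"""End-to-end study pipeline on synthetic cohorts.

Chains the generator, segmentation, GP mapping, LC-domain analysis and
group statistics into one seed-deterministic run that mirrors the study
design: three groups (CTRL / DM / DM_PAD) with 10/12/15 subjects, five
fields of view per subject, a 20-cell reference stack from the DM group
defining the global LC threshold, per-subject GP indices, and per-cell
domain morphometrics on a fixed number of cells per group.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .domains import (
    DomainThreshold,
    build_reference_distribution,
    derive_threshold,
    extract_domains,
    measure_domains,
    per_cell_domain_stats,
)
from .gp import compute_gp, subject_gp_summary
from .io import RunConfig, write_table
from .segmentation import segment_cells
from .stats import GroupComparison, full_report, posthoc_pairwise
from .synthetic import GroupPreset, group_presets, simulate_subject

logger = logging.getLogger("laurdangp")

__all__ = ["StudyResult", "run_synthetic_study", "gp_power_simulation", "DEFAULT_COHORT"]

#: study sample sizes: healthy controls, diabetics without / with PAD
DEFAULT_COHORT: dict[str, int] = {"CTRL": 10, "DM": 12, "DM_PAD": 15}


@dataclass
class StudyResult:
    """Tables and statistics from one synthetic-cohort run."""

    subjects: pd.DataFrame
    cells: pd.DataFrame
    domains: pd.DataFrame
    threshold: DomainThreshold
    comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    config: RunConfig = field(default_factory=RunConfig)

    def save(self, outdir: str | Path, make_plots: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.subjects, outdir / "subjects.csv")
        write_table(self.cells, outdir / "cells_domains.csv")
        write_table(self.domains, outdir / "domains.csv")
        (outdir / "threshold.json").write_text(
            json.dumps(
                {
                    "gp_star": self.threshold.gp_star,
                    "percentile": self.threshold.percentile,
                    "reference_group": self.threshold.source_group,
                    "n_reference_cells": self.threshold.n_reference_cells,
                    "seed": self.config.seed,
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        full_report(
            self.subjects,
            self.cells.loc[self.cells["sampled"]],
            outdir / "report",
            make_plots=make_plots,
        )

    def group_means(self, table: str, column: str) -> dict[str, float]:
        df = self.subjects if table == "subjects" else self.cells.loc[self.cells["sampled"]]
        return {g: float(v[column].mean()) for g, v in df.groupby("group")}


def _segmentation_bounds(preset: GroupPreset) -> tuple[float, float]:
    """Area window bracketing the generator's cell sizes (µm²)."""
    r_lo, r_hi = preset.cell_radius_um
    return 0.4 * np.pi * r_lo**2, 2.5 * np.pi * r_hi**2


def run_synthetic_study(
    n_subjects_by_group: Mapping[str, int] | None = None,
    n_images: int = 5,
    cells_per_image: int = 20,
    image_shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    noise: bool = True,
    config: RunConfig | None = None,
    cells_per_group_morpho: int = 20,
    presets: Mapping[str, GroupPreset] | None = None,
) -> StudyResult:
    """Simulate and analyse a full three-group cohort.

    Returns per-subject GP summaries, per-cell domain statistics (with a
    seed-deterministic sample of ``cells_per_group_morpho`` cells per group
    flagged for the morphometric comparison), the per-domain table, the
    reference threshold, and the group comparisons.
    """
    if n_subjects_by_group is None:
        n_subjects_by_group = DEFAULT_COHORT
    if presets is None:
        presets = group_presets()
    cfg = config or RunConfig(seed=seed)
    master = np.random.default_rng(seed)

    t0 = time.perf_counter()
    per_subject: list[dict] = []  # subject_id, group, gp_maps, masks
    for group, n_subj in n_subjects_by_group.items():
        preset = presets[group]
        min_area, max_area = _segmentation_bounds(preset)
        # cap cells per image at a packable disc density for this group's cell size
        r_hi_px = preset.cell_radius_um[1] / cfg.pixel_size_um
        cap = max(1, int(0.32 * image_shape[0] * image_shape[1] / (np.pi * r_hi_px**2)))
        n_cells_img = min(cells_per_image, cap)
        for s in range(n_subj):
            subject_id = f"{group}_{s:02d}"
            sub_seed = int(master.integers(2**31))
            pairs = simulate_subject(
                preset,
                n_images=n_images,
                seed=sub_seed,
                cells_per_image=n_cells_img,
                image_shape=image_shape,
                pixel_size_um=cfg.pixel_size_um,
                noise=noise,
                G_true=cfg.G,
                subject_id=subject_id,
            )
            masks, gp_maps = [], []
            for img, _truth in pairs:
                masks.append(
                    segment_cells(
                        img,
                        min_area_um2=min_area,
                        max_area_um2=max_area,
                        min_solidity=cfg.min_solidity,
                    )
                )
                gp_maps.append(compute_gp(img, G=cfg.G, denom_floor=cfg.denom_floor))
            per_subject.append(
                {"subject_id": subject_id, "group": group, "gp_maps": gp_maps, "masks": masks}
            )
    logger.info("simulation + segmentation + GP: %.1f s", time.perf_counter() - t0)

    # reference stack and global threshold from the reference group
    t0 = time.perf_counter()
    ref_maps, ref_masks = [], []
    for rec in per_subject:
        if rec["group"] == cfg.reference_group:
            ref_maps.extend(rec["gp_maps"])
            ref_masks.extend(rec["masks"])
    ref = build_reference_distribution(
        ref_maps,
        ref_masks,
        n_cells=cfg.reference_n_cells,
        seed=int(master.integers(2**31)),
        source_group=cfg.reference_group,
    )
    threshold = derive_threshold(ref, percentile=cfg.lc_percentile)
    logger.info("reference threshold gp* = %.4f (%.1f s)",
                threshold.gp_star, time.perf_counter() - t0)

    # per-subject GP summaries, per-image domain extraction and morphometry
    t0 = time.perf_counter()
    subject_rows, cell_rows, domain_rows = [], [], []
    for rec in per_subject:
        summary = subject_gp_summary(
            rec["gp_maps"], rec["masks"], subject_id=rec["subject_id"], group=rec["group"]
        )
        subject_rows.append(
            {
                "subject_id": summary.subject_id,
                "group": summary.group,
                "mean_gp": summary.mean_gp,
                "sd_gp": summary.sd_gp,
                "mean_gp_cellwise": summary.mean_gp_cellwise,
                "n_cells": summary.n_cells,
                "n_pixels": summary.n_pixels,
            }
        )
        for i, (gpm, mask) in enumerate(zip(rec["gp_maps"], rec["masks"])):
            dom_labels = extract_domains(
                gpm, mask, threshold, min_px=cfg.min_domain_px, connectivity=cfg.connectivity
            )
            records = measure_domains(dom_labels, cfg.pixel_size_um, cell_labels=mask.labels)
            stats_df = per_cell_domain_stats(records, mask)
            for row in stats_df.to_dict("records"):
                row.update(subject_id=rec["subject_id"], group=rec["group"], image_index=i)
                cell_rows.append(row)
            for r in records:
                domain_rows.append(
                    {
                        "subject_id": rec["subject_id"],
                        "group": rec["group"],
                        "image_index": i,
                        "domain_id": r.domain_id,
                        "cell_id": r.cell_id,
                        "area_um2": r.area_um2,
                        "perimeter_um": r.perimeter_um,
                        "feret_um": r.feret_um,
                        "circularity": r.circularity,
                    }
                )
    subjects = pd.DataFrame(subject_rows)
    cells = pd.DataFrame(cell_rows)
    domains = pd.DataFrame(domain_rows)
    logger.info("domain extraction + morphometry: %.1f s", time.perf_counter() - t0)

    # fixed-size per-group cell sample for the morphometric comparison
    cells["sampled"] = False
    for group in n_subjects_by_group:
        idx = cells.index[cells["group"] == group]
        take = min(cells_per_group_morpho, len(idx))
        if take < cells_per_group_morpho:
            logger.warning("group %s has only %d cells for morphometrics", group, take)
        chosen = master.choice(idx, size=take, replace=False)
        cells.loc[chosen, "sampled"] = True

    sampled = cells.loc[cells["sampled"]]
    comparisons: dict[str, GroupComparison] = {}
    from .stats import compare_feature

    comparisons["gp"] = compare_feature(
        {g: v["mean_gp"].to_numpy() for g, v in subjects.groupby("group")}, "gp"
    )
    for col in ("n_domains", "mean_feret_um", "mean_circularity"):
        groups = {g: v[col].dropna().to_numpy() for g, v in sampled.groupby("group")}
        if all(len(v) >= 2 for v in groups.values()):
            comparisons[col] = compare_feature(groups, col)
    return StudyResult(
        subjects=subjects,
        cells=cells,
        domains=domains,
        threshold=threshold,
        comparisons=comparisons,
        config=cfg,
    )


def gp_power_simulation(
    n_reps: int = 100,
    seed: int = 0,
    n_by_group: Mapping[str, int] | None = None,
    presets: Mapping[str, GroupPreset] | None = None,
    pair: tuple[str, str] = ("DM", "DM_PAD"),
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates where ``pair`` reaches Holm-adjusted p < alpha.

    Replicates draw per-subject mean GP from the generator's subject model
    (Normal around each group's target with the between-subject SD) at the
    study sample sizes — a design-detectability check for the GP contrast,
    not a reproduction of any particular p-value.
    """
    if n_by_group is None:
        n_by_group = DEFAULT_COHORT
    if presets is None:
        presets = group_presets()
    rng = np.random.default_rng(seed)
    hits = 0
    want = tuple(sorted(pair))
    for _ in range(n_reps):
        sample = {
            g: rng.normal(presets[g].mean_gp, presets[g].subject_sd_gp, n)
            for g, n in n_by_group.items()
        }
        for pw in posthoc_pairwise(sample, method="holm"):
            if tuple(sorted(pw.pair)) == want and pw.adj_p < alpha:
                hits += 1
    return hits / n_reps
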