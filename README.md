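# laurdangp

Analysis pipeline for ratiometric membrane-fluidity imaging of red blood
cells (RBC) stained with the environment-sensitive dye Laurdan, whose
emission shifts blue in ordered (gel / liquid-crystalline) lipid phases and
green in disordered fluid phases. It is aimed at groups studying RBC
membrane remodelling in metabolic disease — for example comparing healthy
controls (CTRL) with type-2-diabetes patients without (DM) and with
peripheral artery disease (DM+PAD) — and at anyone who needs a tested,
scriptable replacement for the ImageJ/Ilastik workflow such studies
typically use.

## What it computes

From a dual-channel confocal image (blue 450/50 nm, green 525/50 nm
emission) the pipeline computes the per-pixel **generalized polarization**

```
GP = (I_blue − G·I_green) / (I_blue + G·I_green),        GP ∈ [−1, 1]
```

with `G` an instrument calibration factor. Higher GP means a more ordered,
less fluid membrane. Per subject, GP is pooled over all segmented RBC
pixels into a single fluidity index. **Liquid-crystalline (LC) domains**
are then isolated by a quartile rule: the pooled GP distribution of a
20-cell reference stack (from the DM group by default) defines a global
threshold `GP*` at its 75th percentile, and connected components of pixels
with `GP > GP*` inside each cell are the LC domains. Each domain is
measured: area, perimeter, maximum **Feret diameter** (rotating calipers
on the pixel-corner convex hull) and **circularity** `4πA/p²` (1 for a
circle, → 0 for elongated shapes). Groups are compared with one-way ANOVA
plus Welch pairwise tests under Holm adjustment (Tukey HSD optional), and
χ² for categorical covariates.

Because studies of this kind rarely deposit raw images, the package ships
a first-class synthetic generator (`laurdangp.synthetic`): dual-channel
fields of view with known per-pixel GP truth, planted elliptical LC
domains of controlled count/size/shape per group, per-subject GP offsets
and per-channel Poisson photon noise. Every pipeline stage is validated
against this ground truth.

## Worked example

```python
from laurdangp import (compute_gp, group_presets, segment_cells,
                       simulate_subject, subject_gp_summary)

preset = group_presets()["DM"]                       # printed group targets
pairs = simulate_subject(preset, n_images=2, seed=42, cells_per_image=6,
                         image_shape=(256, 256), subject_id="DM_demo")
masks = [segment_cells(img, min_area_um2=3, max_area_um2=25) for img, _ in pairs]
gp_maps = [compute_gp(img, G=1.0) for img, _ in pairs]
summary = subject_gp_summary(gp_maps, masks, subject_id="DM_demo", group="DM")
print(f"subject {summary.subject_id}: mean GP = {summary.mean_gp:.4f} "
      f"(SD {summary.sd_gp:.4f}) over {summary.n_cells} cells / {summary.n_pixels} px")
```

prints

```
subject DM_demo: mean GP = 0.5210 (SD 0.1094) over 12 cells / 40732 px
```

The subject's mean GP lands near the DM target of 0.519 (the difference is
the subject's own drawn offset plus shot noise); the large pixelwise SD
reflects the two-phase GP field (fluid background ≈ 0.45, LC domains at
0.70), not estimator error. A full three-group study — simulation,
segmentation, thresholding, morphometry and statistics — is one call:

```python
from laurdangp import run_synthetic_study
study = run_synthetic_study(seed=0)       # CTRL/DM/DM_PAD = 10/12/15 subjects
study.save("study_out")                   # CSVs, threshold.json, report/, plots
```

or, from the shell, `laurdangp run --seed 0 --out study_out`. The
`simulate`, `segment`, `gpmap`, `domains` and `stats` subcommands expose
the individual stages.

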