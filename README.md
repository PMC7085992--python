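# psoaspet

Quantification of whole-psoas muscle structure and [¹⁸F]-FDG metabolism
from co-registered PET/CT, with survival stratification of the resulting
indices — aimed at studies of sarcopenia and neuromuscular disease (e.g.
amyotrophic lateral sclerosis), where muscle quantity, quality and the
spatial pattern of glucose uptake carry prognostic information.

## What it computes

For each subject, from a CT volume (HU) and a PET volume (activity
concentration, kBq/mL):

* **Segmentation.** Both psoas bodies are extracted slice by slice between
  operator-chosen cranial (D12) and caudal (L5–S1) bounds. Each axial
  slice is histogram-equalized within a soft-tissue HU window, edges are
  found with a Canny detector, and the contour around a tracked point
  inside each muscle is closed — directly when the edge chain already
  closes, otherwise by an α-shape (Delaunay α-complex with auto-tuned
  disc radius) that bridges gaps in the chain. Regions are followed down
  the stack by centroid tracking with area-ratio gating; the result is a
  3-label mask (background / left / right) on the CT grid.
* **Structural indices.** Muscle volume `V` (mL) and the average
  attenuation coefficient `AAC` (mean HU over the mask, a muscle-quality
  index). `V` is normalized to the Robinson ideal body weight:
  `V_n = V / IBW` (mL/kg), with `IBW = 52 + 1.9·(h_in − 60)` kg for men
  and `49 + 1.7·(h_in − 60)` kg for women.
* **Metabolic indices.** The CT mask is downsampled to the PET grid by
  exact geometric box overlap (a PET voxel joins the mask when ≥ 50 % of
  its volume is covered), then multiplied against the SUV volume, where
  `SUV = C[kBq/mL] · weight[kg] / dose[MBq]`. Reported are the mean SUV,
  the liver-normalized `N-SUV = SUV / SUV_liver`, and the heterogeneity
  index `VC-SUV = 100 · SD(N-SUV) / mean(N-SUV)` (%) pooled over the
  voxels of both muscles. A myocardial variant enforces a 10 mL minimum
  VOI.
* **Survival analysis.** Each candidate prognostic variable is
  median-split; groups are compared with Kaplan–Meier curves and the
  log-rank test; univariate Cox proportional-hazards models are fitted on
  the split indicator, and a multivariate Cox model is reduced by
  backward elimination on the likelihood-ratio test (variables removed
  while p > 0.1).

Digital phantoms (two tapered elliptic-cylinder muscles flanking a
vertebral block, plus a liver reference ellipsoid, on a fine CT grid and
a coarser offset PET grid) and cohort simulators with known hazard
structure provide ground truth for every stage.

## Worked example

```python
from psoaspet import (PhantomSpec, generate_phantom, default_segmentation_seeds,
                      SegmentationConfig, build_mask, compute_suv,
                      liver_reference, psoas_metrics)

spec = PhantomSpec(ct_noise_sd_hu=0.0, pet_noise_sd_suv=0.0, seed=1)
ct, pet, truth, meta = generate_phantom(spec)
cfg = SegmentationConfig(slice_start=4, slice_stop=36,
                         seeds=default_segmentation_seeds(spec))
mask = build_mask(ct, cfg)
pet_suv = compute_suv(pet, meta)
liver = liver_reference(pet_suv, sphere=(spec.liver_center_mm, 30.0))
m = psoas_metrics(ct, pet_suv, mask, liver, sex=meta.sex, height_cm=meta.height_cm)
print(f"psoas volume      : {m.volume_mL:.1f} mL ({m.volume_per_ibw_mL_per_kg:.2f} mL/kg IBW)")
print(f"AAC               : {m.aac_HU:.1f} HU")
print(f"mean SUV / N-SUV  : {m.suv_mean:.3f} / {m.n_suv:.3f}")
print(f"VC-SUV            : {m.vc_suv_pct:.1f} %")
```

prints

```
psoas volume      : 254.3 mL (3.69 mL/kg IBW)
AAC               : 39.4 HU
mean SUV / N-SUV  : 0.900 / 0.450
VC-SUV            : 8.0 %
```

i.e. the segmentation recovers the phantom's generative conditions — a
muscle of 39.4 HU mean attenuation with liver-normalized uptake 0.45 and
8 % voxel-wise uptake heterogeneity — from the images alone. The same
stages are available from the shell:

```sh
psoaspet simulate --out bundle --seed 1
psoaspet pipeline --bundle bundle --out run
psoaspet survival --cohort bundle/cohort.csv --out run
```

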