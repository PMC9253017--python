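# cardiohelix

Cardiac DT-MRI microstructural helicity and RNA-FISH spatial expression
analysis, with digital left-ventricular phantoms for end-to-end validation.

## The scientific problem

Exercise remodels the heart not only in bulk (wall thickness, LV mass) but in
its tissue microstructure: cardiomyocytes are helically wound, transitioning
smoothly from a right-handed orientation at the endocardium to a left-handed
one at the epicardium. Diffusion tensor MRI (DT-MRI) measures this
non-invasively — the primary eigenvector **e₁** of the per-voxel diffusion
tensor **D** tracks the local myofiber direction. The expression of CITED4, a
transcriptional co-regulator required for exercise-induced cardiac growth,
can meanwhile be mapped spatially with RNA-FISH by counting mRNA spots per
DAPI-stained nucleus. This package implements both quantification chains and
links them region by region on a shared six-segment AHA frame.

## The core statistic

Per voxel, the **helix angle** is

α = atan2(p·l̂, p·ĉ) ∈ [−90°, 90°],  p = e₁ − (e₁·r̂)r̂,

where (r̂, ĉ, l̂) is the local radial / circumferential / longitudinal triad,
and the sign of e₁ is fixed so e₁·ĉ ≥ 0. **Helicity** is the slope of the
linear regression of ring-mean α on normalized transmural depth d ∈ [0, 1]
(endocardium → epicardium), using five equal-depth concentric rings — in
degrees per unit wall depth, per short-axis slice, per AHA segment, and
aggregated into septal (segments 2–3), lateral (segments 5–6) and total
values. The FISH branch reports the CITED4/DAPI ratio (spots per nucleus)
for 6 segments × 3 transmural layers.

Tensors are reconstructed by iterated weighted least squares on the
log-signal, ln Sᵢ = ln S₀ − bᵢ gᵢᵀ **D** gᵢ, with weights equal to the squared
predicted signal (one OLS pass, then two reweighted passes).

Because no imaging data are deposited for this kind of study, the package
ships a first-class synthetic-data module: an annular LV phantom with a
linear transmural helix-angle profile imaged by a Stejskal–Tanner model
(12 directions at b = 500 s/mm², 4 b = 0, 140 µm voxels, Rician noise), a
two-channel FISH image generator, and a cohort generator with
sedentary/exercise/knockout groups — all carrying exact ground truth, so the
analysis chain is validated as a parameter-recovery problem.

## Worked example

```python
from cardiohelix import stats_pipeline as sp

bundle = sp.run_pipeline(seed=1, out_dir="out")
print(open("out/report.md").read())
```

prints (abridged):

```
## Group comparisons (exercise vs sedentary)
- helicity_total: 118.827 -> 136.222 (+14.6%), t=-2.54, p=0.02571
- helicity_lateral: 118.743 -> 138.246 (+16.4%), t=-2.82, p=0.01538
- cited4_total: 2.064 -> 2.919 (+41.4%), t=-6.64, p=2.405e-05
- cited4_lateral: 2.064 -> 3.243 (+57.1%), t=-8.67, p=1.631e-06
- wall_thickness: 1.529 -> 2.227 (+45.7%), t=-21.86, p=4.931e-11

## Helicity vs CITED4/DAPI regressions (pooled)
- total: slope=25.44, R^2=0.697, p=0.0002042, n=14
```

This simulates a 7 + 7 sedentary/exercise cohort (DWI phantom + FISH section
per animal), runs segmentation → tensor fit → helix angles → helicity and
nucleus/spot counting → CITED4/DAPI ratios, and compares the groups.
`helicity_total` is the mean |slope| in degrees per unit transmural depth;
`cited4_*` are spots per nucleus; the regression pools both groups. One
realization of a 14-animal cohort is shown, so recovered percent changes
scatter around the generator's calibrated effect sizes.

A CLI mirrors the library:

```bash
cardiohelix simulate dwi --seed 1 --out sim/
cardiohelix fit --dwi sim/dwi.nii.gz --bval sim/dwi.bval --bvec sim/dwi.bvec --out fit/
cardiohelix helicity --dwi sim/dwi.nii.gz --bval sim/dwi.bval --bvec sim/dwi.bvec --out hel/
cardiohelix quantify-fish --dapi dapi.tiff --cited4 cited4.tiff \
    --inner-radius 110 --outer-radius 300 --out quant/
cardiohelix cohort --seed 1 --out out/
```

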