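# Methods

## Diffusion phantom and signal model

The phantom is a straight circular annulus (a short-axis stack), not a
truncated ellipsoid: the analyses it feeds are per-slice short-axis
measurements, and the cylinder keeps the ground truth analytic. Geometry
defaults: 64×64×8 grid at 140 µm isotropic voxels (the in-plane resolution
of the emulated acquisition), inner radius 1.5 mm, outer radius 3.0 mm —
murine LV scale, chosen so that the exercise morphometry effects (wall
thickening with modest mass gain, which shrinks the cavity) remain
representable on the grid.

The fiber field lies in the local circumferential–longitudinal plane at
helix angle α(d) = α_endo + (α_epi − α_endo)·d, linear in normalized
transmural depth d — the linearity is the model under which a single slope
("helicity") summarizes the wall. Defaults α_endo = +60°, α_epi = −60°
follow the general histology literature on transmural fiber rotation; they
are configurable per AHA segment. The implied true helicity is
α_epi − α_endo degrees per unit depth (−120 by default; the magnitude is
what cohort effects scale).

Signals follow Stejskal–Tanner, S = S₀ exp(−b gᵀDg), with D built from the
orthonormal triad (fiber, in-wall normal, radial) and eigenvalues
λ = (1.7, 0.9, 0.6)×10⁻³ mm²/s (typical fixed myocardium). The transverse
(sheetlet) angle is fixed at zero: only the helix angle is modeled. The
default scheme is 12 gradient directions at b = 500 s/mm² (golden-angle
hemisphere spiral; its design conditioning matches an electrostatically
optimized set) plus 4 b = 0 volumes. Noise is Rician — magnitude of the
complex signal with i.i.d. Gaussian channels of σ = S₀/SNR — at a default
b0 SNR of 25. No eddy-current, motion or Gibbs artifacts are simulated.

## Tensor reconstruction

The fit solves the 7-parameter log-linear system ln Sᵢ = ln S₀ − bᵢgᵢᵀDgᵢ:
one ordinary-least-squares pass, then two reweighted passes with weights
equal to the squared predicted signal (the standard variance-stabilizing
weighting for log-transformed magnitude data); the iteration count is
configurable. Non-positive measurements are excluded per voxel rather than
clamped (clamping biases the log); a voxel with fewer than 7 usable
measurements is flagged rather than fitted. No positive-definiteness repair
is applied — negative eigenvalues flag the voxel instead, because silent
repair would distort helix angles. The b-matrix uses b·ggᵀ only (no
cross-terms).

In the noiseless limit the system is exact and the fit recovers the
generating tensor to machine precision (the round-trip test bounds it at
1e−6 relative). At SNR 25 the per-voxel primary-eigenvector error is
noise-floor limited at ≈5.7° median — it scales as 1/SNR and is independent
of the direction set, i.e. it is an estimation floor of the acquisition, not
an implementation artifact. Ring averaging (hundreds of voxels per ring)
suppresses this to well under 5% error on the helicity slope, which is the
quantity of interest.

## LV frame, depth, rings, segments

The local frame is centroid-based: per slice, r̂ points from the mask
centroid to the voxel, l̂ is the slice normal, ĉ = l̂ × r̂. This is the
simplest frame consistent with short-axis analysis; it is documented as
inaccurate for strongly non-circular walls. Transmural depth uses a
two-sided in-plane Euclidean distance transform,
d = d_endo/(d_endo + d_epi), with a half-voxel offset so d = 0/1 sit at the
tissue interfaces; it is robust to non-circular masks, unlike a radial
coordinate. Five equal-depth rings bin d; six 60° sectors from a
configurable `reference_angle` define the AHA segments — phantoms have no RV
insertion point to anchor the rotation, so it is explicit configuration,
with septal := {2,3} and lateral := {5,6}. Wall thickness is the mean
distance from endocardial-border voxels to the epicardial border; LV mass is
voxel volume × 1.05 mg/mm³.

Myocardium segmentation (when no mask is supplied) is Otsu thresholding of
the mean b0, per-slice morphological closing, then largest-component
selection with a ring-topology check; it recovers the phantom mask exactly
in the noiseless case and at Jaccard > 0.99 under default noise.

## Helicity

Helix angles use the sign convention e₁·ĉ ≥ 0, which confines α to
[−90°, 90°] and makes the arithmetic ring mean valid (no wrap-around); a
circular mean is available for distributions near ±90°. Slopes are fitted by
OLS per (slice, segment) on the *observed* ring-mean depths — not nominal
bin centers — which keeps partial rings unbiased. Segment values average
slices; regional values are unweighted means of member segments; "total" is
the mean over all six. Helicity is kept signed internally, and reported
alongside its magnitude; group comparisons operate on magnitudes, matching
how transmural-gradient increases are described in the field.

## FISH generator and quantification

The synthetic section is an annular tissue region (640² px, radii 110–300 px)
partitioned into 6 segments × 3 layers = 18 ROIs. Nuclei are disks
(radius 4 px, 20 per ROI by default) and mRNA spots are PSF-sized points
(σ = 1.2 px), both blurred and superposed on Gaussian background
(mean 2, SD 1). Spot counts per ROI are deterministic:
round(nuclei × spots-per-nucleus), with a default rate of 2.0 spots/nucleus.
Spots are placed uniformly in the ROI and may fall outside nuclei
(cytoplasmic mRNA) — the assay normalizes by nuclei, not by cell assignment.
In non-overlapping mode, placement margins guarantee each detection belongs
to one ROI, so ideal counting recovers truth exactly; with overlap allowed
(minimum nucleus separation 1.5 radii), watershed splitting and
cluster-area division must resolve merges, and recover counts to ≈2%.

Detection: Otsu threshold (manual absolute threshold supported, recorded as
configuration), connected components with an area band, distance-transform
watershed for over-sized components (nuclei), and area division by the
median single-spot area for clustered dots (spots). Spot detection requires
the Otsu foreground/background separation to exceed 4 image SDs — otherwise
the channel is declared empty. This matters for knockout sections whose
CITED4 channel is pure background; without the guard, thresholding inside
noise fabricates counts. Aggregate ratios are summed spots over summed
nuclei, so totals are conserved.

## Cohort generator

Each animal draws a latent bivariate normal (z_h, z_c) with correlation 0.9;
its true helicity magnitude is the group mean × (1 + cv·z_h) and its CITED4
rate the base rate × (1 + cv·z_c), with cv = 0.15 between animals. Exercise
multiplies helicity spans by +17.1% (septal), +21.5% (lateral), +19.9%
(elsewhere) and CITED4 rates by +32.9% / +71.7% / +59% — the regional
pattern the analysis is meant to detect, with the lateral wall dominant.
The knockout genotype (C4KO) forces CITED4 expression to ≈0, removes the
exercise effect entirely, and carries a −31.7% baseline helicity deficit
versus controls. Exercise also thickens the wall (+47.7%) with a +9.5%
annulus-area (mass) gain, which determines per-animal radii, plus mild
anatomical jitter.

cv = 0.15 is the calibration at which a 17% effect at n = 7 + 7 is
borderline-significant and a 20% effect strongly significant — the
significance structure the regional comparisons assume. Under that cv the
pooled helicity~CITED4 regression reaches R² ≈ 0.65–0.75; a substantially
higher pooled correlation cannot coexist with that noise level in this
multiplicative-noise model, so emulated correlations are "substantial"
rather than near-perfect. Passing tests therefore demonstrate recovery of
the generator's known structure — they do not certify performance on real
tissue, where frame placement, partial-volume effects and staining
variability add error modes the generator does not model.

## Numerical and design choices

- t-tests are pooled-variance Student by default (Welch by flag); the
  two-way ANOVA uses type-II sums of squares (sensible for unbalanced
  genotype designs) with Tukey HSD over the four cells; regressions pool
  groups. No multiple-testing correction is applied across regional
  comparisons by default (a Holm option exists); the statistical unit is the
  per-animal mean.
- Zero-variance degenerate cases: equal-mean constant groups give t = 0,
  p = 1; unequal-mean constant groups are flagged degenerate with p → 0;
  constant-response ANOVA returns all F = 0, p = 1.
- Eigen-decomposition flags voxels with (λ₁−λ₂)/λ₁ < 10⁻³ as degenerate
  (fiber direction undefined); nearly-radial fibers (in-plane projection
  < 10⁻³) are excluded from helix maps. Ring fits require ≥3 rings and ≥5
  voxels per ring.
- All randomness flows from explicit integer seeds; identical seed + spec
  gives bit-identical volumes, images and cohorts.

## Problem sizes

Validation runs use the 64×64×8 phantom (~6,400 myocardial voxels), 640²
FISH sections, cohorts of 7 per group, 1,000 truth-level null cohorts for
type-I calibration, and 50 full imaging replicates for the end-to-end
qualitative checks (with 12 nuclei per ROI in those replicates); a full
cohort simulate-and-analyze cycle takes a few seconds on one CPU.

## Known limitations

Cylindrical geometry and a centroid frame (no curvature, no RV); no sheetlet
(E2A) modeling; no MR artifact simulation; FISH sections are 2-D with
uniform background and no tissue autofluorescence texture; AHA rotational
anchoring is configuration, not anatomy; cohort 2's unbalanced group sizes
are emulated as balanced groups.
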