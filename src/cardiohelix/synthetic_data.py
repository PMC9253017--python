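"""Digital phantoms and synthetic cohorts with known ground truth.

Three generators emulate the study data this package analyzes:

* a short-axis left-ventricular diffusion phantom — a circular annulus whose
  myofiber helix angle varies linearly with transmural depth, imaged with a
  Stejskal-Tanner signal model (12 directions at b = 500 s/mm^2 plus 4 b = 0
  volumes by default) under Rician magnitude noise;
* two-channel fluorescence micrographs — disk-like DAPI nuclei and
  point-like CITED4 mRNA spots on an annular tissue section, with Gaussian
  PSF blur and background noise, organized in 6 AHA segments x 3 transmural
  layers;
* paired sedentary/exercise/knockout cohorts in which exercise increases the
  true helix-angle span and the CITED4 spots-per-nucleus rate with
  lateral-dominant regional placement, and the cardiomyocyte CITED4 knockout
  (C4KO) abolishes both the expression and the exercise effect.

Every generator carries its ground truth out explicitly so that the analysis
chain can be tested as a parameter-recovery problem.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .fish_quant import LAYERS, LATERAL_SEGMENTS, SEPTAL_SEGMENTS, ROISet, build_rois
from .tensor_model import AcquisitionScheme, DWIVolume, default_scheme

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "NoiseModel",
    "FishSpec",
    "FishTruth",
    "CohortSpec",
    "AnimalRecord",
    "make_lv_phantom",
    "simulate_dwi",
    "make_fish_image",
    "cohort_truths",
    "make_cohort",
    "segment_effect_map",
]

N_SEGMENTS = 6


# --------------------------------------------------------------------------
# Diffusion phantom
# --------------------------------------------------------------------------


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and microstructure of the annular LV diffusion phantom.

    Radii are in mm; ``helix_endo``/``helix_epi`` (degrees) may be scalars or
    per-AHA-segment length-6 sequences.  The implied true helicity of a
    segment is ``helix_epi - helix_endo`` in degrees per unit transmural
    depth (depth 0 at the endocardium, 1 at the epicardium).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 8)
    voxel_size: tuple[float, float, float] = (0.14, 0.14, 0.14)
    center: tuple[float, float] | None = None
    inner_radius: float = 1.5
    outer_radius: float = 3.0
    slice_range: tuple[int, int] = (1, 7)
    helix_endo: float | np.ndarray = 60.0
    helix_epi: float | np.ndarray = -60.0
    eigenvalues: tuple[float, float, float] = (1.7e-3, 0.9e-3, 0.6e-3)
    S0: float = 1.0
    reference_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = (
                (self.grid_shape[0] - 1) / 2.0,
                (self.grid_shape[1] - 1) / 2.0,
            )
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValueError("need 0 < inner_radius < outer_radius")
        max_r = min(
            self.center[0] * self.voxel_size[0],
            self.center[1] * self.voxel_size[1],
            (self.grid_shape[0] - 1 - self.center[0]) * self.voxel_size[0],
            (self.grid_shape[1] - 1 - self.center[1]) * self.voxel_size[1],
        )
        if self.outer_radius > max_r:
            raise ValueError(
                f"outer_radius {self.outer_radius} mm exceeds the grid "
                f"half-extent {max_r:.2f} mm about the center"
            )
        lo, hi = self.slice_range
        if not (0 <= lo < hi <= self.grid_shape[2]):
            raise ValueError("slice_range outside the grid")
        endo = np.broadcast_to(np.asarray(self.helix_endo, float), (N_SEGMENTS,)).copy()
        epi = np.broadcast_to(np.asarray(self.helix_epi, float), (N_SEGMENTS,)).copy()
        if np.any(np.abs(endo) > 90) or np.any(np.abs(epi) > 90):
            raise ValueError("helix angles must lie in [-90, 90] degrees")
        self._endo = endo
        self._epi = epi
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")

    @property
    def helix_endo_per_segment(self) -> np.ndarray:
        return self._endo

    @property
    def helix_epi_per_segment(self) -> np.ndarray:
        return self._epi

    @property
    def true_helicity_per_segment(self) -> np.ndarray:
        """Degrees per unit transmural depth, per AHA segment."""
        return self._epi - self._endo

    @property
    def true_helicity(self) -> float:
        return float(self.true_helicity_per_segment.mean())


@dataclasses.dataclass
class PhantomTruth:
    """Analytic ground truth carried by a phantom instance."""

    depth: np.ndarray  # analytic transmural depth, NaN outside mask
    segment_labels: np.ndarray  # 1..6 inside mask
    helix_angle: np.ndarray  # true per-voxel helix angle (degrees)
    helicity_per_segment: np.ndarray
    helicity_global: float


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """MR magnitude noise: none, additive Gaussian, or Rician.

    ``snr`` is S0 over the per-channel noise sigma.
    """

    kind: Literal["none", "gaussian", "rician"] = "rician"
    snr: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.kind != "none" and not self.snr > 0:
            raise ValueError("snr must be > 0")


def _phantom_geometry(spec: PhantomSpec):
    nx, ny, _ = spec.grid_shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    dx = (xs - spec.center[0]) * spec.voxel_size[0]
    dy = (ys - spec.center[1]) * spec.voxel_size[1]
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))
    return dx, dy, r, theta


def make_lv_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, PhantomTruth]:
    """Build the annular fiber phantom.

    Returns ``(fiber_field, mask, truth)``: per-voxel unit fiber vectors
    lying in the local circumferential-longitudinal plane at helix angle
    ``alpha(d) = helix_endo + (helix_epi - helix_endo) * d``, the boolean
    myocardium mask, and the analytic truth (depth, segment labels, per-voxel
    angle, per-segment helicity).
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, r, theta = _phantom_geometry(spec)
    in_plane = (r >= spec.inner_radius) & (r <= spec.outer_radius)
    d2 = np.clip(
        (r - spec.inner_radius) / (spec.outer_radius - spec.inner_radius), 0.0, 1.0
    )
    seg2 = (np.mod(theta - spec.reference_angle, 360.0) // 60.0).astype(int) + 1

    endo = spec.helix_endo_per_segment[seg2 - 1]
    epi = spec.helix_epi_per_segment[seg2 - 1]
    alpha2 = endo + (epi - endo) * d2  # degrees, per in-plane position

    with np.errstate(invalid="ignore", divide="ignore"):
        rhat_x = np.where(r > 0, dx / r, 0.0)
        rhat_y = np.where(r > 0, dy / r, 0.0)
    # c = z x r  (counterclockwise tangent), l = z
    chat_x, chat_y = -rhat_y, rhat_x
    a = np.radians(alpha2)
    fx = np.cos(a) * chat_x
    fy = np.cos(a) * chat_y
    fz = np.sin(a)

    mask = np.zeros((nx, ny, nz), dtype=bool)
    fiber = np.zeros((nx, ny, nz, 3))
    depth = np.full((nx, ny, nz), np.nan)
    seg_labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    helix = np.full((nx, ny, nz), np.nan)
    lo, hi = spec.slice_range
    for z in range(lo, hi):
        mask[:, :, z] = in_plane
        fiber[:, :, z, 0] = np.where(in_plane, fx, 0.0)
        fiber[:, :, z, 1] = np.where(in_plane, fy, 0.0)
        fiber[:, :, z, 2] = np.where(in_plane, fz, 0.0)
        depth[:, :, z] = np.where(in_plane, d2, np.nan)
        seg_labels[:, :, z] = np.where(in_plane, seg2, 0)
        helix[:, :, z] = np.where(in_plane, alpha2, np.nan)
    if not mask.any():
        raise ValueError("phantom annulus contains no voxels on this grid")
    truth = PhantomTruth(
        depth=depth,
        segment_labels=seg_labels,
        helix_angle=helix,
        helicity_per_segment=spec.true_helicity_per_segment.copy(),
        helicity_global=spec.true_helicity,
    )
    return fiber, mask, truth


def simulate_dwi(
    fiber_field: np.ndarray,
    mask: np.ndarray,
    spec: PhantomSpec,
    scheme: AcquisitionScheme | None = None,
    noise: NoiseModel | None = None,
) -> DWIVolume:
    """Stejskal-Tanner simulation: S = S0 exp(-b g^T D g).

    The per-voxel tensor has its primary axis along the fiber, its smallest
    axis along the local radial direction (transverse/sheetlet angle fixed at
    zero), and eigenvalues from ``spec``.  Background voxels carry noise
    only; ``NoiseModel('none')`` gives the exact signal.
    """
    scheme = scheme or default_scheme()
    noise = noise or NoiseModel(kind="none")
    shape = mask.shape
    n_vol = len(scheme)
    data = np.zeros(shape + (n_vol,))

    dx, dy, r, _ = _phantom_geometry(spec)
    xs, ys, zs = np.nonzero(mask)
    rr = r[xs, ys]
    rhat = np.zeros((xs.size, 3))
    rhat[:, 0] = dx[xs, ys] / rr
    rhat[:, 1] = dy[xs, ys] / rr
    e1 = fiber_field[xs, ys, zs]
    e2 = np.cross(rhat, e1)
    l1, l2, l3 = spec.eigenvalues
    b = scheme.bvals
    g = scheme.bvecs
    q = (
        l1 * (e1 @ g.T) ** 2
        + l2 * (e2 @ g.T) ** 2
        + l3 * (rhat @ g.T) ** 2
    )  # (n_vox, n_vol)
    signal = spec.S0 * np.exp(-b[None, :] * q)
    data[xs, ys, zs] = signal

    if noise.kind != "none":
        rng = np.random.default_rng(noise.seed)
        sigma = spec.S0 / noise.snr
        n1 = rng.normal(0.0, sigma, size=data.shape)
        if noise.kind == "gaussian":
            data = data + n1
        else:  # rician magnitude
            n2 = rng.normal(0.0, sigma, size=data.shape)
            data = np.hypot(data + n1, n2)
    return DWIVolume(data=data, voxel_size=spec.voxel_size, scheme=scheme)


# --------------------------------------------------------------------------
# FISH micrographs
# --------------------------------------------------------------------------


@dataclasses.dataclass
class FishSpec:
    """Synthetic two-channel FISH section layout.

    ``spots_per_nucleus`` may be a scalar or a map ``(segment, layer) ->
    rate``; spot counts per ROI are deterministic,
    ``round(n_nuclei * rate)``.  With ``non_overlapping`` set, nuclei keep a
    center distance >= 2 x radius and spots keep ``min_spot_separation``, so
    ideal counting recovers the truth exactly.
    """

    image_shape: tuple[int, int] = (640, 640)
    center: tuple[float, float] | None = None
    inner_radius_px: float = 110.0
    outer_radius_px: float = 300.0
    reference_angle: float = 0.0
    n_nuclei_per_roi: int = 20
    nuclei_radius_px: float = 4.0
    spots_per_nucleus: float | dict = 2.0
    psf_sigma: float = 1.2
    nucleus_amplitude: float = 120.0
    spot_amplitude: float = 60.0
    background_level: float = 2.0
    background_sd: float = 1.0
    non_overlapping: bool = True
    min_spot_separation: float | None = None
    min_nucleus_separation: float | None = None

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = (
                (self.image_shape[0] - 1) / 2.0,
                (self.image_shape[1] - 1) / 2.0,
            )
        if self.n_nuclei_per_roi < 0:
            raise ValueError("n_nuclei_per_roi must be >= 0")
        if self.min_spot_separation is None:
            self.min_spot_separation = (
                4.0 * self.psf_sigma + 2.0 if self.non_overlapping else 0.0
            )
        if self.min_nucleus_separation is None:
            # non-overlapping: disjoint even after PSF blur; otherwise allow
            # partial overlap that watershed splitting must resolve
            self.min_nucleus_separation = (
                2.0 * self.nuclei_radius_px + 4.0 * self.psf_sigma + 2.0
                if self.non_overlapping
                else 1.5 * self.nuclei_radius_px
            )

    def nuclei_detection_params(self) -> dict:
        """Detection parameters matched to this spec's nucleus scale."""
        area = math.pi * self.nuclei_radius_px**2
        # split threshold just above one nucleus: a merged pair always
        # exceeds it, and a large single survives its one-peak watershed
        return {
            "min_area_px": max(4, int(0.3 * area)),
            "max_area_px": int(1.2 * area),
            "min_peak_distance": max(2, int(self.nuclei_radius_px) - 1),
        }

    def rate(self, segment: int, layer: str) -> float:
        if isinstance(self.spots_per_nucleus, dict):
            val = self.spots_per_nucleus[(segment, layer)]
        else:
            val = self.spots_per_nucleus
        if val < 0:
            raise ValueError("spots_per_nucleus must be >= 0")
        return float(val)


@dataclasses.dataclass
class FishTruth:
    """Exact generator truth: object positions and per-ROI counts."""

    nuclei_centers: np.ndarray
    spot_centers: np.ndarray
    nuclei_radius_px: float
    per_roi: pd.DataFrame  # segment, layer, nuclei, spots, spots_per_nucleus

    @property
    def total_nuclei(self) -> int:
        return int(self.per_roi["nuclei"].sum())

    @property
    def total_spots(self) -> int:
        return int(self.per_roi["spots"].sum())


_ROI_GEOMETRY_CACHE: dict[tuple, tuple] = {}


def _cached_roi_geometry(spec: FishSpec):
    """ROI labels + per-ROI edge distance maps, cached by layout geometry."""
    key = (
        spec.image_shape,
        spec.center,
        spec.inner_radius_px,
        spec.outer_radius_px,
        spec.reference_angle,
    )
    if key not in _ROI_GEOMETRY_CACHE:
        rois = build_rois(
            spec.image_shape,
            mode="eighteen_roi",
            geometry={
                "center": spec.center,
                "inner_radius": spec.inner_radius_px,
                "outer_radius": spec.outer_radius_px,
                "reference_angle": spec.reference_angle,
            },
        )
        edts = {
            int(rid): ndimage.distance_transform_edt(rois.label_mask == rid)
            for rid in rois.roi_ids()
        }
        if len(_ROI_GEOMETRY_CACHE) > 8:
            _ROI_GEOMETRY_CACHE.clear()
        _ROI_GEOMETRY_CACHE[key] = (rois, edts)
    return _ROI_GEOMETRY_CACHE[key]


def _sample_points(
    rng: np.random.Generator,
    eligible: np.ndarray,
    n: int,
    min_dist: float,
    existing: list[np.ndarray],
    what: str,
) -> list[np.ndarray]:
    """Rejection-sample n points among eligible pixel coords with a minimum
    pairwise distance against `existing` points; bounded retries."""
    coords = np.argwhere(eligible)
    if coords.shape[0] == 0 and n > 0:
        raise ValueError(f"no eligible pixels to place {what}")
    placed: list[np.ndarray] = []
    pool = np.array(existing, dtype=float).reshape(-1, 2)
    max_tries = 300 * max(n, 1)
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise ValueError(
                f"could not place {n} {what} at min separation {min_dist:.1f} px "
                f"in an ROI of {coords.shape[0]} px: density too high"
            )
        tries += 1
        cand = coords[rng.integers(coords.shape[0])].astype(float)
        cand += rng.uniform(-0.4, 0.4, size=2)
        if min_dist > 0 and pool.shape[0]:
            d2 = ((pool - cand) ** 2).sum(axis=1)
            if d2.min() < min_dist * min_dist:
                continue
        placed.append(cand)
        pool = np.vstack([pool, cand])
    return placed


def make_fish_image(
    spec: FishSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, FishTruth, ROISet]:
    """Render a synthetic (DAPI, CITED4) image pair with exact truth.

    Nuclei are uniform disks and spots are PSF-sized points, both blurred by
    a Gaussian PSF and superposed on Gaussian background noise.  Objects are
    placed inside eroded ROI interiors so each detection belongs
    unambiguously to one ROI.  Identical (spec, seed) gives bit-identical
    images.
    """
    rng = np.random.default_rng(seed)
    rois, roi_edts = _cached_roi_geometry(spec)
    dapi = np.zeros(spec.image_shape)
    cited4 = np.zeros(spec.image_shape)
    nuc_margin = spec.nuclei_radius_px + 2 * spec.psf_sigma + 1
    spot_margin = 2 * spec.psf_sigma + 1

    all_nuclei: list[np.ndarray] = []
    all_spots: list[np.ndarray] = []
    rows = []
    for _, meta in rois.table.iterrows():
        rid, segment, layer = int(meta["roi_id"]), int(meta["segment"]), meta["layer"]
        edge_dist = roi_edts[rid]
        interior = edge_dist > nuc_margin
        n_nuc = int(spec.n_nuclei_per_roi)
        min_nd = float(spec.min_nucleus_separation)
        nuclei = _sample_points(rng, interior, n_nuc, min_nd, all_nuclei, "nuclei")
        all_nuclei.extend(nuclei)

        rate = spec.rate(segment, layer)
        n_spots = int(round(n_nuc * rate))
        sp_interior = edge_dist > spot_margin
        min_sd = float(spec.min_spot_separation)
        spots = _sample_points(rng, sp_interior, n_spots, min_sd, all_spots, "spots")
        all_spots.extend(spots)
        rows.append(
            {
                "roi_id": rid,
                "segment": segment,
                "layer": layer,
                "nuclei": n_nuc,
                "spots": n_spots,
                "spots_per_nucleus": rate,
            }
        )

    # render nuclei as disks (local patches)
    if all_nuclei:
        canvas = np.zeros(spec.image_shape)
        rad = spec.nuclei_radius_px
        w = int(np.ceil(rad)) + 1
        for cx, cy in all_nuclei:
            x0, x1 = int(cx) - w, int(cx) + w + 1
            y0, y1 = int(cy) - w, int(cy) + w + 1
            px, py = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1), indexing="ij")
            patch = ((px - cx) ** 2 + (py - cy) ** 2) <= rad * rad
            canvas[x0:x1, y0:y1][patch] = 1.0
        dapi = spec.nucleus_amplitude * ndimage.gaussian_filter(canvas, spec.psf_sigma)
    # render spots as unit-mass impulses scaled so the blurred peak height
    # equals spot_amplitude
    if all_spots:
        imp = np.zeros(spec.image_shape)
        mass = spec.spot_amplitude * 2.0 * math.pi * spec.psf_sigma**2
        for cx, cy in all_spots:
            imp[int(round(cx)), int(round(cy))] += mass
        cited4 = ndimage.gaussian_filter(imp, spec.psf_sigma)

    dapi = dapi + rng.normal(spec.background_level, spec.background_sd, spec.image_shape)
    cited4 = cited4 + rng.normal(
        spec.background_level, spec.background_sd, spec.image_shape
    )
    np.clip(dapi, 0, None, out=dapi)
    np.clip(cited4, 0, None, out=cited4)

    truth = FishTruth(
        nuclei_centers=np.array(all_nuclei).reshape(-1, 2),
        spot_centers=np.array(all_spots).reshape(-1, 2),
        nuclei_radius_px=spec.nuclei_radius_px,
        per_roi=pd.DataFrame(rows),
    )
    return dapi, cited4, truth, rois


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------


def segment_effect_map(effect: float | dict) -> np.ndarray:
    """Expand a regional effect spec into a per-segment length-6 array.

    A dict may give 'septal' (segments 2-3), 'lateral' (segments 5-6) and
    'other' (segments 1 and 4); a scalar applies everywhere.
    """
    out = np.zeros(N_SEGMENTS)
    if isinstance(effect, dict):
        for s in range(1, N_SEGMENTS + 1):
            if s in SEPTAL_SEGMENTS:
                out[s - 1] = effect.get("septal", effect.get("other", 0.0))
            elif s in LATERAL_SEGMENTS:
                out[s - 1] = effect.get("lateral", effect.get("other", 0.0))
            else:
                out[s - 1] = effect.get("other", 0.0)
    else:
        out[:] = float(effect)
    if np.any(out < -1):
        raise ValueError("effects must be >= -1")
    return out


@dataclasses.dataclass
class CohortSpec:
    """Structure of a synthetic animal cohort.

    Effects are fractional changes of the exercise groups relative to
    sedentary; the C4KO genotype forces CITED4 expression to
    ``ko_expression`` and zeroes the exercise helicity effect, with a
    baseline helicity deficit relative to controls.  ``between_animal_cv``
    is the biological coefficient of variation shared (with correlation
    ``helicity_cited4_correlation``) between an animal's helicity and its
    CITED4 truth.
    """

    n_per_group: int = 7
    groups: tuple = (("sedentary", "wildtype"), ("exercise", "wildtype"))
    helicity_effect: float | dict = dataclasses.field(
        default_factory=lambda: {"septal": 0.171, "lateral": 0.215, "other": 0.199}
    )
    cited4_effect: float | dict = dataclasses.field(
        default_factory=lambda: {"septal": 0.329, "lateral": 0.717, "other": 0.59}
    )
    cited4_base_rate: float = 2.0
    between_animal_cv: float = 0.15
    helicity_cited4_correlation: float = 0.9
    wall_thickness_effect: float = 0.477
    lv_mass_effect: float = 0.095
    ko_baseline_deficit: float = 0.317
    ko_expression: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g in self.groups:
            if g[0] not in ("sedentary", "exercise"):
                raise ValueError(f"unknown activity {g[0]!r}")
            if g[1] not in ("wildtype", "C4KO", "flfl"):
                raise ValueError(f"unknown genotype {g[1]!r}")
        segment_effect_map(self.helicity_effect)
        segment_effect_map(self.cited4_effect)
        if not 0 <= self.between_animal_cv:
            raise ValueError("between_animal_cv must be >= 0")


@dataclasses.dataclass
class AnimalRecord:
    animal_id: str
    activity: str
    genotype: str
    truth: dict
    phantom_spec: PhantomSpec | None = None
    dwi: DWIVolume | None = None
    mask: np.ndarray | None = None
    fish: tuple | None = None  # (dapi, cited4, FishTruth, ROISet)


def _group_geometry(spec: CohortSpec, template: PhantomSpec, exercised: bool):
    """Per-group annulus radii implementing the wall-thickness / mass effects."""
    r_in, r_out = template.inner_radius, template.outer_radius
    if not exercised:
        return r_in, r_out
    w = (r_out - r_in) * (1 + spec.wall_thickness_effect)
    area = (r_out**2 - r_in**2) * (1 + spec.lv_mass_effect)
    s = area / w  # r_out + r_in
    new_in = max((s - w) / 2.0, 0.05)
    return new_in, new_in + w


def cohort_truths(
    spec: CohortSpec, phantom_template: PhantomSpec | None = None
) -> pd.DataFrame:
    """Draw the per-animal ground-truth table (no image rendering).

    Per-animal true helicity magnitude per segment is the group mean times a
    lognormal-free multiplicative factor ``1 + cv * z``; exercise effects
    apply per segment to non-knockout genotypes only.
    """
    template = phantom_template or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    base_span = np.abs(template.true_helicity_per_segment)  # magnitude per segment
    h_eff = segment_effect_map(spec.helicity_effect)
    c_eff = segment_effect_map(spec.cited4_effect)
    rho = spec.helicity_cited4_correlation
    cv = spec.between_animal_cv

    rows = []
    counter = 0
    for activity, genotype in spec.groups:
        exercised = activity == "exercise"
        ko = genotype == "C4KO"
        for _ in range(spec.n_per_group):
            counter += 1
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            zg = rng.normal(size=2)  # independent anatomical variation
            fac_h = max(1 + cv * z[0], 0.2)
            fac_c = max(1 + cv * z[1], 0.05)
            span = base_span * fac_h
            if ko:
                span = span * (1 - spec.ko_baseline_deficit)
            elif exercised:
                span = span * (1 + h_eff)
            if ko:
                rate = np.full(N_SEGMENTS, spec.ko_expression)
            else:
                rate = spec.cited4_base_rate * fac_c * (
                    (1 + c_eff) if exercised else np.ones(N_SEGMENTS)
                )
            r_in, r_out = _group_geometry(spec, template, exercised and not ko)
            # mild per-animal anatomical variation of wall and annulus area
            w = (r_out - r_in) * max(1 + 0.3 * cv * zg[0], 0.5)
            area = (r_out**2 - r_in**2) * max(1 + 0.1 * cv * zg[1], 0.5)
            s = area / w
            r_in = max((s - w) / 2.0, 0.35)
            r_out = r_in + w
            row = {
                "animal_id": f"A{counter:03d}",
                "activity": activity,
                "genotype": genotype,
                "inner_radius": r_in,
                "outer_radius": r_out,
                "dwi_seed": int(rng.integers(2**31)),
                "fish_seed": int(rng.integers(2**31)),
            }
            for s in range(N_SEGMENTS):
                row[f"helicity_seg{s + 1}"] = span[s]
                row[f"cited4_seg{s + 1}"] = rate[s]
            row["helicity_septal"] = span[[1, 2]].mean()
            row["helicity_lateral"] = span[[4, 5]].mean()
            row["helicity_total"] = span.mean()
            row["cited4_septal"] = rate[[1, 2]].mean()
            row["cited4_lateral"] = rate[[4, 5]].mean()
            row["cited4_total"] = rate.mean()
            rows.append(row)
    return pd.DataFrame(rows)


def make_cohort(
    spec: CohortSpec,
    phantom_template: PhantomSpec | None = None,
    fish_template: FishSpec | None = None,
    scheme: AcquisitionScheme | None = None,
    noise: NoiseModel | None = None,
    render: bool = True,
) -> list[AnimalRecord]:
    """Generate a cohort: per-animal truths plus (optionally) rendered DWI
    volumes and FISH image pairs.

    With ``render=False`` only the truth table is materialized into the
    records (used for fast statistical calibration).  All randomness derives
    from ``spec.seed``.
    """
    template = phantom_template or PhantomSpec()
    fish_t = fish_template or FishSpec()
    scheme = scheme or default_scheme()
    truths = cohort_truths(spec, template)

    records: list[AnimalRecord] = []
    for _, row in truths.iterrows():
        truth = row.to_dict()
        rec = AnimalRecord(
            animal_id=row["animal_id"],
            activity=row["activity"],
            genotype=row["genotype"],
            truth=truth,
        )
        if render:
            span = np.array([row[f"helicity_seg{s}"] for s in range(1, 7)])
            sign = np.sign(template.true_helicity_per_segment)
            sign[sign == 0] = -1.0
            # symmetric profile: endo = +span/2, epi = -span/2 (or flipped)
            endo = -sign * span / 2.0
            epi = sign * span / 2.0
            pspec = dataclasses.replace(
                template,
                inner_radius=float(row["inner_radius"]),
                outer_radius=float(row["outer_radius"]),
                helix_endo=np.clip(endo, -90, 90),
                helix_epi=np.clip(epi, -90, 90),
            )
            fiber, mask, _ = make_lv_phantom(pspec)
            nz = noise or NoiseModel(kind="rician", snr=25.0, seed=0)
            nz = dataclasses.replace(nz, seed=int(row["dwi_seed"]) % (2**31))
            dwi = simulate_dwi(fiber, mask, pspec, scheme, nz)
            rates = {
                (s, layer): float(row[f"cited4_seg{s}"])
                for s in range(1, 7)
                for layer in LAYERS
            }
            fspec = dataclasses.replace(fish_t, spots_per_nucleus=rates)
            fish = make_fish_image(fspec, seed=int(row["fish_seed"]) % (2**31))
            rec.phantom_spec = pspec
            rec.dwi = dwi
            rec.mask = mask
            rec.fish = fish
        records.append(rec)
    return records
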