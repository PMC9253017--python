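"""Left-ventricular anatomical reference frame on short-axis image stacks.

Builds everything the helix-angle analysis needs from a binary myocardium
mask: per-slice centroids, local radial/circumferential/longitudinal unit
triads, a normalized transmural depth map (0 at the endocardial border, 1 at
the epicardial border), five equal-depth concentric rings, six 60-degree
AHA angular segments, and simple voxel-count morphometry (wall thickness and
LV mass).

Conventions: 0-based voxel indexing; the slice normal (long axis) defaults
to +z; in-plane polar angle is measured counterclockwise from the +x image
axis; distances use the voxel size in mm.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "MyocardiumMask",
    "LocalFrameField",
    "MorphometryResult",
    "MYOCARDIUM_DENSITY_MG_MM3",
    "segment_myocardium",
    "compute_local_frame",
    "compute_transmural_depth",
    "make_rings",
    "make_aha_segments",
    "mask_morphometry",
]

MYOCARDIUM_DENSITY_MG_MM3 = 1.05


@dataclasses.dataclass
class MyocardiumMask:
    """Binary LV myocardium mask with geometry metadata.

    ``annular_slices`` lists slice indices whose in-plane component has ring
    topology (an enclosed cavity); only those participate in transmural
    analyses.
    """

    mask: np.ndarray  # (x, y, z) bool
    voxel_size: tuple[float, float, float]
    long_axis: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("empty myocardium mask")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.long_axis = self.long_axis / np.linalg.norm(self.long_axis)
        self._centroids: dict[int, tuple[float, float]] = {}
        self._annular: list[int] = []
        for z in range(self.mask.shape[2]):
            sl = self.mask[:, :, z]
            if not sl.any():
                continue
            cx, cy = ndimage.center_of_mass(sl)
            self._centroids[z] = (float(cx), float(cy))
            filled = ndimage.binary_fill_holes(sl)
            if filled.sum() > sl.sum():
                self._annular.append(z)

    @property
    def annular_slices(self) -> list[int]:
        return list(self._annular)

    def centroid(self, z: int) -> tuple[float, float]:
        return self._centroids[z]

    def cavity(self, z: int) -> np.ndarray:
        """In-plane cavity (endocardial lumen) of slice z."""
        sl = self.mask[:, :, z]
        return ndimage.binary_fill_holes(sl) & ~sl


@dataclasses.dataclass
class LocalFrameField:
    """Per-voxel orthonormal (radial, circumferential, longitudinal) triads.

    ``valid`` is False where the radial direction is undefined (voxel at the
    slice centroid).  Triads are right-handed with c = l x r.
    """

    radial: np.ndarray  # (x, y, z, 3)
    circumferential: np.ndarray
    longitudinal: np.ndarray
    valid: np.ndarray  # (x, y, z) bool


@dataclasses.dataclass
class MorphometryResult:
    wall_thickness_mm: float
    lv_mass_mg: float
    per_slice_thickness_mm: dict[int, float]


def segment_myocardium(
    b0_volume: np.ndarray,
    voxel_size: tuple[float, float, float],
    threshold: float | None = None,
    closing_radius: int = 1,
) -> MyocardiumMask:
    """Threshold a b=0 volume and keep the largest ring-topology component.

    Otsu thresholding by default (``threshold`` overrides), followed by a
    morphological closing to suppress salt noise.  Raises if no slice of the
    resulting component has ring topology, advising a manual mask.
    """
    vol = np.asarray(b0_volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("b0 volume must be 3-D")
    if threshold is None:
        if np.ptp(vol) == 0:
            raise ValueError(
                "uniform b0 volume: no threshold separates tissue; "
                "supply a manual mask"
            )
        threshold = float(threshold_otsu(vol.ravel()))
    binary = vol > threshold
    if closing_radius > 0:
        # in-plane closing; salt specks stay isolated and fall out of the
        # largest-component selection below
        struct2 = ndimage.generate_binary_structure(2, 1)
        for z in range(binary.shape[2]):
            binary[:, :, z] = ndimage.binary_closing(
                binary[:, :, z], structure=struct2, iterations=closing_radius
            )
    labels, n = ndimage.label(binary)
    if n == 0:
        raise ValueError(
            "no foreground component found after thresholding; "
            "supply a manual myocardium mask"
        )
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    mm = MyocardiumMask(mask=largest, voxel_size=voxel_size)
    if not mm.annular_slices:
        raise ValueError(
            "largest component has no ring-topology slice; "
            "supply a manual myocardium mask"
        )
    return mm


def compute_local_frame(mm: MyocardiumMask) -> LocalFrameField:
    """Centroid-based local frame: r points outward from the per-slice
    centroid, l is the long axis, c = l x r."""
    shape = mm.mask.shape
    radial = np.zeros(shape + (3,))
    circ = np.zeros(shape + (3,))
    longi = np.zeros(shape + (3,))
    valid = np.zeros(shape, dtype=bool)
    lax = mm.long_axis
    sx, sy, _ = mm.voxel_size
    for z in range(shape[2]):
        sl = mm.mask[:, :, z]
        if not sl.any():
            continue
        cx, cy = mm.centroid(z)
        xs, ys = np.nonzero(sl)
        dx = (xs - cx) * sx
        dy = (ys - cy) * sy
        norm = np.hypot(dx, dy)
        ok = norm > 1e-12
        r = np.zeros((xs.size, 3))
        r[ok, 0] = dx[ok] / norm[ok]
        r[ok, 1] = dy[ok] / norm[ok]
        c = np.cross(lax[None, :], r)
        radial[xs, ys, z] = r
        circ[xs, ys, z] = c
        longi[xs, ys, z] = lax
        valid[xs, ys, z] = ok
    return LocalFrameField(
        radial=radial, circumferential=circ, longitudinal=longi, valid=valid
    )


def compute_transmural_depth(mm: MyocardiumMask) -> np.ndarray:
    """Normalized transmural depth d in [0, 1] per myocardial voxel.

    Per annular slice, d = dist_endo / (dist_endo + dist_epi) with in-plane
    Euclidean distances to the cavity and to the outside; a half-voxel offset
    places d=0/d=1 at the tissue interfaces rather than the first voxel
    center.  Non-annular slices are NaN (excluded downstream).
    """
    shape = mm.mask.shape
    depth = np.full(shape, np.nan)
    sx, sy, _ = mm.voxel_size
    h = 0.5 * float(np.hypot(sx, sy) / np.sqrt(2.0))  # half in-plane voxel
    for z in mm.annular_slices:
        sl = mm.mask[:, :, z]
        cavity = mm.cavity(z)
        filled = sl | cavity
        d_endo = ndimage.distance_transform_edt(~cavity, sampling=(sx, sy))
        d_epi = ndimage.distance_transform_edt(filled, sampling=(sx, sy))
        de = np.maximum(d_endo - h, 0.0)
        dp = np.maximum(d_epi - h, 0.0)
        total = de + dp
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(total > 0, de / total, 0.5)
        depth[:, :, z] = np.where(sl, np.clip(d, 0.0, 1.0), np.nan)
    return depth


def make_rings(depth: np.ndarray, n_rings: int = 5) -> np.ndarray:
    """Equal-depth transmural ring labels 1..n_rings (0 outside / undefined).

    Ring k covers d in [(k-1)/n, k/n), with the last ring closed at d = 1.
    """
    rings = np.zeros(depth.shape, dtype=np.uint8)
    valid = np.isfinite(depth)
    k = np.floor(depth[valid] * n_rings).astype(int)
    k = np.clip(k, 0, n_rings - 1)
    rings[valid] = k + 1
    return rings


def make_aha_segments(
    mm: MyocardiumMask, reference_angle: float = 0.0, n_segments: int = 6
) -> np.ndarray:
    """Angular AHA segment labels 1..n_segments per myocardial voxel.

    Segments are 60-degree sectors counted counterclockwise from
    ``reference_angle`` (degrees, measured from the +x image axis) about the
    per-slice centroid; sector lower edges are inclusive.
    """
    shape = mm.mask.shape
    labels = np.zeros(shape, dtype=np.uint8)
    width = 360.0 / n_segments
    for z in range(shape[2]):
        sl = mm.mask[:, :, z]
        if not sl.any():
            continue
        cx, cy = mm.centroid(z)
        xs, ys = np.nonzero(sl)
        theta = np.degrees(np.arctan2(ys - cy, xs - cx))
        rel = np.mod(theta - reference_angle, 360.0)
        labels[xs, ys, z] = (rel // width).astype(np.uint8) + 1
    return labels


def mask_morphometry(mm: MyocardiumMask) -> MorphometryResult:
    """Wall thickness (mean endo-border distance to the epicardial border,
    mm) and LV mass (voxel volume x 1.05 mg/mm^3)."""
    if not mm.annular_slices:
        raise ValueError("no annular slice: wall thickness undefined")
    sx, sy, sz = mm.voxel_size
    per_slice: dict[int, float] = {}
    for z in mm.annular_slices:
        sl = mm.mask[:, :, z]
        cavity = mm.cavity(z)
        filled = sl | cavity
        endo_border = sl & ndimage.binary_dilation(cavity)
        if not endo_border.any():
            continue
        d_epi = ndimage.distance_transform_edt(filled, sampling=(sx, sy))
        # border voxel centers sit ~half a voxel inside each interface
        per_slice[z] = float(d_epi[endo_border].mean() + 0.5 * sx)
    thickness = float(np.mean(list(per_slice.values())))
    mass = float(mm.mask.sum() * sx * sy * sz * MYOCARDIUM_DENSITY_MG_MM3)
    return MorphometryResult(
        wall_thickness_mm=thickness, lv_mass_mg=mass, per_slice_thickness_mm=per_slice
    )
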