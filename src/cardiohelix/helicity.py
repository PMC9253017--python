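"""Helix angles and the transmural helicity statistic.

The helix angle of a voxel is the angle between the primary diffusion
eigenvector's projection onto the local circumferential-longitudinal wall
plane and the circumferential direction, positive toward the long axis and
confined to [-90, 90] degrees by a sign convention on e1.  Helicity is the
slope of the ring-mean helix angle regressed on normalized transmural depth
(degrees per unit depth), fitted per short-axis slice, per AHA segment, and
aggregated into septal (segments 2-3), lateral (segments 5-6) and total
values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .lv_geometry import LocalFrameField
from .tensor_model import EigenSystemField

__all__ = [
    "HelixAngleMap",
    "RingProfile",
    "HelicityResult",
    "DEFAULT_REGIONS",
    "helix_angle_map",
    "ring_means",
    "helicity_slope",
    "regional_helicity",
]

DEFAULT_REGIONS = {"septal": (2, 3), "lateral": (5, 6)}
GLOBAL_SEGMENT = 0  # segment code for whole-slice (all segments pooled) rows


@dataclasses.dataclass
class HelixAngleMap:
    """Per-voxel helix angle (degrees, [-90, 90]); NaN where invalid."""

    alpha: np.ndarray
    valid: np.ndarray


@dataclasses.dataclass
class RingProfile:
    """Ring-mean helix angles, tidy per (slice, segment, ring).

    ``segment`` 0 denotes the whole slice pooled across segments.  ``d_mean``
    is the observed mean transmural depth of the ring's voxels, used as the
    regression abscissa.
    """

    table: pd.DataFrame  # slice, segment, ring, alpha_mean, d_mean, n


@dataclasses.dataclass
class HelicityResult:
    """Helicity (degrees per unit transmural depth) at several granularities.

    ``fits`` holds one OLS line per (slice, segment) unit; ``per_segment``
    averages each segment's slices; ``global_`` averages the whole-slice
    fits; ``regions`` maps septal/lateral/total to signed means, with
    ``regions_abs`` the same on magnitudes.
    """

    fits: pd.DataFrame  # slice, segment, helicity, intercept, r2, n_rings
    per_segment: pd.Series  # index: segment 1..6
    global_: float
    regions: dict
    regions_abs: dict


def helix_angle_map(
    es: EigenSystemField | np.ndarray,
    frame: LocalFrameField,
    mask: np.ndarray,
    min_plane_norm: float = 1e-3,
) -> HelixAngleMap:
    """Compute per-voxel helix angles from the primary eigenvector field.

    The e1 sign is fixed so that e1 . c >= 0 (tie broken by e1 . l >= 0);
    e1 is projected onto the circumferential-longitudinal plane and
    alpha = atan2(p . l, p . c).  Voxels with a nearly radial fiber
    (projection norm < ``min_plane_norm``), an invalid frame, or a
    degenerate tensor are marked invalid.
    """
    e1 = es.e1 if isinstance(es, EigenSystemField) else np.asarray(es)
    mask = np.asarray(mask, dtype=bool)
    alpha = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)

    sel = mask & frame.valid
    if isinstance(es, EigenSystemField):
        sel &= ~es.degenerate
    idx = np.nonzero(sel)
    v = e1[idx]
    c = frame.circumferential[idx]
    l = frame.longitudinal[idx]
    r = frame.radial[idx]

    vc = np.einsum("ij,ij->i", v, c)
    vl = np.einsum("ij,ij->i", v, l)
    flip = (vc < 0) | ((vc == 0) & (vl < 0))
    sgn = np.where(flip, -1.0, 1.0)
    v = v * sgn[:, None]
    # project out the radial component
    vr = np.einsum("ij,ij->i", v, r)
    p = v - vr[:, None] * r
    pc = np.einsum("ij,ij->i", p, c)
    pl = np.einsum("ij,ij->i", p, l)
    pnorm = np.hypot(pc, pl)
    ok = pnorm >= min_plane_norm
    ang = np.degrees(np.arctan2(pl, pc))
    # sign convention keeps pc >= 0, hence ang in [-90, 90]
    ang = np.clip(ang, -90.0, 90.0)
    a_full = np.full(mask.shape, np.nan)
    a_full[idx] = np.where(ok, ang, np.nan)
    v_full = np.zeros(mask.shape, dtype=bool)
    v_full[idx] = ok
    alpha[...] = a_full
    valid[...] = v_full
    return HelixAngleMap(alpha=alpha, valid=valid)


def ring_means(
    hmap: HelixAngleMap,
    rings: np.ndarray,
    aha: np.ndarray,
    depth: np.ndarray,
    min_voxels: int = 5,
) -> RingProfile:
    """Arithmetic mean helix angle per (slice, AHA segment, ring).

    Also emits whole-slice rows (segment 0) pooling all segments.  Rings
    with fewer than ``min_voxels`` valid voxels are excluded (recorded with
    their count and NaN mean).
    """
    rows = []
    nz = hmap.alpha.shape[2]
    ring_ids = np.unique(rings[rings > 0])
    for z in range(nz):
        a = hmap.alpha[:, :, z]
        ok = hmap.valid[:, :, z]
        rg = rings[:, :, z]
        sg = aha[:, :, z]
        dd = depth[:, :, z]
        if not ok.any():
            continue
        for seg in [GLOBAL_SEGMENT, *np.unique(sg[sg > 0])]:
            seg_sel = ok if seg == GLOBAL_SEGMENT else (ok & (sg == seg))
            for k in ring_ids:
                sel = seg_sel & (rg == k)
                n = int(sel.sum())
                rows.append(
                    {
                        "slice": z,
                        "segment": int(seg),
                        "ring": int(k),
                        "alpha_mean": float(a[sel].mean()) if n >= min_voxels else np.nan,
                        "d_mean": float(dd[sel].mean()) if n >= min_voxels else np.nan,
                        "n": n,
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        good = table.dropna(subset=["d_mean"])
        # observed mean depths must increase with ring index within a unit
        for _, grp in good.groupby(["slice", "segment"]):
            d = grp.sort_values("ring")["d_mean"].to_numpy()
            if np.any(np.diff(d) <= 0):
                raise AssertionError("ring mean depths not strictly increasing")
    return RingProfile(table=table)


def helicity_slope(
    profile: RingProfile, min_rings: int = 3, regions: dict | None = None
) -> HelicityResult:
    """Fit helicity: OLS slope of ring-mean angle on ring-mean depth.

    One fit per (slice, segment) with >= ``min_rings`` usable rings; units
    failing that are excluded.  Per-segment values average a segment's slice
    fits; the global value averages the whole-slice fits; regional values
    are unweighted means of their segments' values, with the 'total' region
    the mean over all six segments.
    """
    regions = regions or DEFAULT_REGIONS
    tab = profile.table.dropna(subset=["alpha_mean", "d_mean"])
    fits = []
    for (z, seg), grp in tab.groupby(["slice", "segment"]):
        if len(grp) < min_rings:
            continue
        d = grp["d_mean"].to_numpy()
        a = grp["alpha_mean"].to_numpy()
        if np.ptp(d) == 0:
            continue
        slope, intercept = np.polyfit(d, a, 1)
        pred = slope * d + intercept
        ss_res = float(((a - pred) ** 2).sum())
        ss_tot = float(((a - a.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        fits.append(
            {
                "slice": int(z),
                "segment": int(seg),
                "helicity": float(slope),
                "intercept": float(intercept),
                "r2": r2,
                "n_rings": int(len(grp)),
            }
        )
    fits_df = pd.DataFrame(fits)
    if fits_df.empty:
        raise ValueError("no (slice, segment) unit had enough rings to fit")

    seg_df = fits_df[fits_df["segment"] != GLOBAL_SEGMENT]
    per_segment = seg_df.groupby("segment")["helicity"].mean()
    glob_fits = fits_df[fits_df["segment"] == GLOBAL_SEGMENT]["helicity"]
    global_ = float(glob_fits.mean()) if len(glob_fits) else float(per_segment.mean())

    result = HelicityResult(
        fits=fits_df,
        per_segment=per_segment,
        global_=global_,
        regions={},
        regions_abs={},
    )
    result.regions = regional_helicity(result, regions, signed=True)
    result.regions_abs = regional_helicity(result, regions, signed=False)
    return result


def regional_helicity(
    result: HelicityResult, regions: dict | None = None, signed: bool = True
) -> dict:
    """Aggregate per-segment helicity into named regions plus 'total'.

    Each region is the unweighted mean of its member segments; 'total' is
    the mean over all six.  Missing member segments mark the region partial
    (value still computed from available members, NaN if none).
    """
    regions = regions or DEFAULT_REGIONS
    vals = result.per_segment if signed else result.per_segment.abs()
    out: dict[str, float] = {}
    for name, segs in regions.items():
        member = vals.reindex(list(segs))
        out[name] = float(member.mean()) if member.notna().any() else float("nan")
        if member.isna().any():
            out[f"{name}_partial"] = True
    all6 = vals.reindex(range(1, 7))
    out["total"] = float(all6.mean()) if all6.notna().any() else float("nan")
    return out
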