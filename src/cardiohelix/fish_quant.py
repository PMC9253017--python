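"""RNA-FISH spot and nucleus counting with AHA-segment x layer ROIs.

Quantifies single-molecule mRNA spots (CITED4 channel) and nuclei (DAPI
channel) by thresholding and connected-component counting, within regions of
interest organized as six 60-degree angular segments times three transmural
layers (endo-, mid-, epicardium), and forms the per-ROI spots-per-nucleus
ratio (CITED4/DAPI).  Overlapping nuclei are split by distance-transform
watershed; clustered spots are resolved by dividing the component area by
the median single-spot area.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "ROISet",
    "SpotCountResult",
    "LAYERS",
    "SEPTAL_SEGMENTS",
    "LATERAL_SEGMENTS",
    "build_rois",
    "detect_nuclei",
    "detect_spots",
    "quantify",
]

LAYERS = ("endo", "mid", "epi")
SEPTAL_SEGMENTS = (2, 3)
LATERAL_SEGMENTS = (5, 6)


@dataclasses.dataclass
class ROISet:
    """Label-mask ROI partition of a tissue section.

    ``label_mask`` assigns each pixel an ROI id (0 = outside any ROI);
    ``table`` maps roi_id -> (segment, layer).  In ``whole_image`` mode there
    is a single ROI with segment 0 / layer 'all'.
    """

    label_mask: np.ndarray
    table: pd.DataFrame  # columns: roi_id, segment, layer, area_px

    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()


@dataclasses.dataclass
class SpotCountResult:
    """Counts and CITED4/DAPI ratios per ROI with regional aggregates.

    Aggregate ratios are summed spots over summed nuclei (not means of
    ratios), so aggregation is conservative in counts.
    """

    per_roi: pd.DataFrame  # segment, layer, cited4, dapi, ratio
    per_segment: pd.DataFrame  # segment, cited4, dapi, ratio
    regions: pd.DataFrame  # region (septal/lateral/total), cited4, dapi, ratio


def _annulus_geometry(shape, geometry):
    cx, cy = geometry.get("center", ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0))
    xs, ys = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dx = xs - cx
    dy = ys - cy
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))
    return r, theta


def build_rois(
    image_shape: tuple[int, int],
    mode: Literal["eighteen_roi", "whole_image"] = "eighteen_roi",
    geometry: dict | None = None,
    tissue_mask: np.ndarray | None = None,
) -> ROISet:
    """Build the ROI partition for a short-axis tissue section.

    ``eighteen_roi`` mode partitions an annular tissue region into 6 angular
    segments x 3 radial layers (endo: d < 1/3, mid: 1/3 <= d < 2/3, epi:
    d >= 2/3 of the transmural span).  ``geometry`` supplies ``center``
    (pixels), ``inner_radius`` and ``outer_radius`` (pixels) and
    ``reference_angle`` (degrees).  ``whole_image`` mode returns one ROI
    covering the tissue mask (or the full image).
    """
    if mode == "whole_image":
        label_mask = np.zeros(image_shape, dtype=np.int32)
        region = (
            np.ones(image_shape, dtype=bool) if tissue_mask is None else tissue_mask
        )
        label_mask[region] = 1
        table = pd.DataFrame(
            [{"roi_id": 1, "segment": 0, "layer": "all", "area_px": int(region.sum())}]
        )
        return ROISet(label_mask=label_mask, table=table)

    if geometry is None or "inner_radius" not in geometry or "outer_radius" not in geometry:
        raise ValueError("eighteen_roi mode needs geometry with inner/outer radius")
    r_in = float(geometry["inner_radius"])
    r_out = float(geometry["outer_radius"])
    if not (0 < r_in < r_out):
        raise ValueError("need 0 < inner_radius < outer_radius")
    ref = float(geometry.get("reference_angle", 0.0))
    r, theta = _annulus_geometry(image_shape, geometry)
    annulus = (r >= r_in) & (r <= r_out)
    if tissue_mask is not None:
        annulus &= tissue_mask
    d = np.clip((r - r_in) / (r_out - r_in), 0.0, 1.0)
    layer_idx = np.clip(np.floor(d * 3).astype(int), 0, 2)
    seg = (np.mod(theta - ref, 360.0) // 60.0).astype(int) + 1

    label_mask = np.zeros(image_shape, dtype=np.int32)
    rows = []
    for s in range(1, 7):
        for li, layer in enumerate(LAYERS):
            roi_id = (s - 1) * 3 + li + 1
            sel = annulus & (seg == s) & (layer_idx == li)
            label_mask[sel] = roi_id
            rows.append(
                {
                    "roi_id": roi_id,
                    "segment": s,
                    "layer": layer,
                    "area_px": int(sel.sum()),
                }
            )
    return ROISet(label_mask=label_mask, table=pd.DataFrame(rows))


def _binarize(
    image: np.ndarray, threshold_policy, min_contrast_sd: float = 0.0
) -> np.ndarray:
    """Threshold an image; with Otsu, ``min_contrast_sd`` > 0 requires the
    foreground/background class separation to exceed that many image SDs
    (guards against thresholding inside pure background noise)."""
    img = np.asarray(image, dtype=float)
    if threshold_policy in (None, "otsu"):
        if np.ptp(img) == 0:
            raise ValueError(
                "uniform image: Otsu cannot separate signal; "
                "supply a manual absolute threshold"
            )
        thr = float(threshold_otsu(img))
        if min_contrast_sd > 0:
            fg = img > thr
            if fg.all() or not fg.any():
                return np.zeros(img.shape, dtype=bool)
            sep = img[fg].mean() - img[~fg].mean()
            if sep < min_contrast_sd * img.std():
                return np.zeros(img.shape, dtype=bool)
    else:
        thr = float(threshold_policy)
    return img > thr


def detect_nuclei(
    dapi: np.ndarray,
    roi: np.ndarray | None = None,
    threshold_policy="otsu",
    min_area_px: int = 30,
    max_area_px: int = 2000,
    min_peak_distance: int = 5,
) -> tuple[int, np.ndarray]:
    """Count DAPI nuclei: threshold, area-filter, watershed-split large blobs.

    Returns (count, centroids).  ``roi`` restricts counting to a boolean
    region.  Components above ``max_area_px`` are split by watershed on the
    distance transform.
    """
    img = np.asarray(dapi, dtype=float)
    if np.ptp(img) == 0 and img.max() == 0:
        return 0, np.empty((0, 2))
    binary = _binarize(img, threshold_policy)
    if roi is not None:
        binary &= roi
    labels = cc_label(binary)
    centroids: list[tuple[float, float]] = []
    for prop in regionprops(labels):
        if prop.area < min_area_px:
            continue
        if prop.area <= max_area_px:
            centroids.append(prop.centroid)
            continue
        # split merged nuclei
        comp = labels == prop.label
        dist = ndimage.distance_transform_edt(comp)
        peaks = peak_local_max(
            dist, min_distance=min_peak_distance, labels=comp, exclude_border=False
        )
        if len(peaks) < 2:
            centroids.append(prop.centroid)
            continue
        markers = np.zeros_like(labels)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        ws = watershed(-dist, markers, mask=comp)
        for sub in regionprops(ws):
            if sub.area >= min_area_px:
                centroids.append(sub.centroid)
    return len(centroids), np.array(centroids).reshape(-1, 2)


def detect_spots(
    cited4: np.ndarray,
    roi: np.ndarray | None = None,
    threshold_policy="otsu",
    min_area_px: int = 1,
    max_single_spot_area_px: int = 9,
) -> int:
    """Count mRNA spots: threshold + connected components.

    Components up to ``max_single_spot_area_px`` count 1; larger components
    (clustered dots) count round(area / median single-spot area).
    """
    img = np.asarray(cited4, dtype=float)
    if np.ptp(img) == 0:
        return 0 if img.max() == 0 else _raise_uniform()
    binary = _binarize(img, threshold_policy, min_contrast_sd=4.0)
    if roi is not None:
        binary &= roi
    labels = cc_label(binary)
    areas = np.array(
        [p.area for p in regionprops(labels) if p.area >= min_area_px], dtype=float
    )
    if areas.size == 0:
        return 0
    singles = areas[areas <= max_single_spot_area_px]
    unit = float(np.median(singles)) if singles.size else float(max_single_spot_area_px)
    count = 0
    for a in areas:
        count += 1 if a <= max_single_spot_area_px else max(1, int(round(a / unit)))
    return count


def _raise_uniform():
    raise ValueError(
        "saturated uniform image: no threshold separates signal; "
        "supply a manual absolute threshold"
    )


def quantify(
    dapi: np.ndarray,
    cited4: np.ndarray,
    rois: ROISet,
    nuclei_params: dict | None = None,
    spot_params: dict | None = None,
) -> SpotCountResult:
    """Count nuclei and spots per ROI and aggregate.

    Detection runs once on each full channel; each detected object is
    assigned to the ROI containing it (nuclei by centroid, spot clusters
    proportionally by member pixels).  Aggregate ratios are summed spots over
    summed nuclei; ROIs without nuclei have ratio NaN.
    """
    if dapi.shape != cited4.shape or dapi.shape != rois.label_mask.shape:
        raise ValueError("channels and ROI mask must share one image frame")
    nuclei_params = dict(nuclei_params or {})
    spot_params = dict(spot_params or {})

    in_any_roi = rois.label_mask > 0
    _, centroids = detect_nuclei(dapi, roi=None, **nuclei_params)
    nuclei_per_roi: dict[int, int] = {int(i): 0 for i in rois.roi_ids()}
    for cx, cy in centroids:
        rid = int(rois.label_mask[int(round(cx)), int(round(cy))])
        if rid > 0:
            nuclei_per_roi[rid] += 1

    spots_per_roi = _spots_by_roi(cited4, rois, spot_params, in_any_roi)

    rows = []
    for _, meta in rois.table.iterrows():
        rid = int(meta["roi_id"])
        c = spots_per_roi.get(rid, 0)
        n = nuclei_per_roi.get(rid, 0)
        rows.append(
            {
                "roi_id": rid,
                "segment": int(meta["segment"]),
                "layer": meta["layer"],
                "cited4": int(c),
                "dapi": int(n),
                "ratio": c / n if n > 0 else np.nan,
            }
        )
    per_roi = pd.DataFrame(rows)

    per_segment = (
        per_roi.groupby("segment", as_index=False)[["cited4", "dapi"]].sum()
    )
    per_segment["ratio"] = np.where(
        per_segment["dapi"] > 0, per_segment["cited4"] / per_segment["dapi"], np.nan
    )

    def _region(segs) -> dict:
        sub = per_roi[per_roi["segment"].isin(segs)] if segs else per_roi
        c, n = int(sub["cited4"].sum()), int(sub["dapi"].sum())
        return {"cited4": c, "dapi": n, "ratio": c / n if n > 0 else np.nan}

    regions = pd.DataFrame(
        [
            {"region": "septal", **_region(SEPTAL_SEGMENTS)},
            {"region": "lateral", **_region(LATERAL_SEGMENTS)},
            {"region": "total", **_region(None)},
        ]
    )
    return SpotCountResult(per_roi=per_roi, per_segment=per_segment, regions=regions)


def _spots_by_roi(cited4, rois, spot_params, in_any_roi) -> dict[int, int]:
    """Spot counts per ROI; clustered components are apportioned by pixels."""
    img = np.asarray(cited4, dtype=float)
    out: dict[int, int] = {int(i): 0 for i in rois.roi_ids()}
    if np.ptp(img) == 0 and img.max() == 0:
        return out
    threshold_policy = spot_params.pop("threshold_policy", "otsu")
    min_area = spot_params.pop("min_area_px", 1)
    max_single = spot_params.pop("max_single_spot_area_px", 9)
    binary = _binarize(img, threshold_policy, min_contrast_sd=4.0)
    labels = cc_label(binary)
    props = [p for p in regionprops(labels) if p.area >= min_area]
    singles = np.array([p.area for p in props if p.area <= max_single], dtype=float)
    unit = float(np.median(singles)) if singles.size else float(max_single)
    for p in props:
        n_spots = 1 if p.area <= max_single else max(1, int(round(p.area / unit)))
        coords = p.coords
        rids = rois.label_mask[coords[:, 0], coords[:, 1]]
        rids = rids[rids > 0]
        if rids.size == 0:
            continue
        # majority ROI takes the whole component's count
        vals, counts = np.unique(rids, return_counts=True)
        out[int(vals[np.argmax(counts)])] += n_spots
    return out
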