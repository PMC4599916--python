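"""Mask construction and per-object intensity measurement.

The DAPI channel yields the hepatocyte nuclear mask (threshold, connected
components, area filter). The cytoplasmic mask combines phalloidin and DAPI:
each nucleus grows outward into the phalloidin-bounded cell interior, the
growth capped at a fixed distance and partitioned by nearest-nucleus
territory so neighbouring cytoplasms never share pixels. HSCs are segmented
from manually drawn GFAP polygons when available (matching the original
manual procedure) or by GFAP thresholding as the automated surrogate; their
nuclear/cytoplasmic split is never attempted — only whole-cell means are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledMask",
    "SegmentationParams",
    "segment_nuclei",
    "segment_cytoplasm",
    "segment_hsc",
    "remove_objects_overlapping",
    "measure_intensities",
]


@dataclass
class LabeledMask:
    """A label image: 0 = background, k > 0 = object k (labels consecutive)."""

    labels: np.ndarray
    n_objects: int
    compartment: str  # nucleus | cytoplasm | hsc

    def pixels(self, k: int):
        return np.nonzero(self.labels == k)


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and object-filter settings.

    ``cyto_expansion`` caps how far (in pixels) cytoplasm may grow from the
    nuclear boundary. ``exclude_border`` drops objects touching the frame
    edge (off by default).
    """

    threshold_method: str = "otsu"  # otsu | fixed
    fixed_threshold: float = 0.5
    min_area: int = 20
    max_area: int = 10000
    cyto_expansion: float = 8.0
    exclude_border: bool = False

    def __post_init__(self):
        if self.threshold_method not in ("otsu", "fixed"):
            raise ConfigurationError(f"unknown threshold method {self.threshold_method!r}")
        if not (0.0 <= self.fixed_threshold <= 1.0):
            raise ConfigurationError("fixed threshold must lie in [0, 1]")
        if not self.min_area < self.max_area:
            raise ConfigurationError("require min_area < max_area")


def _validate_image(img, name="image") -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise InputError(f"{name} must be 2D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    if arr.min() < 0 or arr.max() > 1:
        raise InputError(f"{name} values must lie in [0, 1]")
    return arr


def _threshold(arr: np.ndarray, params: SegmentationParams) -> np.ndarray:
    if params.threshold_method == "fixed":
        return arr > params.fixed_threshold
    if np.ptp(arr) < 1e-12:  # degenerate/blank image: no foreground
        return np.zeros(arr.shape, dtype=bool)
    return arr > threshold_otsu(arr)


def _filter_and_relabel(labels: np.ndarray, params: SegmentationParams, compartment: str) -> LabeledMask:
    n = int(labels.max())
    if n == 0:
        return LabeledMask(labels.astype(np.int32), 0, compartment)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    keep = (areas >= params.min_area) & (areas <= params.max_area)
    keep[0] = False
    if params.exclude_border:
        border = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        keep[border[border > 0]] = False
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    out = mapping[labels]
    return LabeledMask(out, int(keep.sum()), compartment)


def segment_nuclei(dapi, params: SegmentationParams = SegmentationParams()) -> LabeledMask:
    """Label hepatocyte nuclei in the DAPI channel.

    Blank or degenerate images yield zero objects rather than an error.
    """
    arr = _validate_image(dapi, "dapi")
    fg = _threshold(arr, params)
    labels = cc_label(fg, connectivity=1)
    return _filter_and_relabel(labels, params, "nucleus")


def segment_cytoplasm(
    phalloidin,
    dapi,
    nuclei: LabeledMask,
    params: SegmentationParams = SegmentationParams(),
) -> LabeledMask:
    """One cytoplasm object per nucleus, label-matched to the nuclear mask.

    Cytoplasm pixels lie inside the phalloidin-enclosed cell interior
    (boundary ridges excluded), outside every nucleus, within
    ``cyto_expansion`` pixels of their own nucleus, and in the nearest-
    nucleus territory — so objects of adjacent cells are pixel-disjoint.
    """
    ph = _validate_image(phalloidin, "phalloidin")
    da = _validate_image(dapi, "dapi")
    if ph.shape != da.shape or ph.shape != nuclei.labels.shape:
        raise InputError(
            f"shape mismatch: phalloidin {ph.shape}, dapi {da.shape}, "
            f"nuclei {nuclei.labels.shape}"
        )
    out = np.zeros_like(nuclei.labels)
    if nuclei.n_objects == 0:
        return LabeledMask(out, 0, "cytoplasm")
    ridge = _threshold(ph, params)
    interior = ndi.binary_fill_holes(ridge) | _threshold(da, params) | (nuclei.labels > 0)
    dist, (inds_r, inds_c) = ndi.distance_transform_edt(
        nuclei.labels == 0, return_indices=True
    )
    territory = nuclei.labels[inds_r, inds_c]
    cyto = (
        interior
        & ~ridge
        & (nuclei.labels == 0)
        & (dist <= params.cyto_expansion)
    )
    out[cyto] = territory[cyto]
    return LabeledMask(out, nuclei.n_objects, "cytoplasm")


def _polygon_is_simple(poly: np.ndarray) -> bool:
    from shapely.geometry import Polygon

    return Polygon([(float(r), float(c)) for r, c in poly]).is_valid


def segment_hsc(
    gfap,
    params: SegmentationParams = SegmentationParams(),
    manual_rois=None,
) -> LabeledMask:
    """Label HSCs from the GFAP channel.

    When ``manual_rois`` (a list of (k, 2) polygon vertex arrays in
    (row, col)) is given, the rasterized polygons become the objects,
    mirroring manual segmentation; otherwise GFAP thresholding with area
    filtering is used.
    """
    arr = _validate_image(gfap, "gfap")
    if manual_rois is not None:
        out = np.zeros(arr.shape, dtype=np.int32)
        for k, poly in enumerate(manual_rois, start=1):
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise InputError("each ROI must be a (k>=3, 2) vertex array")
            if poly.min() < 0 or (poly[:, 0] >= arr.shape[0]).any() or (
                poly[:, 1] >= arr.shape[1]
            ).any():
                raise InputError(f"ROI {k} extends outside the frame")
            if not _polygon_is_simple(poly):
                raise InputError(f"ROI {k} is self-intersecting")
            rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=arr.shape)
            out[rr, cc] = k
        return LabeledMask(out, len(manual_rois), "hsc")
    fg = _threshold(arr, params)
    labels = cc_label(fg, connectivity=1)
    return _filter_and_relabel(labels, params, "hsc")


def remove_objects_overlapping(mask: LabeledMask, other: LabeledMask) -> LabeledMask:
    """Drop objects of ``mask`` that share any pixel with ``other`` and relabel.

    Used to keep HSC nuclear footprints (GFAP-positive) out of the
    hepatocyte nuclear mask before cytoplasm growth and measurement.
    """
    if mask.labels.shape != other.labels.shape:
        raise InputError("masks must share dimensions")
    if mask.n_objects == 0 or other.n_objects == 0:
        return mask
    overlapping = np.unique(mask.labels[(mask.labels > 0) & (other.labels > 0)])
    keep = np.ones(mask.n_objects + 1, dtype=bool)
    keep[0] = False
    keep[overlapping] = False
    mapping = np.zeros(mask.n_objects + 1, dtype=np.int32)
    mapping[keep] = np.arange(1, int(keep.sum()) + 1)
    return LabeledMask(mapping[mask.labels], int(keep.sum()), mask.compartment)


def _object_means(target: np.ndarray, mask: LabeledMask):
    idx = np.arange(1, mask.n_objects + 1)
    if mask.n_objects == 0:
        return np.empty(0), np.empty(0), np.empty((0, 2))
    areas = ndi.sum_labels(np.ones_like(target), mask.labels, index=idx)
    means = np.full(mask.n_objects, np.nan)
    ok = areas > 0
    if ok.any():
        means[ok] = ndi.mean(target, mask.labels, index=idx[ok])
    centroids = np.full((mask.n_objects, 2), np.nan)
    if ok.any():
        com = ndi.center_of_mass(np.ones_like(target), mask.labels, index=idx[ok])
        centroids[ok] = np.asarray(com)
    return means, areas, centroids


def measure_intensities(
    target,
    nuclei: LabeledMask | None,
    cytoplasm: LabeledMask | None,
    hsc: LabeledMask | None = None,
    image_id: str = "image-00",
) -> pd.DataFrame:
    """Per-object mean target intensities as a CellMeasurement table.

    Hepatocyte rows carry the nuclear mean (over the nucleus object) and the
    cytoplasmic mean (over the matching cytoplasm object); HSC rows carry a
    whole-cell mean only. Objects with zero pixels are excluded with a logged
    warning.
    """
    arr = _validate_image(target, "target")
    for mask, name in ((nuclei, "nuclei"), (cytoplasm, "cytoplasm"), (hsc, "hsc")):
        if mask is not None and mask.labels.shape != arr.shape:
            raise InputError(f"{name} mask shape {mask.labels.shape} != target {arr.shape}")
    rows = []
    if nuclei is not None and nuclei.n_objects > 0:
        if cytoplasm is None or cytoplasm.n_objects != nuclei.n_objects:
            raise InputError("cytoplasm mask must be label-matched to the nuclear mask")
        n_means, n_areas, centroids = _object_means(arr, nuclei)
        c_means, c_areas, _ = _object_means(arr, cytoplasm)
        for k in range(nuclei.n_objects):
            if n_areas[k] == 0 or c_areas[k] == 0:
                logger.warning(
                    "image %s: hepatocyte object %d has an empty compartment; excluded",
                    image_id, k + 1,
                )
                continue
            rows.append({
                "image_id": image_id, "cell_id": k + 1, "cell_type": "hepatocyte",
                "y": centroids[k, 0], "x": centroids[k, 1],
                "i_nuclear": n_means[k], "i_cytoplasmic": c_means[k],
                "i_wholecell": np.nan,
            })
    if hsc is not None and hsc.n_objects > 0:
        w_means, w_areas, w_centroids = _object_means(arr, hsc)
        offset = nuclei.n_objects if nuclei is not None else 0
        for k in range(hsc.n_objects):
            if w_areas[k] == 0:
                logger.warning("image %s: HSC object %d has zero pixels; excluded", image_id, k + 1)
                continue
            rows.append({
                "image_id": image_id, "cell_id": offset + k + 1, "cell_type": "hsc",
                "y": w_centroids[k, 0], "x": w_centroids[k, 1],
                "i_nuclear": np.nan, "i_cytoplasmic": np.nan,
                "i_wholecell": w_means[k],
            })
    columns = ["image_id", "cell_id", "cell_type", "y", "x",
               "i_nuclear", "i_cytoplasmic", "i_wholecell"]
    return pd.DataFrame(rows, columns=columns)
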