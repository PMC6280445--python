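"""Nuclear segmentation and per-cell fluorescence measurement.

The measurement stage of the pipeline: segment individual cells on the
nuclear (DAPI) channel, then record for every cell and every marker channel
the mean fluorescence concentration — dye intensity per um^2 — defined as

    intensity = sum(pixel values under the cell label) / (cell area in um^2)

optionally divided by a detector gain recorded in the image sidecar, so the
value is on the same arbitrary-units-per-um^2 scale as table-based inputs.
Intensities are computed from raw pixels; background subtraction is an
explicit opt-in flag.

Segmentation recipe: Gaussian smoothing, automatic global threshold (Otsu,
computed shift-invariantly) or a fixed value, optional splitting of touching
objects by a distance-transform watershed, and small-object removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .synthetic import CELL_META_COLUMNS  # shared cell-table schema  # noqa: F401


@dataclass
class SegmentationParams:
    """Knobs of the nuclear segmentation recipe (physical units).

    ``threshold=None`` selects the automatic (Otsu) threshold; a float fixes
    it.  ``min_area_um2`` removes debris below a plausible nucleus size.
    ``split_touching`` runs the distance-transform watershed; for sparse,
    non-touching nuclei it is a no-op.
    """

    smoothing_sigma_um: float = 0.5
    threshold: float | None = None
    min_area_um2: float = 8.0
    split_touching: bool = True
    min_peak_distance_um: float = 3.0

    def validate(self) -> None:
        if self.smoothing_sigma_um < 0:
            raise ValueError("smoothing sigma must be >= 0")
        if self.min_area_um2 <= 0:
            raise ValueError("minimum object area must be > 0")


def segment_cells(
    nuclear: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float = 0.5,
) -> np.ndarray:
    """Segment nuclei into a label mask (0 = background, labels 1..K).

    A blank (constant) image yields an empty mask rather than an error.
    The automatic threshold is computed on the image minus its minimum, so
    adding a constant offset to every pixel leaves the mask unchanged.
    """
    params = params or SegmentationParams()
    params.validate()
    if nuclear.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {nuclear.shape}")
    img = nuclear.astype(float)
    img -= img.min()  # offset invariance for the automatic threshold
    if img.max() == 0:
        return np.zeros(nuclear.shape, dtype=np.int32)
    sigma_px = params.smoothing_sigma_um / pixel_size_um
    if sigma_px > 0:
        img = gaussian(img, sigma=sigma_px, preserve_range=True)
    thr = params.threshold if params.threshold is not None else (
        threshold_otsu(img)
    )
    binary = img > thr
    min_area_px = max(int(round(params.min_area_um2 / pixel_size_um**2)), 1)
    # removes objects with area <= min_area_px - 1, i.e. below the minimum
    binary = remove_small_objects(binary, max_size=min_area_px - 1)
    if not binary.any():
        return np.zeros(nuclear.shape, dtype=np.int32)
    if params.split_touching:
        labels = _watershed_split(binary, params, pixel_size_um)
    else:
        labels, _ = ndi.label(binary)
    labels = _drop_small_labels(labels, min_area_px)
    return labels.astype(np.int32)


def _watershed_split(
    binary: np.ndarray, params: SegmentationParams, pixel_size_um: float
) -> np.ndarray:
    distance = ndi.distance_transform_edt(binary)
    min_dist_px = max(int(round(params.min_peak_distance_um / pixel_size_um)), 1)
    peaks = peak_local_max(
        distance,
        min_distance=min_dist_px,
        labels=binary,
        exclude_border=False,
    )
    if len(peaks) == 0:
        labels, _ = ndi.label(binary)
        return labels
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-distance, markers, mask=binary)


def _drop_small_labels(labels: np.ndarray, min_area_px: int) -> np.ndarray:
    if labels.max() == 0:
        return labels
    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts < min_area_px)
    out = labels.copy()
    out[np.isin(out, too_small[too_small > 0])] = 0
    # relabel consecutively so labels are 1..K
    uniq = np.unique(out)
    uniq = uniq[uniq > 0]
    remap = np.zeros(out.max() + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[out]


def measure_cells(
    mask: np.ndarray,
    channels: np.ndarray,
    channel_names: tuple[str, ...],
    pixel_size_um: float = 0.5,
    intensity_gain: float = 1.0,
    patient_id: str = "",
    core_id: str = "",
    background_subtract: bool = False,
) -> pd.DataFrame:
    """Per-cell mean intensity per channel from a label mask.

    ``channels`` is a (C, H, W) stack matching ``channel_names``.  Each
    cell's intensity for a channel is the pixel sum under its label divided
    by its area in um^2 (and by ``intensity_gain`` when the image sidecar
    records one).  Centroids are physical coordinates (um) of the label's
    center of mass measured from the top-left pixel center; one record per
    nonzero label.  ``background_subtract`` removes the per-channel modal
    (background) mean, clipping at zero; default off.
    """
    channels = np.asarray(channels)
    if channels.ndim == 2:
        channels = channels[None]
    if channels.shape[1:] != mask.shape:
        raise ValueError(
            f"channel stack shape {channels.shape[1:]} does not match mask "
            f"shape {mask.shape}"
        )
    if len(channel_names) != channels.shape[0]:
        raise ValueError(
            f"{channels.shape[0]} channels but {len(channel_names)} names"
        )
    labels = np.unique(mask)
    labels = labels[labels > 0]
    px_area = pixel_size_um * pixel_size_um
    records: dict[str, np.ndarray] = {}
    if len(labels) == 0:
        cols = list(CELL_META_COLUMNS) + list(channel_names)
        return pd.DataFrame(columns=cols)

    areas_px = ndi.sum_labels(np.ones_like(mask, dtype=float), mask, labels)
    area_um2 = areas_px * px_area
    cy, cx = np.array(
        ndi.center_of_mass(np.ones_like(mask, dtype=float), mask, labels)
    ).T
    records["cell_id"] = labels.astype(np.int64)
    records["patient_id"] = np.full(len(labels), patient_id, dtype=object)
    records["core_id"] = np.full(len(labels), core_id, dtype=object)
    # pixel index i has its center at (i + 0.5) * pixel_size
    records["x_um"] = (cx + 0.5) * pixel_size_um
    records["y_um"] = (cy + 0.5) * pixel_size_um
    records["area_um2"] = area_um2
    records["is_reference"] = np.zeros(len(labels), dtype=bool)
    records["subtype"] = np.full(len(labels), "", dtype=object)
    for c, name in enumerate(channel_names):
        chan = channels[c].astype(float)
        sums = ndi.sum_labels(chan, mask, labels)
        intensity = sums / area_um2 / intensity_gain
        if background_subtract:
            bg = np.median(chan[mask == 0]) / px_area / intensity_gain
            intensity = np.clip(intensity - bg, 0.0, None)
        records[name] = intensity
    return pd.DataFrame(records)


def define_analysis_region(
    cells: pd.DataFrame, polygon_um
) -> pd.DataFrame:
    """Restrict a cell table to a manually defined analysis region.

    ``polygon_um`` is a sequence of (x, y) vertices in um.  A cell is kept
    iff its centroid lies inside the polygon or on its boundary.
    """
    from shapely.geometry import Point, Polygon

    vertices = list(polygon_um)
    if len(vertices) < 3:
        raise ValueError(
            f"analysis region needs >= 3 vertices, got {len(vertices)}"
        )
    poly = Polygon(vertices)
    if not poly.is_valid or poly.area == 0:
        raise ValueError("analysis region polygon is degenerate")
    xs = cells["x_um"].to_numpy()
    ys = cells["y_um"].to_numpy()
    keep = np.fromiter(
        (poly.covers(Point(x, y)) for x, y in zip(xs, ys)),
        dtype=bool,
        count=len(cells),
    )
    return cells[keep]


def match_labels(
    predicted: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5
) -> tuple[int, int, int]:
    """Greedy maximum-overlap matching of predicted vs truth labels.

    Returns ``(n_matched, n_predicted, n_truth)`` where a match requires
    intersection-over-union >= ``iou_threshold``.  Utility for validating
    segmentation against rendered ground-truth masks.
    """
    pred_ids = np.unique(predicted)
    pred_ids = pred_ids[pred_ids > 0]
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]
    matched = 0
    used = set()
    pred_areas = {p: int((predicted == p).sum()) for p in pred_ids}
    for t in truth_ids:
        t_mask = truth == t
        t_area = int(t_mask.sum())
        overlap_labels, overlap_counts = np.unique(
            predicted[t_mask], return_counts=True
        )
        best_iou, best_p = 0.0, None
        for p, inter in zip(overlap_labels, overlap_counts):
            if p == 0 or p in used:
                continue
            union = t_area + pred_areas[int(p)] - int(inter)
            iou = inter / union
            if iou > best_iou:
                best_iou, best_p = iou, int(p)
        if best_p is not None and best_iou >= iou_threshold:
            matched += 1
            used.add(best_p)
    return matched, len(pred_ids), len(truth_ids)
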