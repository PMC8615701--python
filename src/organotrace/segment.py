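"""Nucleus, perinuclear-ring, cell-area and organoid segmentation.

The high-content readouts downstream all rest on labeled masks:

* nuclei from the nuclear-stain (Hoechst) channel — smoothed global Otsu
  threshold plus a distance-transform watershed to split touching nuclei;
* a perinuclear cytoplasmic ring per nucleus — nearest-nucleus label
  expansion minus the nuclei, the region over which cytoplasmic EGFP is
  averaged;
* organoid footprints from the summed, normalized Hoechst + EGFP
  channels, with physical areas and radial distances per organoid;
* the total cell area from the tubulin channel, the mask inside which
  texture is scored;
* allocation of each nucleus to the organoid *core* or *periphery*: a
  nucleus whose centroid lies within ``rim_width_px`` (default 100) of the
  organoid circumference — measured by the Euclidean distance transform of
  the organoid mask — belongs to the periphery, anything deeper to the
  core.

Conventions: pixel indices are 0-based (row, col); physical positions are
(col + 0.5, row + 0.5) * pixel_size_um; areas are pixel counts times
pixel_size_um**2.  Thresholding guards against pure-noise images by
requiring the foreground/background intensity separation to exceed three
background standard deviations; otherwise the mask is empty.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import expand_labels, watershed

logger = logging.getLogger("organotrace")

__all__ = [
    "LabelImage",
    "OrganoidRecord",
    "RegionAssignment",
    "segment_nuclei",
    "derive_cytoplasm_rings",
    "segment_organoids",
    "assign_core_periphery",
    "segment_cell_area",
    "estimate_background",
]

DEFAULT_AREA_THRESHOLD_UM2 = 8000.0  # large/small organoid cut-off
DEFAULT_RIM_WIDTH_PX = 100  # periphery rim measured from the circumference


@dataclass
class LabelImage:
    """Integer-labeled mask sharing geometry with its source image."""

    labels: np.ndarray
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


@dataclass
class OrganoidRecord:
    organoid_id: int
    centroid_xy_um: tuple[float, float]
    area_um2: float
    distance_um: float
    size_class: str  # "small" | "large"


@dataclass
class RegionAssignment:
    nucleus_id: int
    organoid_id: int
    zone: str  # "core" | "periphery"
    rim_width_px: int
    boundary_distance_px: float


def _separated_foreground(smoothed: np.ndarray, min_separation_sd: float = 3.0,
                          method: str = "otsu"):
    """Thresholded foreground, or None when the split does not beat the noise.

    ``method='otsu'`` maximizes inter-class variance (bright, compact
    objects such as nuclei); ``method='triangle'`` tracks the background
    shoulder of the histogram and keeps dim diffuse signal foreground
    (whole organoid / cell footprints).
    """
    if np.ptp(smoothed) == 0:
        return None
    th = (threshold_triangle(smoothed) if method == "triangle"
          else threshold_otsu(smoothed))
    fg = smoothed > th
    if not fg.any() or fg.all():
        return None
    bg_sd = float(smoothed[~fg].std())
    sep = float(smoothed[fg].mean() - smoothed[~fg].mean())
    if sep < min_separation_sd * max(bg_sd, 1e-12):
        return None
    return fg


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def segment_nuclei(
    hoechst_image: np.ndarray,
    min_area_px: int = 120,
    max_area_px: int = 5000,
    pixel_size_um: float = 1.0,
    smooth_sigma: float = 2.0,
    min_distance_px: int = 10,
) -> LabelImage:
    """Segment nuclei from the nuclear-stain channel.

    Smoothed global Otsu threshold, then a distance-transform watershed
    seeded at distance maxima to split touching nuclei.  Objects outside
    [min_area_px, max_area_px] are discarded; surviving labels are
    consecutive from 1.  An image without signal yields an empty mask.
    """
    img = np.asarray(hoechst_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if min_area_px >= max_area_px:
        raise ValueError("min_area_px must be < max_area_px")

    sm = ndi.gaussian_filter(img, smooth_sigma)
    fg = _separated_foreground(sm)
    if fg is None:
        logger.warning("segment_nuclei: no foreground found; empty mask")
        return LabelImage(np.zeros(img.shape, np.int32), pixel_size_um,
                          "hoechst")

    dist = ndi.distance_transform_edt(fg)
    coords = peak_local_max(dist, min_distance=min_distance_px, labels=fg,
                            exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, coords.shape[0] + 1)
    labels = watershed(-dist, markers, mask=fg)

    sizes = np.bincount(labels.ravel())
    bad = np.nonzero((sizes < min_area_px) | (sizes > max_area_px))[0]
    labels[np.isin(labels, bad[bad > 0])] = 0
    return LabelImage(_relabel_consecutive(labels), pixel_size_um, "hoechst")


def derive_cytoplasm_rings(nuclei: LabelImage,
                           ring_width_px: int = 5) -> LabelImage:
    """Perinuclear cytoplasmic ring per nucleus.

    Each nucleus is expanded by ``ring_width_px`` towards its nearest-
    nucleus Voronoi region (ties go to the nearer nucleus), and the nuclei
    themselves are subtracted, so rings are pairwise disjoint, disjoint
    from every nucleus, and carry the label of their nucleus.
    """
    if ring_width_px < 1:
        raise ValueError("ring_width_px must be >= 1")
    labels = nuclei.labels
    expanded = expand_labels(labels, distance=ring_width_px)
    rings = np.where((expanded > 0) & (labels == 0), expanded, 0)
    return LabelImage(rings.astype(np.int32), nuclei.pixel_size_um,
                      nuclei.channel)


def segment_organoids(
    hoechst_image: np.ndarray,
    egfp_image: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 500.0,
    center_xy_um: tuple[float, float] | None = None,
    area_threshold_um2: float = DEFAULT_AREA_THRESHOLD_UM2,
    smooth_sigma: float = 3.0,
    closing_radius_px: float = 15.0,
) -> tuple[LabelImage, list[OrganoidRecord]]:
    """Segment organoid footprints from combined Hoechst + EGFP signal.

    Both channels are min-max normalized, summed, smoothed, Otsu-
    thresholded, morphologically closed by ``closing_radius_px`` (bridging
    the gaps between individual cells of one organoid) and hole-filled.
    Objects smaller than ``min_area_um2`` are dropped.  Each record carries the centroid in physical
    coordinates, the cross-sectional area, the radial distance from
    ``center_xy_um`` (default: the image center) and the size class
    ("large" iff area > ``area_threshold_um2``).
    """
    h = np.asarray(hoechst_image, dtype=float)
    e = np.asarray(egfp_image, dtype=float)
    if h.shape != e.shape:
        raise ValueError("channel shapes must match")

    def _norm(x):
        ptp = np.ptp(x)
        return (x - x.min()) / ptp if ptp > 0 else np.zeros_like(x)

    combined = ndi.gaussian_filter(_norm(h) + _norm(e), smooth_sigma)
    fg = _separated_foreground(combined, method="triangle")
    if fg is None:
        logger.warning("segment_organoids: no foreground found; empty mask")
        return (LabelImage(np.zeros(h.shape, np.int32), pixel_size_um,
                           "hoechst+egfp"), [])
    if closing_radius_px > 0:
        # distance-transform closing: fast equivalent of a disk closing
        dilated = ndi.distance_transform_edt(~fg) <= closing_radius_px
        fg = ndi.distance_transform_edt(dilated) > closing_radius_px
    fg = ndi.binary_fill_holes(fg)
    labels, _ = ndi.label(fg, structure=np.ones((3, 3), dtype=int))

    min_area_px = min_area_um2 / pixel_size_um**2
    sizes = np.bincount(labels.ravel())
    bad = np.nonzero(sizes < min_area_px)[0]
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels = _relabel_consecutive(labels)

    if center_xy_um is None:
        center_xy_um = ((h.shape[1] / 2.0) * pixel_size_um,
                        (h.shape[0] / 2.0) * pixel_size_um)
    records = []
    for prop in regionprops(labels):
        cy, cx = prop.centroid
        centroid = ((cx + 0.5) * pixel_size_um, (cy + 0.5) * pixel_size_um)
        area = prop.area * pixel_size_um**2
        dist = math.hypot(centroid[0] - center_xy_um[0],
                          centroid[1] - center_xy_um[1])
        records.append(OrganoidRecord(
            organoid_id=int(prop.label),
            centroid_xy_um=centroid,
            area_um2=float(area),
            distance_um=float(dist),
            size_class="large" if area > area_threshold_um2 else "small",
        ))
    return LabelImage(labels, pixel_size_um, "hoechst+egfp"), records


def assign_core_periphery(
    organoid_mask: LabelImage,
    nuclei: LabelImage,
    rim_width_px: int = DEFAULT_RIM_WIDTH_PX,
) -> list[RegionAssignment]:
    """Allocate each nucleus to organoid core or periphery.

    The distance of every in-organoid pixel to the organoid boundary is
    the Euclidean distance transform of the organoid mask; a nucleus is
    *periphery* iff this distance at its centroid is <= ``rim_width_px``,
    otherwise *core*.  Nuclei outside every organoid are skipped with a
    warning, so core + periphery partition each organoid's nuclei.
    """
    if rim_width_px <= 0:
        raise ValueError("rim_width_px must be positive")
    org = organoid_mask.labels
    dist = ndi.distance_transform_edt(org > 0)
    out = []
    for prop in regionprops(nuclei.labels):
        r, c = (int(round(x)) for x in prop.centroid)
        r = min(max(r, 0), org.shape[0] - 1)
        c = min(max(c, 0), org.shape[1] - 1)
        org_id = int(org[r, c])
        if org_id == 0:
            logger.warning("nucleus %d lies outside every organoid; skipped",
                           prop.label)
            continue
        d = float(dist[r, c])
        zone = "periphery" if d <= rim_width_px else "core"
        out.append(RegionAssignment(int(prop.label), org_id, zone,
                                    rim_width_px, d))
    return out


def segment_cell_area(
    eyfp_image: np.ndarray,
    pixel_size_um: float = 1.0,
    smooth_sigma: float = 2.0,
    min_object_px: int = 64,
) -> LabelImage:
    """Total-cell-area mask from the tubulin channel (single label).

    Thresholded, hole-filled tubulin signal; the mask inside which texture
    is scored.  A constant positive image is entirely foreground; an image
    whose intensity split does not beat the noise yields an empty mask
    with a warning.
    """
    img = np.asarray(eyfp_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if np.ptp(img) == 0:
        if img.flat[0] > 0:
            return LabelImage(np.ones(img.shape, np.int32), pixel_size_um,
                              "eyfp")
        logger.warning("segment_cell_area: empty image; empty mask")
        return LabelImage(np.zeros(img.shape, np.int32), pixel_size_um,
                          "eyfp")
    sm = ndi.gaussian_filter(img, smooth_sigma)
    fg = _separated_foreground(sm)
    if fg is None:
        logger.warning("segment_cell_area: no foreground found; empty mask")
        return LabelImage(np.zeros(img.shape, np.int32), pixel_size_um,
                          "eyfp")
    fg = ndi.binary_fill_holes(fg)
    comp, n = ndi.label(fg)
    if n:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        fg = np.isin(comp, np.nonzero(sizes >= min_object_px)[0])
    return LabelImage(fg.astype(np.int32), pixel_size_um, "eyfp")


def estimate_background(
    image: np.ndarray,
    foreground_mask: np.ndarray,
    dilate_px: int = 5,
    fallback_percentile: float = 5.0,
) -> float:
    """Median intensity of pixels clearly outside the foreground.

    The foreground is dilated by ``dilate_px`` before sampling so blurred
    object tails do not contaminate the estimate.  If fewer than 1% of
    pixels remain background, the estimate falls back to the
    ``fallback_percentile`` of the whole image (logged).
    """
    img = np.asarray(image, dtype=float)
    fg = np.asarray(foreground_mask, dtype=bool)
    if img.shape != fg.shape:
        raise ValueError("image and foreground_mask shapes must match")
    if dilate_px > 0 and fg.any():
        fg = ndi.binary_dilation(fg, structure=disk(dilate_px))
    bg = ~fg
    if bg.mean() < 0.01:
        logger.warning("estimate_background: <1%% background pixels; "
                       "falling back to the %gth percentile",
                       fallback_percentile)
        return float(np.percentile(img, fallback_percentile))
    return float(np.median(img[bg]))
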