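"""Per-cell translocation ratio and Haralick-contrast texture scoring.

**Nuclear translocation ratio.**  For every cell the background-corrected
mean EGFP intensity is measured over its nucleus (``n``) and its
perinuclear cytoplasmic ring (``c``); the relative nuclear translocation
is ``n / (n + c)``, 0 for a fully cytoplasmic and 1 for a fully nuclear
receptor.  Corrected intensities are floored at 0 so the ratio stays in
[0, 1]; a cell with no signal above background in either region is
flagged invalid and excluded from aggregates rather than raising.  Region
*means* (not sums) are used so the statistic is robust to the different
pixel counts of nucleus and ring.

**Haralick contrast.**  Texture is scored on the gray-level co-occurrence
matrix (GLCM): intensities inside the cell-area mask are quantized to
``levels`` gray levels over a fixed intensity range, pairs of pixels at
each offset are counted (both pixels inside the mask), the counts are
symmetrized and normalized to probabilities P(i, j), and the contrast is

    contrast = sum_ij P(i, j) * (i - j)**2

High contrast means frequent large intensity jumps at the pair distance —
the signature of bright tubulin bundles on a diffuse background.  The
quantization range is held fixed across a time series (by default the
global range of the series), so contrast changes reflect texture, not
intensity rescaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segment import LabelImage

logger = logging.getLogger("organotrace")

__all__ = [
    "GLCMatrix",
    "translocation_ratio",
    "measure_cells",
    "quantize_intensities",
    "compute_glcm",
    "haralick_contrast",
    "contrast_timecourse",
]

DEFAULT_GLCM_LEVELS = 32
DEFAULT_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


# ---------------------------------------------------------------------------
# translocation ratio
# ---------------------------------------------------------------------------

def translocation_ratio(nuc_raw: float, cyt_raw: float,
                        background: float) -> float:
    """Relative nuclear translocation from raw region means.

    ``n = max(nuc_raw - background, 0)``, ``c = max(cyt_raw - background,
    0)``, ratio ``n / (n + c)``.  Returns NaN when ``n + c == 0`` (no
    signal above background): the caller flags such cells invalid.
    """
    if not (np.isfinite(nuc_raw) and np.isfinite(cyt_raw)
            and np.isfinite(background)):
        raise ValueError("inputs must be finite")
    if background < 0:
        raise ValueError("background must be >= 0")
    n = max(nuc_raw - background, 0.0)
    c = max(cyt_raw - background, 0.0)
    if n + c == 0.0:
        return math.nan
    return n / (n + c)


def measure_cells(
    egfp_image: np.ndarray,
    nuclei: LabelImage,
    rings: LabelImage,
    background: float,
    frame_time_h: float = math.nan,
    well_id: str = "",
    organoid_labels: LabelImage | None = None,
    zones: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-cell EGFP measurements and translocation ratios.

    One row per nucleus label: raw nuclear and ring means, the
    background-corrected translocation ratio, the nucleus centroid in
    physical coordinates, and optional organoid id / core-periphery zone
    annotations.  Cells whose ring is empty or whose corrected signal
    vanishes carry ``valid=False``.
    """
    img = np.asarray(egfp_image, dtype=float)
    labs = nuclei.labels
    if img.shape != labs.shape or img.shape != rings.labels.shape:
        raise ValueError("image and mask shapes must match")
    n = nuclei.n_objects
    if n == 0:
        return pd.DataFrame(columns=[
            "cell_id", "well_id", "frame_time_h", "nuc_mean", "cyt_mean",
            "ratio", "valid", "x_um", "y_um", "organoid_id", "zone",
        ])

    ids = np.arange(1, n + 1)
    nuc_means = ndi.mean(img, labels=labs, index=ids)
    ring_sizes = np.bincount(rings.labels.ravel(), minlength=n + 1)[1:]
    cyt_means = np.full(n, math.nan)
    has_ring = ring_sizes > 0
    if has_ring.any():
        cyt_means[has_ring] = ndi.mean(img, labels=rings.labels,
                                       index=ids[has_ring])

    centroids = ndi.center_of_mass(np.ones_like(labs), labels=labs, index=ids)
    psz = nuclei.pixel_size_um

    rows = []
    n_invalid = n_clipped = 0
    for k, nuc_id in enumerate(ids):
        row_c, col_c = centroids[k]
        org_id = None
        if organoid_labels is not None:
            r = min(max(int(round(row_c)), 0), labs.shape[0] - 1)
            c = min(max(int(round(col_c)), 0), labs.shape[1] - 1)
            v = int(organoid_labels.labels[r, c])
            org_id = v if v > 0 else None
        zone = zones.get(int(nuc_id)) if zones else None

        if not has_ring[k]:
            ratio, valid = math.nan, False
            n_invalid += 1
        else:
            ratio = translocation_ratio(float(nuc_means[k]),
                                        float(cyt_means[k]), background)
            valid = not math.isnan(ratio)
            if not valid:
                n_invalid += 1
        rows.append({
            "cell_id": int(nuc_id),
            "well_id": well_id,
            "frame_time_h": frame_time_h,
            "nuc_mean": float(nuc_means[k]),
            "cyt_mean": float(cyt_means[k]) if has_ring[k] else math.nan,
            "ratio": ratio,
            "valid": valid,
            "x_um": (col_c + 0.5) * psz,
            "y_um": (row_c + 0.5) * psz,
            "organoid_id": org_id,
            "zone": zone,
        })
    if n_invalid:
        logger.info("measure_cells: %d/%d cells flagged invalid",
                    n_invalid, n)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLCM / Haralick contrast
# ---------------------------------------------------------------------------

@dataclass
class GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix."""

    levels: int
    offsets: tuple[tuple[int, int], ...]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be (levels, levels)")
        if (m < 0).any():
            raise ValueError("matrix entries must be non-negative")
        if not math.isclose(m.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("matrix must sum to 1")
        self.matrix = m


def quantize_intensities(
    image: np.ndarray,
    levels: int,
    value_range: tuple[float, float],
) -> np.ndarray:
    """Linearly rescale intensities to integer gray levels 0..levels-1."""
    lo, hi = value_range
    img = np.asarray(image, dtype=float)
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.intp)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    image: np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_GLCM_LEVELS,
    offsets: Sequence[tuple[int, int]] = DEFAULT_GLCM_OFFSETS,
    value_range: tuple[float, float] | None = None,
) -> GLCMatrix:
    """Gray-level co-occurrence matrix within a mask.

    For each offset (dy, dx), every pixel pair (p, p + offset) with both
    pixels inside the mask contributes a count; counts are summed over
    offsets, symmetrized and normalized.  ``value_range`` fixes the
    quantization range (defaults to the in-mask min/max of this image;
    pass an explicit range for comparability across a time series).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    offsets = tuple((int(dy), int(dx)) for dy, dx in offsets)
    if not offsets:
        raise ValueError("offsets must be non-empty")
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes must match")

    if value_range is None:
        if not m.any():
            raise ValueError("mask is empty")
        value_range = (float(img[m].min()), float(img[m].max()))
    q = quantize_intensities(img, levels, value_range)

    counts = np.zeros((levels, levels), dtype=float)
    h, w = img.shape
    total_pairs = 0
    for dy, dx in offsets:
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        ys2 = slice(max(0, dy), min(h, h + dy))
        xs2 = slice(max(0, dx), min(w, w + dx))
        valid = m[ys, xs] & m[ys2, xs2]
        a = q[ys, xs][valid]
        b = q[ys2, xs2][valid]
        np.add.at(counts, (a, b), 1.0)
        total_pairs += a.size
    if total_pairs == 0:
        raise ValueError("mask admits no pixel pair at any offset")
    counts = counts + counts.T
    return GLCMatrix(levels, offsets, counts / counts.sum())


def haralick_contrast(glcm: GLCMatrix) -> float:
    """Haralick contrast: sum_ij P(i, j) * (i - j)**2."""
    i, j = np.indices(glcm.matrix.shape)
    return float(np.sum(glcm.matrix * (i - j) ** 2))


def contrast_timecourse(
    stack: np.ndarray,
    masks: Sequence[np.ndarray] | np.ndarray,
    times_h: Sequence[float] | None = None,
    levels: int = DEFAULT_GLCM_LEVELS,
    offsets: Sequence[tuple[int, int]] = DEFAULT_GLCM_OFFSETS,
    value_range: tuple[float, float] | None = None,
    detrend_control: Sequence[float] | None = None,
    well_id: str = "",
) -> pd.DataFrame:
    """Haralick contrast per frame of a time-lapse.

    ``masks`` is one mask per frame (or a single mask broadcast to all).
    Unless given, the quantization range is the global in-mask range of
    the whole stack, so scores are comparable across frames.  When a
    contrast trajectory of an untreated control is supplied via
    ``detrend_control``, its fitted linear trend (e.g. photobleaching) is
    subtracted from the scores; the correction is anchored at t = 0 so
    only the drift, not the offset, is removed.
    """
    stack = np.asarray(stack)
    n_frames = stack.shape[0]
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        masks = [masks] * n_frames
    if len(masks) != n_frames:
        raise ValueError("need one mask per frame")
    t = (np.arange(n_frames, dtype=float) if times_h is None
         else np.asarray(times_h, dtype=float))
    if t.size != n_frames:
        raise ValueError("times_h must align with frames")

    if value_range is None:
        lo = min(float(stack[j][np.asarray(masks[j], bool)].min())
                 for j in range(n_frames))
        hi = max(float(stack[j][np.asarray(masks[j], bool)].max())
                 for j in range(n_frames))
        value_range = (lo, hi)

    rows = []
    for j in range(n_frames):
        mask = np.asarray(masks[j], bool)
        g = compute_glcm(stack[j], mask, levels, offsets, value_range)
        rows.append({
            "well_id": well_id,
            "frame": j,
            "frame_time_h": float(t[j]),
            "contrast": haralick_contrast(g),
            "n_pixels_in_mask": int(mask.sum()),
        })
    out = pd.DataFrame(rows)

    if detrend_control is not None:
        ctrl = np.asarray(detrend_control, dtype=float)
        if ctrl.size != n_frames:
            raise ValueError("detrend_control must align with frames")
        slope, intercept = np.polyfit(t, ctrl, 1)
        trend = slope * (t - t[0])
        out["contrast_raw"] = out["contrast"]
        out["contrast"] = out["contrast"] - trend
    return out
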