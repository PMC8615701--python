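"""Synthetic fluorescence-microscopy and plate-data generation.

Every downstream stage of the package (segmentation, per-cell ratio and
texture quantification, spatial binning, kinetic and dose-response fitting)
is exercised against images produced here, for which the complete ground
truth is known.  The generator emulates the assays of a live-cell
organoid drug-response study:

* two-channel monolayer / organoid fields — a nuclear stain channel
  (Hoechst) and an EGFP-tagged androgen-receptor channel whose signal
  partitions between nucleus and cytoplasm with a known
  ``nuclear_fraction``;
* time-lapse stacks in which the nuclear fraction follows a lagged
  logistic transition (drug-induced nuclear translocation);
* organoids placed at known positions inside a hemispherical scaffold
  dome, with a position-dependent response lag;
* single-channel tubulin images whose fibrous "bundle" texture grows with
  a stabilization level (taxane effect), quantified downstream by Haralick
  contrast;
* viability plates following a four-parameter logistic dose-response with
  multiplicative lognormal noise.

Cells are rendered as flat disks (nucleus) plus annuli (cytoplasm), not as
realistic morphologies: recovery of programmed parameters, not visual
realism, is what the downstream tests measure.  By default the cytoplasmic
annulus has the same area as the nucleus (``cyto_radius = sqrt(2) *
nucleus_radius``), so the mean-intensity translocation ratio used
downstream equals the programmed nuclear fraction exactly in the noise-free
limit.  Rendering first paints noiseless signal, then applies a Gaussian
PSF blur, adds a constant background and Gaussian read noise, and
quantizes to the camera bit depth.  All randomness flows through explicit
seeds; identical inputs and seed give bit-identical images.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from scipy import special

from .kinetics import four_param_logistic

logger = logging.getLogger("organotrace")

__all__ = [
    "ImagingConfig",
    "CellSpec",
    "KineticModel",
    "OrganoidSpec",
    "DomeLayout",
    "GroundTruth",
    "DomeTimelapse",
    "linear_lag",
    "random_cell_layout",
    "organoid_cell_layout",
    "render_monolayer_frame",
    "render_translocation_timelapse",
    "render_dome_timelapse",
    "render_tubulin_frame",
    "render_tubulin_timelapse",
    "simulate_viability_plate",
    "save_stack",
]

SeedLike = int | np.random.SeedSequence


# ---------------------------------------------------------------------------
# configuration and ground-truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Virtual-microscope parameters.

    Defaults emulate a high-content confocal with a 40x objective and a
    16-bit sCMOS camera at 2x2 binning (0.325 um/pixel).
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.325
    bit_depth: int = 16
    background_level: float = 100.0
    noise_sd: float = 2.0
    psf_sigma_px: float = 1.0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not (0 <= self.background_level < 2**self.bit_depth):
            raise ValueError("background_level outside camera range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class CellSpec:
    """One rendered cell: nuclear disk plus cytoplasmic annulus.

    ``total_egfp`` is the integrated EGFP signal of the cell in counts;
    ``nuclear_fraction`` of it is painted inside the nucleus and the rest
    in the annulus, so the programmed fraction is the ground truth the
    downstream translocation ratio must recover.
    """

    center_xy: tuple[float, float]  # (x=col, y=row), pixels
    nucleus_radius_px: float = 14.0
    cyto_radius_px: float = 14.0 * math.sqrt(2.0)
    total_egfp: float = 200_000.0
    nuclear_fraction: float = 0.5
    hoechst_intensity: float = 400.0

    def __post_init__(self):
        if not (0.0 <= self.nuclear_fraction <= 1.0):
            raise ValueError("nuclear_fraction must lie in [0, 1]")
        if not (self.cyto_radius_px > self.nucleus_radius_px > 0):
            raise ValueError("require cyto_radius_px > nucleus_radius_px > 0")


@dataclass(frozen=True)
class KineticModel:
    """Lagged logistic transition of the nuclear fraction in time.

    nuclear_fraction(t) = baseline + (plateau - baseline) *
    logistic((t - lag_h - t50_h) / slope_h), clipped to [0, 1]; the frame
    at t <= 0 (pre-treatment baseline) is exactly ``baseline``.  The true
    half-transition time of the simulated curve is ``lag_h + t50_h``.
    """

    baseline: float = 0.2
    plateau: float = 0.85
    t50_h: float = 0.75
    slope_h: float = 0.25
    lag_h: float = 0.0

    def __post_init__(self):
        if self.plateau < self.baseline:
            raise ValueError("plateau must be >= baseline for activation readouts")
        if self.slope_h <= 0:
            raise ValueError("slope_h must be positive")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")

    @property
    def true_t_half(self) -> float:
        return self.lag_h + self.t50_h

    def value(self, t):
        t = np.asarray(t, dtype=float)
        f = self.baseline + (self.plateau - self.baseline) * special.expit(
            (t - self.lag_h - self.t50_h) / self.slope_h
        )
        f = np.clip(f, 0.0, 1.0)
        return np.where(t <= 0, self.baseline, f)


@dataclass(frozen=True)
class OrganoidSpec:
    organoid_id: int
    position_xy_um: tuple[float, float]
    n_cells: int
    organoid_radius_um: float


@dataclass(frozen=True)
class DomeLayout:
    """Organoids at known positions in a circular scaffold dome.

    ``lag_vs_distance`` maps radial distance from the dome center (um) to
    the kinetic lag (h) applied to the organoid at that distance, emulating
    slower drug penetration towards the dome core.
    """

    center_xy_um: tuple[float, float]
    dome_radius_um: float
    organoids: tuple[OrganoidSpec, ...]
    lag_vs_distance: Callable[[float], float]

    def __post_init__(self):
        ids = [o.organoid_id for o in self.organoids]
        if len(ids) != len(set(ids)):
            raise ValueError("organoid ids must be unique")
        for o in self.organoids:
            if self.distance_um(o) > self.dome_radius_um:
                raise ValueError(
                    f"organoid {o.organoid_id} lies outside the dome"
                )

    def distance_um(self, organoid: OrganoidSpec) -> float:
        dx = organoid.position_xy_um[0] - self.center_xy_um[0]
        dy = organoid.position_xy_um[1] - self.center_xy_um[1]
        return math.hypot(dx, dy)


def linear_lag(max_lag_h: float, dome_radius_um: float,
               inverted: bool = True) -> Callable[[float], float]:
    """Linear distance-to-lag mapping over [0, dome_radius_um].

    With ``inverted=True`` (default) the lag is largest at the dome center
    and zero at the rim, emulating drug diffusing inward from the medium.
    """
    def lag(distance_um: float) -> float:
        x = min(max(distance_um / dome_radius_um, 0.0), 1.0)
        return max_lag_h * (1.0 - x) if inverted else max_lag_h * x
    return lag


@dataclass
class GroundTruth:
    """Programmed per-cell / per-organoid / per-plate parameters.

    ``cells`` has one row per cell (id, position in um, geometry, static
    nuclear_fraction for single frames); ``fractions`` one row per
    (cell, frame) for time-lapses; ``organoids`` one row per organoid
    (position, distance from dome center, programmed lag, area);
    ``plate`` holds 4PL parameters of a simulated viability plate.
    """

    cells: pd.DataFrame
    fractions: pd.DataFrame | None = None
    organoids: pd.DataFrame | None = None
    plate: dict | None = None


@dataclass
class DomeTimelapse:
    """Per-organoid image stacks plus shared ground truth.

    Each organoid is imaged in its own field (as a high-content microscope
    visits fields across the well); ``field_origins_um`` maps organoid id
    to the physical (x, y) of that field's pixel (0, 0), so local centroids
    convert to dome coordinates.
    """

    stacks: dict[int, np.ndarray]
    field_configs: dict[int, ImagingConfig]
    field_origins_um: dict[int, tuple[float, float]]
    times_h: np.ndarray
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# layout helpers
# ---------------------------------------------------------------------------

def _rng(seed: SeedLike) -> np.random.Generator:
    return np.random.default_rng(seed)


def _check_layout(cells: Sequence[CellSpec], config: ImagingConfig) -> None:
    for c in cells:
        x, y = c.center_xy
        r = c.cyto_radius_px
        if not (r <= x <= config.width_px - r and r <= y <= config.height_px - r):
            raise ValueError("cell does not fit inside the frame")
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            d = math.hypot(a.center_xy[0] - b.center_xy[0],
                           a.center_xy[1] - b.center_xy[1])
            if d < a.cyto_radius_px + b.cyto_radius_px:
                raise ValueError(
                    "overlapping cytoplasm disks: layout rejected "
                    "(per-cell ground truth would be ambiguous)"
                )


def random_cell_layout(
    n_cells: int,
    config: ImagingConfig,
    seed: SeedLike,
    nuclear_fraction: float | Sequence[float] | None = None,
    margin_px: float = 4.0,
    max_tries: int = 20_000,
    **cell_kwargs,
) -> list[CellSpec]:
    """Place ``n_cells`` non-overlapping cells uniformly in the frame.

    ``nuclear_fraction`` may be a scalar (all cells), a sequence (per
    cell), or ``None`` to draw each fraction uniformly from [0, 1].
    """
    rng = _rng(seed)
    probe = CellSpec(center_xy=(0.0, 0.0), **{k: v for k, v in cell_kwargs.items()
                                              if k in ("nucleus_radius_px", "cyto_radius_px")}
                     ) if cell_kwargs else CellSpec(center_xy=(0.0, 0.0))
    rc = probe.cyto_radius_px
    lo_x, hi_x = rc + margin_px, config.width_px - rc - margin_px
    lo_y, hi_y = rc + margin_px, config.height_px - rc - margin_px
    if lo_x >= hi_x or lo_y >= hi_y:
        raise ValueError("frame too small for the requested cell size")

    if nuclear_fraction is None:
        fracs = rng.uniform(0.0, 1.0, size=n_cells)
    else:
        fracs = np.broadcast_to(np.asarray(nuclear_fraction, dtype=float),
                                (n_cells,))

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place non-overlapping cells; "
                             "reduce n_cells or enlarge the frame")
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if all(math.hypot(x - cx, y - cy) >= 2 * rc + 1.0
               for cx, cy in centers):
            centers.append((x, y))
    return [
        CellSpec(center_xy=c, nuclear_fraction=float(f), **cell_kwargs)
        for c, f in zip(centers, fracs)
    ]


def organoid_cell_layout(
    n_cells: int,
    organoid_radius_px: float,
    center_xy: tuple[float, float],
    seed: SeedLike,
    max_tries: int = 20_000,
    **cell_kwargs,
) -> list[CellSpec]:
    """Pack non-overlapping cells inside a circular organoid footprint."""
    rng = _rng(seed)
    probe = CellSpec(center_xy=(0.0, 0.0), **{k: v for k, v in cell_kwargs.items()
                                              if k in ("nucleus_radius_px", "cyto_radius_px")}
                     ) if cell_kwargs else CellSpec(center_xy=(0.0, 0.0))
    rc = probe.cyto_radius_px
    rmax = organoid_radius_px - rc
    if rmax <= 0:
        raise ValueError("organoid too small for the requested cell size")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not pack cells into organoid; "
                             "reduce n_cells or enlarge organoid")
        r = rmax * math.sqrt(rng.uniform())
        th = rng.uniform(0.0, 2.0 * math.pi)
        x = center_xy[0] + r * math.cos(th)
        y = center_xy[1] + r * math.sin(th)
        if all(math.hypot(x - cx, y - cy) >= 2 * rc + 1.0
               for cx, cy in centers):
            centers.append((x, y))
    return [CellSpec(center_xy=c, **cell_kwargs) for c in centers]


# ---------------------------------------------------------------------------
# low-level rendering
# ---------------------------------------------------------------------------

def _disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float):
    """Boolean disk mask restricted to its bounding box (slices, mask)."""
    h, w = shape
    r0 = max(int(math.floor(cy - r)) - 1, 0)
    r1 = min(int(math.ceil(cy + r)) + 2, h)
    c0 = max(int(math.floor(cx - r)) - 1, 0)
    c1 = min(int(math.ceil(cx + r)) + 2, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    return (slice(r0, r1), slice(c0, c1)), mask


def _paint_amount(canvas: np.ndarray, cx: float, cy: float,
                  r_in: float, r_out: float, amount: float) -> None:
    """Spread ``amount`` uniformly over the annulus r_in < d <= r_out.

    The per-pixel density is amount / n_pixels, so the painted sum equals
    ``amount`` exactly regardless of discretization.
    """
    h, w = canvas.shape
    r0 = max(int(math.floor(cy - r_out)) - 1, 0)
    r1 = min(int(math.ceil(cy + r_out)) + 2, h)
    c0 = max(int(math.floor(cx - r_out)) - 1, 0)
    c1 = min(int(math.ceil(cx + r_out)) + 2, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    region = (d2 <= r_out * r_out) & (d2 > r_in * r_in)
    sl = (slice(r0, r1), slice(c0, c1))
    npx = int(region.sum())
    if npx == 0 or amount <= 0:
        return
    canvas[sl][region] += amount / npx


def _render_cell_channels(
    cells: Sequence[CellSpec],
    fractions: np.ndarray,
    config: ImagingConfig,
) -> np.ndarray:
    """Noiseless, unblurred 2-channel signal (no background)."""
    shape = (config.height_px, config.width_px)
    hoechst = np.zeros(shape, dtype=float)
    egfp = np.zeros(shape, dtype=float)
    for cell, frac in zip(cells, fractions):
        x, y = cell.center_xy
        rn, rc = cell.nucleus_radius_px, cell.cyto_radius_px
        sl, nuc = _disk_mask(shape, x, y, rn)
        hoechst[sl][nuc] += cell.hoechst_intensity
        _paint_amount(egfp, x, y, 0.0, rn, cell.total_egfp * frac)
        _paint_amount(egfp, x, y, rn, rc, cell.total_egfp * (1.0 - frac))
    return np.stack([hoechst, egfp])


def _finalize(signal: np.ndarray, config: ImagingConfig,
              rng: np.random.Generator) -> np.ndarray:
    """PSF blur + background + read noise + quantization to the camera."""
    out = np.empty_like(signal)
    for c in range(signal.shape[0]):
        ch = signal[c]
        if config.psf_sigma_px > 0:
            ch = ndi.gaussian_filter(ch, config.psf_sigma_px, mode="nearest")
        ch = ch + config.background_level
        if config.noise_sd > 0:
            ch = ch + rng.normal(0.0, config.noise_sd, size=ch.shape)
        out[c] = ch
    np.clip(out, 0, config.max_count, out=out)
    return np.rint(out).astype(np.uint16)


def _cell_truth_table(cells: Sequence[CellSpec],
                      config: ImagingConfig) -> pd.DataFrame:
    psz = config.pixel_size_um
    return pd.DataFrame({
        "cell_id": np.arange(1, len(cells) + 1),
        "x_um": [(c.center_xy[0] + 0.5) * psz for c in cells],
        "y_um": [(c.center_xy[1] + 0.5) * psz for c in cells],
        "nucleus_radius_px": [c.nucleus_radius_px for c in cells],
        "cyto_radius_px": [c.cyto_radius_px for c in cells],
        "total_egfp": [c.total_egfp for c in cells],
        "nuclear_fraction": [c.nuclear_fraction for c in cells],
    })


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

def render_monolayer_frame(
    cells: Sequence[CellSpec],
    config: ImagingConfig,
    seed: SeedLike,
) -> tuple[np.ndarray, GroundTruth]:
    """Render one two-channel frame (Hoechst, EGFP) plus its ground truth.

    Channel 0 carries the nuclear stain; channel 1 distributes each cell's
    ``total_egfp`` between nucleus and cytoplasmic annulus according to its
    ``nuclear_fraction``.  Layouts with overlapping cytoplasm disks are
    rejected.  Returns a (2, H, W) uint16 image.
    """
    _check_layout(cells, config)
    rng = _rng(seed)
    fractions = np.array([c.nuclear_fraction for c in cells], dtype=float)
    signal = _render_cell_channels(cells, fractions, config)
    image = _finalize(signal, config, rng)
    return image, GroundTruth(cells=_cell_truth_table(cells, config))


def render_translocation_timelapse(
    cells: Sequence[CellSpec],
    kinetics: KineticModel | Sequence[KineticModel],
    times_h: Sequence[float],
    config: ImagingConfig,
    seed: SeedLike,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a (T, 2, H, W) stack with logistic translocation kinetics.

    ``kinetics`` is either one model applied to every cell (one treatment
    condition) or a per-cell sequence.  The first frame is pre-treatment:
    its nuclear fraction is the model baseline.  Times must be strictly
    increasing.
    """
    _check_layout(cells, config)
    t = np.asarray(times_h, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times_h must be a non-empty 1-D sequence")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times_h must be strictly increasing")

    if isinstance(kinetics, KineticModel):
        models = [kinetics] * len(cells)
    else:
        models = list(kinetics)
        if len(models) != len(cells):
            raise ValueError("need one KineticModel per cell")

    rng = _rng(seed)
    # fractions[i, j]: cell i at frame j; frame 0 is baseline by contract
    fractions = np.stack([m.value(t) for m in models])
    fractions[:, 0] = [m.baseline for m in models]

    frames = []
    for j in range(t.size):
        signal = _render_cell_channels(cells, fractions[:, j], config)
        frames.append(_finalize(signal, config, rng))
    stack = np.stack(frames)

    cells_tab = _cell_truth_table(cells, config)
    cells_tab["lag_h"] = [m.lag_h for m in models]
    cells_tab["true_t_half"] = [m.true_t_half for m in models]
    frac_tab = pd.DataFrame({
        "cell_id": np.repeat(cells_tab["cell_id"].to_numpy(), t.size),
        "frame": np.tile(np.arange(t.size), len(cells)),
        "time_h": np.tile(t, len(cells)),
        "nuclear_fraction": fractions.ravel(),
    })
    return stack, GroundTruth(cells=cells_tab, fractions=frac_tab)


def render_dome_timelapse(
    layout: DomeLayout,
    kinetics: KineticModel,
    times_h: Sequence[float],
    config: ImagingConfig,
    seed: int,
    core_extra_lag_h: float | Mapping[int, float] = 0.0,
    rim_width_px: int = 100,
    field_margin_px: int = 32,
    **cell_kwargs,
) -> DomeTimelapse:
    """Render each organoid of a dome as its own time-lapse field.

    Each organoid is a packed cluster of cells; its kinetic lag is
    ``layout.lag_vs_distance`` evaluated at the organoid's radial distance
    from the dome center.  Optionally cells deeper than ``rim_width_px``
    from the organoid circumference (the "core") receive an extra lag, per
    organoid id or globally, emulating slower drug penetration into large
    organoids.
    """
    t = np.asarray(times_h, dtype=float)
    psz = config.pixel_size_um
    stacks: dict[int, np.ndarray] = {}
    fconfigs: dict[int, ImagingConfig] = {}
    origins: dict[int, tuple[float, float]] = {}
    cell_rows, frac_rows, org_rows = [], [], []

    for org in layout.organoids:
        distance = layout.distance_um(org)
        base_lag = float(layout.lag_vs_distance(distance))
        if isinstance(core_extra_lag_h, Mapping):
            extra = float(core_extra_lag_h.get(org.organoid_id, 0.0))
        else:
            extra = float(core_extra_lag_h)

        radius_px = org.organoid_radius_um / psz
        side = int(math.ceil(2 * radius_px)) + 2 * field_margin_px
        fcfg = replace(config, width_px=side, height_px=side)
        center_px = (side / 2.0, side / 2.0)

        ss = np.random.SeedSequence(entropy=[int(seed), int(org.organoid_id)])
        layout_ss, render_ss = ss.spawn(2)
        cells = organoid_cell_layout(org.n_cells, radius_px, center_px,
                                     layout_ss, **cell_kwargs)

        models = []
        zones = []
        for c in cells:
            d_center = math.hypot(c.center_xy[0] - center_px[0],
                                  c.center_xy[1] - center_px[1])
            depth = radius_px - d_center  # distance from circumference
            zone = "periphery" if depth <= rim_width_px else "core"
            lag = base_lag + (extra if zone == "core" else 0.0)
            zones.append(zone)
            models.append(replace(kinetics, lag_h=lag))

        stack, gt = render_translocation_timelapse(cells, models, t, fcfg,
                                                   render_ss)
        origin = (org.position_xy_um[0] - center_px[0] * psz,
                  org.position_xy_um[1] - center_px[1] * psz)
        stacks[org.organoid_id] = stack
        fconfigs[org.organoid_id] = fcfg
        origins[org.organoid_id] = origin

        ct = gt.cells.copy()
        ct["cell_id"] = [f"{org.organoid_id}:{k}" for k in ct["cell_id"]]
        ct["x_um"] += origin[0]
        ct["y_um"] += origin[1]
        ct["organoid_id"] = org.organoid_id
        ct["zone"] = zones
        cell_rows.append(ct)
        ft = gt.fractions.copy()
        ft["cell_id"] = [f"{org.organoid_id}:{k}" for k in ft["cell_id"]]
        ft["organoid_id"] = org.organoid_id
        frac_rows.append(ft)
        org_rows.append({
            "organoid_id": org.organoid_id,
            "x_um": org.position_xy_um[0],
            "y_um": org.position_xy_um[1],
            "distance_um": distance,
            "lag_h": base_lag,
            "core_extra_lag_h": extra,
            "radius_um": org.organoid_radius_um,
            "area_um2": math.pi * org.organoid_radius_um**2,
            "n_cells": org.n_cells,
        })

    truth = GroundTruth(
        cells=pd.concat(cell_rows, ignore_index=True),
        fractions=pd.concat(frac_rows, ignore_index=True),
        organoids=pd.DataFrame(org_rows),
    )
    return DomeTimelapse(stacks, fconfigs, origins, t, truth)


# ---------------------------------------------------------------------------
# tubulin texture
# ---------------------------------------------------------------------------

def _tubulin_geometry(config: ImagingConfig, rng: np.random.Generator,
                      max_bundles: int, bundle_width_px: int,
                      bundle_length_px: float):
    """Cell-area mask plus a fixed list of candidate bundle strokes.

    All ``max_bundles`` candidates are drawn up-front from the rng, so for
    a fixed seed the bundle set at stabilization s is a subset of the set
    at any s' > s (nested textures along a treatment ramp).
    """
    from skimage.draw import line as draw_line

    h, w = config.height_px, config.width_px
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = 0.45 * w, 0.42 * h
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    strokes = []
    for _ in range(max_bundles):
        while True:
            x0 = rng.uniform(0.15 * w, 0.85 * w)
            y0 = rng.uniform(0.15 * h, 0.85 * h)
            if mask[int(y0), int(x0)]:
                break
        theta = rng.uniform(0.0, math.pi)
        length = max(rng.normal(bundle_length_px, bundle_length_px / 4), 8.0)
        x1 = x0 + length * math.cos(theta)
        y1 = y0 + length * math.sin(theta)
        x1 = min(max(x1, 0), w - 1)
        y1 = min(max(y1, 0), h - 1)
        rr, cc = draw_line(int(round(y0)), int(round(x0)),
                           int(round(y1)), int(round(x1)))
        strokes.append((rr, cc))
    return mask, strokes


def _render_tubulin_signal(mask, strokes, n_bundles, config, rng,
                           diffuse_level, bundle_amplitude,
                           bundle_width_px, intensity_scale):
    from skimage.morphology import disk

    h, w = config.height_px, config.width_px
    # smooth diffuse field: constant + low-frequency modulation
    modulation = ndi.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 15.0)
    mmax = np.abs(modulation).max()
    if mmax > 0:
        modulation = modulation / mmax
    signal = np.where(mask, diffuse_level * (1.0 + 0.15 * modulation), 0.0)

    if n_bundles > 0:
        canvas = np.zeros((h, w), dtype=bool)
        for rr, cc in strokes[:n_bundles]:
            canvas[rr, cc] = True
        if bundle_width_px > 1:
            canvas = ndi.binary_dilation(canvas,
                                         structure=disk(bundle_width_px // 2))
        signal = signal + np.where(canvas & mask, bundle_amplitude, 0.0)
    return signal * intensity_scale


def render_tubulin_frame(
    stabilization: float,
    config: ImagingConfig,
    seed: SeedLike,
    max_bundles: int = 40,
    bundle_width_px: int = 3,
    bundle_length_px: float = 60.0,
    diffuse_level: float = 600.0,
    bundle_amplitude: float = 1500.0,
    intensity_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one tubulin frame at a given stabilization level in [0, 1].

    The cell area is an elliptical region of diffuse signal; stabilization
    adds ``round(stabilization * max_bundles)`` bright line-segment bundles
    of fixed width, so Haralick contrast of the frame grows with the
    stabilization level.  ``intensity_scale`` < 1 emulates photobleaching.
    Returns ``(image, cell_area_mask)``.
    """
    if not (0.0 <= stabilization <= 1.0):
        raise ValueError("stabilization must lie in [0, 1]")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    geom_ss, noise_ss = ss.spawn(2)
    rng_geom = np.random.default_rng(geom_ss)
    mask, strokes = _tubulin_geometry(config, rng_geom, max_bundles,
                                      bundle_width_px, bundle_length_px)
    n_bundles = int(round(stabilization * max_bundles))
    signal = _render_tubulin_signal(mask, strokes, n_bundles, config,
                                    rng_geom, diffuse_level,
                                    bundle_amplitude, bundle_width_px,
                                    intensity_scale)
    image = _finalize(signal[None], config, np.random.default_rng(noise_ss))[0]
    return image, mask


def render_tubulin_timelapse(
    stabilizations: Sequence[float],
    times_h: Sequence[float],
    config: ImagingConfig,
    seed: int,
    bleach_rate_per_h: float = 0.0,
    **frame_kwargs,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a tubulin stack along a stabilization ramp.

    The bundle geometry is drawn once from the seed so textures nest along
    the ramp; read noise differs per frame.  ``bleach_rate_per_h`` applies
    an exponential intensity decay exp(-rate * t) to the signal (off by
    default), exercising the bleaching caveat of long time-lapses.
    Returns (stack (T, H, W), cell-area mask, ground-truth table).
    """
    s = np.asarray(stabilizations, dtype=float)
    t = np.asarray(times_h, dtype=float)
    if s.size != t.size:
        raise ValueError("stabilizations and times_h must align")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times_h must be strictly increasing")
    frames = []
    mask = None
    for j, (sj, tj) in enumerate(zip(s, t)):
        scale = math.exp(-bleach_rate_per_h * tj)
        frame_ss = np.random.SeedSequence(entropy=[int(seed), 0])
        # same entropy for every frame -> identical geometry; per-frame noise
        geom_ss, _ = frame_ss.spawn(2)
        noise_ss = np.random.SeedSequence(entropy=[int(seed), 1, j])
        rng_geom = np.random.default_rng(geom_ss)
        kw = dict(max_bundles=40, bundle_width_px=3, bundle_length_px=60.0,
                  diffuse_level=600.0, bundle_amplitude=1500.0)
        kw.update(frame_kwargs)
        m, strokes = _tubulin_geometry(config, rng_geom, kw["max_bundles"],
                                       kw["bundle_width_px"],
                                       kw["bundle_length_px"])
        n_bundles = int(round(sj * kw["max_bundles"]))
        signal = _render_tubulin_signal(m, strokes, n_bundles, config,
                                        rng_geom, kw["diffuse_level"],
                                        kw["bundle_amplitude"],
                                        kw["bundle_width_px"], scale)
        frames.append(_finalize(signal[None], config,
                                np.random.default_rng(noise_ss))[0])
        mask = m
    truth = pd.DataFrame({"frame": np.arange(t.size), "time_h": t,
                          "stabilization": s})
    return np.stack(frames), mask, truth


# ---------------------------------------------------------------------------
# viability plates
# ---------------------------------------------------------------------------

def simulate_viability_plate(
    doses: Sequence[float],
    pl4: tuple[float, float, float, float],
    cv: float,
    replicates: int,
    seed: SeedLike,
    vehicle_wells: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a viability plate read out under a 4PL dose-response.

    ``pl4`` is (top, bottom, ec50, hill).  Each well's response is the 4PL
    value multiplied by lognormal noise with coefficient of variation
    ``cv`` (mean 1), matching the multiplicative error of luminescence
    viability readouts.  Vehicle wells (dose 0) respond at ``top``.
    """
    top, bottom, ec50, hill = (float(x) for x in pl4)
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if hill == 0:
        raise ValueError("hill must be non-zero")
    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise ValueError("doses must be positive (vehicle wells are added "
                         "automatically at dose 0)")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    n_vehicle = replicates if vehicle_wells is None else int(vehicle_wells)

    rng = _rng(seed)
    all_doses = np.concatenate([np.zeros(n_vehicle), np.repeat(d, replicates)])
    expected = four_param_logistic(all_doses, top, bottom, ec50, hill)
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        noise = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma,
                              size=all_doses.size)
    else:
        noise = np.ones_like(all_doses)
    rep_idx = np.concatenate([np.arange(n_vehicle),
                              np.tile(np.arange(replicates), d.size)])
    table = pd.DataFrame({
        "well_id": [f"d{dose:g}_r{r}" for dose, r in zip(all_doses, rep_idx)],
        "dose": all_doses,
        "replicate": rep_idx,
        "response": expected * noise,
        "expected_response": expected,
    })
    truth = GroundTruth(cells=pd.DataFrame(),
                        plate={"top": top, "bottom": bottom,
                               "ec50": ec50, "hill": hill, "cv": cv})
    return table, truth


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def save_stack(path: str | Path, stack: np.ndarray,
               pixel_size_um: float) -> None:
    """Write a (T, H, W) or (H, W) stack as multi-page TIFF.

    The pixel size is recorded in the TIFF resolution tags (pixels per
    centimeter), the convention downstream readers understand.
    """
    ppcm = 1.0e4 / pixel_size_um
    tifffile.imwrite(str(path), np.asarray(stack),
                     photometric="minisblack",
                     resolution=(ppcm, ppcm), resolutionunit="CENTIMETER")
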