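"""End-to-end scenario orchestration, image I/O and reporting.

A scenario chains the full quantification path — synthetic (or supplied)
images -> segmentation -> per-cell tables -> aggregated curves -> kinetic /
dose-response fits -> group comparisons — deterministically from one
config and seed.  Four scenarios cover the experimental designs the
package models:

* ``monolayer_scaffold``: 2D monolayers covered by no gel / synthetic
  hydrogel / Matrigel, with programmed translocation lags per condition;
  recovers per-condition t1/2 and compares them pairwise.
* ``dome_binning``: organoids distributed in a scaffold dome with a
  distance-dependent lag; recovers per-radial-bin t1/2.
* ``core_periphery``: large and small organoids whose core cells may lag
  their periphery; recovers the core-periphery t1/2 difference per size
  class.
* ``dose_response``: viability plates for two conditions; 4PL fits,
  EC50s with bootstrap CIs and an extra-sum-of-squares curve comparison.

Configs are plain dictionaries (YAML on disk); ``default_config`` returns
the study conditions for each scenario.  Reports carry provenance (config
hash, seed, package version), per-stage tables, fitted parameters and QC
counters, and every table is written as CSV next to a JSON fit summary.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .kinetics import (SigmoidFit, compare_dose_curves, compare_t_half,
                       fit_4pl, fit_sigmoid_time, normalize_to_vehicle)
from .quantify import measure_cells
from .segment import (assign_core_periphery, derive_cytoplasm_rings,
                      estimate_background, segment_nuclei, segment_organoids)
from .simulate import (DomeLayout, ImagingConfig, KineticModel, OrganoidSpec,
                       linear_lag, random_cell_layout,
                       render_dome_timelapse, render_translocation_timelapse,
                       simulate_viability_plate)
from .spatial import BinningScheme, bin_timecourses, zone_timecourses

logger = logging.getLogger("organotrace")

__all__ = [
    "SCENARIOS",
    "RunConfig",
    "RunReport",
    "default_config",
    "run_scenario",
    "read_image_stack",
    "analyze_translocation_stack",
    "analyze_organoid_stack",
    "match_to_ground_truth",
]

SCENARIOS = ("monolayer_scaffold", "dome_binning", "core_periphery",
             "dose_response")

_DEFAULT_SEGMENTATION = {
    "min_area_px": 120,
    "max_area_px": 5000,
    "smooth_sigma": 2.0,
    "min_distance_px": 10,
    "ring_width_px": 5,
    "rim_width_px": 100,
    "area_threshold_um2": 8000.0,
    "organoid_closing_px": 25.0,
}

_DEFAULT_IMAGING = {
    "width_px": 512, "height_px": 512, "pixel_size_um": 0.325,
    "bit_depth": 16, "background_level": 100.0, "noise_sd": 2.0,
    "psf_sigma_px": 1.0,
}

_DEFAULT_KINETICS = {
    "baseline": 0.2, "plateau": 0.85, "t50_h": 0.75, "slope_h": 0.25,
}


def default_config(scenario: str) -> dict:
    """Study-condition defaults for each scenario."""
    if scenario == "monolayer_scaffold":
        sim = {
            "conditions": {"no_gel": 0.0, "noviogel": 1.0, "matrigel": 3.0},
            "n_experiments": 3,
            "n_cells": 20,
            "times_h": {"start": 0.0, "stop": 8.0, "step": 0.25},
            "imaging": dict(_DEFAULT_IMAGING),
            "kinetics": dict(_DEFAULT_KINETICS),
        }
    elif scenario == "dome_binning":
        sim = {
            "dome_radius_um": 2250.0,
            "n_bins": 9,
            "bin_width_um": 250.0,
            "organoids_per_bin": 2,
            "cells_per_organoid": 6,
            "organoid_radius_um": 26.0,
            "max_lag_h": 2.0,
            "lag_increases_with_distance": False,  # drug diffuses inward
            "times_h": {"start": 0.0, "stop": 5.0, "step": 0.5},
            "imaging": dict(_DEFAULT_IMAGING),
            "kinetics": dict(_DEFAULT_KINETICS),
        }
    elif scenario == "core_periphery":
        # organoid cells are smaller and tightly packed, so the segmented
        # footprint tracks the programmed circular cross-section
        sim = {
            "n_large": 3, "large_radius_um": 70.0, "large_cells": 90,
            "large_core_extra_lag_h": 1.0,
            "n_small": 3, "small_radius_um": 48.75, "small_cells": 40,
            "small_core_extra_lag_h": 0.0,
            "nucleus_radius_px": 8.0,
            "times_h": {"start": 0.0, "stop": 5.0, "step": 0.5},
            "imaging": dict(_DEFAULT_IMAGING),
            "kinetics": dict(_DEFAULT_KINETICS),
        }
    elif scenario == "dose_response":
        sim = {
            "doses": list(np.geomspace(0.01, 10.0, 8)),
            "replicates": 3,
            "cv": 0.05,
            "conditions": {
                "single_cells": {"top": 1000.0, "bottom": 0.0,
                                 "ec50": 0.5, "hill": 1.0},
                "organoids": {"top": 1000.0, "bottom": 0.0,
                              "ec50": 5.0, "hill": 1.0},
            },
            "n_boot": 1000,
        }
    else:
        raise ValueError(f"unknown scenario {scenario!r}; "
                         f"choose from {SCENARIOS}")
    return {
        "scenario": scenario,
        "seed": 0,
        "simulate": sim,
        "inputs": None,
        "segmentation": dict(_DEFAULT_SEGMENTATION),
    }


@dataclass
class RunConfig:
    """Validated scenario configuration."""

    scenario: str
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    segmentation: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' / 'inputs' must be set")
        seg = dict(_DEFAULT_SEGMENTATION)
        seg.update(self.segmentation or {})
        self.segmentation = seg
        self.seed = int(self.seed)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {"scenario", "seed", "simulate", "inputs", "segmentation"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**{k: copy.deepcopy(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario, "seed": self.seed,
            "simulate": copy.deepcopy(self.simulate),
            "inputs": copy.deepcopy(self.inputs),
            "segmentation": copy.deepcopy(self.segmentation),
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything a run produced, traceable to its tables."""

    provenance: dict
    tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    fits: dict = dc_field(default_factory=dict)
    comparisons: list[dict] = dc_field(default_factory=list)
    qc: dict = dc_field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        with open(out / "fits.json", "w") as fh:
            json.dump(self.fits, fh, indent=2, default=_jsonable)
        with open(out / "report.json", "w") as fh:
            json.dump({"provenance": self.provenance,
                       "comparisons": self.comparisons,
                       "qc": self.qc}, fh, indent=2, default=_jsonable)
        with open(out / "provenance.txt", "w") as fh:
            for k, v in self.provenance.items():
                fh.write(f"{k}: {v}\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, float) and math.isnan(x):
        return None
    return str(x)


def _fit_curve_or_flag(times, values) -> dict:
    """Sigmoid fit as a dict; a curve too sparse to fit is flagged
    unconverged instead of raising (e.g. a bin lost in some frames)."""
    try:
        return _sigmoid_fit_dict(fit_sigmoid_time(times, values))
    except ValueError as exc:
        logger.warning("curve not fittable: %s", exc)
        return {"baseline": None, "plateau": None, "t50_h": None,
                "slope_h": None, "converged": False,
                "plateau_reached": False, "t_half": None,
                "t_half_label": "not attained", "rss": None,
                "n_points": len(times)}


def _sigmoid_fit_dict(fit: SigmoidFit) -> dict:
    return {
        "baseline": fit.baseline, "plateau": fit.plateau,
        "t50_h": fit.t50_h, "slope_h": fit.slope_h,
        "converged": fit.converged, "plateau_reached": fit.plateau_reached,
        "t_half": fit.t_half, "t_half_label": fit.t_half_label,
        "rss": fit.rss, "n_points": fit.n_points,
    }


def _times_from_cfg(spec) -> np.ndarray:
    if isinstance(spec, Mapping):
        n = int(round((spec["stop"] - spec["start"]) / spec["step"])) + 1
        return spec["start"] + spec["step"] * np.arange(n)
    return np.asarray(spec, dtype=float)


def _child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=[int(seed), *map(int, key)])


# ---------------------------------------------------------------------------
# reusable analysis blocks
# ---------------------------------------------------------------------------

def analyze_translocation_stack(
    stack: np.ndarray,
    times_h: Sequence[float],
    pixel_size_um: float,
    segmentation: Mapping[str, Any] | None = None,
    well_id: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, SigmoidFit]:
    """Segment and quantify a (T, 2, H, W) translocation stack.

    Per frame: nuclei from channel 0, perinuclear rings, background from
    the EGFP channel outside the cell footprint, per-cell ratios.  Returns
    (per-cell table, mean-ratio curve, sigmoid fit of the mean curve).
    """
    seg = dict(_DEFAULT_SEGMENTATION)
    seg.update(segmentation or {})
    t = np.asarray(times_h, dtype=float)
    if stack.ndim != 4 or stack.shape[1] != 2:
        raise ValueError("expected a (T, 2, H, W) stack")
    if stack.shape[0] != t.size:
        raise ValueError("times_h must align with frames")

    frames = []
    for j in range(t.size):
        hoechst, egfp = stack[j, 0], stack[j, 1]
        nuclei = segment_nuclei(
            hoechst, seg["min_area_px"], seg["max_area_px"],
            pixel_size_um=pixel_size_um, smooth_sigma=seg["smooth_sigma"],
            min_distance_px=seg["min_distance_px"])
        rings = derive_cytoplasm_rings(nuclei, seg["ring_width_px"])
        footprint = (nuclei.labels > 0) | (rings.labels > 0)
        background = estimate_background(egfp, footprint)
        cells = measure_cells(egfp, nuclei, rings, background,
                              frame_time_h=float(t[j]), well_id=well_id)
        frames.append(cells)
    cells = pd.concat(frames, ignore_index=True)
    valid = cells[cells["valid"]]
    curve = (valid.groupby("frame_time_h")["ratio"]
             .agg(mean_ratio="mean", n_cells="size").reset_index())
    fit = fit_sigmoid_time(curve["frame_time_h"], curve["mean_ratio"])
    return cells, curve, fit


def analyze_organoid_stack(
    stack: np.ndarray,
    times_h: Sequence[float],
    pixel_size_um: float,
    segmentation: Mapping[str, Any] | None = None,
    well_id: str = "",
    center_xy_um: tuple[float, float] | None = None,
    field_origin_um: tuple[float, float] = (0.0, 0.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and quantify one organoid field of a (T, 2, H, W) stack.

    Adds organoid id, core/periphery zone, organoid area / size class and
    radial distance from ``center_xy_um`` (dome coordinates; local
    centroids are shifted by ``field_origin_um``).  Returns (per-cell
    table, per-organoid table).
    """
    seg = dict(_DEFAULT_SEGMENTATION)
    seg.update(segmentation or {})
    t = np.asarray(times_h, dtype=float)

    cell_frames, organoid_rows = [], []
    for j in range(t.size):
        hoechst, egfp = stack[j, 0], stack[j, 1]
        org_mask, org_records = segment_organoids(
            hoechst, egfp, pixel_size_um,
            area_threshold_um2=seg["area_threshold_um2"],
            closing_radius_px=seg["organoid_closing_px"])
        nuclei = segment_nuclei(
            hoechst, seg["min_area_px"], seg["max_area_px"],
            pixel_size_um=pixel_size_um, smooth_sigma=seg["smooth_sigma"],
            min_distance_px=seg["min_distance_px"])
        rings = derive_cytoplasm_rings(nuclei, seg["ring_width_px"])
        footprint = (nuclei.labels > 0) | (rings.labels > 0)
        background = estimate_background(egfp, footprint)
        assignments = assign_core_periphery(org_mask, nuclei,
                                            seg["rim_width_px"])
        zones = {a.nucleus_id: a.zone for a in assignments}
        cells = measure_cells(egfp, nuclei, rings, background,
                              frame_time_h=float(t[j]), well_id=well_id,
                              organoid_labels=org_mask, zones=zones)
        cells["x_um"] += field_origin_um[0]
        cells["y_um"] += field_origin_um[1]

        by_id = {r.organoid_id: r for r in org_records}
        cells["area_um2"] = [
            by_id[o].area_um2 if o in by_id else math.nan
            for o in cells["organoid_id"]
        ]
        cells["size_class"] = [
            by_id[o].size_class if o in by_id else None
            for o in cells["organoid_id"]
        ]
        if center_xy_um is not None:
            dists = {}
            for r in org_records:
                gx = r.centroid_xy_um[0] + field_origin_um[0]
                gy = r.centroid_xy_um[1] + field_origin_um[1]
                dists[r.organoid_id] = math.hypot(gx - center_xy_um[0],
                                                  gy - center_xy_um[1])
            cells["distance_um"] = [
                dists.get(o, math.nan) for o in cells["organoid_id"]
            ]
        cell_frames.append(cells)
        for r in org_records:
            organoid_rows.append({
                "well_id": well_id, "frame_time_h": float(t[j]),
                "organoid_id": r.organoid_id,
                "x_um": r.centroid_xy_um[0] + field_origin_um[0],
                "y_um": r.centroid_xy_um[1] + field_origin_um[1],
                "area_um2": r.area_um2, "size_class": r.size_class,
            })
    return (pd.concat(cell_frames, ignore_index=True),
            pd.DataFrame(organoid_rows))


def match_to_ground_truth(
    cells: pd.DataFrame,
    truth_cells: pd.DataFrame,
    max_dist_um: float = 5.0,
) -> pd.DataFrame:
    """Match measured cells to ground-truth cells by nearest position.

    Greedy nearest-neighbor matching on (x_um, y_um) within
    ``max_dist_um``; returns the inner join with truth columns suffixed
    ``_true``.
    """
    if cells.empty or truth_cells.empty:
        return pd.DataFrame()
    mx = cells[["x_um", "y_um"]].to_numpy(float)
    tx = truth_cells[["x_um", "y_um"]].to_numpy(float)
    d2 = ((mx[:, None, :] - tx[None, :, :]) ** 2).sum(axis=2)
    pairs = []
    used_m, used_t = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(d2, axis=None), d2.shape))[0]
    for i, j in order:
        if i in used_m or j in used_t:
            continue
        if d2[i, j] > max_dist_um**2:
            break
        used_m.add(i)
        used_t.add(j)
        pairs.append((i, j))
    if not pairs:
        return pd.DataFrame()
    mi, ti = zip(*pairs)
    left = cells.iloc[list(mi)].reset_index(drop=True)
    right = (truth_cells.iloc[list(ti)].reset_index(drop=True)
             .add_suffix("_true"))
    return pd.concat([left, right], axis=1)


# ---------------------------------------------------------------------------
# scenario runners
# ---------------------------------------------------------------------------

def _imaging_from(sim: Mapping[str, Any]) -> ImagingConfig:
    return ImagingConfig(**sim.get("imaging", _DEFAULT_IMAGING))


def _kinetics_from(sim: Mapping[str, Any], lag_h: float = 0.0) -> KineticModel:
    kw = dict(_DEFAULT_KINETICS)
    kw.update(sim.get("kinetics", {}))
    return KineticModel(lag_h=lag_h, **kw)


def _iter_monolayer_stacks(config: RunConfig):
    """Yield (condition, experiment, stack, times, pixel_size) wells.

    Simulation mode renders the wells; input mode reads per-channel TIFF
    stacks from ``inputs['conditions'][name]`` (a list of
    ``{hoechst, egfp}`` path pairs per experiment).
    """
    if config.simulate is not None:
        sim = config.simulate
        times = _times_from_cfg(sim["times_h"])
        imaging = _imaging_from(sim)
        conditions: Mapping[str, float] = sim["conditions"]
        for e in range(int(sim["n_experiments"])):
            for c_idx, (name, lag) in enumerate(conditions.items()):
                ss = _child_seed(config.seed, e, c_idx)
                layout_ss, render_ss = ss.spawn(2)
                cells_spec = random_cell_layout(
                    int(sim["n_cells"]), imaging, layout_ss,
                    nuclear_fraction=_kinetics_from(sim).baseline)
                model = _kinetics_from(sim, lag_h=float(lag))
                stack, _ = render_translocation_timelapse(
                    cells_spec, model, times, imaging, render_ss)
                yield name, e, stack, times, imaging.pixel_size_um
    else:
        inputs = config.inputs
        times = np.asarray(inputs["frame_times_h"], dtype=float)
        for name, experiments in inputs["conditions"].items():
            for e, channels in enumerate(experiments):
                hoechst, psz, _ = read_image_stack(
                    [channels["hoechst"]],
                    pixel_size_um=inputs.get("pixel_size_um"))
                egfp, _, _ = read_image_stack(
                    [channels["egfp"]],
                    pixel_size_um=inputs.get("pixel_size_um"))
                if hoechst.shape != egfp.shape:
                    raise ValueError("channel stacks disagree in shape")
                stack = np.stack([hoechst, egfp], axis=1)
                yield name, e, stack, times, psz


def _run_monolayer(config: RunConfig, report: RunReport) -> None:
    all_cells, curve_rows, fit_rows = [], [], []
    t50s: dict[str, list[float]] = {}
    for name, e, stack, times, psz in _iter_monolayer_stacks(config):
        well = f"{name}_exp{e}"
        cells, curve, fit = analyze_translocation_stack(
            stack, times, psz, config.segmentation, well_id=well)
        cells["condition"] = name
        cells["experiment"] = e
        all_cells.append(cells)
        curve["condition"] = name
        curve["experiment"] = e
        curve_rows.append(curve)
        fit_rows.append({"condition": name, "experiment": e,
                         **_sigmoid_fit_dict(fit)})
        t50s.setdefault(name, [])
        if fit.t_half is not None:
            t50s[name].append(fit.t_half)

    report.tables["cells"] = pd.concat(all_cells, ignore_index=True)
    report.tables["curves"] = pd.concat(curve_rows, ignore_index=True)
    report.fits["sigmoid_fits"] = fit_rows
    report.fits["t_half_by_condition"] = {
        k: {"values": v, "mean": float(np.mean(v)) if v else None}
        for k, v in t50s.items()
    }
    names = list(t50s)
    ref = names[0]
    deltas = {
        f"{name}-{ref}": float(np.mean(t50s[name]) - np.mean(t50s[ref]))
        for name in names[1:] if t50s[name] and t50s[ref]
    }
    report.fits["delta_t_half_vs_reference"] = deltas
    usable = {k: v for k, v in t50s.items() if len(v) >= 2}
    if len(usable) >= 2:
        report.comparisons = [vars(c) for c in compare_t_half(usable)]


def _run_dome(config: RunConfig, report: RunReport) -> None:
    sim = config.simulate
    times = _times_from_cfg(sim["times_h"])
    imaging = _imaging_from(sim)
    scheme = BinningScheme(center_xy_um=(0.0, 0.0),
                           bin_width_um=float(sim["bin_width_um"]),
                           n_bins=int(sim["n_bins"]))
    rng = np.random.default_rng(_child_seed(config.seed, 0))

    organoids = []
    oid = 1
    for b in range(scheme.n_bins):
        for _ in range(int(sim["organoids_per_bin"])):
            lo = b * scheme.bin_width_um
            hi = lo + scheme.bin_width_um
            # keep a margin so segmentation jitter cannot cross a bin edge
            d = rng.uniform(lo + 0.1 * scheme.bin_width_um,
                            hi - 0.1 * scheme.bin_width_um)
            th = rng.uniform(0, 2 * math.pi)
            organoids.append(OrganoidSpec(
                oid, (d * math.cos(th), d * math.sin(th)),
                int(sim["cells_per_organoid"]),
                float(sim["organoid_radius_um"])))
            oid += 1
    layout = DomeLayout(
        center_xy_um=(0.0, 0.0),
        dome_radius_um=float(sim["dome_radius_um"]),
        organoids=tuple(organoids),
        lag_vs_distance=linear_lag(
            float(sim["max_lag_h"]), float(sim["dome_radius_um"]),
            inverted=not bool(sim.get("lag_increases_with_distance", False))),
    )
    dome = render_dome_timelapse(layout, _kinetics_from(sim), times, imaging,
                                 config.seed)

    cell_tabs, org_tabs = [], []
    for org_id, stack in dome.stacks.items():
        cells, orgs = analyze_organoid_stack(
            stack, times, imaging.pixel_size_um, config.segmentation,
            well_id=f"organoid{org_id}", center_xy_um=(0.0, 0.0),
            field_origin_um=dome.field_origins_um[org_id])
        cells["layout_organoid_id"] = org_id
        cell_tabs.append(cells)
        org_tabs.append(orgs)
    cells = pd.concat(cell_tabs, ignore_index=True)
    report.tables["cells"] = cells
    report.tables["organoids"] = pd.concat(org_tabs, ignore_index=True)

    binned = bin_timecourses(cells.dropna(subset=["distance_um"]), scheme)
    report.tables["binned_curves"] = binned
    fits = []
    for b, grp in binned.groupby("bin_index"):
        fits.append({"bin_index": int(b),
                     **_fit_curve_or_flag(grp["frame_time_h"],
                                          grp["mean_ratio"])})
    report.fits["per_bin"] = fits
    t50 = [f["t_half"] for f in fits if f["t_half"] is not None]
    report.fits["t_half_spread_h"] = (max(t50) - min(t50)) if t50 else None


def _run_core_periphery(config: RunConfig, report: RunReport) -> None:
    sim = config.simulate
    times = _times_from_cfg(sim["times_h"])
    imaging = _imaging_from(sim)

    organoids, extras = [], {}
    oid = 1
    for _ in range(int(sim["n_large"])):
        organoids.append(OrganoidSpec(oid, (0.0, 0.0), int(sim["large_cells"]),
                                      float(sim["large_radius_um"])))
        extras[oid] = float(sim["large_core_extra_lag_h"])
        oid += 1
    for _ in range(int(sim["n_small"])):
        organoids.append(OrganoidSpec(oid, (0.0, 0.0), int(sim["small_cells"]),
                                      float(sim["small_radius_um"])))
        extras[oid] = float(sim["small_core_extra_lag_h"])
        oid += 1
    layout = DomeLayout(center_xy_um=(0.0, 0.0), dome_radius_um=1000.0,
                        organoids=tuple(organoids),
                        lag_vs_distance=lambda d: 0.0)
    rn = float(sim.get("nucleus_radius_px", 8.0))
    dome = render_dome_timelapse(
        layout, _kinetics_from(sim), times, imaging, config.seed,
        core_extra_lag_h=extras,
        rim_width_px=int(config.segmentation["rim_width_px"]),
        nucleus_radius_px=rn, cyto_radius_px=rn * math.sqrt(2.0))

    cell_tabs = []
    for org_id, stack in dome.stacks.items():
        cells, _ = analyze_organoid_stack(
            stack, times, imaging.pixel_size_um, config.segmentation,
            well_id=f"organoid{org_id}")
        cells["layout_organoid_id"] = org_id
        cell_tabs.append(cells)
    cells = pd.concat(cell_tabs, ignore_index=True)
    report.tables["cells"] = cells

    zone_curves = zone_timecourses(cells.dropna(subset=["zone"]),
                                   normalize=True)
    report.tables["zone_curves"] = zone_curves
    fits, deltas = [], {}
    for (size_class, zone), grp in zone_curves.groupby(["size_class", "zone"]):
        fits.append({"size_class": size_class, "zone": zone,
                     **_fit_curve_or_flag(grp["frame_time_h"],
                                          grp["mean_ratio"])})
    by_key = {(f["size_class"], f["zone"]): f["t_half"] for f in fits}
    for size_class in ("large", "small"):
        core = by_key.get((size_class, "core"))
        peri = by_key.get((size_class, "periphery"))
        deltas[size_class] = (core - peri
                              if core is not None and peri is not None
                              else None)
    report.fits["per_zone"] = fits
    report.fits["delta_t_half_core_minus_periphery"] = deltas


def _run_dose(config: RunConfig, report: RunReport) -> None:
    sim = config.simulate
    doses = np.asarray(sim["doses"], dtype=float)
    tables, fits = {}, {}
    datasets = {}
    for c_idx, (name, pl4) in enumerate(sim["conditions"].items()):
        table, _ = simulate_viability_plate(
            doses, (pl4["top"], pl4["bottom"], pl4["ec50"], pl4["hill"]),
            float(sim["cv"]), int(sim["replicates"]),
            _child_seed(config.seed, c_idx))
        table = normalize_to_vehicle(table)
        table["condition"] = name
        tables[name] = table
        fit = fit_4pl(table["dose"], table["viability_pct"],
                      n_boot=int(sim.get("n_boot", 0)),
                      seed=int(np.random.default_rng(
                          _child_seed(config.seed, 100 + c_idx)
                      ).integers(2**31)))
        fits[name] = {
            "top": fit.top, "bottom": fit.bottom, "ec50": fit.ec50,
            "hill": fit.hill, "rss": fit.rss, "warning": fit.warning,
            "ci95_ec50": fit.ci95_ec50,
        }
        datasets[name] = table
    report.tables["doses"] = pd.concat(tables.values(), ignore_index=True)
    report.fits["four_pl"] = fits
    names = list(sim["conditions"])
    if len(names) == 2:
        # for the curve comparison both arms are scaled by one pooled
        # vehicle mean (shared plate scale); per-arm vehicle factors would
        # inject a spurious between-curve scale difference into the F-test
        a, b = (datasets[n] for n in names)
        pooled_ref = float(pd.concat([a, b])
                           .loc[lambda t: t["dose"] == 0, "response"].mean())
        va = a["response"] / pooled_ref * 100.0
        vb = b["response"] / pooled_ref * 100.0
        cmp = compare_dose_curves(a["dose"], va, b["dose"], vb)
        report.comparisons = [{
            "test": "extra-sum-of-squares F (shared vs separate 4PL)",
            "groups": names, "f_statistic": cmp.f_statistic,
            "df_num": cmp.df_num, "df_den": cmp.df_den,
            "p_value": cmp.p_value,
            "ec50_ratio": fits[names[1]]["ec50"] / fits[names[0]]["ec50"],
        }]


def run_scenario(config: RunConfig | Mapping[str, Any],
                 out_dir: str | Path | None = None) -> RunReport:
    """Run one scenario end to end; optionally write all outputs.

    Deterministic given (config, seed): rerunning with the same arguments
    reproduces byte-identical tables.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    report = RunReport(provenance={
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config.config_hash,
        "version": __version__,
    })
    runner = {
        "monolayer_scaffold": _run_monolayer,
        "dome_binning": _run_dome,
        "core_periphery": _run_core_periphery,
        "dose_response": _run_dose,
    }[config.scenario]
    runner(config, report)

    if "cells" in report.tables:
        cells = report.tables["cells"]
        report.qc["n_cells"] = int(len(cells))
        report.qc["n_invalid_cells"] = int((~cells["valid"]).sum())
    if out_dir is not None:
        report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# image input
# ---------------------------------------------------------------------------

def read_image_stack(
    paths: Sequence[str | Path],
    pixel_size_um: float | None = None,
    frame_times_h: Sequence[float] | None = None,
) -> tuple[np.ndarray, float, np.ndarray | None]:
    """Read and concatenate TIFF stacks along the frame axis.

    The pixel size comes from the TIFF resolution tags unless supplied
    explicitly (an explicit value wins; a mismatch with the tags is
    logged).  Frame times must be supplied when the files carry none.
    Returns (stack, pixel_size_um, times or None).
    """
    arrays, tag_pixel_sizes = [], []
    for path in paths:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None and unit is not None:
                num, den = res.value
                if num > 0 and getattr(unit.value, "name", str(unit.value)):
                    # resolution is pixels per unit; we write CENTIMETER
                    unit_name = getattr(unit.value, "name", str(unit.value))
                    per_px_cm = den / num
                    if unit_name.upper() == "CENTIMETER":
                        tag_pixel_sizes.append(per_px_cm * 1.0e4)
                    elif unit_name.upper() == "INCH":
                        tag_pixel_sizes.append(per_px_cm * 2.54e4)
        if arr.ndim == 2:
            arr = arr[None]
        arrays.append(arr)
    shapes = {a.shape[-2:] for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes across files: {shapes}")
    stack = np.concatenate(arrays, axis=0)

    tag_psz = float(np.median(tag_pixel_sizes)) if tag_pixel_sizes else None
    if pixel_size_um is not None:
        if tag_psz is not None and not math.isclose(pixel_size_um, tag_psz,
                                                    rel_tol=1e-3):
            logger.warning("pixel size %.4f um from config overrides %.4f um "
                           "from TIFF tags", pixel_size_um, tag_psz)
        psz = float(pixel_size_um)
    elif tag_psz is not None:
        psz = tag_psz
    else:
        raise ValueError("pixel size neither in TIFF tags nor supplied")

    times = None
    if frame_times_h is not None:
        times = np.asarray(frame_times_h, dtype=float)
        if times.size != stack.shape[0]:
            raise ValueError("frame_times_h must match total frame count")
    return stack, psz, times
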