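# Output data dictionary

All scenario outputs are plain CSV/JSON written by `organotrace run` (or
`RunReport.write`). Physical units: micrometres (µm), hours (h),
camera counts.

## cells.csv — one row per (cell, frame)

| column | meaning |
|---|---|
| `cell_id` | nucleus label within its frame/field (int, from 1) |
| `well_id` | well/field identifier, e.g. `matrigel_exp0`, `organoid3` |
| `frame_time_h` | frame time since treatment (h); 0 = pre-treatment baseline |
| `nuc_mean` | raw mean EGFP over the nucleus (counts) |
| `cyt_mean` | raw mean EGFP over the perinuclear ring (counts) |
| `ratio` | relative nuclear translocation in [0, 1]; NaN if invalid |
| `valid` | False when no signal above background or the ring is empty |
| `x_um`, `y_um` | nucleus centroid, physical coordinates |
| `organoid_id` | enclosing organoid label (empty outside organoids) |
| `zone` | `core` / `periphery` within the organoid (empty if n/a) |
| `area_um2` | enclosing organoid cross-sectional area |
| `size_class` | `large` iff organoid area > 8000 µm², else `small` |
| `distance_um` | organoid radial distance from the dome center |
| `condition`, `experiment` | treatment condition and experiment index (monolayer scenario) |
| `layout_organoid_id` | generator's organoid id (simulated dome scenarios) |

## curves.csv (monolayer) — mean ratio per condition/experiment/time

`frame_time_h`, `mean_ratio`, `n_cells`, `condition`, `experiment`.

## binned_curves.csv (dome) — radial-bin aggregation

`bin_index` (0-based, half-open 250 µm bins), `frame_time_h`,
`mean_ratio` (unweighted mean over in-bin cells), `n_cells`.

## zone_curves.csv (core/periphery) — zone aggregation

`size_class`, `zone`, `frame_time_h`, `mean_ratio` (min-max normalized
per curve), `n_cells`.

## organoids.csv — one row per (organoid, frame)

`well_id`, `frame_time_h`, `organoid_id`, `x_um`, `y_um`, `area_um2`,
`size_class`.

## doses.csv (dose-response) — one row per well

`well_id`, `dose` (0 = vehicle), `replicate`, `response` (raw),
`expected_response` (noise-free 4PL value), `viability_pct`
(vehicle-normalized), `condition`.

## fits.json

* `sigmoid_fits` / `per_bin` / `per_zone`: logistic time fits —
  `baseline`, `plateau`, `t50_h`, `slope_h`, `converged`,
  `plateau_reached`, `t_half` (null = not attained), `t_half_label`,
  `rss`, `n_points`.
* `t_half_by_condition`, `delta_t_half_vs_reference` (monolayer);
  `t_half_spread_h` (dome);
  `delta_t_half_core_minus_periphery` (core/periphery).
* `four_pl`: `top`, `bottom`, `ec50`, `hill`, `rss`, `warning`,
  `ci95_ec50` (bootstrap 95% interval).

## report.json

`provenance` (scenario, seed, config hash, package version),
`comparisons` (Welch t-tests with Bonferroni-adjusted p, or the
extra-sum-of-squares F-test), and `qc` counters (total and
invalid-flagged cells).

## Simulator ground-truth tables (`organotrace simulate`)

* `*_truth_cells.csv`: `cell_id`, `x_um`, `y_um`, `nucleus_radius_px`,
  `cyto_radius_px`, `total_egfp`, `nuclear_fraction`, and for domes
  `organoid_id`, `zone`, `lag_h`, `true_t_half`.
* `*_truth_fractions.csv`: `cell_id`, `frame`, `time_h`,
  `nuclear_fraction` — the programmed per-frame truth.
* `truth_organoids.csv`: `organoid_id`, `x_um`, `y_um`, `distance_um`,
  `lag_h`, `core_extra_lag_h`, `radius_um`, `area_um2`, `n_cells`.
* `truth_stabilization.csv`: `frame`, `time_h`, `stabilization`.
* `*_truth_4pl.json`: programmed `top`, `bottom`, `ec50`, `hill`, `cv`.

Images are 16-bit multi-page TIFF, one file per channel per well/field,
with the pixel size in the TIFF resolution tags (pixels per centimetre).
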