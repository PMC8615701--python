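# organotrace

Image-based quantification of drug-response **kinetics** in organoid
models of prostate cancer — how 3D scaffolds, position inside a scaffold
dome, and organoid size delay the onset of drug effect.

Drug testing on organoids embedded in Matrigel or synthetic hydrogel
domes is notoriously variable: the scaffold slows drug penetration,
organoids at the dome center respond later than those at the rim, and
cells in the core of a large organoid respond later than its periphery.
`organotrace` implements the quantification chain needed to measure these
delays from live-cell fluorescence time-lapses — normally locked inside
commercial high-content software — as an open, tested Python library,
together with a synthetic-microscopy generator that provides exact ground
truth so every stage is verifiable without proprietary data.

## What it computes

* **Nuclear AR translocation** per cell and time point: segment nuclei
  (Hoechst), derive perinuclear cytoplasmic rings, and score
  `ratio = n / (n + c)` from background-corrected mean EGFP intensities
  (0 = fully cytoplasmic, 1 = fully nuclear).
* **Tubulin stabilization** (taxane effect) as the Haralick contrast
  `Σ P(i,j)(i−j)²` of the gray-level co-occurrence matrix inside the
  segmented cell area, with fixed quantization across a time series and
  optional bleaching detrend against an untreated control.
* **Kinetics**: logistic fits
  `v(t) = baseline + (plateau − baseline)/(1 + e^{−(t−t50)/slope})`
  give t½ per condition; conditions are compared with pairwise unpaired
  two-tailed Welch t-tests and Bonferroni correction. Curves whose
  plateau the experiment never reaches report t½ as **"not attained"**
  instead of a number.
* **Spatial structure**: radial distance `√(x² + y²)` from the dome
  center, 9 × 250 µm radial bins with per-bin mean curves, and
  core/periphery allocation of nuclei by a 100-pixel rim from the
  organoid circumference, split by size class (> 8000 µm² = large).
* **Dose-response**: 4PL fits
  `r(d) = bottom + (top − bottom)/(1 + (d/ec50)^hill)` with bootstrap
  EC50 confidence intervals, and whole-curve comparison by the
  extra-sum-of-squares F-test (shared vs separate 4PLs).
* **Synthetic data**: two-channel monolayer and organoid time-lapses with
  programmed translocation kinetics, dome layouts with
  position-dependent lags, tubulin textures with a controllable
  stabilization level, and 4PL viability plates with multiplicative
  noise — all seeded, bit-reproducible, and emitted with ground-truth
  tables.

See `docs/methods.md` for models, defaults and limitations, and
`docs/data_dictionary.md` for every output column.

## Worked example

Render a Matrigel-covered monolayer whose programmed translocation lag is
3 h, then run the full analysis path (segmentation → per-cell ratios →
mean curve → t½ fit) and compare against the programmed truth:

```python
import numpy as np
from organotrace import (ImagingConfig, KineticModel, random_cell_layout,
                         render_translocation_timelapse)
from organotrace.pipeline import analyze_translocation_stack

imaging = ImagingConfig()                     # 512x512, 0.325 um/px, 16-bit
times = np.arange(0.0, 8.01, 0.25)            # every 15 min for 8 h
matrigel = KineticModel(lag_h=3.0)            # scaffold delays the response
cells = random_cell_layout(20, imaging, seed=1,
                           nuclear_fraction=matrigel.baseline)
stack, truth = render_translocation_timelapse(cells, matrigel, times,
                                              imaging, seed=2)
cells_table, curve, fit = analyze_translocation_stack(
    stack, times, imaging.pixel_size_um)
print(f"cells measured: {cells_table['valid'].sum()} "
      f"across {len(times)} frames")
print(f"fitted t1/2 = {fit.t_half_label} h "
      f"(programmed {matrigel.true_t_half:.2f} h)")
print(f"baseline {fit.baseline:.3f} -> plateau {fit.plateau:.3f}")
```

prints

```
cells measured: 660 across 33 frames
fitted t1/2 = 3.748 h (programmed 3.75 h)
baseline 0.244 -> plateau 0.813
```

The fitted half-transition time recovers the programmed `lag + t50 =
3.75 h` to within a few hundredths of an hour; the fitted baseline and
plateau track the programmed nuclear-fraction range (0.2 → 0.85) up to
the small bias of disk/annulus discretization.

## Command line

```bash
# write synthetic data (TIFF + ground-truth CSV)
organotrace simulate monolayer|dome|tubulin|plate --out DIR --seed 1

# run a full scenario (simulate -> segment -> quantify -> fit -> report)
organotrace run --scenario monolayer_scaffold --out DIR --seed 1
organotrace run --config my_config.yaml --out DIR
```

Scenarios: `monolayer_scaffold` (0/1/3 h scaffold lags, three
experiments), `dome_binning` (organoids across a 2250 µm dome, 9 radial
bins), `core_periphery` (large vs small organoids, 1 h core lag), and
`dose_response` (two arms with a 10× EC50 shift). Each writes
`cells.csv`, aggregated curve tables, `fits.json`, `report.json` and a
provenance file; every default is overridable from one YAML config.

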