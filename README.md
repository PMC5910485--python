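# poredirection

Quantification of directionally asymmetric small-molecule uptake into
electropermeabilized cells: electrode-aligned regional photometry of
time-lapse fluorescence stacks, concentration calibration,
asymmetry-difference kinetics with exponential-decay fitting, and the
supporting diffusion physics — exercised end-to-end on a bundled synthetic
reaction–diffusion image simulator.

## What it does

A pulsed electric field transiently permeabilizes the cell membrane;
impermeant fluorescent dyes then enter preferentially at the pole facing one
electrode or the other depending on pulse regimen. The pipeline quantifies
this:

1. **`synthetic_data`** — simulates dye uptake into a disc-shaped cell:
   angularly localized membrane influx with exponential resealing,
   intracellular reaction–diffusion with optional intercalation binding,
   rendering through a calibration curve with camera noise. Every stack
   carries exact ground truth (per-frame concentration fields, cumulative
   influx).
2. **`image_io`** — multi-page 16-bit TIFF stacks with YAML metadata
   (frame interval, pixel size, field axis, anode side, pulse time);
   long-format traces CSV.
3. **`calibration`** — per-dye linear intensity↔concentration standard
   curves from replicate tables (lysate procedure) or anchored to a known
   extracellular concentration (calcein procedure).
4. **`pattern_analysis`** — the core computation: each cell mask is divided
   into 1-pixel rows parallel to the electrodes, rows are grouped into
   anode/middle/cathode thirds (equal polar groups, remainder to the
   middle; 50 rows → 16/18/16), and the group value is the average of row
   means. Includes centroid tracking and second-order Savitzky–Golay
   smoothing.
5. **`kinetics`** — anode−cathode and region−middle difference traces,
   decaying-exponential fits `A·exp(−(t−t₀)/τ)` anchored at the post-pulse
   dominant-sign extremum, and middle-region crossover times.
6. **`physics`** — Einstein–Smoluchowski diffusion-time estimates
   (the MSD prefactor 2/4/6 is an explicit argument; see note below),
   Stokes–Einstein coefficients, dye mobility ratios, and a bundled dye
   property table (YP1, Pr, calcein).
7. **`cli`** — reproducible command-line workflow.

## CLI

```sh
# simulate one pulse regimen (writes stack.tif, stack.yaml, truth.csv, ...)
poredirection simulate --scenario nanosecond_multi_anode --out-dir out --seed 1

# fit a calibration line from a replicate table
poredirection calibrate --points yp1_points.csv --dye YP1 --out yp1_curve.csv

# track cells and extract regional traces
poredirection analyze --stack out/stack.tif --meta out/stack.yaml \
    --calib out/calibration.csv --out traces.csv

# exponential fits + crossover times of the difference traces
poredirection fit --traces traces.csv --pulse-time 5 --out fits.csv

# diffusion arithmetic
poredirection physics difftime --distance-um 12 --D 1e-10 --factor 4
poredirection physics ratio --dye YP1 --dye Pr

# everything at once, plus fixture generation
poredirection run-all --scenario microsecond_bipolar --out-dir run1 --seed 1
poredirection make-fixtures --seed 1 --out-dir fixtures
```

Scenarios: `microsecond_bipolar` (bipolar influx with a brief anode-favoring
transient, cathode-dominant overall), `nanosecond_multi_anode` (purely
anode-side), `nanosecond_single_symmetric` (weak, slightly anode-favoring),
`symmetric_low` (strictly symmetric, calcein-style).

## Conventions

Pixel indices are 0-based; frames are indexed (y, x). `field_axis` names the
image axis the field runs along; a partition "row" is the set of in-mask
pixels sharing one coordinate along the field axis (rows parallel to the
electrodes). `anode_side` ∈ {low, high} marks which end of the field axis
faces the anode. Concentrations are µM, lengths µm, time s; intensities are
arbitrary 16-bit-range units on disk, float internally.
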