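# glucest

Simulation and analysis pipeline for GluCEST MRI of mouse-brain phantoms:

- **phantom** — seeded synthetic CEST/WASSR acquisitions over a digital
  mouse-brain phantom (100×100, 16 mm FOV) with known ground truth:
  per-ROI glutamate levels calibrated exactly to target MTRasym values,
  a smooth seeded B0 field, and Gaussian signal noise. Signal model:
  sum of unit-peak Lorentzians (water, amide, glutamate, NOE, MT).
- **zspec** — frequency-axis handling (ppm ↔ Hz at the nominal 400 MHz
  field, so 3 ppm ↔ 1200 Hz), Z-spectrum normalization, bounded
  multi-pool Lorentzian fitting, natural cubic-spline resampling.
- **b0corr** — per-pixel water center frequency from the WASSR sweep
  (Lorentzian fit, spline-argmin fallback) and resampling-based
  correction of the CEST stack back onto the nominal axis.
- **asym** — MTRasym(Δ) = (S(−Δ) − S(Δ))/S0, per-pixel glutamate maps at
  3 ppm, per-ROI group-mean tables (age × genotype), age-trend reports.
- **harmonize** — additive young→old data-offset harmonization fitted on
  training subjects only, plus seeded translation/rotation/crop
  augmentation with full provenance.
- **classify** — AD-vs-WT SVM (RBF, scikit-learn) on standardized
  in-mask pixels with subject-level stratified splits (augmented copies
  never cross the split), confusion-matrix metrics and the rate-pair
  F1 harmonic mean.
- **cli / io / pipeline** — NIfTI + JSON-sidecar and CSV artifacts, and
  a stage-by-stage command line.

## CLI

Each stage reads the previous stage's artifacts from the run directory:

```sh
glucest simulate -o runs/demo --seed 0     # phantoms for all 8 cohort cells
glucest b0map    -o runs/demo              # WASSR → per-pixel B0 maps
glucest correct  -o runs/demo              # shift CEST stacks onto nominal axis
glucest mtrasym  -o runs/demo              # per-pixel glutamate maps
glucest roitable -o runs/demo              # ROI × (age, genotype) mean table CSV
glucest harmonize -o runs/demo             # fit + apply the age data offset
glucest classify -o runs/demo              # SVM metrics JSON
glucest report   -o runs/demo              # summary CSVs + run manifest
```

Configuration comes from a YAML file (`-c cfg.yaml`) or flags; every
artifact embeds the config hash and seed, and a rerun with the same
config and seed is byte-identical for CSV/JSON outputs.

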