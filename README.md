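# diffusemap

Reconstruction, modeling and diagnostics of three-dimensional diffuse X-ray
scattering maps from protein-crystal rotation series.

The package covers the full analysis chain:

* **geometry** — pixel-to-reciprocal-space mapping (q = 2π/d convention),
  polarization and solid-angle corrections, per-frame scale factors
  (deliberately no Lorentz correction: pixel intensities are averaged, not
  integrated);
* **masking** — Bragg removal by spot prediction plus a 3σ local-window
  filter and a 5×MAD radial filter, strictly without replacement;
* **background** — per-frame radial-profile correction: a second-degree
  polynomial plus a scaled, shifted amorphous reference profile, followed
  by PCA removal of residual radial variance between frames;
* **mapping** — merging into a 3×(or 5×)-oversampled reciprocal-space grid,
  Laue/Friedel symmetrization, symmetry correlation statistics, radial
  average subtraction and positivity offset;
* **models** — analytic diffuse predictions for five disorder models:
  rigid-body translations, rigid-body rotations (Monte Carlo), liquid-like
  motions with an exponential correlation kernel (asymmetric-unit-confined
  and extended/intermolecular variants), discrete probability-weighted
  ensembles, and a B-factor-renormalized elastic-network / general Gaussian
  covariance model;
* **fitting** — multiplicity-weighted correlation coefficients and
  coarse-to-fine disorder-parameter scans;
* **diagnostics** — speckle fall-off profiles versus distance δq to the
  nearest reciprocal-lattice node (with 1/δq² and 8πγ³/(1+γ²δq²)² fits) and
  map autocorrelation with unit-cell translation-peak detection;
* **synthetic** — toy crystals, explicit sampled-ensemble oracles for every
  disorder model, and a rotation-image renderer (Bragg spots, isotropic
  backgrounds, contaminant profile, scale jitter, Poisson noise) with
  ground-truth sidecars, so the entire pipeline is testable at desk scale.

## Command-line interface

```bash
# render a synthetic rotation series with known ground truth
diffuse simulate --scenario roundtrip --seed 1 --out sim/

# reconstruct a diffuse map from an HDF5 frame stack
diffuse build --frames sim/frames.h5 --out maps/run1 \
    --background-components 2 --mask-report masks.csv

# fit a disorder model to a reconstructed map
diffuse fit --model llm-ext --map maps/run1.csv --pdb model.pdb \
    --cell 42.9,52.4,89.1,90,90,90 --spacegroup P212121 --out fit.json

# speckle fall-off and autocorrelation diagnostics
diffuse speckle --map maps/run1.csv --config sim/config.yaml --out falloff.csv
diffuse autocorr --map maps/run1.csv --config sim/config.yaml --out peaks.csv
```

Maps are written as CSV (h, k, l, intensity, n_obs, multiplicity, snr), a
JSON statistics sidecar and a CCP4/MRC-style binary volume.

## Notes on conventions

* Scattering vectors use |q| = 4π sin θ/λ = 2π/d.
* The orientation matrix has the 2π-scaled reciprocal-cell vectors as
  columns, so q = A·(h,k,l).
* Oversampling is odd so grid nodes coincide with integral Miller indices.
* Debye–Waller damping is exp(−σ²|q|²) with B = 8π²σ² (per-axis σ).
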