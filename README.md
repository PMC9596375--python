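# emshift

Toolkit for dual-indicator redox potentiometry of receptor-bound cofactors:

- **`emshift.thermo`** — closed-form Nernst math and the thermodynamic cycle
  linking a bound ligand's midpoint-potential shift to differential binding
  of its oxidized and reduced forms
  (`delta_em = -(RT/nF) * ln(kd_red/kd_ox)`).
- **`emshift.simulate`** — forward simulator for the enzyme-driven
  equilibration assay (two redox couples at a shared solution potential,
  electron equivalents delivered at a constant rate, absorbance spectra from
  Gaussian-band basis envelopes with exactly-enforced isosbestic points),
  plus generators for single-site calorimetry thermograms, Hill
  fluorescence-quench titrations and shared-amplitude cleavage titrations.
- **`emshift.extract`** — the inference pipeline: plateau detection,
  isosbestic-anchored oxidized-fraction traces, optional reference-dye
  subtraction, paired Nernst-term regression, and midpoint read-out from the
  intercept (`E_m = E_m,dye + b`), with replicate averaging and a
  one-electron-intermediate spectral check.
- **`emshift.fits`** — binding-isotherm estimators: exact single-site
  calorimetry fit (displaced-volume correction, optional dilution offset),
  Hill fit with the amplitude fixed to 1, joint one-site fit with a shared
  amplitude (censoring non-binders), spectrum normalization and peak-shift
  metrics.
- **`emshift.io` / `emshift.cli`** — CSV formats, schema-validated YAML
  configuration, provenance sidecars, and the `emshift` command.

All potentials are millivolts vs SHE; temperatures are kelvin.

## CLI

```sh
# thermodynamic cycle, both directions
emshift thermo --delta-em -40 --temp 295
emshift thermo --kd-ox 2.43e-7 --kd-red 5.59e-6

# simulate an assay and re-extract the configured midpoint
emshift simulate-assay --config run.yaml --out spectra.csv
emshift extract-em spectra.csv --config extract.yaml

# isotherms
emshift simulate-itc --kd 2.43e-7 --dh -8 --out itc.csv
emshift fit-itc itc.csv --subtract-dilution
emshift simulate-quench --kd 1e-6 --hill 2 --out quench.csv
emshift fit-quench quench.csv
emshift fit-probing curve_ox.csv curve_red.csv
emshift spectral-shift free.csv bound.csv
```

Example `run.yaml`:

```yaml
flavin: {preset: free-FAD, e_m_mv: -209}
reference_dye: {preset: AQS, e_m_mv: -225}
temperature_k: 295
noise_sd_au: 0.0
seed: 0
```

Example `extract.yaml`:

```yaml
dye_name: AQS
dye_e_m_mv: -225
dye_wavelength_nm: 335   # ligand isosbestic: reads the dye
flavin_wavelength_nm: 355  # dye isosbestic: reads the ligand
temperature_k: 295
```

For the low-potential dye (`PSF`, read at 540 nm with the ligand at 456 nm)
set `subtract_dye: true` and `dye_preset: PSF` so the dye's contribution at
the ligand channel is removed using its basis spectrum.

## Notes

- Spectral band amplitudes/widths in `BASIS_PRESETS` are simulator
  conventions (no published absorptivities are encoded); isosbestic
  constraints are enforced exactly by rescaling the reduced envelope.
- The mediator and oxygen-scrubbing components of the real assay are treated
  as kinetically instantaneous and spectrally silent; electron delivery is
  pseudo-zero-order.
- Nernst regression places the reference-dye terms on the y-axis so the
  intercept equals `E_m,ligand - E_m,dye` and the slope equals
  `n_dye / n_ligand` (1 for matched two-electron couples).
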