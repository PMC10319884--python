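# mirhsi

Simulation and analysis toolkit for **scanless mid-infrared (MIR)
hyperspectral chemical imaging by chirped-pulse upconversion**.

A broadband sub-cycle MIR pulse (3–30 µm) globally illuminates a sample;
the transmitted field — main pulse plus the picosecond free-induction-decay
(FID) tails of the molecular absorption lines — is mixed with a 1.8 ps
linearly chirped pulse at 790 nm in a thin GaSe film on the image plane.
Type-I sum-frequency generation translates the MIR spectrum into the
638–752 nm window of a silicon hyperspectral camera, which records a
640 × 480 × 1069 data cube covering 640–3015 cm⁻¹ at 2.6–3.7 cm⁻¹
resolution. Chemometric mapping of the cube then identifies chemical
components per pixel.

The package provides, fully testable without any experimental data:

* **`mirhsi.forward`** — a physics-based instrument simulator: super-Gaussian
  MIR source solved to its 13.6 fs envelope, Beer–Lambert transmission with
  Kramers–Kronig-consistent Lorentzian lines, chirped-pulse SFG, the camera's
  resolution kernel, 12-bit quantization, 2.77 % multiplicative frame noise
  and shot-like noise, and a Gaussian imaging PSF.
* **`mirhsi.phantoms`** — ground-truth scenes: the five-channel microfluidic
  device, a copper mesh grid, a water-flow image sequence at the 5 kHz
  frame rate, and random blob fields.
* **`mirhsi.phase_matching`** — GaSe refractive indices (embedded Sellmeier
  set), collinear type-I phase mismatch Δk, conversion efficiency
  η ∝ L² sinc²(ΔkL/2) and band-coverage verdicts (thin film vs fringed
  thick crystal).
* **`mirhsi.retrieval`** — measured spectra → calibrated MIR transmittance:
  photon-energy axis mapping (1/λ_MIR = 1/λ_SFG − 1/λ_CP), background
  ratioing, removal of the cross-phase-modulation artifact by correcting the
  parabolic phase of the spectrum's Fourier transform, chirp-rate calibration
  from the spectrally resolved cross-correlation, and CO₂-based wavenumber
  calibration.
* **`mirhsi.chemometrics`** — additive averaging *I*₍ave₎ = S/n, the
  normalized difference spectral index NDSI = (I₁−I₂)/(I₁+I₂), the spectral
  angle mapper, Fisher linear discriminant analysis maximising
  J(w) = (wᵀS_B w)/(wᵀS_W w), constrained random teaching-region sampling,
  and the 10–90 % edge-response resolution estimator.
* **`mirhsi.cli`** — `mirhsi simulate / phasematch / retrieve / analyze /
  edge / report`, reading YAML pipeline configs and writing ENVI cubes,
  CSV spectra, PNG class maps and JSON run records.

## Worked example

```python
import numpy as np
import mirhsi as M

config  = M.OpticalConfig(n_bands=1069)      # the instrument's sampling
library = M.default_library()

mir      = M.generate_mir_pulse(config)
cp, cal  = M.generate_chirped_pulse(config)

sample   = M.apply_sample(mir, {"co2": 1.0}, library)
meas, bg = M.measure_pair(sample, mir, cp, config=config)

t = M.compute_transmittance(meas, bg, cal)
print("retrieved CO2 band centre: %.1f cm-1" % M.line_center(t, 2349.0))
print("minimum transmittance:     %.3f" % t.values[t.mask].min())

t_cal, offset = M.calibrate_wavenumber(t)
print("wavenumber calibration offset: %.2f cm-1" % offset)
```

prints

```
retrieved CO2 band centre: 2348.5 cm-1
minimum transmittance:     0.647
wavenumber calibration offset: 0.57 cm-1
```

— the CO₂ asymmetric-stretch band injected by the forward model at
2349 cm⁻¹ is recovered within one resolution element (3.4 cm⁻¹ at this
wavelength); its depth matches exp(−0.45) of the library line after the
instrument's spectral smoothing; and the rigid CO₂ calibration offset is
small because the simulated axis is already aligned.

A full imaging run from the shell:

```bash
mirhsi simulate --seed 1 --out run/          # 64x48x256 desk-scale cube pair
mirhsi retrieve --cube run/cube --background run/background --out run/
mirhsi analyze --transmittance run/transmittance --labels run/truth_labels.png \
               --method lda --out run/
mirhsi report                                 # axis-mapping numbers
```

## Layout

```
src/mirhsi/       library (config, fields, library, forward, phantoms,
                  phase_matching, retrieval, chemometrics, cube, envi, cli)
tests/            pytest suite (unit, property and end-to-end tests)
scripts/          acceptance.py
docs/methods.md   model description, parameter choices, limitations
```
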