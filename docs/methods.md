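# Methods

This note describes the models implemented in `mirhsi`, the parameter
choices that matter, the numerical decisions behind them, and what the
synthetic data can and cannot show about the real instrument.

## Instrument model

### Fields and units

All optical fields are complex analytic signals (positive-frequency
content only) carrying their true carriers, sampled on a uniform time
grid of 32768 points at 1 fs (power-of-two length for FFT efficiency;
the 32.8 ps span holds the chirped pulse four times over and lets the
FID of a 10 cm⁻¹-wide line decay below 10⁻¹³ of its peak before the grid
edge). The 1 fs step places the Nyquist frequency at 500 THz, above the
highest sum-frequency carrier (~480 THz). Time is in fs, frequency in
cycles/fs, wavelength in nm, wavenumber in cm⁻¹; `mirhsi.constants`
holds the two speed-of-light constants that connect them. Every field
transformation up to detection conserves energy between domains
(Parseval) to better than 10⁻⁹ relative — this is asserted by a test.

### MIR source

The source spectrum is a super-Gaussian of order 3 centred mid-band
(333–3333 cm⁻¹) with flat spectral phase. Its width is solved by a
bracketed root find so that the intensity-envelope FWHM equals the
configured 13.6 fs exactly (to below one time step). A consequence worth
stating: a 13.6 fs pulse cannot be spectrally flat over a 3000 cm⁻¹
band, so the band edges carry reduced (but non-zero, ≥10⁻⁶ of peak)
spectral intensity and the in-window shoulders of the spectrum are
sloped. Only relative transmittance matters after background ratioing,
but the slope does interact with the chirp correction (see below).

### Sample interaction

Each absorption line multiplies the field spectrum by
`exp(-(s/2)·γ/(γ + i(ν−ν₀)))` with γ = FWHM/2: the real part is a
unit-peak Lorentzian of peak optical depth *s* (intensity transmittance
e⁻ˢ at centre), the imaginary part its Kramers–Kronig phase partner.
This causal response is what produces the physical FID tail — the field
envelope decays as exp(−π·c·FWHM·t), verified against that closed form
in the tests. Optical depths of a mixture add exactly (Beer–Lambert
composition, asserted to 10⁻¹²). Opaque structures (channel walls, mesh
bars) use a wavelength-independent "gray" optical depth.

The shipped species library carries the diagnostic bands of the five
microchannel substances (glycerin, glucose, albumin, DOPC, soybean
oil), water (1640 cm⁻¹ O–H bend) and CO₂. Strengths (0.35–0.55) and
widths (30–90 cm⁻¹) are representative of thin liquid/cast films in a
25 µm channel; the CO₂ entry models the unresolved asymmetric-stretch
band as a single 35 cm⁻¹ envelope at 2349 cm⁻¹, since the instrument's
2.6–3.7 cm⁻¹ resolution cannot separate rovibrational lines.

### Chirped pulse

A Gaussian spectrum at 790 nm with quadratic spectral phase φ₂ chosen
from the closed-form Gaussian relation so the stretched duration equals
1.8 ps. The transform-limited duration is 70 fs: the 783 nm long-pass
filter that separates the chirped pulse from the SFG light roughly
halves the 35 fs oscillator bandwidth, and this bandwidth sets the chirp
rate a = φ₂/(τ_g⁴+φ₂²) ≈ 2.2×10⁻⁵ rad/fs². The analytic rate is
returned by the generator as the calibration oracle. The chirp sign is
positive (instantaneous frequency rises with time), which places the
FID artifact on the high-wavenumber side of each line; the retrieval
reads the sign from the calibration, so either convention works.

### Detection

The product field E_CP(t)·E_MIR(t) is spectrally filtered by the
phase-matching amplitude √η(ν) (thin-crystal approximation: the chirped
pulse treated as quasi-monochromatic, so the transfer is a function of
MIR wavenumber alone), squared, convolved with a Gaussian kernel of
0.15 nm FWHM (the camera's wavelength resolution, evaluated at the
window centre), sampled at `n_bands` points over 638–752 nm, scaled so
the background peaks at 85 % of full scale, and digitised to 12 bits.
One gain is shared by a sample/background pair (`measure_pair`,
`simulate_cube`), as a real exposure setting would be.

Noise model, matching the two summary figures available: one
multiplicative log-normal frame factor of RMS 2.77 % per spectral frame,
plus per-band Gaussian shot-like noise scaled so the SNR at full scale
is 1365. The random nitrogen-oxide/water artifact bands seen in long
acquisitions are not modelled (off by default per the design intent; the
plumbing to add extra absorbers to the background path is
`apply_sample` itself).

### Imaging

Cubes are assembled per unique (mixture, gray) pixel class — one
spectral simulation per class, not per pixel — then blurred with an
isotropic Gaussian PSF. The PSF width (σ = 5.852 µm) is a configured
stand-in chosen so that the 10–90 % edge response is ≈15 µm; the
estimator itself is validated against the closed form 2.5631·σ of an
ideal Gaussian-blurred step. Desk-scale cubes default to 64×48×256
(12.5 µm pitch over the 800×600 µm field); the full 640×480×1069 scale
is a configuration flag away and changes nothing structurally. At 256
bands the 0.15 nm kernel is undersampled (≈0.45 nm steps), which costs
about 0.007 of round-trip accuracy; spectral-accuracy tests therefore
run the instrument's stated 1069-band sampling.

## Phase matching

GaSe ordinary/extraordinary indices come from a standard published
Sellmeier parameterisation (Handbook of Nonlinear Optical Crystals
coefficient set; validity window 0.62–18 µm as embedded). The tests
assert self-consistency of the model (index-ellipse identities at
θ = 0°/90°, Δk sign-change location against a dense-grid scan, sinc
zeros, L² small-thickness scaling), not absolute literature accuracy,
because fringe positions depend on a coefficient set the imaging work
itself does not print. Type-I o+o→e collinear mixing with no walk-off —
appropriate for a film a few µm thick on the image plane. The
propagation angle defaults to 26.5°, which near-maximises the minimum
in-band efficiency of the 4.4 µm film (0.70 over 640–3015 cm⁻¹); the
internal angle of the real, cleaved film is not derivable from the
available information, so θ is an explicit parameter. The thickness is
likewise a parameter, not a fitted value. On this model a 100 µm
crystal produces 15 full sinc fringes across the band while any film
below ~5 µm keeps the whole band strictly phase-matched, which is the
behaviour the thin-film configuration exists to exploit.

## Retrieval

### Axis and resolution bookkeeping

Photon-energy conservation 1/λ_MIR = 1/λ_SFG − 1/λ_CP maps the window
edges to 3316 and 15634 nm (640–3016 cm⁻¹); dν = 10⁷·dλ/λ² gives
3.69 cm⁻¹ at 638 nm and 2.65 cm⁻¹ at 752 nm for 0.15 nm sampling. Both
identities hold per band, exactly, and are asserted as such. Two
resolution scales coexist in this instrument — the camera-limited
2.6–3.7 cm⁻¹ and the inverse chirped-pulse duration (~18 cm⁻¹ for
1.8 ps, which truncates the FID of lines narrower than that); the
package book-keeps the camera figure per band and leaves the second as
a physical property of the simulation itself.

### Chirp calibration

The spectrally resolved cross-correlation (SFG spectrum versus
MIR-pulse delay) is simulated by the forward model over the full SFG
support — the diagnostic scan bypasses the short-pass detection filter,
because clipping the spectrum biases any centroid. Since the MIR pulse
is transform-limited and short, the whole upconverted spectrum shifts
with delay at exactly the chirp rate, so the intensity-weighted spectral
centroid versus delay, fitted linearly with per-delay weights, recovers
*a*; on simulated maps the recovery is within 0.01 %. (A per-frequency
centroid of delay — the transposed reading — fails here: the source
bandwidth, ~90 THz, far exceeds the chirp sweep, ~8 THz, so that
centroid reflects envelope overlap, not the chirp. This is a property of
any ultra-broadband source, not of the simulation.) An unchirped map
yields a degenerate fit and raises a calibration error; a non-monotone
centroid trace sets a warning flag on the result.

### Cross-phase-modulation correction

The measured spectrum is the squared magnitude of the product field, so
its inverse Fourier transform is the field autocorrelation; the chirp
imprints a parabolic phase a·τ²/2 on the FID sidebands, which appears
in the spectral domain as an oscillation extending away from each
absorption line. The correction transforms the *fluctuation part* of
the background-ratioed spectrum to the delay domain, multiplies by
exp(−i·sign(τ)·a·τ²/2), and transforms back. Two numerical choices
matter and were fixed by analysis rather than convention:

1. **Hermitian phase.** The spectrum is real, so its interferogram is
   Hermitian; multiplying by a symmetric exp(−i a τ²/2) and taking the
   real part is equivalent to multiplying the interferogram by
   cos(aτ²/2) — no correction at all. The sign(τ) factor applies the
   phase conjugately to the two Hermitian halves and keeps the
   corrected spectrum exactly real.
2. **√background normalisation.** The FID sideband at frequency ω
   carries one factor of the source spectral amplitude at the line and
   one at ω itself. Dividing the fluctuation by √(background) before
   the transform and again after it weights both factors correctly;
   normalising by the background once (a plain ratio) misweights
   sidebands wherever the source spectrum is sloped, which produced
   several-percent dip errors at band-shoulder lines (e.g. 851 cm⁻¹)
   before this was fixed.

The interferogram is zero-padded (512 grid points each side) to
suppress circular wrap from the finite band. With a = 0 the operation
is the identity to 10⁻⁹, making reapplication with zero residual chirp
idempotent. On noiseless simulations the correction reduces the
artifact in the CO₂ sideband window by ~29× and the full round trip
(forward model → retrieval vs the known input transmittance) is
accurate to ≤0.015 everywhere on the axis at 1069-band sampling, with
line centres recovered within one resolution element at 851, 1030,
1640 and 2349 cm⁻¹. Bands whose background falls below 1 % of full
scale are masked and their ratio pinned to 1 before the transform so
they cannot ring into valid bands.

### Wavenumber calibration

A rigid axis offset aligns the absorption centroid in the 2300–2400 cm⁻¹
window to the CO₂ reference (2349 cm⁻¹). A centroid, not individual
line positions, because the band is unresolved at this resolution; a
rigid shift, not a stretch, because one reference band constrains one
degree of freedom. A spectrum with no dip deeper than 0.02 in the
window raises an error and is left unshifted.

## Chemometrics

Additive averaging and NDSI are the literal arithmetic definitions, with
empty band selections rejected and zero-sum NDSI pixels flagged rather
than propagated as NaN. The spectral angle mapper normalises both pixel
and teaching spectra to unit length before the inner product — raw
inner products would be brightness-biased, and normalisation is what
makes the method a spectral *angle* mapper and classification invariant
under per-pixel scaling (asserted as a property). Zero-norm pixels take
the reserved unclassified label 0.

Fisher LDA builds between/within-class scatter from teaching spectra
and solves the symmetric-definite generalized eigenproblem
S_B w = λ S_W w (up to C−1 components, nearest-centroid assignment in
the projected space — the multi-class extension of the two-class
construction). A ridge proportional to trace(S_W)/n is added only when
S_W is singular or near-singular, and is recorded on the model. The
two-class solution is checked against the closed form S_W⁻¹(μ₁−μ₂) and
the returned criterion against a 10⁵-draw random-direction search.
Classification operates on retrieved transmittance, optionally
restricted to the diagnostic teaching-peak bands of the five species.

Teaching regions are axis-aligned rectangles rejection-sampled under
strict inequalities on width, height and area, non-overlapping, and
reproducible by seed; with a label map they are additionally confined
to one class's pixels (the "location information" workflow). Failure to
place the requested count within an attempt budget raises an error
reporting the achieved count.

On the noiseless desk-scale microchannel phantom SAM labels 100 % of
in-channel pixels correctly; at the 2.77 % frame-noise level LDA on the
thirteen teaching peaks stays ≥95 % (measured: 100 %). These figures
are properties of the synthetic conditions — five spectrally disjoint
absorbers at good SNR — and should be read as a validation of the
algorithm chain, not as a predicted accuracy for real tissue.

## What the generator does and does not emulate

Emulated: band-limited detection with background ratioing, FID-driven
chirp artifacts, camera resolution and quantization, frame-to-frame
gain fluctuation, shot-noise scaling, PSF blur, the microfluidic /
mesh / flow scene geometries at their stated dimensions and timing
(0.2 ms frame spacing at 5 kHz).

Not emulated: absolute radiometry (all intensities are relative to the
background peak), polarization and walk-off, Fresnel/étalon effects of
the film and substrate, water-vapour line structure, the random
nitrogen-oxide artifact bands, detector dark/readout structure beyond
the two summary noise figures, and any spatial heterogeneity of real
samples beyond the phantom classes. Passing tests therefore demonstrate
correctness of the computational chain under the stated physics, not
instrument-level agreement with laboratory data.

## Known limitations

* Lines narrower than ~18 cm⁻¹ lose FID beyond the chirped-pulse window
  and retrieve with reduced depth; the effect is physical, not numeric.
* The parabolic-phase correction leaves a residual that grows roughly
  quadratically with line optical depth (the uncorrected |FID|² term);
  at the shipped strengths it stays below ~0.015 of transmittance.
* Lines within ~60 cm⁻¹ of the 640 or 3015 cm⁻¹ band edge lose wing
  information to the window and retrieve less accurately; the chirp
  direction decides which edge is worse.
* ENVI I/O covers the subset of the format this package writes (BSQ
  write; BSQ/BIL/BIP read, little-endian, text header).
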