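"""Physics-based forward model of the upconversion imaging instrument.

The simulated chain per pixel is:

1. a broadband MIR pulse (super-Gaussian spectrum over the source band,
   envelope solved to the configured FWHM),
2. Beer-Lambert transmission through the sample: every absorption line
   multiplies the field spectrum by exp(-(s/2) L(nu) + i phi(nu)) with a
   unit-peak Lorentzian L and its Kramers-Kronig phase partner, which
   produces the picosecond free-induction-decay (FID) tail in time,
3. sum-frequency mixing with a linearly chirped pulse at 790 nm
   (product field), filtered by the crystal phase-matching transfer,
4. the camera: spectral-resolution kernel, restriction to the 638-752 nm
   window, band sampling, multiplicative frame noise, shot-like noise,
   clipping and quantization.

All randomness is drawn from one integer seed, and identical seeds give
bit-identical cubes.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.optimize import brentq

from .config import ConfigError, OpticalConfig
from .constants import C_CM_FS, C_NM_FS
from .cube import HyperspectralCube
from .fields import FieldTrace, freq_grid, from_spectrum, time_grid, to_spectrum
from .library import SpeciesLibrary
from .phantoms import PhantomMap
from .retrieval import ChirpCalibration, MeasuredSpectrum

_LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# pulse generation
# ---------------------------------------------------------------------------

def generate_mir_pulse(config: OpticalConfig) -> FieldTrace:
    """Transform-limited broadband MIR pulse.

    The spectral amplitude is a super-Gaussian centred mid-band whose
    width is solved numerically so that the intensity-envelope FWHM
    equals ``config.mir_pulse_fwhm_fs``; the spectrum then covers the
    full source band at a low but non-zero level (a 13.6 fs pulse cannot
    be spectrally flat over a 3000 cm^-1 band).
    """
    t = time_grid(config.n_time, config.dt_fs)
    f = freq_grid(config.n_time, config.dt_fs)
    f_lo = C_CM_FS * config.mir_band_lo_cm
    f_hi = C_CM_FS * config.mir_band_hi_cm
    fc = 0.5 * (f_lo + f_hi)
    m = config.mir_spectral_order

    def make(width):
        amp = np.exp(-0.5 * ((f - fc) / width) ** (2 * m))
        amp[f <= 0] = 0.0
        return from_spectrum(amp)

    def fwhm_err(width):
        e = make(width)
        from .fields import fwhm

        return fwhm(t, np.abs(e) ** 2) - config.mir_pulse_fwhm_fs

    w_min = 2.0 / (config.n_time * config.dt_fs)  # a couple of grid bins
    w_max = 0.45 / config.dt_fs
    try:
        width = brentq(fwhm_err, w_min, w_max, xtol=1e-10)
    except ValueError as exc:
        raise ConfigError(
            "cannot realise the requested MIR pulse duration on this time grid"
        ) from exc
    field = make(width)
    field = field / np.abs(field).max()
    return FieldTrace(t, field, kind="mir", meta={"spectral_width": width, "config": config})


def _cp_phi2(config: OpticalConfig) -> tuple[float, float]:
    """(Gaussian spectral width tau_g, quadratic spectral phase phi2) in fs units."""
    tau0 = config.cp_transform_limit_fs
    T = config.cp_duration_fs
    tau_g = tau0 / (2.0 * np.sqrt(_LN2))
    if T < tau0:
        raise ConfigError("chirped-pulse duration shorter than its transform limit")
    phi2 = tau_g**2 * np.sqrt((T / tau0) ** 2 - 1.0)
    return tau_g, phi2


def generate_chirped_pulse(config: OpticalConfig) -> tuple[FieldTrace, ChirpCalibration]:
    """Linearly chirped Gaussian pulse at the upconversion wavelength.

    A quadratic spectral phase phi2 stretches the transform-limited
    pulse to the configured duration.  The returned calibration carries
    the exact analytic chirp rate a = phi2 / (tau_g^4 + phi2^2)
    (d instantaneous angular frequency / d time, rad/fs^2) for use as an
    oracle and by the retrieval.
    """
    t = time_grid(config.n_time, config.dt_fs)
    f = freq_grid(config.n_time, config.dt_fs)
    f0 = C_NM_FS / config.cp_center_wavelength_nm
    tau_g, phi2 = _cp_phi2(config)
    w = 2.0 * np.pi * (f - f0)
    spec = np.exp(-0.5 * (w * tau_g) ** 2) * np.exp(-0.5j * phi2 * w**2)
    spec[f <= 0] = 0.0
    field = from_spectrum(spec)
    field = field / np.abs(field).max()
    chirp_rate = phi2 / (tau_g**4 + phi2**2)
    cal = ChirpCalibration(
        chirp_rate_rad_fs2=float(chirp_rate),
        reference_wavelength_nm=config.cp_center_wavelength_nm,
        residual=0.0,
    )
    return FieldTrace(t, field, kind="cp", meta={"phi2": phi2, "tau_g": tau_g}), cal


# ---------------------------------------------------------------------------
# sample interaction
# ---------------------------------------------------------------------------

def transmission_spectrum(nu_cm: np.ndarray, lines, gray_od: float = 0.0) -> np.ndarray:
    """Complex field transmission of a set of Lorentzian lines.

    Each line contributes exp(-H) with H = (s/2) * g / (g + i (nu-nu0)),
    whose real part is a unit-peak Lorentzian of HWHM g and whose
    imaginary part is the Kramers-Kronig phase partner.  `gray_od` adds
    a wavelength-independent optical depth (opaque structures).
    """
    H = np.zeros(np.shape(nu_cm), dtype=complex)
    for center, strength, fwhm_cm in lines:
        g = fwhm_cm / 2.0
        H = H + (strength / 2.0) * g / (g + 1j * (np.asarray(nu_cm) - center))
    return np.exp(-(H + gray_od / 2.0))


def apply_sample(
    mir: FieldTrace,
    mixture: dict[str, float],
    library: SpeciesLibrary,
    gray_od: float = 0.0,
) -> FieldTrace:
    """Transmit the MIR field through a species mixture (Beer-Lambert).

    Mixture values scale each species' line strengths (effective optical
    depth); an empty mixture with gray_od = 0 returns the field
    unchanged.  The output shows the FID tail after the main pulse.
    """
    lines = library.lines_for_mixture(mixture)
    if not lines and gray_od == 0.0:
        return mir.with_field(mir.field.copy(), kind="sample")
    f = freq_grid(mir.n, mir.dt_fs)
    nu = f / C_CM_FS
    tr = transmission_spectrum(nu, lines, gray_od)
    out = from_spectrum(to_spectrum(mir.field) * tr)
    return mir.with_field(out, kind="sample")


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _pm_amplitude(f: np.ndarray, pm, config: OpticalConfig) -> np.ndarray:
    """Phase-matching amplitude transfer sqrt(eta) over the fine frequency grid."""
    if pm is None:
        return np.ones_like(f)
    nu = f / C_CM_FS
    if callable(pm) and not hasattr(pm, "thickness_um"):
        eta = np.asarray(pm(nu), dtype=float)
    else:
        from .phase_matching import conversion_efficiency

        lo, hi = pm.sellmeier["range_um"]
        # clip evaluation to the Sellmeier validity window; out-of-band
        # frequencies lie outside the detection window anyway
        nu_eval = np.clip(nu, 1.0e4 / hi + 1.0, 1.0e4 / lo - 1.0)
        eta = conversion_efficiency(
            pm, nu_eval, config.cp_center_wavelength_nm, normalize=True
        )
    eta = np.maximum(eta, 0.0)
    return np.sqrt(eta)


def frame_factors(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """Multiplicative frame factors: log-normal, unit mean, RMS deviation `rms`."""
    if rms <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(rms**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))


def sfg_and_measure(
    mir: FieldTrace,
    cp: FieldTrace,
    pm=None,
    config: OpticalConfig | None = None,
    rng: np.random.Generator | None = None,
    gain: float | None = None,
    quantize: bool = True,
):
    """Upconvert, detect and digitise one spectrum.

    Computes the product field E_cp(t)E_mir(t), applies the
    phase-matching amplitude transfer in MIR frequency, takes the
    magnitude-squared spectrum, convolves with the camera resolution
    kernel, samples the detection window and digitises.  With `rng`
    given, one multiplicative frame factor and per-band shot-like noise
    are applied.  Returns a :class:`MeasuredSpectrum`; with
    quantize=False the continuous counts are returned instead (used
    internally to share one gain across a cube).
    """
    if config is None:
        config = OpticalConfig()
    if mir.n != cp.n or abs(mir.dt_fs - cp.dt_fs) > 1e-12:
        raise ValueError("MIR and chirped pulse must share one time grid")
    f = freq_grid(mir.n, mir.dt_fs)
    mir_field = mir.field
    if pm is not None:
        mir_field = from_spectrum(to_spectrum(mir_field) * _pm_amplitude(f, pm, config))
    product = mir_field * cp.field
    spec = np.abs(to_spectrum(product)) ** 2

    # camera resolution kernel: spectral_sampling_nm FWHM at window centre
    lam_mid = 0.5 * (config.detection_lo_nm + config.detection_hi_nm)
    df_res = C_NM_FS * config.spectral_sampling_nm / lam_mid**2
    df_grid = f[1] - f[0]
    spec = gaussian_filter1d(spec, df_res / (2.0 * np.sqrt(2.0 * _LN2)) / df_grid)

    lam = config.wavelength_axis()
    f_det = C_NM_FS / lam
    if f_det.max() > f.max() or f_det.min() < f.min():
        raise ConfigError("detection window outside the simulated spectral grid")
    counts = np.interp(f_det, f, spec)

    if gain is None:
        peak = counts.max()
        if peak <= 0:
            raise ValueError("no signal in the detection window")
        gain = 0.85 * config.full_scale / peak
    counts = counts * gain

    if rng is not None:
        counts = counts * frame_factors(rng, 1, config.frame_noise_rms)[0]
        sigma = np.sqrt(np.maximum(counts, 0.0) * config.full_scale) / config.max_snr
        counts = counts + rng.normal(0.0, 1.0, counts.shape) * sigma

    if not quantize:
        return MeasuredSpectrum(lam, counts, role="raw"), gain
    dig = np.clip(np.rint(counts), 0, config.full_scale).astype(np.uint16)
    return MeasuredSpectrum(lam, dig, role="sample")


def measure_pair(
    sample_field: FieldTrace,
    mir: FieldTrace,
    cp: FieldTrace,
    pm=None,
    config: OpticalConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Measure a sample spectrum and its background with one shared gain.

    The detector gain is fixed by the background (empty-path) spectrum,
    exactly as a real acquisition exposes for the unattenuated beam, so
    the ratio of the two returned spectra is an unbiased transmittance.
    """
    if config is None:
        config = OpticalConfig()
    _, gain = sfg_and_measure(mir, cp, pm, config, rng=None, gain=None, quantize=False)
    background = sfg_and_measure(mir, cp, pm, config, rng=rng, gain=gain)
    background.role = "background"
    sample = sfg_and_measure(sample_field, cp, pm, config, rng=rng, gain=gain)
    return sample, background


def cross_correlation_map(
    mir: FieldTrace,
    cp: FieldTrace,
    delays_fs: np.ndarray,
    config: OpticalConfig | None = None,
    n_freq: int = 256,
):
    """Spectrally resolved cross-correlation between MIR and chirped pulse.

    Scans the delay of the MIR pulse and records the SFG spectrum at each
    step, the measurement from which the instantaneous frequency of the
    chirped pulse is calibrated.  The frequency axis spans the full SFG
    support (this diagnostic bypasses the short-pass detection filter,
    so the spectrum is never clipped).  Returns (frequency axis 1/fs,
    delays, intensity map of shape (n_freq, n_delays)).
    """
    if config is None:
        config = OpticalConfig()
    f = freq_grid(mir.n, mir.dt_fs)
    mir_spec = to_spectrum(mir.field)
    f0 = C_NM_FS / config.cp_center_wavelength_nm
    margin = 0.1 * C_CM_FS * (config.mir_band_hi_cm - config.mir_band_lo_cm)
    f_lo = f0 + C_CM_FS * config.mir_band_lo_cm - margin
    f_hi = f0 + C_CM_FS * config.mir_band_hi_cm + margin
    f_axis = np.linspace(f_lo, f_hi, n_freq)
    out = np.empty((n_freq, len(delays_fs)))
    for j, tau in enumerate(delays_fs):
        shifted = from_spectrum(mir_spec * np.exp(-2j * np.pi * f * tau))
        spec = np.abs(to_spectrum(shifted * cp.field)) ** 2
        out[:, j] = np.interp(f_axis, f, spec)
    return f_axis, np.asarray(delays_fs, dtype=float), out


# ---------------------------------------------------------------------------
# hyperspectral cubes
# ---------------------------------------------------------------------------

def _unique_pixel_kinds(phantom: PhantomMap):
    """Group pixels sharing one (mixture, gray_od) so each spectrum is computed once."""
    h, w, s = phantom.scales.shape
    flat = np.column_stack(
        [phantom.scales.reshape(h * w, s), phantom.gray_od.reshape(h * w, 1)]
    )
    keys = np.round(flat, 9)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    return uniq, inverse.reshape(h, w)


def simulate_cube(
    phantom: PhantomMap,
    library: SpeciesLibrary,
    config: OpticalConfig | None = None,
    seed: int = 0,
    noise: bool = True,
    pm=None,
) -> tuple[HyperspectralCube, HyperspectralCube]:
    """Simulate a hyperspectral cube and its paired background cube.

    Per-pixel spectra are produced by apply_sample -> sfg_and_measure
    (cached per unique mixture), spatially blurred with the Gaussian
    PSF, then digitised with the configured noise model.  The background
    cube uses an empty mixture, emulating the nitrogen-purged reference
    acquisition.  Deterministic given (phantom, config, seed).
    """
    if config is None:
        config = OpticalConfig()
    rng = np.random.default_rng(seed)
    mir = generate_mir_pulse(config)
    cp, _ = generate_chirped_pulse(config)

    bg_spec, gain = sfg_and_measure(mir, cp, pm, config, rng=None, gain=None, quantize=False)

    uniq, kind_map = _unique_pixel_kinds(phantom)
    spectra = np.empty((len(uniq), config.n_bands))
    for i, row in enumerate(uniq):
        mixture = {
            name: float(v) for name, v in zip(phantom.species, row[:-1]) if v > 0
        }
        gray = float(row[-1])
        if not mixture and gray == 0.0:
            spectra[i] = bg_spec.counts
            continue
        smp = apply_sample(mir, mixture, library, gray_od=gray)
        ms, _ = sfg_and_measure(mir=smp, cp=cp, pm=pm, config=config, rng=None,
                                gain=gain, quantize=False)
        spectra[i] = ms.counts

    h, w = kind_map.shape
    data = spectra[kind_map.reshape(-1)].reshape(h, w, config.n_bands)

    sigma_px = config.psf_sigma_um / phantom.pixel_pitch_um
    if sigma_px > 0:
        data = gaussian_filter(data, sigma=(sigma_px, sigma_px, 0.0), mode="nearest")

    fs = config.full_scale

    def digitise(arr, use_noise):
        if use_noise:
            factors = frame_factors(rng, arr.shape[-1], config.frame_noise_rms)
            arr = arr * factors[None, None, :]
            sigma = np.sqrt(np.maximum(arr, 0.0) * fs) / config.max_snr
            arr = arr + rng.normal(0.0, 1.0, arr.shape) * sigma
        return np.clip(np.rint(arr), 0, fs).astype(np.uint16)

    lam = config.wavelength_axis()
    meta = {"seed": seed, "config_digest": config.digest(), "gain": gain,
            "pixel_pitch_um": phantom.pixel_pitch_um}
    cube = HyperspectralCube(digitise(data, noise), lam, config=config.to_dict(),
                             seed=seed, meta=dict(meta, role="sample"))
    bg_data = np.broadcast_to(bg_spec.counts, (h, w, config.n_bands)).copy()
    background = HyperspectralCube(digitise(bg_data, noise), lam, config=config.to_dict(),
                                   seed=seed, meta=dict(meta, role="background"))
    return cube, background
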