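"""From measured SFG spectra to calibrated MIR transmittance.

The chain implemented here mirrors the instrument's data reduction:

* photon-energy conservation maps the visible detection axis onto the
  MIR axis (1/lambda_MIR = 1/lambda_SFG - 1/lambda_CP),
* the sample spectrum is ratioed against a nitrogen-purged background,
* the cross-phase-modulation artifact of chirped-pulse upconversion --
  an oscillation emitted by the free-induction decay, displaced along
  the axis by the chirp -- is removed by correcting the parabolic phase
  of the Fourier transform of the spectrum (the field autocorrelation),
* the wavenumber axis is calibrated against the CO2 absorption band.

The parabolic-phase correction operates on the Hermitian interferogram,
multiplying by exp(-i sign(tau) a tau^2 / 2); the fluctuation part of
the spectrum is normalised by sqrt(background) on both sides of the
transform because the FID sideband carries one factor of the source
amplitude at the line and one at the artifact frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import C_CM_FS


class AxisError(ValueError):
    """Non-physical or mismatched spectral axes."""


class CalibrationError(ValueError):
    """Chirp or wavenumber calibration could not be established."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MeasuredSpectrum:
    """Counts versus wavelength within the detection window."""

    wavelength_nm: np.ndarray
    counts: np.ndarray
    role: str = "sample"

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.wavelength_nm.shape != self.counts.shape:
            raise AxisError("axis and counts must have the same length")
        d = np.diff(self.wavelength_nm)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise AxisError("wavelength axis must be monotone")

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavelength_nm, self.counts]),
                   delimiter=",", header="wavelength_nm,counts", comments="")

    @classmethod
    def from_csv(cls, path, role="sample") -> "MeasuredSpectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1], role=role)


@dataclass
class ChirpCalibration:
    """Linear-chirp calibration of the upconversion pulse.

    chirp_rate_rad_fs2 is d(instantaneous angular frequency)/d(delay);
    its sign encodes the chirp direction and is used as-is by the
    parabolic-phase correction.
    """

    chirp_rate_rad_fs2: float
    reference_wavelength_nm: float = 790.0
    residual: float = 0.0
    monotone: bool = True

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump({
                "chirp_rate_rad_fs2": self.chirp_rate_rad_fs2,
                "reference_wavelength_nm": self.reference_wavelength_nm,
                "residual": self.residual,
                "monotone": self.monotone,
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ChirpCalibration":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TransmittanceSpectrum:
    """Transmittance on an ascending MIR wavenumber axis."""

    wavenumber_cm: np.ndarray
    values: np.ndarray
    resolution_cm: np.ndarray = None
    mask: np.ndarray = None          # True where the band is trustworthy

    def __post_init__(self) -> None:
        self.wavenumber_cm = np.asarray(self.wavenumber_cm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)
        if self.resolution_cm is None:
            self.resolution_cm = np.full_like(self.values, np.nan)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavenumber_cm, self.values]),
                   delimiter=",", header="wavenumber_cm-1,transmittance", comments="")


# ---------------------------------------------------------------------------
# axis bookkeeping
# ---------------------------------------------------------------------------

def sfg_to_mir_axis(sfg_wavelength_nm, cp_wavelength_nm: float = 790.0):
    """Map detection wavelengths to the MIR axis by photon-energy conservation.

    Returns (mir_wavelength_nm, mir_wavenumber_cm).
    """
    sfg = np.asarray(sfg_wavelength_nm, dtype=float)
    if np.any(sfg >= cp_wavelength_nm):
        raise AxisError("SFG wavelength must be shorter than the chirped-pulse wavelength")
    inv = 1.0 / sfg - 1.0 / cp_wavelength_nm
    mir_nm = 1.0 / inv
    return mir_nm, 1.0e7 / mir_nm


def wavenumber_resolution(wavelength_nm, sampling_nm: float):
    """Wavenumber increment (cm^-1) of one wavelength step: 1e7 dl / l^2."""
    lam = np.asarray(wavelength_nm, dtype=float)
    return 1.0e7 * sampling_nm / lam**2


# ---------------------------------------------------------------------------
# chirp calibration from the cross-correlation map
# ---------------------------------------------------------------------------

def instantaneous_frequency(freq_axis_fs, delays_fs, intensity_map,
                            weight_floor: float = 0.2) -> ChirpCalibration:
    """Fit the chirp rate from a spectrally resolved cross-correlation.

    At each delay step the whole upconverted spectrum is displaced by
    the instantaneous frequency of the chirped pulse, so the
    intensity-weighted spectral centroid traces the chirp directly: a
    weighted linear fit of centroid angular frequency versus delay
    yields the chirp rate as its slope.  The map must cover the full
    SFG spectral support (the calibration scan bypasses the short-pass
    detection filter); a clipped spectrum would bias the centroid.
    Delays whose total intensity falls below `weight_floor` of the
    maximum are excluded (there the pulses no longer overlap and the
    centroid is noise).
    """
    f = np.asarray(freq_axis_fs, dtype=float)
    tau = np.asarray(delays_fs, dtype=float)
    m = np.asarray(intensity_map, dtype=float)
    if m.shape != (f.size, tau.size):
        raise AxisError("map shape must be (n_freq, n_delays)")
    col_sum = m.sum(axis=0)
    good = col_sum > weight_floor * col_sum.max()
    if good.sum() < 3:
        raise CalibrationError("cross-correlation map has too little signal")
    centroid = 2.0 * np.pi * (f @ m[:, good]) / col_sum[good]
    w = col_sum[good]
    t = tau[good]
    W = w / w.sum()
    tc = t - np.sum(W * t)
    cc = centroid - np.sum(W * centroid)
    slope = np.sum(W * tc * cc) / np.sum(W * tc**2)
    # degenerate when the fitted sweep is tiny compared to the spectral spread
    spread = 2.0 * np.pi * (f.max() - f.min())
    if abs(slope) * (t.max() - t.min()) < 1e-3 * spread:
        raise CalibrationError("degenerate fit: pulse appears unchirped")
    resid = np.sqrt(np.sum(W * (cc - slope * tc) ** 2))
    monotone = bool(np.all(np.diff(centroid) >= 0) or np.all(np.diff(centroid) <= 0))
    return ChirpCalibration(chirp_rate_rad_fs2=float(slope),
                            residual=float(resid), monotone=monotone)


# ---------------------------------------------------------------------------
# the cross-phase-modulation (parabolic phase) correction
# ---------------------------------------------------------------------------

def xpm_correct(wavenumber_cm, ratio, calibration: ChirpCalibration,
                background=None, pad: int = 512):
    """Remove the chirp-induced oscillation from a ratioed spectrum.

    `ratio` (sample/background) and optionally the background counts
    must be sampled on a uniform ascending wavenumber grid.  The
    fluctuation part of the spectrum is transformed to the delay domain,
    the parabolic phase a tau^2/2 is removed on the Hermitian
    interferogram, and the result transformed back.  When `background`
    is given, the fluctuation is weighted by sqrt(background) on both
    sides of the transform (see module docstring); otherwise a smooth
    baseline of the ratio itself is used.  With a = 0 the operation is
    the identity.
    """
    if calibration is None:
        raise CalibrationError("xpm_correct requires a chirp calibration")
    nu = np.asarray(wavenumber_cm, dtype=float)
    R = np.asarray(ratio, dtype=float)
    ratio_1d = R.ndim == 1
    R = np.atleast_2d(R)
    d = np.diff(nu)
    if not np.allclose(d, d[0], rtol=1e-6):
        raise AxisError("xpm_correct needs a uniform wavenumber grid (resample first)")
    a = calibration.chirp_rate_rad_fs2

    if background is not None:
        sq = np.sqrt(np.maximum(np.asarray(background, dtype=float), 1e-30))
        sq = np.atleast_2d(sq)
        base = np.ones_like(R)
        Z = (R - base) * sq
        weight = sq
    else:
        from scipy.ndimage import gaussian_filter1d

        base = gaussian_filter1d(R, max(3.0, R.shape[-1] / 16.0), axis=-1)
        Z = R - base
        weight = np.ones_like(R)

    n = R.shape[-1]
    Zp = np.zeros(R.shape[:-1] + (n + 2 * pad,))
    Zp[..., pad:pad + n] = Z
    dw = 2.0 * np.pi * C_CM_FS * d[0]          # rad/fs per grid step
    tau = 2.0 * np.pi * np.fft.fftfreq(n + 2 * pad, dw)
    phase = np.exp(-1j * np.sign(tau) * 0.5 * a * tau**2)
    Zc = np.fft.fft(np.fft.ifft(Zp, axis=-1) * phase, axis=-1)[..., pad:pad + n]
    out = base + Zc.real / weight
    return out[0] if ratio_1d else out


# ---------------------------------------------------------------------------
# transmittance computation
# ---------------------------------------------------------------------------

def _resample_plan(wavelength_nm, cp_wavelength_nm, n_grid):
    """Uniform MIR wavenumber grid + linear-interp indices/weights from band axis."""
    _, nu = sfg_to_mir_axis(wavelength_nm, cp_wavelength_nm)
    order = np.argsort(nu)
    nu_sorted = nu[order]
    nu_grid = np.linspace(nu_sorted[0], nu_sorted[-1], n_grid)
    idx = np.clip(np.searchsorted(nu_sorted, nu_grid) - 1, 0, nu_sorted.size - 2)
    frac = (nu_grid - nu_sorted[idx]) / (nu_sorted[idx + 1] - nu_sorted[idx])
    frac = np.clip(frac, 0.0, 1.0)
    return nu_grid, order, idx, frac


def _apply_plan(values, order, idx, frac):
    v = np.asarray(values, dtype=float)[..., order]
    return v[..., idx] * (1.0 - frac) + v[..., idx + 1] * frac


def compute_transmittance(
    sample: MeasuredSpectrum,
    background: MeasuredSpectrum,
    calibration: ChirpCalibration,
    cp_wavelength_nm: float | None = None,
    n_grid: int = 2048,
    masking_floor: float = 0.01,
    full_scale: float = 4095.0,
    sampling_nm: float = 0.15,
    pad: int = 512,
) -> TransmittanceSpectrum:
    """Background-ratioed, chirp-corrected MIR transmittance.

    Bands whose background counts fall below `masking_floor * full_scale`
    are masked (ratio forced to 1 there so they cannot ring into valid
    bands through the transform).
    """
    if sample.wavelength_nm.shape != background.wavelength_nm.shape or not np.allclose(
        sample.wavelength_nm, background.wavelength_nm
    ):
        raise AxisError("sample and background must share one wavelength axis")
    if cp_wavelength_nm is None:
        cp_wavelength_nm = calibration.reference_wavelength_nm

    bg = np.asarray(background.counts, dtype=float)
    smp = np.asarray(sample.counts, dtype=float)
    valid = bg > masking_floor * full_scale
    ratio = np.ones_like(bg)
    np.divide(smp, bg, out=ratio, where=valid)

    nu_grid, order, idx, frac = _resample_plan(sample.wavelength_nm, cp_wavelength_nm, n_grid)
    R_u = _apply_plan(ratio, order, idx, frac)
    bg_u = _apply_plan(np.where(valid, bg, 0.0), order, idx, frac)
    valid_u = _apply_plan(valid.astype(float), order, idx, frac) > 0.999

    corrected = xpm_correct(nu_grid, R_u, calibration, background=bg_u, pad=pad)
    lam_u = 1.0e7 / (nu_grid + 1.0e7 / cp_wavelength_nm)
    res = wavenumber_resolution(lam_u, sampling_nm)
    return TransmittanceSpectrum(nu_grid, np.maximum(corrected, 0.0),
                                 resolution_cm=res, mask=valid_u)


def line_center(spectrum: TransmittanceSpectrum, guess_cm: float,
                halfwidth_cm: float = 40.0) -> float:
    """Absorption-line centre: parabolic refinement of the transmittance minimum."""
    nu = spectrum.wavenumber_cm
    sel = np.abs(nu - guess_cm) < halfwidth_cm
    if not np.any(sel):
        raise ValueError("guess outside the spectrum")
    v = spectrum.values[sel]
    x = nu[sel]
    i = int(np.clip(np.argmin(v), 1, v.size - 2))
    denom = v[i - 1] - 2 * v[i] + v[i + 1]
    frac = 0.5 * (v[i - 1] - v[i + 1]) / denom if denom != 0 else 0.0
    return float(x[i] + frac * (x[1] - x[0]))


# ---------------------------------------------------------------------------
# wavenumber calibration against CO2
# ---------------------------------------------------------------------------

def calibrate_wavenumber(
    spectrum: TransmittanceSpectrum,
    reference_center_cm: float = 2349.0,
    window_cm: tuple[float, float] = (2300.0, 2400.0),
    min_depth: float = 0.02,
):
    """Rigid axis shift aligning the CO2 absorption centroid to its reference.

    Returns (shifted spectrum, offset_cm) where offset is added to the
    axis.  Raises :class:`CalibrationError` when no dip deeper than
    `min_depth` exists in the window (the spectrum is left unshifted).
    """
    nu = spectrum.wavenumber_cm
    sel = (nu >= window_cm[0]) & (nu <= window_cm[1]) & spectrum.mask
    if not np.any(sel):
        raise CalibrationError("calibration window not covered by the spectrum")
    depth = np.maximum(1.0 - spectrum.values[sel], 0.0)
    if depth.max() < min_depth:
        raise CalibrationError(
            f"no absorption dip deeper than {min_depth} in {window_cm} cm^-1"
        )
    centroid = float(np.sum(nu[sel] * depth) / np.sum(depth))
    offset = reference_center_cm - centroid
    shifted = TransmittanceSpectrum(nu + offset, spectrum.values.copy(),
                                    spectrum.resolution_cm.copy(), spectrum.mask.copy())
    return shifted, offset


# ---------------------------------------------------------------------------
# whole-cube retrieval
# ---------------------------------------------------------------------------

@dataclass
class TransmittanceCube:
    """Per-pixel transmittance spectra on a common MIR wavenumber grid."""

    data: np.ndarray                 # (rows, cols, n_grid)
    wavenumber_cm: np.ndarray        # ascending
    mask: np.ndarray = None          # (n_grid,) trustworthy bands
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.data.shape[-1], dtype=bool)

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    def band_near(self, wavenumber_cm: float) -> int:
        return int(np.argmin(np.abs(self.wavenumber_cm - wavenumber_cm)))


def retrieve_cube(cube, background, calibration: ChirpCalibration,
                  n_grid: int = 1024, masking_floor: float = 0.01,
                  pad: int = 256) -> TransmittanceCube:
    """Vectorised per-pixel transmittance retrieval over a cube pair."""
    lam = cube.wavelength_nm
    if not np.allclose(lam, background.wavelength_nm):
        raise AxisError("cube and background share no common wavelength axis")
    cp_nm = cube.cp_wavelength_nm
    full_scale = float(2 ** int(cube.config.get("bit_depth", 12)) - 1)

    smp = cube.data.astype(float)
    bg = background.data.astype(float)
    valid = bg > masking_floor * full_scale
    ratio = np.ones_like(smp)
    np.divide(smp, bg, out=ratio, where=valid)

    nu_grid, order, idx, frac = _resample_plan(lam, cp_nm, n_grid)
    R_u = _apply_plan(ratio.reshape(-1, lam.size), order, idx, frac)
    bg_u = _apply_plan(np.where(valid, bg, 0.0).reshape(-1, lam.size), order, idx, frac)
    corrected = xpm_correct(nu_grid, R_u, calibration, background=bg_u, pad=pad)
    corrected = np.maximum(corrected, 0.0).reshape(cube.rows, cube.cols, n_grid)
    band_mask = _apply_plan(valid.all(axis=(0, 1)).astype(float), order, idx, frac) > 0.999
    return TransmittanceCube(corrected, nu_grid, band_mask,
                             meta={"cp_wavelength_nm": cp_nm, "seed": cube.seed})
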