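"""Unit conventions used throughout the package.

Time is measured in femtoseconds, optical frequency in cycles/fs (PHz),
wavelength in nanometres and wavenumber in cm^-1.  All conversions go
through the two speed-of-light constants below.
"""

#: speed of light in nm/fs (= 1e-6 * c in m/s)
C_NM_FS = 299.792458

#: speed of light in cm/fs, so  f[1/fs] = C_CM_FS * wavenumber[cm^-1]
C_CM_FS = 2.99792458e-5


def wavenumber_to_freq(nu_cm: float) -> float:
    """Wavenumber (cm^-1) to optical frequency (1/fs)."""
    return C_CM_FS * nu_cm


def freq_to_wavenumber(f_fs: float) -> float:
    """Optical frequency (1/fs) to wavenumber (cm^-1)."""
    return f_fs / C_CM_FS


def wavelength_to_freq(lam_nm: float) -> float:
    """Wavelength (nm) to optical frequency (1/fs)."""
    return C_NM_FS / lam_nm


def wavelength_to_wavenumber(lam_nm: float) -> float:
    """Wavelength (nm) to wavenumber (cm^-1);  1e7/lambda."""
    return 1.0e7 / lam_nm
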