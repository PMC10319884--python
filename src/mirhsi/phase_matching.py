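"""Type-I (o + o -> e) sum-frequency phase matching in thin GaSe films.

The conversion efficiency of collinear SFG in a crystal of thickness L
is proportional to L^2 sinc^2(dk L / 2).  A thick crystal therefore
shows spectral fringes with exact zeros, while a film a few micrometres
thick phase-matches the entire 640-3015 cm^-1 band with strictly
positive efficiency.

Refractive indices come from an embedded Sellmeier parameterisation of
GaSe (see docs/methods.md for provenance); the model also accepts
user-supplied coefficient sets, which the tests use to build degenerate
(dispersionless) crystals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class WavelengthRangeError(ValueError):
    """Wavelength outside the validity range of the Sellmeier fit."""


#: GaSe Sellmeier coefficients (lambda in um), n^2 = c0 + c1/l^2 + c2/l^4 + c3/l^6
#: + c4 l^2/(l^2 - c5); standard published set for the 0.65-18 um window.
GASE_SELLMEIER = {
    "o": (7.443, 0.4050, 0.0186, 0.0061, 3.1485, 2194.0),
    "e": (5.76, 0.3879, -0.2288, 0.1223, 1.8550, 1780.0),
    "range_um": (0.62, 18.0),
}


def _sellmeier_n(lam_um: np.ndarray, coeffs) -> np.ndarray:
    c0, c1, c2, c3, c4, c5 = coeffs
    l2 = lam_um**2
    n2 = c0 + c1 / l2 + c2 / l2**2 + c3 / l2**3 + c4 * l2 / (l2 - c5)
    return np.sqrt(n2)


@dataclass(frozen=True)
class CrystalModel:
    """A uniaxial nonlinear crystal cut for collinear type-I SFG.

    theta_deg is the propagation angle from the optic axis.  The default
    angle near-maximises the mid-band efficiency of the thin-film
    configuration used for full-band upconversion.
    """

    name: str = "GaSe"
    thickness_um: float = 4.4
    theta_deg: float = 26.5
    sellmeier: dict = field(default_factory=lambda: dict(GASE_SELLMEIER))

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError("crystal thickness must be positive")

    def _check_range(self, lam_nm) -> None:
        lo, hi = self.sellmeier["range_um"]
        lam_um = np.asarray(lam_nm) * 1e-3
        if np.any(lam_um < lo) or np.any(lam_um > hi):
            raise WavelengthRangeError(
                f"wavelength outside Sellmeier validity range {lo}-{hi} um"
            )


def refractive_index(crystal: CrystalModel, wavelength_nm, polarization: str):
    """Refractive index at `wavelength_nm`.

    polarization "o" gives the ordinary index; "e" gives the
    extraordinary wave index n_e(theta) from the standard index ellipse
        1/n_e(theta)^2 = cos^2(theta)/n_o^2 + sin^2(theta)/n_e^2 .
    """
    crystal._check_range(wavelength_nm)
    lam_um = np.asarray(wavelength_nm, dtype=float) * 1e-3
    n_o = _sellmeier_n(lam_um, crystal.sellmeier["o"])
    if polarization == "o":
        return n_o
    if polarization == "e":
        n_e = _sellmeier_n(lam_um, crystal.sellmeier["e"])
        th = np.radians(crystal.theta_deg)
        return 1.0 / np.sqrt(np.cos(th) ** 2 / n_o**2 + np.sin(th) ** 2 / n_e**2)
    raise ValueError(f"polarization must be 'o' or 'e', got {polarization!r}")


def sfg_wavelength_nm(mir_wavenumber_cm, cp_wavelength_nm: float):
    """Collinear SFG wavelength from energy conservation."""
    return 1.0 / (1.0 / cp_wavelength_nm + np.asarray(mir_wavenumber_cm) * 1e-7)


def delta_k(crystal: CrystalModel, mir_wavenumber_cm, cp_wavelength_nm: float = 790.0):
    """Collinear phase mismatch dk = k_e(SFG) - k_o(CP) - k_o(MIR), in rad/um."""
    mir_wavenumber_cm = np.asarray(mir_wavenumber_cm, dtype=float)
    lam_mir_nm = 1.0e7 / mir_wavenumber_cm
    lam_sfg_nm = sfg_wavelength_nm(mir_wavenumber_cm, cp_wavelength_nm)

    def k(n, lam_nm):  # rad/um
        return 2.0 * np.pi * n / (lam_nm * 1e-3)

    n_sfg = refractive_index(crystal, lam_sfg_nm, "e")
    n_cp = refractive_index(crystal, cp_wavelength_nm, "o")
    n_mir = refractive_index(crystal, lam_mir_nm, "o")
    return k(n_sfg, lam_sfg_nm) - k(n_cp, cp_wavelength_nm) - k(n_mir, lam_mir_nm)


def conversion_efficiency(
    crystal: CrystalModel,
    mir_wavenumber_cm,
    cp_wavelength_nm: float = 790.0,
    normalize: bool = True,
):
    """Relative SFG efficiency  eta ~ L^2 sinc^2(dk L / 2).

    With `normalize` the curve is scaled to its maximum over the given
    wavenumbers; pass normalize=False to compare different thicknesses.
    """
    dk = delta_k(crystal, mir_wavenumber_cm, cp_wavelength_nm)
    arg = dk * crystal.thickness_um / 2.0
    eta = crystal.thickness_um**2 * np.sinc(arg / np.pi) ** 2
    if normalize and np.ndim(eta) > 0 and eta.size > 1:
        eta = eta / eta.max()
    return eta


def band_coverage(
    crystal: CrystalModel,
    band_lo_cm: float,
    band_hi_cm: float,
    threshold: float = 0.0,
    cp_wavelength_nm: float = 790.0,
    grid_step_cm: float = 1.0,
):
    """Scan the band on a <= 1 cm^-1 grid and report the efficiency minimum.

    Returns (min_efficiency, covered, wavenumber_at_min); `covered` is
    True when the normalized efficiency stays strictly above `threshold`
    everywhere in the band.
    """
    if band_lo_cm > band_hi_cm:
        raise ValueError("band must satisfy lo <= hi")
    if band_lo_cm == band_hi_cm:
        nu = np.array([band_lo_cm])
    else:
        n = max(2, int(np.ceil((band_hi_cm - band_lo_cm) / grid_step_cm)) + 1)
        nu = np.linspace(band_lo_cm, band_hi_cm, n)
    eta = np.atleast_1d(conversion_efficiency(crystal, nu, cp_wavelength_nm, normalize=False))
    eta = eta / eta.max()
    i = int(np.argmin(eta))
    return float(eta[i]), bool(eta[i] > threshold), float(np.atleast_1d(nu)[i])


def efficiency_curve_csv(crystal: CrystalModel, band_lo_cm, band_hi_cm, path,
                         cp_wavelength_nm: float = 790.0, grid_step_cm: float = 1.0):
    """Write (wavenumber_cm-1, efficiency) to a two-column CSV file."""
    n = max(2, int(np.ceil((band_hi_cm - band_lo_cm) / grid_step_cm)) + 1)
    nu = np.linspace(band_lo_cm, band_hi_cm, n)
    eta = conversion_efficiency(crystal, nu, cp_wavelength_nm)
    data = np.column_stack([nu, eta])
    np.savetxt(path, data, delimiter=",", header="wavenumber_cm-1,efficiency", comments="")
    return nu, eta
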