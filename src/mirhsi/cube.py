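"""The hyperspectral data cube container.

A cube is a rows x cols x bands array with a wavelength axis (nm, the
detection axis of the camera) from which the MIR wavenumber axis is
derived through photon-energy conservation with the chirped pulse.
Raw cubes hold integer counts; retrieved cubes hold float transmittance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class HyperspectralCube:
    data: np.ndarray                 # (rows, cols, bands)
    wavelength_nm: np.ndarray        # (bands,), strictly monotone
    config: dict = field(default_factory=dict)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be rows x cols x bands")
        if self.data.shape[2] != self.wavelength_nm.size:
            raise ValueError("wavelength axis length must equal the number of bands")
        d = np.diff(self.wavelength_nm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotone")

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def cp_wavelength_nm(self) -> float:
        return float(self.config.get("cp_center_wavelength_nm", 790.0))

    def mir_wavenumber_cm(self) -> np.ndarray:
        """Per-band MIR wavenumber, 1e7/lambda_SFG - 1e7/lambda_CP (cm^-1)."""
        return 1.0e7 / self.wavelength_nm - 1.0e7 / self.cp_wavelength_nm

    def band_near(self, wavenumber_cm: float) -> int:
        """Index of the band whose MIR wavenumber is closest to the target."""
        return int(np.argmin(np.abs(self.mir_wavenumber_cm() - wavenumber_cm)))

    def pixel_spectrum(self, row: int, col: int) -> np.ndarray:
        return np.asarray(self.data[row, col], dtype=float)

    def save(self, path) -> None:
        from .envi import write_envi_cube

        write_envi_cube(self, path)

    @classmethod
    def load(cls, path) -> "HyperspectralCube":
        from .envi import read_envi_cube

        return read_envi_cube(path)
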