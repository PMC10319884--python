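"""Complex optical fields on a uniform time grid.

Fields are stored as analytic signals (positive-frequency content only)
with their true optical carriers, so a product of two fields directly
yields the sum-frequency component.  The FFT conventions place t = 0 at
the centre of the grid and return frequency axes in ascending order.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np


def time_grid(n_time: int, dt_fs: float) -> np.ndarray:
    """Uniform time axis in fs, centred on zero."""
    return (np.arange(n_time) - n_time // 2) * dt_fs


def to_spectrum(field: np.ndarray) -> np.ndarray:
    """Field sampled on a centred time grid -> spectrum on an ascending frequency grid."""
    return np.fft.fftshift(np.fft.fft(np.fft.ifftshift(field)))


def from_spectrum(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_spectrum`."""
    return np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(spectrum)))


def freq_grid(n_time: int, dt_fs: float) -> np.ndarray:
    """Frequency axis (1/fs) matching :func:`to_spectrum`, ascending."""
    return np.fft.fftshift(np.fft.fftfreq(n_time, dt_fs))


def fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a sampled non-negative curve.

    Edge positions are linearly interpolated between samples, so the
    result is accurate to well below one grid step for smooth envelopes.
    """
    y = np.asarray(y, dtype=float)
    ymax = y.max()
    if ymax <= 0:
        raise ValueError("curve has no positive values")
    y = y / ymax
    above = np.where(y >= 0.5)[0]
    if len(above) == 0:
        raise ValueError("curve never reaches half maximum")
    i0, i1 = above[0], above[-1]

    def cross(i_out, i_in):
        if i_out < 0 or i_out >= len(x):
            return x[i_in]
        return x[i_out] + (0.5 - y[i_out]) * (x[i_in] - x[i_out]) / (y[i_in] - y[i_out])

    return cross(i1 + 1, i1) - cross(i0 - 1, i0)


@dataclass
class FieldTrace:
    """A complex optical field on a uniform time grid.

    Attributes
    ----------
    t_fs : time axis (fs), uniform, centred on zero.
    field : complex analytic amplitude per sample.
    kind : which pulse this is ("mir", "cp", "sfg", "sample").
    """

    t_fs: np.ndarray
    field: np.ndarray
    kind: str = "mir"
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_fs = np.asarray(self.t_fs, dtype=float)
        self.field = np.asarray(self.field, dtype=complex)
        if self.t_fs.shape != self.field.shape:
            raise ValueError("time grid and field must have the same shape")
        dt = np.diff(self.t_fs)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
            raise ValueError("time grid must be uniform")

    @property
    def dt_fs(self) -> float:
        return float(self.t_fs[1] - self.t_fs[0])

    @property
    def n(self) -> int:
        return self.field.size

    def intensity(self) -> np.ndarray:
        return np.abs(self.field) ** 2

    def envelope_fwhm_fs(self) -> float:
        return fwhm(self.t_fs, self.intensity())

    def spectrum(self) -> tuple[np.ndarray, np.ndarray]:
        """(frequency axis 1/fs, complex spectral amplitude)."""
        return freq_grid(self.n, self.dt_fs), to_spectrum(self.field)

    def spectral_intensity(self) -> tuple[np.ndarray, np.ndarray]:
        f, s = self.spectrum()
        return f, np.abs(s) ** 2

    def energy_time(self) -> float:
        return float(np.sum(self.intensity()) * self.dt_fs)

    def energy_freq(self) -> float:
        _, s = self.spectrum()
        return float(np.sum(np.abs(s) ** 2) / self.n * self.dt_fs)

    def with_field(self, field: np.ndarray, kind: str | None = None) -> "FieldTrace":
        return FieldTrace(self.t_fs, field, kind or self.kind, dict(self.meta))
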