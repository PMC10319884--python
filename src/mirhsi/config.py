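"""Instrument and pipeline configuration objects.

`OpticalConfig` collects every physical parameter of the simulated
instrument: the broadband mid-infrared (MIR) source, the stretched
chirped pulse used for sum-frequency upconversion, the visible detection
window of the hyperspectral camera, and the digitisation/noise model.
Defaults describe the instrument at desk scale (a 256-band cube); the
full-scale 1069-band configuration is available through
:meth:`OpticalConfig.full_scale_instrument`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a configuration is physically or numerically invalid."""


@dataclass(frozen=True)
class OpticalConfig:
    # MIR source
    mir_band_lo_cm: float = 333.0          # 30 um
    mir_band_hi_cm: float = 3333.0         # 3 um
    mir_pulse_fwhm_fs: float = 13.6        # intensity-envelope FWHM
    mir_spectral_order: int = 3            # super-Gaussian order of the source spectrum

    # chirped upconversion pulse
    cp_center_wavelength_nm: float = 790.0
    cp_duration_ps: float = 1.8            # stretched intensity-envelope FWHM
    cp_transform_limit_fs: float = 70.0    # TL duration of the long-pass-filtered bandwidth

    # detection
    detection_lo_nm: float = 638.0
    detection_hi_nm: float = 752.0
    spectral_sampling_nm: float = 0.15
    n_bands: int = 256                     # desk scale; full instrument uses 1069
    bit_depth: int = 12
    frame_noise_rms: float = 0.0277        # multiplicative frame-to-frame RMS
    max_snr: float = 1365.0                # shot-noise-limited SNR at full scale
    repetition_rate_hz: float = 5000.0

    # imaging
    psf_sigma_um: float = 5.852            # Gaussian PSF; 10-90% edge response ~15 um

    # numerical time grid (power-of-two length)
    n_time: int = 32768
    dt_fs: float = 1.0

    def __post_init__(self) -> None:
        if not self.detection_lo_nm < self.detection_hi_nm:
            raise ConfigError("detection window must satisfy lo < hi")
        if self.spectral_sampling_nm <= 0:
            raise ConfigError("spectral_sampling_nm must be positive")
        if not 0 < self.mir_band_lo_cm < self.mir_band_hi_cm:
            raise ConfigError("MIR band must satisfy 0 < lo < hi")
        if self.n_bands < 2:
            raise ConfigError("n_bands must be at least 2")
        if self.bit_depth < 1 or self.bit_depth > 16:
            raise ConfigError("bit_depth must be in 1..16")
        if self.n_time & (self.n_time - 1):
            raise ConfigError("n_time must be a power of two")
        if self.dt_fs <= 0:
            raise ConfigError("dt_fs must be positive")
        if self.cp_duration_ps * 1e3 < self.cp_transform_limit_fs:
            raise ConfigError("chirped-pulse duration below its transform limit")
        # the complex field grid must hold carriers up to the SFG band edge
        from .constants import C_CM_FS, C_NM_FS
        f_max = C_NM_FS / self.cp_center_wavelength_nm + C_CM_FS * self.mir_band_hi_cm
        if 1.0 / self.dt_fs < 2.0 * f_max:
            raise ConfigError(
                "time step too coarse: cannot represent the sum-frequency carrier "
                f"({f_max:.3f}/fs needs dt < {0.5 / f_max:.3f} fs)"
            )
        if self.mir_pulse_fwhm_fs < 4 * self.dt_fs:
            raise ConfigError("time grid too coarse to resolve the MIR pulse envelope")
        if self.n_time * self.dt_fs < 4 * self.cp_duration_ps * 1e3:
            raise ConfigError("time grid span must be at least 4x the chirped-pulse duration")

    # -- derived quantities -------------------------------------------------
    @property
    def full_scale(self) -> int:
        """Maximum digital count, 2^bit_depth - 1."""
        return (1 << self.bit_depth) - 1

    @property
    def frame_period_ms(self) -> float:
        """Frame spacing of discrete-frequency imaging, 1/repetition_rate."""
        return 1.0e3 / self.repetition_rate_hz

    @property
    def cp_duration_fs(self) -> float:
        return self.cp_duration_ps * 1.0e3

    def wavelength_axis(self) -> "np.ndarray":
        import numpy as np

        return np.linspace(self.detection_lo_nm, self.detection_hi_nm, self.n_bands)

    @classmethod
    def full_scale_instrument(cls, **overrides) -> "OpticalConfig":
        """The 640x480x1069 configuration reported for the real instrument."""
        return cls(n_bands=1069, **overrides)

    def replace(self, **changes) -> "OpticalConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, recorded in output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "OpticalConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown optical config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Configuration of a full simulate -> retrieve -> analyze pipeline run.

    Serialized as YAML with five blocks; unknown keys are rejected so a
    typo cannot silently fall back to a default.
    """

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    phantom: dict = field(default_factory=lambda: {"kind": "microchannel5"})
    retrieval: dict = field(default_factory=lambda: {"masking_floor": 0.01})
    analysis: dict = field(default_factory=lambda: {"method": "sam"})
    seed: int = 0
    output_dir: str = "mirhsi_out"

    _TOP_KEYS = {"optical", "phantom", "retrieval", "analysis", "seed", "output_dir"}

    def to_dict(self) -> dict:
        return {
            "optical": self.optical.to_dict(),
            "phantom": dict(self.phantom),
            "retrieval": dict(self.retrieval),
            "analysis": dict(self.analysis),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - cls._TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        kwargs = {}
        if "optical" in d:
            kwargs["optical"] = OpticalConfig.from_dict(d["optical"])
        for k in ("phantom", "retrieval", "analysis", "seed", "output_dir"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)
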