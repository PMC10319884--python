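"""Spatial phantoms: ground-truth scenes for the simulator.

A :class:`PhantomMap` stores, per pixel, the effective optical-depth
scale of each species plus a wavelength-independent ("gray") optical
depth for opaque structures such as channel walls or the bars of a
copper mesh grid.  Integer ground-truth labels accompany every phantom
so classification accuracy can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .library import MICROCHANNEL_SPECIES

MAX_ROWS, MAX_COLS = 480, 640


@dataclass
class PhantomMap:
    species: list[str]               # names indexing the last axis of `scales`
    scales: np.ndarray               # (rows, cols, n_species) optical-depth scales
    gray_od: np.ndarray              # (rows, cols) broadband optical depth
    labels: np.ndarray               # (rows, cols) int ground truth, 0 = background
    legend: dict[int, str]           # label -> class name
    pixel_pitch_um: float = 12.5
    time_ms: float | None = None     # frame timestamp for image sequences

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.gray_od = np.asarray(self.gray_od, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        rows, cols = self.gray_od.shape
        if rows > MAX_ROWS or cols > MAX_COLS:
            raise ValueError(f"phantom exceeds the {MAX_COLS} x {MAX_ROWS} sensor")
        if self.scales.shape[:2] != (rows, cols) or self.labels.shape != (rows, cols):
            raise ValueError("scales / labels shape mismatch")
        if self.scales.shape[2] != len(self.species):
            raise ValueError("species list does not match scales depth")
        if np.any(self.scales < 0) or np.any(self.gray_od < 0):
            raise ValueError("optical depths must be non-negative")

    @property
    def rows(self) -> int:
        return self.gray_od.shape[0]

    @property
    def cols(self) -> int:
        return self.gray_od.shape[1]


def _empty(rows, cols, species):
    return (
        np.zeros((rows, cols, len(species))),
        np.zeros((rows, cols)),
        np.zeros((rows, cols), dtype=np.int32),
    )


def _microchannel5(rows=48, cols=64, pixel_pitch_um=12.5, channel_width_um=100.0,
                   species=None, wall_od=0.8, fill_scale=1.0):
    """Five parallel vertical microchannels, one species each.

    Default geometry matches the microfluidic device at desk scale:
    100 um wide channels on a partially transmitting substrate.
    """
    species = list(species or MICROCHANNEL_SPECIES)
    if len(species) != 5:
        raise ValueError("microchannel5 needs exactly five species")
    scales, gray, labels = _empty(rows, cols, species)
    gray[:] = wall_od
    width_px = max(1, int(round(channel_width_um / pixel_pitch_um)))
    centers = (np.arange(1, 6) * cols / 6.0).round().astype(int)
    for i, c in enumerate(centers):
        lo = max(0, c - width_px // 2)
        hi = min(cols, lo + width_px)
        scales[:, lo:hi, i] = fill_scale
        gray[:, lo:hi] = 0.0
        labels[:, lo:hi] = i + 1
    legend = {i + 1: s for i, s in enumerate(species)}
    return PhantomMap(species, scales, gray, labels, legend, pixel_pitch_um)


def _mesh_grid(rows=96, cols=128, pixel_pitch_um=1.25, bar_width_um=30.0,
               period_um=120.0, bar_od=8.0):
    """Opaque copper mesh: dark bars of the stated width on a square grid."""
    species: list[str] = []
    scales = np.zeros((rows, cols, 0))
    gray = np.zeros((rows, cols))
    labels = np.ones((rows, cols), dtype=np.int32)
    if bar_width_um > 0:
        y = (np.arange(rows) * pixel_pitch_um) % period_um
        x = (np.arange(cols) * pixel_pitch_um) % period_um
        bar_y = y < bar_width_um
        bar_x = x < bar_width_um
        mask = bar_y[:, None] | bar_x[None, :]
        gray[mask] = bar_od
        labels[mask] = 0
    return PhantomMap(species, scales, gray, labels, {1: "open"}, pixel_pitch_um)


def _flow_sequence(n_frames=6, rows=48, cols=64, pixel_pitch_um=12.5,
                   channel_width_um=200.0, velocity_mm_s=2.5,
                   repetition_rate_hz=5000.0, meniscus_width_um=25.0,
                   meniscus_od=1.5, wall_od=0.8, start_row_um=100.0):
    """Water draining from a microchannel, one frame per laser shot.

    The water column ends at a meniscus front (a localized extra
    transmission dip from refraction) that advances along the channel at
    the given velocity; frames are spaced by 1/repetition_rate.
    """
    frames = []
    width_px = max(1, int(round(channel_width_um / pixel_pitch_um)))
    c0 = cols // 2 - width_px // 2
    dt_ms = 1.0e3 / repetition_rate_hz
    for k in range(n_frames):
        t_ms = k * dt_ms
        scales, gray, labels = _empty(rows, cols, ["water"])
        gray[:] = wall_od
        gray[:, c0:c0 + width_px] = 0.0
        front_um = start_row_um + velocity_mm_s * t_ms  # 1 mm/s = 1 um/ms
        front_px = front_um / pixel_pitch_um
        r = np.arange(rows)
        wet = r[:, None] >= front_px
        channel = np.zeros((rows, cols), bool)
        channel[:, c0:c0 + width_px] = True
        scales[wet & channel, 0] = 1.0
        labels[wet & channel] = 1
        men = (np.abs(r[:, None] - front_px) * pixel_pitch_um <= meniscus_width_um / 2)
        gray[men & channel] += meniscus_od
        frames.append(PhantomMap(["water"], scales, gray, labels, {1: "water"},
                                 pixel_pitch_um, time_ms=t_ms))
    return frames


def _blobs(rows=48, cols=64, pixel_pitch_um=12.5, n_classes=3, seed=0,
           smooth_px=5.0, species=None, fill_scale=1.0):
    """Random multi-class regions for classifier tests.

    Smoothed Gaussian random fields are compared pixelwise; each pixel
    takes the class whose field is largest, provided it clears the
    background field.
    """
    rng = np.random.default_rng(seed)
    species = list(species or MICROCHANNEL_SPECIES[:n_classes])
    if len(species) != n_classes:
        raise ValueError("species list must match n_classes")
    fields = gaussian_filter(
        rng.standard_normal((n_classes + 1, rows, cols)), sigma=(0, smooth_px, smooth_px)
    )
    fields[0] += 0.05  # slight preference for background
    winner = np.argmax(fields, axis=0)  # 0 = background
    scales, gray, labels = _empty(rows, cols, species)
    for i in range(n_classes):
        mask = winner == i + 1
        scales[mask, i] = fill_scale
        labels[mask] = i + 1
    legend = {i + 1: s for i, s in enumerate(species)}
    return PhantomMap(species, scales, gray, labels, legend, pixel_pitch_um)


_KINDS = {
    "microchannel5": _microchannel5,
    "mesh_grid": _mesh_grid,
    "flow_sequence": _flow_sequence,
    "blobs": _blobs,
}


def make_phantom(kind: str, **params):
    """Build a phantom (or frame sequence) of the given kind.

    Kinds: microchannel5, mesh_grid, flow_sequence, blobs.
    """
    try:
        builder = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {sorted(_KINDS)}") from None
    return builder(**params)
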