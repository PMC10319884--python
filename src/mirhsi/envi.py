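"""Minimal ENVI raster I/O for hyperspectral cubes.

Writes a text header (`<path>.hdr`) plus a raw binary file in BSQ
interleave; reads BSQ, BIL and BIP.  The wavelength list is stored in
nm, the derived MIR wavenumber list as a second header entry, and the
RNG seed and configuration hash travel in the header so any cube on
disk names the run that produced it.
"""

from __future__ import annotations

import json
import os
import re

import numpy as np

from .cube import HyperspectralCube


class EnviFormatError(ValueError):
    """Malformed or inconsistent ENVI header / data pair."""


_DTYPE_TO_ENVI = {"uint8": 1, "int16": 2, "int32": 3, "float32": 4,
                  "float64": 5, "uint16": 12, "uint32": 13}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}


def write_envi_cube(cube: HyperspectralCube, path) -> None:
    """Write `path` (raw BSQ binary) and `path`.hdr (text header)."""
    path = str(path)
    data = cube.data
    dtype = data.dtype.name
    if dtype not in _DTYPE_TO_ENVI:
        data = data.astype(np.float64)
        dtype = "float64"
    rows, cols, bands = data.shape
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelength_nm)
    wn = ", ".join(f"{w:.4f}" for w in cube.mir_wavenumber_cm())
    lines = [
        "ENVI",
        "description = {mirhsi simulated hyperspectral cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[dtype]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = nm",
        "wavelength = {" + wl + "}",
        "mir wavenumber = {" + wn + "}",
    ]
    if cube.seed is not None:
        lines.append(f"mirhsi seed = {cube.seed}")
    if cube.config:
        lines.append("mirhsi config = " + json.dumps(cube.config))
    if cube.meta:
        meta = {k: v for k, v in cube.meta.items() if isinstance(v, (int, float, str))}
        lines.append("mirhsi meta = " + json.dumps(meta))
    with open(path + ".hdr", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    # BSQ: band-sequential
    with open(path, "wb") as fh:
        np.ascontiguousarray(np.moveaxis(data, 2, 0)).tofile(fh)


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("missing ENVI magic line")
    entries: dict[str, str] = {}
    # join brace-delimited multi-line values
    body = text.split("\n", 1)[1] if "\n" in text else ""
    pattern = re.compile(r"^([^=\n]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        entries[key] = val
    return entries


def _parse_list(val: str) -> list[float]:
    return [float(x) for x in val.strip("{} \n").replace("\n", " ").split(",") if x.strip()]


def read_envi_cube(path) -> HyperspectralCube:
    """Read an ENVI cube written by this package (BSQ/BIL/BIP, byte order 0)."""
    path = str(path)
    hdr_path = path + ".hdr" if os.path.exists(path + ".hdr") else path
    if hdr_path == path and not path.endswith(".hdr"):
        raise EnviFormatError(f"no header found for {path}")
    data_path = path[:-4] if path.endswith(".hdr") else path
    with open(hdr_path) as fh:
        hdr = _parse_header(fh.read())
    try:
        cols = int(hdr["samples"])
        rows = int(hdr["lines"])
        bands = int(hdr["bands"])
        dtype = np.dtype(_ENVI_TO_DTYPE[int(hdr["data type"])])
        interleave = hdr.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise EnviFormatError(f"incomplete ENVI header: {exc}") from exc
    if int(hdr.get("byte order", "0")) != 0:
        raise EnviFormatError("only byte order 0 (little endian) is supported")

    raw = np.fromfile(data_path, dtype=dtype)
    expected = rows * cols * bands
    if raw.size != expected:
        raise EnviFormatError(
            f"data size {raw.size} does not match header ({rows}x{cols}x{bands})"
        )
    if interleave == "bsq":
        data = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2)
    elif interleave == "bil":
        data = np.moveaxis(raw.reshape(rows, bands, cols), 1, 2)
    elif interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    else:
        raise EnviFormatError(f"unsupported interleave {interleave!r}")

    if "wavelength" not in hdr:
        raise EnviFormatError("header has no wavelength list")
    wavelength = np.array(_parse_list(hdr["wavelength"]))
    if wavelength.size != bands:
        raise EnviFormatError("wavelength list length does not match band count")
    config = json.loads(hdr["mirhsi config"]) if "mirhsi config" in hdr else {}
    meta = json.loads(hdr["mirhsi meta"]) if "mirhsi meta" in hdr else {}
    seed = int(hdr["mirhsi seed"]) if "mirhsi seed" in hdr else None
    return HyperspectralCube(data.copy(), wavelength, config=config, seed=seed, meta=meta)
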