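"""Absorption-line libraries for the simulated samples.

Each species is a set of Lorentzian lines (centre, dimensionless peak
optical depth, FWHM).  Band positions are the diagnostic peaks of the
five microfluidic test substances plus water and carbon dioxide; line
strengths and widths are representative of thin liquid films / cast
films in a ~25 um channel and of the purge-gas CO2 band as seen at a
few-cm^-1 instrument resolution (the rotational fine structure is not
resolved, so the band is modelled as one broadened envelope).
"""

from __future__ import annotations

from dataclasses import dataclass, field


class UnknownSpeciesError(KeyError):
    """A requested species is not present in the library."""


@dataclass(frozen=True)
class AbsorptionLine:
    """One Lorentzian absorption line.

    center_cm : band centre in cm^-1
    strength : peak optical depth (intensity transmittance at centre = exp(-strength))
    fwhm_cm : full width at half maximum in cm^-1
    """

    center_cm: float
    strength: float
    fwhm_cm: float

    def __post_init__(self) -> None:
        if self.center_cm <= 0:
            raise ValueError("line centre must be positive")
        if self.strength < 0:
            raise ValueError("line strength must be non-negative")
        if self.fwhm_cm <= 0:
            raise ValueError("line width must be positive")


@dataclass
class SpeciesLibrary:
    """Named absorbers, each a list of :class:`AbsorptionLine`."""

    species: dict[str, list[AbsorptionLine]] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.species

    def __getitem__(self, name: str) -> list[AbsorptionLine]:
        try:
            return self.species[name]
        except KeyError:
            raise UnknownSpeciesError(
                f"species {name!r} not in library (have: {sorted(self.species)})"
            ) from None

    def names(self) -> list[str]:
        return sorted(self.species)

    def add(self, name: str, lines: list[AbsorptionLine]) -> None:
        self.species[name] = list(lines)

    def lines_for_mixture(self, mixture: dict[str, float]) -> list[tuple[float, float, float]]:
        """Flatten a {species: scale} mixture into (centre, scaled strength, fwhm) triples."""
        out = []
        for name, scale in mixture.items():
            if scale < 0:
                raise ValueError(f"mixture scale for {name!r} must be non-negative")
            for ln in self[name]:
                out.append((ln.center_cm, ln.strength * scale, ln.fwhm_cm))
        return out


def default_library() -> SpeciesLibrary:
    """The shipped species set.

    Fingerprint-region peaks for glycerin, glucose, DOPC
    (1,2-dioleoyl-sn-glycero-3-phosphocholine) and soybean oil,
    amide I/II for albumin, the O-H bending band of water and the
    asymmetric-stretch band of CO2.
    """
    L = AbsorptionLine
    lib = SpeciesLibrary()
    lib.add("glycerin", [
        L(851.0, 0.45, 40.0),    # CH2 rocking
        L(920.0, 0.40, 40.0),    # C-O symmetric stretch
        L(1030.0, 0.55, 45.0),   # C-O stretch
    ])
    lib.add("glucose", [
        L(1142.0, 0.50, 40.0),   # CH2 bending
        L(1360.0, 0.35, 40.0),   # C-1-H bending
        L(1427.0, 0.35, 40.0),   # CH2 bending
    ])
    lib.add("albumin", [
        L(1542.0, 0.45, 55.0),   # amide II (N-H bend / C-N stretch)
        L(1658.0, 0.55, 60.0),   # amide I (C=O stretch)
    ])
    lib.add("dopc", [
        L(1089.0, 0.45, 40.0),   # PO2- symmetric stretch
        L(1250.0, 0.40, 45.0),   # PO2- asymmetric stretch
    ])
    lib.add("soybean_oil", [
        L(1463.0, 0.40, 35.0),   # CH2 bending
        L(1747.0, 0.55, 30.0),   # ester C=O stretch
    ])
    lib.add("water", [
        L(1640.0, 0.50, 90.0),   # O-H bending
    ])
    lib.add("co2", [
        L(2349.0, 0.45, 35.0),   # asymmetric stretch, unresolved band envelope
    ])
    return lib


#: the five microchannel samples, in the order they are injected
MICROCHANNEL_SPECIES = ["glycerin", "glucose", "albumin", "dopc", "soybean_oil"]

#: the diagnostic "teaching" peaks used for classification, per species (cm^-1)
TEACHING_PEAKS = {
    "glycerin": [851.0, 920.0, 1030.0],
    "glucose": [1142.0, 1360.0, 1427.0],
    "albumin": [1542.0, 1658.0],
    "dopc": [1089.0, 1250.0],
    "soybean_oil": [1463.0, 1747.0],
}
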