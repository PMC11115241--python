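"""X-ray source spectra and material attenuation tables.

The simulator works on a discrete energy grid (keV). Source fluence follows a
Kramers bremsstrahlung shape truncated at the tube potential; material
attenuation is interpolated log-log from a compact table of mass-attenuation
coefficients (cm^2/g) at standard knot energies, with the iodine K-edge at
33.1694 keV represented by an explicit below/above pair so the discontinuity
survives interpolation.

Units convention used throughout the package:

* water, acrylic, aluminum, calcium concentration maps are in g/mL, so their
  per-unit attenuation is the mass-attenuation coefficient itself (cm^-1 per
  g/mL == cm^2/g);
* iodine concentration maps are in mg/mL, so its per-unit attenuation carries
  an extra factor of 1e-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IODINE_K_EDGE_KEV = 33.1694

#: mass attenuation coefficients (cm^2/g) at knot energies (keV); approximate
#: transcriptions of standard published photon cross-section tables.
_MASS_ATTENUATION = {
    "water": {
        10.0: 5.329, 15.0: 1.673, 20.0: 0.8096, 30.0: 0.3756,
        40.0: 0.2683, 50.0: 0.2269, 60.0: 0.2059, 80.0: 0.1837,
    },
    "iodine": {
        10.0: 67.47, 15.0: 22.10, 20.0: 9.925, 30.0: 3.226,
        33.1693: 2.450, 33.1695: 12.01,
        40.0: 7.550, 50.0: 4.211, 60.0: 2.623, 80.0: 1.236,
    },
    "acrylic": {
        10.0: 3.357, 15.0: 1.101, 20.0: 0.5714, 30.0: 0.3032,
        40.0: 0.2350, 50.0: 0.2074, 60.0: 0.1924, 80.0: 0.1751,
    },
    "aluminum": {
        10.0: 26.23, 15.0: 7.955, 20.0: 3.441, 30.0: 1.128,
        40.0: 0.5685, 50.0: 0.3681, 60.0: 0.2778, 80.0: 0.2018,
    },
    "calcium": {
        10.0: 28.51, 15.0: 9.662, 20.0: 4.080, 30.0: 1.376,
        40.0: 0.6998, 50.0: 0.4541, 60.0: 0.3406, 80.0: 0.2345,
    },
}

#: unit of the concentration maps per material -> factor converting the mass
#: attenuation coefficient into attenuation per unit concentration.
_UNIT_FACTOR = {
    "water": 1.0,       # g/mL
    "iodine": 1e-3,     # mg/mL
    "acrylic": 1.0,     # g/mL
    "aluminum": 1.0,    # g/mL
    "calcium": 1.0,     # g/mL
}

MATERIALS = tuple(_MASS_ATTENUATION)


@dataclass(frozen=True)
class EnergyGrid:
    """Discrete photon energy samples (keV) with relative source fluence.

    Weights are normalized to sum to 1 on construction.
    """

    energies: np.ndarray
    source_weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.source_weights, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("energy grid needs at least 2 samples")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be positive and strictly increasing")
        if w.shape != e.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "source_weights", w / w.sum())

    @property
    def n_energies(self) -> int:
        return self.energies.size

    def mean_energy(self) -> float:
        """Fluence-weighted mean photon energy, keV."""
        return float(np.sum(self.energies * self.source_weights))


def kramers_spectrum(kvp: float = 60.0, e_min: float = 10.0,
                     step: float = 1.0) -> EnergyGrid:
    """Kramers bremsstrahlung spectrum for a tungsten-anode tube.

    Fluence ~ (kvp/E - 1) above ``e_min``; the beryllium exit window of the
    modeled source is spectrally negligible above 10 keV, so no extra
    filtration term is applied.
    """
    energies = np.arange(e_min, kvp, step, dtype=float)
    weights = np.clip(kvp / energies - 1.0, 0.0, None)
    return EnergyGrid(energies, weights)


@dataclass(frozen=True)
class MaterialTable:
    """Per-material linear attenuation per unit concentration vs energy.

    ``mu_per_unit(material, E)`` returns cm^-1 per g/mL for water-like
    materials and cm^-1 per mg/mL for iodine (the unit its maps use).
    """

    knots: dict = field(default_factory=lambda: _MASS_ATTENUATION)

    def materials(self) -> tuple:
        return tuple(self.knots)

    def mass_attenuation(self, material: str, energies) -> np.ndarray:
        """Mass attenuation coefficient (cm^2/g) by log-log interpolation."""
        if material not in self.knots:
            raise KeyError(f"unknown material {material!r}")
        table = self.knots[material]
        e_knots = np.array(sorted(table))
        mu_knots = np.array([table[e] for e in e_knots])
        e = np.asarray(energies, dtype=float)
        if np.any(e < e_knots[0]) or np.any(e > e_knots[-1]):
            raise ValueError(
                f"energy outside tabulated range [{e_knots[0]}, {e_knots[-1]}] keV")
        out = np.exp(np.interp(np.log(e), np.log(e_knots), np.log(mu_knots)))
        return out

    def mu_per_unit(self, material: str, energies) -> np.ndarray:
        """Linear attenuation (cm^-1) per unit concentration of ``material``."""
        return self.mass_attenuation(material, energies) * _UNIT_FACTOR[material]


def effective_energy(grid: EnergyGrid, channel_weights: np.ndarray) -> float:
    """Mean detected energy (keV) under given per-energy channel weights."""
    w = np.asarray(channel_weights, dtype=float) * grid.source_weights
    if w.sum() <= 0:
        raise ValueError("channel admits no photons on this grid")
    return float(np.sum(grid.energies * w) / w.sum())
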