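"""Tabulated photon interaction data for silicon.

The packaged constants file holds a synthetic XCOM-style decomposition of the
silicon mass attenuation coefficient into photoelectric, incoherent (Compton)
and coherent (Rayleigh) components on a 5-200 keV grid.  The totals are
anchored to the NIST standard-grid mass attenuation coefficients for silicon;
the split into components is a documented reconstruction (exact Klein-Nishina
incoherent part with an empirical binding correction, power-law coherent part,
photoelectric remainder) consistent with the printed attenuation of silicon at
CT energies.  Values are interpolated log-log between grid nodes;
extrapolation outside the tabulated range is an error.

Units: energies keV, mass attenuation cm^2/g, linear attenuation mm^-1,
distances mm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "CrossSectionTable",
    "load_silicon",
    "SILICON_DENSITY_G_CM3",
]

SILICON_DENSITY_G_CM3 = 2.33

_DATA_FILE = "silicon_attenuation_synthetic_xcom.csv"


@dataclass(frozen=True)
class CrossSectionTable:
    """Partial mass attenuation cross sections on an ascending energy grid.

    Parameters
    ----------
    energy_grid:
        Photon energies in keV, strictly increasing.
    photo, incoherent, coherent:
        Mass attenuation components in cm^2/g at the grid energies.
    density:
        Material density in g/cm^3.
    """

    energy_grid: np.ndarray
    photo: np.ndarray
    incoherent: np.ndarray
    coherent: np.ndarray
    density: float = SILICON_DENSITY_G_CM3
    # cached logs for log-log interpolation
    _log_e: np.ndarray = field(init=False, repr=False)
    _log_photo: np.ndarray = field(init=False, repr=False)
    _log_incoh: np.ndarray = field(init=False, repr=False)
    _log_coh: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("energy_grid", "photo", "incoherent", "coherent"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if np.any(arr <= 0):
                raise ValueError(f"{name} entries must be strictly positive")
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        object.__setattr__(self, "_log_e", np.log(self.energy_grid))
        object.__setattr__(self, "_log_photo", np.log(self.photo))
        object.__setattr__(self, "_log_incoh", np.log(self.incoherent))
        object.__setattr__(self, "_log_coh", np.log(self.coherent))

    # -- range handling -------------------------------------------------
    @property
    def e_min(self) -> float:
        return float(self.energy_grid[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_grid[-1])

    def _check_range(self, energy_keV) -> np.ndarray:
        e = np.asarray(energy_keV, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise ValueError(
                f"energy outside tabulated range [{self.e_min}, {self.e_max}] keV"
            )
        return e

    def _interp(self, energy_keV, log_vals: np.ndarray) -> np.ndarray:
        e = np.asarray(energy_keV, dtype=float)
        return np.exp(np.interp(np.log(e), self._log_e, log_vals))

    # -- operations ------------------------------------------------------
    def mass_attenuation(self, energy_keV, include_coherent: bool = True):
        """Total mass attenuation coefficient in cm^2/g (log-log interpolated)."""
        e = self._check_range(energy_keV)
        total = self._interp(e, self._log_photo) + self._interp(e, self._log_incoh)
        if include_coherent:
            total = total + self._interp(e, self._log_coh)
        return total

    def mu(self, energy_keV, include_coherent: bool = True):
        """Linear attenuation coefficient in mm^-1."""
        return self.mass_attenuation(energy_keV, include_coherent) * self.density / 10.0

    def mu_clamped(self, energy_keV, include_coherent: bool = True):
        """mu() with energies clamped into the tabulated range.

        Convenience for likelihood evaluation, where a trial incident energy
        can leave a residual photon energy below the table floor; there the
        attenuation is so large that any finite path is opaque, so clamping
        at the table edge is a safe, smooth surrogate.
        """
        e = np.clip(np.asarray(energy_keV, dtype=float), self.e_min, self.e_max)
        return self.mu(e, include_coherent)

    def interaction_probability(self, energy_keV, path_length_mm,
                                include_coherent: bool = True):
        """Beer-Lambert probability 1 - exp(-mu(E) * L) of interacting in [0, L]."""
        length = np.asarray(path_length_mm, dtype=float)
        if np.any(length < 0):
            raise ValueError("path length must be non-negative")
        return -np.expm1(-self.mu(energy_keV, include_coherent) * length)

    def type_probabilities(self, energy_keV):
        """Relative (photoelectric, Compton) interaction probabilities.

        The ratio uses photoelectric and incoherent cross sections only; the
        coherent component deposits no energy and never produces an event.
        """
        e = self._check_range(energy_keV)
        photo = self._interp(e, self._log_photo)
        incoh = self._interp(e, self._log_incoh)
        total = photo + incoh
        return photo / total, incoh / total

    def p_photo(self, energy_keV):
        return self.type_probabilities(energy_keV)[0]

    def p_compton(self, energy_keV):
        return self.type_probabilities(energy_keV)[1]


def _parse_table(text: str) -> CrossSectionTable:
    density = SILICON_DENSITY_G_CM3
    lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            if "density_g_per_cm3" in line:
                density = float(line.split(":")[1])
            continue
        if line.strip():
            lines.append(line)
    data = np.genfromtxt(io.StringIO("\n".join(lines)), delimiter=",", names=True)
    return CrossSectionTable(
        energy_grid=data["energy_keV"],
        photo=data["photo_cm2_per_g"],
        incoherent=data["incoherent_cm2_per_g"],
        coherent=data["coherent_cm2_per_g"],
        density=density,
    )


def load_silicon() -> CrossSectionTable:
    """Load the packaged silicon cross-section table."""
    text = resources.files("comptrack.data").joinpath(_DATA_FILE).read_text()
    return _parse_table(text)


def load_table(path) -> CrossSectionTable:
    """Load a cross-section table from an external CSV in the packaged format."""
    with open(path) as fh:
        return _parse_table(fh.read())
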