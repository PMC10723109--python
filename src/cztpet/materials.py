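"""Photon attenuation data for CZT (Cd0.9Zn0.1Te, 5.9 g/cm^3).

The package ships a tabulated set of linear attenuation coefficients on a
50-1500 keV grid (``data/czt_attenuation.csv``), regenerable with
``scripts/make_attenuation_table.py``.  The table is computed from:

* incoherent: Klein-Nishina total cross section per electron times the
  molecular electron count, with a small effective incoherent-scattering-
  function correction at low energy;
* photoelectric: per-element cross sections with a Z^4.5 partition and a
  smoothly varying power law in energy (local exponent ~2.9 near 100 keV
  flattening to ~2.2 near 1.5 MeV), anchored so that at 511 keV the chance of
  an interacting photon Compton-scattering is the literature value of 83%;
* coherent (Rayleigh): an E^-2 power law anchored at 511 keV.  Coherent
  scattering is reported but excluded from transport (it deposits no energy
  and is ~2% of the total at 511 keV).

There are no K-edges in the tabulated range (Cd/Zn/Te K-edges all lie below
50 keV), so log-log interpolation is smooth.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .constants import (
    ATOMIC_NUMBER,
    CZT_MOLECULAR_DENSITY,
    CZT_STOICHIOMETRY,
    CZT_Z_PER_MOLECULE,
)
from .kinematics import klein_nishina_total

_COMPTON_FRACTION_511 = 0.83  # P(Compton | interaction) at 511 keV
_COHERENT_MU_511 = 0.010  # cm^-1

ENERGY_MIN = 50.0
ENERGY_MAX = 1500.0


@dataclass(frozen=True)
class CrossSectionSet:
    """Linear attenuation coefficients [1/cm] for CZT at one energy."""

    energy: float
    photoelectric: float
    incoherent: float
    coherent: float
    total: float
    molecular_density: float = CZT_MOLECULAR_DENSITY

    @property
    def transport_total(self) -> float:
        """Attenuation used in transport: photoelectric + incoherent."""
        return self.photoelectric + self.incoherent

    @property
    def compton_fraction(self) -> float:
        """P(Compton | interaction) with coherent scattering excluded."""
        return self.incoherent / (self.incoherent + self.photoelectric)


def _incoherent_mu(energy):
    """Incoherent linear attenuation [1/cm]; KN x Z with binding correction."""
    corr = 1.0 - 0.17 * np.exp(-np.asarray(energy, float) / 80.0)
    return CZT_MOLECULAR_DENSITY * CZT_Z_PER_MOLECULE * klein_nishina_total(energy) * corr


def _photoelectric_mu(energy):
    """Photoelectric linear attenuation [1/cm] (smooth power law, 511 anchor)."""
    energy = np.asarray(energy, dtype=float)
    mu_inc_511 = _incoherent_mu(511.0)
    mu_pe_511 = mu_inc_511 * (1.0 - _COMPTON_FRACTION_511) / _COMPTON_FRACTION_511
    # ln mu quadratic in ln E: local slope -2.9 at 100 keV, -2.2 at 1500 keV
    c = 0.7 / (2.0 * (np.log(1500.0) - np.log(100.0)))
    b = -2.9 - 2.0 * c * np.log(100.0)
    ln_e = np.log(energy)
    ln_511 = np.log(511.0)
    shape = b * (ln_e - ln_511) + c * (ln_e**2 - ln_511**2)
    return mu_pe_511 * np.exp(shape)


def _coherent_mu(energy):
    return _COHERENT_MU_511 * (511.0 / np.asarray(energy, dtype=float)) ** 2


def compute_attenuation_table(n_points: int = 160) -> np.ndarray:
    """Build the (energy, pe, incoherent, coherent, total) table, shape (n, 5)."""
    e = np.geomspace(ENERGY_MIN, ENERGY_MAX, n_points)
    pe = _photoelectric_mu(e)
    inc = _incoherent_mu(e)
    coh = _coherent_mu(e)
    return np.column_stack([e, pe, inc, coh, pe + inc + coh])


def element_photoelectric_weights():
    """Per-element share of the molecular photoelectric cross section (Z^4.5)."""
    w = {el: CZT_STOICHIOMETRY[el] * ATOMIC_NUMBER[el] ** 4.5 for el in CZT_STOICHIOMETRY}
    tot = sum(w.values())
    return {el: v / tot for el, v in w.items()}


def _load_table() -> np.ndarray:
    ref = importlib.resources.files("cztpet") / "data" / "czt_attenuation.csv"
    with ref.open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


class AttenuationTable:
    """Log-log interpolator over the shipped CZT attenuation table."""

    def __init__(self, table: np.ndarray | None = None):
        self._table = _load_table() if table is None else np.asarray(table, float)
        self._log_e = np.log(self._table[:, 0])
        self._log_mu = np.log(self._table[:, 1:4])

    @property
    def energies(self) -> np.ndarray:
        return self._table[:, 0]

    def _interp(self, energy):
        energy = np.asarray(energy, dtype=float)
        if np.any((energy < ENERGY_MIN) | (energy > ENERGY_MAX)):
            raise ValueError(
                f"energy outside tabulated range [{ENERGY_MIN}, {ENERGY_MAX}] keV"
            )
        ln_e = np.log(energy)
        cols = [np.exp(np.interp(ln_e, self._log_e, self._log_mu[:, j])) for j in range(3)]
        return cols  # pe, incoherent, coherent

    def cross_sections(self, energy: float) -> CrossSectionSet:
        pe, inc, coh = (float(c) for c in self._interp(energy))
        return CrossSectionSet(
            energy=float(energy),
            photoelectric=pe,
            incoherent=inc,
            coherent=coh,
            total=pe + inc + coh,
        )

    # vectorised accessors used by the transport engine
    def mu_transport(self, energy):
        pe, inc, _ = self._interp(energy)
        return pe + inc

    def compton_fraction(self, energy):
        pe, inc, _ = self._interp(energy)
        return inc / (inc + pe)


_DEFAULT_TABLE: AttenuationTable | None = None


def default_table() -> AttenuationTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AttenuationTable()
    return _DEFAULT_TABLE


def cross_sections(energy: float) -> CrossSectionSet:
    """Interpolated CZT attenuation coefficients at ``energy`` [keV]."""
    return default_table().cross_sections(energy)
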