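"""Physical constants and CZT material parameters (units: mm, keV, ns, Bq)."""

import numpy as np

#: electron rest energy [keV]
MEC2 = 511.0

#: classical electron radius [cm]
R_E_CM = 2.8179403262e-13

#: Thomson cross section [cm^2]
SIGMA_THOMSON = 8.0 * np.pi / 3.0 * R_E_CM**2

#: Avogadro's number [1/mol]
N_AVOGADRO = 6.02214076e23

# Cd_0.9 Zn_0.1 Te -- the detector compound
CZT_DENSITY_G_CM3 = 5.9
ATOMIC_MASS = {"Cd": 112.414, "Zn": 65.38, "Te": 127.60}
ATOMIC_NUMBER = {"Cd": 48, "Zn": 30, "Te": 52}
CZT_STOICHIOMETRY = {"Cd": 0.9, "Zn": 0.1, "Te": 1.0}

#: molar mass of one CZT "molecule" [g/mol]
CZT_MOLAR_MASS = sum(CZT_STOICHIOMETRY[el] * ATOMIC_MASS[el] for el in CZT_STOICHIOMETRY)

#: molecular density n0 of CZT [1/cm^3]
CZT_MOLECULAR_DENSITY = CZT_DENSITY_G_CM3 / CZT_MOLAR_MASS * N_AVOGADRO

#: electrons per CZT molecule
CZT_Z_PER_MOLECULE = sum(
    CZT_STOICHIOMETRY[el] * ATOMIC_NUMBER[el] for el in CZT_STOICHIOMETRY
)

#: atomic unit of momentum expressed as a fraction of m_e * c (fine-structure constant)
ALPHA_FS = 1.0 / 137.035999

#: half-lives [s]
HALF_LIFE_S = {"Na-22": 2.6018 * 365.25 * 86400.0, "Cu-64": 12.7004 * 3600.0}

#: energies below this are deposited locally during transport [keV]
TRANSPORT_ENERGY_CUTOFF = 50.0
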