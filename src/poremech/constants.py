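"""Physical constants and unit helpers.

Force-spectroscopy code works in SI (N, m, J); free-energy code works in
kJ/mol and nm, the units of the molecular-simulation side.
"""

#: Boltzmann constant (J/K)
KB_J = 1.380649e-23

#: Boltzmann constant (kJ/mol/K) = molar gas constant / 1000
KB_KJMOL = 8.31446261815324e-3

#: Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23

NM = 1e-9  # m
NN = 1e-9  # N


def kT_J(temperature: float) -> float:
    """Thermal energy in joules at `temperature` (K)."""
    return KB_J * temperature


def kT_kJmol(temperature: float) -> float:
    """Thermal energy in kJ/mol at `temperature` (K)."""
    return KB_KJMOL * temperature
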