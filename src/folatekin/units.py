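"""Physical constants and the unit conventions used across the package.

Conventions: masses in ng, volumes in L, concentrations in micromolar (uM),
molar masses in Da (g/mol), times in minutes, energies in kJ/mol.  Every
conversion between these scales lives here so that no module carries its own
powers of ten.
"""

from __future__ import annotations

#: Mass of a proton in Da; monoisotopic, for charge-state arithmetic on
#: protonated peptide ions.  Override per call for average-mass workflows.
PROTON_MASS_DA: float = 1.00728

#: Gas constant, J mol^-1 K^-1.
R_GAS: float = 8.314

#: Celsius -> Kelvin offset.
KELVIN_OFFSET: float = 273.15

NG_PER_G: float = 1e9
UM_PER_M: float = 1e6
MINUTES_PER_HOUR: float = 60.0


def ng_to_mol(mass_ng: float, molar_mass_da: float) -> float:
    """Convert a mass in ng to moles given a molar mass in Da (g/mol)."""
    if molar_mass_da <= 0:
        raise ValueError(f"molar mass must be positive, got {molar_mass_da}")
    return (mass_ng / NG_PER_G) / molar_mass_da


def mol_per_l_to_um(conc_m: float) -> float:
    """Convert mol/L to uM."""
    return conc_m * UM_PER_M


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + KELVIN_OFFSET
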