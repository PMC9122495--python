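"""Internal unit system and physical constants.

Internal units follow the GROMACS convention: length nm, time ps, mass g/mol
(amu), energy kJ/mol.  Temperatures are Kelvin.  Spring constants quoted in
the membrane-biophysics literature in kcal/mol/A^2 are converted on input.
"""

# Boltzmann constant, kJ/mol/K
KB = 8.31446261815324e-3

#: kcal/mol -> kJ/mol
KCAL_TO_KJ = 4.184

#: kcal/mol/A^2 -> kJ/mol/nm^2  (4.184 * 100)
KCAL_A2_TO_KJ_NM2 = KCAL_TO_KJ * 100.0

#: A -> nm
A_TO_NM = 0.1

#: fs -> ps
FS_TO_PS = 1e-3


def kBT(temperature: float) -> float:
    """Thermal energy in kJ/mol at ``temperature`` Kelvin."""
    return KB * temperature


def spring_kcal_to_internal(k_kcal_A2: float) -> float:
    """Convert a spring constant from kcal/mol/A^2 to kJ/mol/nm^2."""
    return k_kcal_A2 * KCAL_A2_TO_KJ_NM2


def spring_internal_to_kcal(k_kj_nm2: float) -> float:
    return k_kj_nm2 / KCAL_A2_TO_KJ_NM2
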