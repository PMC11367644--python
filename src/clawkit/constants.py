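"""Physical constants and unit conversions used throughout the package.

All free energies handled by the umbrella-sampling and competition modules
are in kJ/mol; calorimetric quantities are in kcal/mol (the unit ITC
instruments report). Reaction coordinates are in Angstrom in all user-facing
data; harmonic spring constants are accepted in kJ mol^-1 nm^-2 (the unit
simulation packages print) and converted internally.
"""

# Gas constant, kcal mol^-1 K^-1 (CODATA, used for dG = RT ln Kd)
R_KCAL_PER_MOL_K = 1.98720425864083e-3

# Boltzmann/gas constant, kJ mol^-1 K^-1 (molar kB for Boltzmann factors)
KB_KJ_PER_MOL_K = 0.0083144626

# 1 nm = 10 A, so a spring constant in kJ mol^-1 nm^-2 is divided by 100
# to act on displacements measured in Angstrom.
ANGSTROM_PER_NM = 10.0
SPRING_NM2_TO_A2 = 1.0 / ANGSTROM_PER_NM**2


def kt_kj(temperature_k: float) -> float:
    """Thermal energy kB*T in kJ/mol at the given temperature (K)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KJ_PER_MOL_K * temperature_k
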