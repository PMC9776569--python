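"""Physical constants in the internal unit system (nm, kJ/mol, e, K)."""

import math

#: molar gas constant, kJ mol^-1 K^-1
R_KJ_MOL_K = 8.314462618e-3

#: Coulomb constant e^2/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB_KJ_NM = 138.935458

#: kcal -> kJ
KCAL_TO_KJ = 4.184

#: mol/L -> particles per nm^3
MOLAR_TO_PER_NM3 = 0.602214076

LN10 = math.log(10.0)


def kt_kj(temperature: float) -> float:
    """Thermal energy k_B*T (per mole: R*T), kJ/mol."""
    return R_KJ_MOL_K * temperature


def debye_kappa(ionic_strength: float, eps_out: float, temperature: float) -> float:
    """Inverse Debye length, nm^-1, for a 1:1 electrolyte.

    kappa^2 = 8 pi f n / (eps_out k T) with f the Coulomb constant and n the
    number density of each ionic species (= ionic strength for 1:1 salt).
    """
    if ionic_strength <= 0:
        return 0.0
    n = MOLAR_TO_PER_NM3 * ionic_strength
    kappa2 = 8.0 * math.pi * COULOMB_KJ_NM * n / (eps_out * kt_kj(temperature))
    return math.sqrt(kappa2)
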