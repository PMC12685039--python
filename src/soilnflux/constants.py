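"""Physical constants for trace-gas flux conversion and soil physics.

All flux arithmetic in this package reports nitrogen mass, not gas mass:
``M_N`` is grams of N per mole of gas (NO carries one N atom, N2O two),
so a mole fraction converts directly to µg N m⁻³.
"""

from dataclasses import dataclass

# grams of N per mole of gas
M_N = {"NO": 14.0, "N2O": 28.0}

SPECIES = ("NO", "N2O")


@dataclass(frozen=True)
class PhysicalConstants:
    """Standard-state constants used in the ideal-gas conversion factor."""

    t0_k: float = 273.0          # standard temperature
    v0_l_mol: float = 22.4       # molar volume at standard state, L mol⁻¹
    p0_hpa: float = 1013.0       # standard pressure
    particle_density: float = 2.65  # quartz particle density, g cm⁻³


CONSTANTS = PhysicalConstants()

# 1 µg N m⁻² h⁻¹ sustained for one day = 24 µg N m⁻² = 2.4e-4 kg N ha⁻¹
KG_HA_PER_UGM2H_DAY = 2.4e-4


def mole_fraction_to_mass(species: str, temp_k, pressure_hpa,
                          constants: PhysicalConstants = CONSTANTS):
    """µg N m⁻³ per nmol mol⁻¹ at the given chamber temperature/pressure.

    At 273 K and 1013 hPa this is M_N / 22.4 (0.625 for NO, 1.25 for N2O).
    """
    if species not in M_N:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    return (M_N[species] / constants.v0_l_mol
            * (pressure_hpa / constants.p0_hpa)
            * (constants.t0_k / temp_k))
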