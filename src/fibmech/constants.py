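"""Physical constants and unit conversions used throughout the package.

Internal unit system: lengths in Å, energies in kcal/mol, time in ns,
temperature in K, forces reported in pN. Every conversion lives here so the
whole package shares a single constants table.
"""

#: Boltzmann constant in kcal/(mol·K).
BOLTZMANN_KCAL_PER_MOL_K = 1.987204259e-3

#: kT at the standard simulation temperature of 300 K, kcal/mol.
KT_300K = 0.5962

#: Force conversion: 1 kcal/mol/Å expressed in piconewtons.
PN_PER_KCAL_PER_MOL_ANG = 69.48

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Calcium–partner contact cutoff, Å (strict inequality).
CONTACT_CUTOFF = 4.0

#: Solvent probe radius for accessible-surface calculations, Å.
WATER_PROBE_RADIUS = 1.4

#: Radius assigned to the calcium ion, Å.  With a 1.4 Å probe the isolated
#: ion has accessible area 4π(1.5+1.4)² = 105.68 Å², the reference area used
#: to normalise calcium SASA to percent.
CALCIUM_RADIUS = 1.5

#: Reference (100%) calcium solvent-accessible surface area, Å².
CALCIUM_REFERENCE_SASA = 105.7

#: Van der Waals radii by element symbol, Å.  "CA" denotes the calcium ion.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "CA": CALCIUM_RADIUS,
    "NA": 2.27,
    "MG": 1.73,
}


def kt(temperature: float) -> float:
    """Thermal energy kT in kcal/mol at *temperature* (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KCAL_PER_MOL_K * temperature
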