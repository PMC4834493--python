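"""Physical constants and unit conventions.

Energy is kcal/mol throughout, lengths along collective variables are in
dimensionless CV units ("u"), time is ps.  With the effective mass expressed
in kcal/mol·ps²/u², velocities come out in u/ps and no unit conversions are
needed inside the integrators.
"""

# Boltzmann / gas constant in kcal/mol/K
KB = 0.0019872

# SI constants used only for the Eyring prefactor kT/h
KB_SI = 1.380649e-23  # J/K
H_SI = 6.62607015e-34  # J*s

# 1 M standard-state volume per molecule, Å^3
V0_STANDARD = 1660.0

# default simulation temperature (K); RT = 0.5962 kcal/mol
T_DEFAULT = 300.0
# H/D exchange analysis temperature (K); RT = 0.5922 kcal/mol
T_HDX = 298.0

# default effective mass for toy Langevin dynamics, kcal/mol*ps^2/u^2
MASS_DEFAULT = 1.0


def kt(temperature: float) -> float:
    """Thermal energy kB*T in kcal/mol."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return KB * temperature


def eyring_prefactor(temperature: float) -> float:
    """kB*T/h in s^-1 (≈ 6.25e12 s^-1 at 300 K)."""
    return KB_SI * temperature / H_SI
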