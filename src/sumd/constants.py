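"""Physical constants and unit conventions.

The package works in a single unit system throughout:

========  ===========
quantity  unit
========  ===========
length    angstrom (A)
time      picosecond (ps)
mass      atomic mass unit (amu, = g/mol)
energy    kcal/mol
temperature  kelvin (K)
========  ===========

Internally the integrator uses amu*A^2/ps^2 for kinetic terms; since
1 amu*A^2/ps^2 = 10 J/mol exactly (amu = g/mol), the conversion factor
from kcal/mol is 4184/10 = 418.4.
"""

#: Boltzmann constant in kcal/(mol K)
KB = 1.987204259e-3

#: kcal/mol expressed in internal energy units (amu A^2 / ps^2)
KCAL_TO_INTERNAL = 418.4


def kbt_internal(temperature: float) -> float:
    """kB*T in internal units (amu A^2/ps^2) at ``temperature`` kelvin."""
    return KB * temperature * KCAL_TO_INTERNAL
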