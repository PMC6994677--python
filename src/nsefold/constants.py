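"""Physical constants and unit conversions.

The package works in a single internal unit system chosen to match how
small-angle and spin-echo results are reported:

====================  =========
momentum transfer q   1/Å
length                Å
time                  ns
diffusion             Å²/ns
viscosity             mPa·s
temperature           K
scattering length     fm
====================  =========

The only non-trivial constant is Boltzmann's constant expressed in these
units.  With η in mPa·s (= 1e-3 Pa·s), lengths in Å and times in ns, the
combination k_B·T / η has units Å³/ns when k_B is scaled by 1e? — working
through SI: k_B = 1.380649e-23 J/K = 13.80649 mPa·s·Å³/(ns·K).
"""

import numpy as np

#: Boltzmann constant in mPa·s · Å³ / (ns · K).
KB = 13.80649

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: 1 Å³ expressed in litres (for overlap-concentration conversions).
ANGSTROM3_IN_LITRE = 1e-27

#: Elementary charge squared over 4·π·ε0·k_B, in Å·K.  Dividing by the
#: relative dielectric constant and the temperature gives the Bjerrum
#: length in Å:  l_B = BJERRUM_SCALE / (eps_r · T).
BJERRUM_SCALE = 1.671009e5

NM_TO_A = 10.0
US_TO_NS = 1e3


def bjerrum_length(temperature: float, dielectric: float) -> float:
    """Bjerrum length in Å (≈7.1 Å for water at 298 K, eps_r = 78.3)."""
    return BJERRUM_SCALE / (dielectric * temperature)


def stokes_einstein_diffusion(radius: float, eta: float, temperature: float) -> float:
    """D = k_B T / (6 π η R) in Å²/ns for R in Å, η in mPa·s."""
    return KB * temperature / (6.0 * np.pi * eta * radius)
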