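"""Physical constants and unit conventions.

Unit policy across the package:

* step-parameter interface: angstroms and degrees (the convention of
  3DNA-style ``bp_step`` tables);
* internal geometry: angstroms and radians;
* forces: pN; energies: pN*nm; persistence lengths and contour lengths: nm.
"""

#: Boltzmann constant times temperature at 298 K, in pN*nm.
KBT_PN_NM = 4.114

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 298.0

ANGSTROM_PER_NM = 10.0


def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kB*T in pN*nm at the given temperature (K)."""
    return KBT_PN_NM * (temperature / DEFAULT_TEMPERATURE)
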