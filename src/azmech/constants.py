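"""Physical constants and unit conventions.

Package-wide units: length in nm, force in pN, lifetime in ns,
temperature in K.  The coarse-grained simulator works internally in
angstrom / kcal/mol / reduced time and converts at its boundary.
"""

#: Reference temperature (room temperature), K.
T_REF = 298.0

#: kB*T at 298 K in pN nm (package-wide convention).
KBT_REF = 4.114

#: Boltzmann constant in pN nm / K, consistent with the 4.114 convention.
KB_PN_NM = KBT_REF / T_REF

#: 1 kcal/mol/angstrom expressed in pN.
KCAL_PER_MOL_ANGSTROM_IN_PN = 69.4786

#: angstrom -> nm
ANGSTROM_IN_NM = 0.1


def kbt(temperature: float) -> float:
    """kB*T in pN nm at the given temperature in K."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return KB_PN_NM * temperature
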