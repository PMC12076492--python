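"""Physical constants and unit conventions.

Internal unit system (used consistently across the package):

===========  =====================
quantity     unit
===========  =====================
length / CV  angstrom (A)
energy       kJ/mol
force const  kJ/mol/A^2
mass         amu
time         ps
temperature  K
===========  =====================

Force constants quoted in kJ/mol/nm^2 (the convention of most MD engines)
convert as 1 kJ/mol/nm^2 = 0.01 kJ/mol/A^2, e.g. 500 kJ/mol/nm^2 = 5 kJ/mol/A^2.
"""

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621

#: 1 kJ/mol expressed in amu*A^2/ps^2 (acceleration = KJMOL_IN_AMU_A2_PS2 * F/m).
KJMOL_IN_AMU_A2_PS2 = 100.0

#: Standard atomic masses, amu.  Covers the elements occurring in proteins and
#: common ligands; extend via the ``masses`` argument of geometry helpers.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "MN": 54.938,
    "SE": 78.971,
}


def mass_of(element: str, masses: dict | None = None) -> float:
    """Look up the atomic mass of ``element`` (case-insensitive symbol).

    Raises ``KeyError`` with a clear message for unknown elements.
    """
    table = ATOMIC_MASSES if masses is None else masses
    key = element.strip().upper()
    if key not in table:
        # fall back to exact key for user-supplied tables with odd casing
        if element in table:
            return table[element]
        raise KeyError(f"no mass known for element {element!r}")
    return table[key]
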