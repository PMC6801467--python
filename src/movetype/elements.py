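"""Per-element parameter tables for the default potential.

Values are generic molecular-mechanics numbers (epsilon in kcal/mol, r_min in
Angstrom for the homonuclear pair minimum, solvation sigma in kcal/mol/A^2 of
solvent-accessible surface). They parameterize the package's documented
default potential; any of them can be overridden through a potential config
file (see :mod:`movetype.potential`).
"""

from __future__ import annotations

# element -> (epsilon kcal/mol, r_min Angstrom); r_min is the homonuclear
# equilibrium distance, combined across elements by the arithmetic mean.
VDW_TABLE: dict[str, tuple[float, float]] = {
    "H": (0.0157, 2.40),
    "C": (0.0860, 3.82),
    "N": (0.1700, 3.65),
    "O": (0.2100, 3.32),
    "S": (0.2500, 4.00),
    "P": (0.2000, 4.20),
    "F": (0.0610, 3.50),
    "CL": (0.2650, 3.90),
    "BR": (0.3200, 4.10),
    "I": (0.4000, 4.40),
}
VDW_DEFAULT: tuple[float, float] = (0.10, 3.60)

# Atomic solvation parameters, kcal/mol per A^2 of accessible area
# (hydrophobic carbon/sulfur pay to be buried; polar N/O gain exposure).
SOLVATION_SIGMA: dict[str, float] = {
    "C": 0.016,
    "S": 0.021,
    "N": -0.006,
    "O": -0.006,
    "H": 0.0,
}
SOLVATION_DEFAULT = 0.0

# Heavy elements that can donate/accept hydrogen bonds.
POLAR_ELEMENTS = {"N", "O"}

PROBE_RADIUS = 1.4  # water probe for accessible-surface areas, Angstrom


def vdw_params(element: str) -> tuple[float, float]:
    """(epsilon, r_min) for one element symbol, case-insensitive."""
    return VDW_TABLE.get(element.upper(), VDW_DEFAULT)


def solvation_sigma(element: str) -> float:
    return SOLVATION_SIGMA.get(element.upper(), SOLVATION_DEFAULT)
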