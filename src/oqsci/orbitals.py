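"""Qubit-register sizing from Gaussian-basis function counts.

A molecular Hamiltonian on M spatial orbitals needs 2M qubits under
Jordan-Wigner.  This module counts contracted basis functions per element
for a few common basis sets (spherical harmonics for d shells), enough to
size registers for the hydrides and first/second-row systems the toolkit
targets.
"""

from __future__ import annotations

import re

__all__ = ["basis_function_count", "spin_orbital_count", "parse_formula"]

# contracted shells per element: (n_s, n_p, n_d); spherical d -> 5 functions
_SHELLS: dict[str, dict[str, tuple[int, int, int]]] = {
    "6-31g": {
        "H": (2, 0, 0),
        "He": (2, 0, 0),
        "Li": (3, 2, 0),
        "C": (3, 2, 0),
        "N": (3, 2, 0),
        "O": (3, 2, 0),
        "F": (3, 2, 0),
        "Si": (4, 3, 0),
        "P": (4, 3, 0),
        "S": (4, 3, 0),
        "Cl": (4, 3, 0),
    },
    "cc-pvdz": {
        "H": (2, 1, 0),
        "He": (2, 1, 0),
        "Li": (3, 2, 1),
        "C": (3, 2, 1),
        "N": (3, 2, 1),
        "O": (3, 2, 1),
        "F": (3, 2, 1),
        "Si": (4, 3, 1),
        "P": (4, 3, 1),
        "S": (4, 3, 1),
        "Cl": (4, 3, 1),
    },
}

_DEGENERACY = (1, 3, 5)  # s, p, spherical d


def parse_formula(formula: str) -> dict[str, int]:
    """'SiH4' -> {'Si': 1, 'H': 4}."""
    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def basis_function_count(formula: str, basis: str) -> int:
    """Number of contracted spatial basis functions for a molecule."""
    table = _SHELLS.get(basis.lower())
    if table is None:
        raise ValueError(f"unknown basis {basis!r}; known: {sorted(_SHELLS)}")
    total = 0
    for element, n in parse_formula(formula).items():
        if element not in table:
            raise ValueError(f"element {element} not tabulated for {basis}")
        shells = table[element]
        total += n * sum(c * d for c, d in zip(shells, _DEGENERACY))
    return total


def spin_orbital_count(formula: str, basis: str) -> int:
    """Qubits needed under Jordan-Wigner: two spin orbitals per function."""
    return 2 * basis_function_count(formula, basis)
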