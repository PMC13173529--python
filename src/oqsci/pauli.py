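"""Qubit-space Hamiltonians: Pauli-string algebra and the Jordan-Wigner map.

A Pauli string on ``n`` qubits is stored symplectically as a pair of integer
masks ``(x, z)``: bit ``q`` of ``x`` flips qubit ``q``, bit ``q`` of ``z``
applies a phase, and a qubit with both bits set carries a Y.  The canonical
operator associated with ``(x, z)`` is

    W(x, z) = i**popcount(x & z) * X^x * Z^z

which makes ``W`` exactly the tensor product of literal I/X/Y/Z matrices.

The fermion-to-qubit mapping is Jordan-Wigner under the blocked spin-orbital
ordering, so computational-basis bit ``q`` equals the occupancy of spin
orbital ``q`` — the property the occupancy-sampling scheme reads off
measurement bitstrings directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .determinants import MolecularIntegrals, SpinOrbitalBasis

__all__ = ["PauliHamiltonian", "jordan_wigner", "l1_norm", "pauli_action"]

_CHARS = {(0, 0): "I", (1, 0): "X", (0, 1): "Z", (1, 1): "Y"}
_MASKS = {"I": (0, 0), "X": (1, 0), "Z": (0, 1), "Y": (1, 1)}


def string_to_masks(s: str) -> tuple[int, int]:
    """Parse a qubit-0-first I/X/Y/Z word into (x, z) masks."""
    x = z = 0
    for q, ch in enumerate(s):
        xb, zb = _MASKS[ch]
        x |= xb << q
        z |= zb << q
    return x, z


def masks_to_string(x: int, z: int, n_qubits: int) -> str:
    return "".join(
        _CHARS[((x >> q) & 1, (z >> q) & 1)] for q in range(n_qubits)
    )


def _mul(x1: int, z1: int, x2: int, z2: int) -> tuple[int, int, complex]:
    """Product W(x1,z1) @ W(x2,z2) = phase * W(x3,z3)."""
    x3, z3 = x1 ^ x2, z1 ^ z2
    e = (
        (x1 & z1).bit_count()
        + (x2 & z2).bit_count()
        + 2 * (z1 & x2).bit_count()
        - (x3 & z3).bit_count()
    ) % 4
    return x3, z3, (1j) ** e


@dataclass
class PauliHamiltonian:
    """Weighted sum of Pauli strings H = sum_j h_j sigma_j on ``n_qubits``.

    Terms are keyed by the symplectic masks; coefficients are real (molecular
    Hamiltonians are real under Jordan-Wigner).  ``lambda_norm`` is the l1
    norm sum_j |h_j| over all stored terms.
    """

    n_qubits: int
    coeffs: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def lambda_norm(self) -> float:
        return float(sum(abs(c) for c in self.coeffs.values()))

    @property
    def terms(self) -> list[tuple[float, str]]:
        """(coefficient, pauli word) pairs; words are qubit-0-first."""
        return [
            (c, masks_to_string(x, z, self.n_qubits))
            for (x, z), c in sorted(self.coeffs.items())
        ]

    def __len__(self) -> int:
        return len(self.coeffs)

    def split_identity(self) -> tuple[float, "PauliHamiltonian"]:
        """Separate the identity coefficient (an energy offset) from the rest.

        Identity terms only contribute a global phase under time evolution, so
        samplers exclude them and use the l1 norm of the remainder.
        """
        rest = {k: v for k, v in self.coeffs.items() if k != (0, 0)}
        offset = self.coeffs.get((0, 0), 0.0)
        return offset, PauliHamiltonian(self.n_qubits, rest)

    def to_dense(self) -> np.ndarray:
        """Dense 2^n x 2^n matrix (small-n diagnostics only)."""
        dim = 1 << self.n_qubits
        H = np.zeros((dim, dim), dtype=complex)
        idx = np.arange(dim)
        for (x, z), c in self.coeffs.items():
            flipped, phase = pauli_action(x, z, idx)
            H[flipped, idx] += c * phase
        return H


def pauli_action(
    x: int, z: int, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply W(x, z) to computational basis states ``idx``.

    Returns (flipped indices, per-state phases):
    W|b> = i**|x&z| * (-1)**popcount(b & z) |b ^ x>.
    """
    y_phase = (1j) ** ((x & z).bit_count() % 4)
    signs = 1.0 - 2.0 * (np.bitwise_count(idx & z) & 1)
    return idx ^ x, y_phase * signs


def l1_norm(H: PauliHamiltonian) -> float:
    """lambda = sum_j |h_j| over the stored terms."""
    return H.lambda_norm


# ---------------------------------------------------------------------------
# Jordan-Wigner construction

_EPS_INTEGRAL = 1e-14


def _ladder(p: int, dagger: bool) -> list[tuple[int, int, complex]]:
    """JW ladder operator on spin orbital p as a 2-term Pauli sum.

    a_p  = Z_{<p} (X_p + iY_p)/2,  a†_p = Z_{<p} (X_p - iY_p)/2.
    Terms are (x, z, coeff) with the W(x, z) canonical-phase convention.
    """
    zmask = (1 << p) - 1
    x_term = (1 << p, zmask, 0.5)
    # W on a Y site includes the i of Y; coefficient is ±1/(2i) * i = ∓? keep
    # it simple: Y_p with Z string is W(1<<p, zmask | 1<<p) exactly.
    y_coeff = -0.5j if dagger else 0.5j
    y_term = (1 << p, zmask | (1 << p), y_coeff)
    return [x_term, y_term]


def _accumulate_product(
    acc: dict[tuple[int, int], complex],
    ops: list[list[tuple[int, int, complex]]],
    scale: float,
) -> None:
    """Add scale * prod(ops) (each op a Pauli sum) into the accumulator."""
    partial: list[tuple[int, int, complex]] = [(0, 0, 1.0 + 0j)]
    for op in ops:
        nxt: list[tuple[int, int, complex]] = []
        for x1, z1, c1 in partial:
            for x2, z2, c2 in op:
                x3, z3, ph = _mul(x1, z1, x2, z2)
                nxt.append((x3, z3, c1 * c2 * ph))
        partial = nxt
    for x, z, c in partial:
        key = (x, z)
        acc[key] = acc.get(key, 0.0) + scale * c


def jordan_wigner(
    basis: SpinOrbitalBasis, ints: MolecularIntegrals, drop_tol: float = 1e-10
) -> PauliHamiltonian:
    """Map the second-quantized molecular Hamiltonian to 2M qubits.

    H = E_core + sum_{sigma,pq} h_pq a†_{p sigma} a_{q sigma}
      + 1/2 sum_{sigma tau, pqrs} (pq|rs) a†_{p sigma} a†_{r tau}
                                          a_{s tau} a_{q sigma}

    with (pq|rs) in chemists' notation.  Terms with |coefficient| <= drop_tol
    are removed after merging.
    """
    M = basis.M
    n = 2 * M
    acc: dict[tuple[int, int], complex] = {(0, 0): complex(ints.e_core)}

    h, g = ints.h, ints.g
    for sigma in (0, 1):
        off = sigma * M
        for p in range(M):
            for q in range(M):
                if abs(h[p, q]) <= _EPS_INTEGRAL:
                    continue
                _accumulate_product(
                    acc,
                    [_ladder(off + p, True), _ladder(off + q, False)],
                    h[p, q],
                )
    for sigma in (0, 1):
        for tau in (0, 1):
            so, to = sigma * M, tau * M
            for p in range(M):
                for q in range(M):
                    for r in range(M):
                        for s in range(M):
                            val = g[p, q, r, s]
                            if abs(val) <= _EPS_INTEGRAL:
                                continue
                            _accumulate_product(
                                acc,
                                [
                                    _ladder(so + p, True),
                                    _ladder(to + r, True),
                                    _ladder(to + s, False),
                                    _ladder(so + q, False),
                                ],
                                0.5 * val,
                            )

    coeffs: dict[tuple[int, int], float] = {}
    for key, c in acc.items():
        if abs(c.imag) > 1e-9:
            raise RuntimeError(f"non-real Pauli coefficient {c} for {key}")
        if abs(c.real) > drop_tol:
            coeffs[key] = float(c.real)
    return PauliHamiltonian(n, coeffs)
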