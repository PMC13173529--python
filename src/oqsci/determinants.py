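"""Bit-level Slater-determinant algebra.

Determinants are stored as a pair of occupation bitmasks, one per spin
channel, over ``M`` spatial orbitals.  Spin orbitals use the *blocked*
ordering: spin-orbital index ``i`` (``0 <= i < M``) is the alpha spatial
orbital ``i`` and index ``M + i`` is the beta spatial orbital ``i``.  This
keeps each spin channel's occupancy vector contiguous, which the
occupancy-sampling machinery relies on.

Hamiltonian matrix elements between determinants are evaluated with the
Slater-Condon rules; the fermionic phase convention is: occupation masks are
ordered by ascending spin-orbital index and the sign of moving an electron
between two spin orbitals is ``(-1)**(number of occupied spin orbitals
strictly between them)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterator

import numpy as np

__all__ = [
    "SpinOrbitalBasis",
    "Determinant",
    "MolecularIntegrals",
    "excitation_degree",
    "slater_condon_element",
    "connected_determinants",
    "hartree_fock_determinant",
    "space_dimension",
    "singles_count",
    "cas_space",
]


@dataclass(frozen=True)
class SpinOrbitalBasis:
    """Spatial-orbital count and per-spin electron numbers.

    Parameters
    ----------
    M:
        Number of spatial orbitals; the qubit register has ``2 * M`` sites.
    n_alpha, n_beta:
        Electron count in the alpha / beta spin channel.
    """

    M: int
    n_alpha: int
    n_beta: int
    ordering: str = "blocked"

    def __post_init__(self) -> None:
        if not (0 <= self.n_alpha <= self.M and 0 <= self.n_beta <= self.M):
            raise ValueError(
                f"electron counts ({self.n_alpha},{self.n_beta}) incompatible "
                f"with M={self.M}"
            )
        if self.ordering != "blocked":
            raise ValueError("only the blocked spin-orbital ordering is supported")

    @property
    def n_spin_orbitals(self) -> int:
        return 2 * self.M

    @property
    def n_electrons(self) -> int:
        return self.n_alpha + self.n_beta


@dataclass(frozen=True, order=True)
class Determinant:
    """A Slater determinant as per-spin occupation bitmasks.

    Bit ``i`` of ``occ_alpha`` (resp. ``occ_beta``) is 1 iff alpha (beta)
    spatial orbital ``i`` is occupied.  Equality and ordering are purely
    bitwise, which gives the deterministic lexicographic tie-break used
    throughout the screening code.
    """

    occ_alpha: int
    occ_beta: int

    def popcounts(self) -> tuple[int, int]:
        return self.occ_alpha.bit_count(), self.occ_beta.bit_count()

    def spin_orbital_mask(self, M: int) -> int:
        """Combined occupation mask over 2M spin orbitals (blocked order)."""
        return self.occ_alpha | (self.occ_beta << M)

    def alpha_list(self) -> list[int]:
        return _bits(self.occ_alpha)

    def beta_list(self) -> list[int]:
        return _bits(self.occ_beta)

    def to_bitstring(self, M: int) -> str:
        """Qubit-0-first bitstring (leftmost char = spin orbital 0)."""
        mask = self.spin_orbital_mask(M)
        return "".join("1" if (mask >> q) & 1 else "0" for q in range(2 * M))

    @classmethod
    def from_bitstring(cls, s: str, M: int) -> "Determinant":
        if len(s) != 2 * M:
            raise ValueError(f"bitstring length {len(s)} != 2M = {2 * M}")
        mask = 0
        for q, ch in enumerate(s):
            if ch == "1":
                mask |= 1 << q
        return cls(mask & ((1 << M) - 1), mask >> M)

    def sector_valid(self, basis: SpinOrbitalBasis) -> bool:
        na, nb = self.popcounts()
        return na == basis.n_alpha and nb == basis.n_beta


def _bits(mask: int) -> list[int]:
    out = []
    while mask:
        low = mask & -mask
        out.append(low.bit_length() - 1)
        mask ^= low
    return out


@dataclass
class MolecularIntegrals:
    """Molecular one- and two-electron integrals in the spatial-orbital basis.

    ``h`` is the (M, M) core Hamiltonian, ``g`` the (M, M, M, M)
    electron-repulsion tensor in chemists' notation ``(pq|rs)`` with the
    standard 8-fold permutational symmetry.  ``e_core`` is a constant energy
    offset (nuclear repulsion plus any frozen-core contribution).
    """

    e_core: float
    h: np.ndarray
    g: np.ndarray
    symmetry_tol: float = 1e-8

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        M = self.h.shape[0]
        if self.h.shape != (M, M) or self.g.shape != (M, M, M, M):
            raise ValueError("integral arrays have inconsistent shapes")
        if not np.allclose(self.h, self.h.T, atol=self.symmetry_tol):
            raise ValueError("one-electron integrals are not symmetric")
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            if not np.allclose(
                self.g, np.transpose(self.g, perm), atol=self.symmetry_tol
            ):
                raise ValueError(
                    "two-electron integrals violate 8-fold permutational symmetry"
                )

    @property
    def M(self) -> int:
        return self.h.shape[0]


# ---------------------------------------------------------------------------
# counting


def space_dimension(M: int, n_alpha: int, n_beta: int) -> int:
    """Exact FCI space size ``C(M, n_alpha) * C(M, n_beta)``."""
    if min(M, n_alpha, n_beta) < 0:
        raise ValueError("arguments must be non-negative")
    return comb(M, n_alpha) * comb(M, n_beta)


def singles_count(basis: SpinOrbitalBasis) -> int:
    """Number of distinct single excitations S = Nα(M−Nα) + Nβ(M−Nβ)."""
    M, na, nb = basis.M, basis.n_alpha, basis.n_beta
    return na * (M - na) + nb * (M - nb)


def hartree_fock_determinant(basis: SpinOrbitalBasis) -> Determinant:
    """Aufbau determinant: lowest-index orbitals filled in each spin channel."""
    return Determinant((1 << basis.n_alpha) - 1, (1 << basis.n_beta) - 1)


def cas_space(
    basis: SpinOrbitalBasis, M_act: int, N_act: int
) -> Iterator[Determinant]:
    """Enumerate the complete-active-space determinants.

    The active window of ``M_act`` orbitals holds ``N_act`` electrons and is
    placed directly above a doubly occupied frozen core, i.e. symmetrically
    around the Fermi level under the file's orbital ordering.  Orbitals above
    the window stay empty.
    """
    n_total = basis.n_electrons
    if (n_total - N_act) % 2 != 0:
        raise ValueError("frozen-core electron count must be even")
    n_core = (n_total - N_act) // 2
    na_act = basis.n_alpha - n_core
    nb_act = basis.n_beta - n_core
    if n_core < 0 or n_core + M_act > basis.M:
        raise ValueError(f"active window ({M_act}o,{N_act}e) does not fit in basis")
    if not (0 <= na_act <= M_act and 0 <= nb_act <= M_act):
        raise ValueError("active electron counts infeasible for the window")
    core_mask = (1 << n_core) - 1
    window = range(n_core, n_core + M_act)
    for occ_a in itertools.combinations(window, na_act):
        mask_a = core_mask
        for i in occ_a:
            mask_a |= 1 << i
        for occ_b in itertools.combinations(window, nb_act):
            mask_b = core_mask
            for i in occ_b:
                mask_b |= 1 << i
            yield Determinant(mask_a, mask_b)


def fci_space(basis: SpinOrbitalBasis) -> Iterator[Determinant]:
    """Enumerate the full (Nα, Nβ) sector."""
    yield from cas_space(basis, basis.M, basis.n_electrons)


# ---------------------------------------------------------------------------
# excitation structure


def excitation_degree(d1: Determinant, d2: Determinant) -> int:
    """Number of electron moves relating two determinants (half Hamming)."""
    diff = (d1.occ_alpha ^ d2.occ_alpha).bit_count() + (
        d1.occ_beta ^ d2.occ_beta
    ).bit_count()
    return diff // 2


def _perm_sign(mask: int, i: int, a: int) -> int:
    """Sign of moving one electron i -> a within occupation ``mask``.

    Counts occupied spin orbitals strictly between the two indices; ``mask``
    is the occupation *before* the move (orbital i occupied, a empty).
    """
    lo, hi = (i, a) if i < a else (a, i)
    between = mask & (((1 << hi) - 1) ^ ((1 << (lo + 1)) - 1))
    return -1 if between.bit_count() & 1 else 1


def _excitation_info(
    m1: int, m2: int
) -> tuple[tuple[int, ...], tuple[int, ...], int]:
    """Holes, particles and fermionic sign relating two spin-orbital masks.

    Holes/particles are returned ascending; the sign corresponds to pairing
    the k-th hole with the k-th particle, applied sequentially.
    """
    holes = _bits(m1 & ~m2)
    parts = _bits(m2 & ~m1)
    sign = 1
    cur = m1
    for i, a in zip(holes, parts):
        sign *= _perm_sign(cur, i, a)
        cur = (cur ^ (1 << i)) | (1 << a)
    return tuple(holes), tuple(parts), sign


class _SpinOrbitalIntegrals:
    """Spin-orbital views of the spatial integrals under blocked ordering."""

    def __init__(self, ints: MolecularIntegrals):
        self.ints = ints
        self.M = ints.M

    def h(self, I: int, J: int) -> float:
        M = self.M
        if (I >= M) != (J >= M):
            return 0.0
        return self.ints.h[I % M, J % M]

    def g(self, I: int, J: int, K: int, L: int) -> float:
        """Chemists' (IJ|KL) over spin orbitals."""
        M = self.M
        if (I >= M) != (J >= M) or (K >= M) != (L >= M):
            return 0.0
        return self.ints.g[I % M, J % M, K % M, L % M]


def slater_condon_element(
    d1: Determinant, d2: Determinant, ints: MolecularIntegrals
) -> float:
    """Hamiltonian matrix element <d1|H|d2> via the Slater-Condon rules.

    Zero when the determinants differ by more than a double excitation; the
    diagonal includes the core-energy offset.
    """
    M = ints.M
    for mask in (d1.occ_alpha, d1.occ_beta, d2.occ_alpha, d2.occ_beta):
        if mask >> M:
            raise ValueError("determinant occupies an orbital outside the basis")
    so = _SpinOrbitalIntegrals(ints)
    m1 = d1.spin_orbital_mask(M)
    m2 = d2.spin_orbital_mask(M)
    degree = excitation_degree(d1, d2)
    if degree > 2:
        return 0.0

    if degree == 0:
        occ = _bits(m1)
        e = ints.e_core
        for I in occ:
            e += so.h(I, I)
        for idx, I in enumerate(occ):
            for J in occ[idx + 1 :]:
                e += so.g(I, I, J, J) - so.g(I, J, J, I)
        return e

    holes, parts, sign = _excitation_info(m1, m2)

    if degree == 1:
        (i,), (a,) = holes, parts
        e = so.h(i, a)
        for J in _bits(m1 & m2):
            e += so.g(i, a, J, J) - so.g(i, J, J, a)
        return sign * e

    (i, j), (a, b) = holes, parts
    return sign * (so.g(i, a, j, b) - so.g(i, b, j, a))


def connected_determinants(
    d: Determinant, basis: SpinOrbitalBasis
) -> Iterator[Determinant]:
    """All distinct sector-valid determinants one or two excitations from d.

    Each determinant is yielded exactly once and never equals ``d``.
    """
    occ_a, occ_b = d.alpha_list(), d.beta_list()
    M = basis.M
    vir_a = [i for i in range(M) if not (d.occ_alpha >> i) & 1]
    vir_b = [i for i in range(M) if not (d.occ_beta >> i) & 1]

    def move(mask: int, holes: tuple[int, ...], parts: tuple[int, ...]) -> int:
        for i in holes:
            mask ^= 1 << i
        for a in parts:
            mask |= 1 << a
        return mask

    # singles
    for i in occ_a:
        for a in vir_a:
            yield Determinant(move(d.occ_alpha, (i,), (a,)), d.occ_beta)
    for i in occ_b:
        for a in vir_b:
            yield Determinant(d.occ_alpha, move(d.occ_beta, (i,), (a,)))
    # same-spin doubles
    for i, j in itertools.combinations(occ_a, 2):
        for a, b in itertools.combinations(vir_a, 2):
            yield Determinant(move(d.occ_alpha, (i, j), (a, b)), d.occ_beta)
    for i, j in itertools.combinations(occ_b, 2):
        for a, b in itertools.combinations(vir_b, 2):
            yield Determinant(d.occ_alpha, move(d.occ_beta, (i, j), (a, b)))
    # opposite-spin doubles
    for i in occ_a:
        for a in vir_a:
            new_a = move(d.occ_alpha, (i,), (a,))
            for j in occ_b:
                for b in vir_b:
                    yield Determinant(new_a, move(d.occ_beta, (j,), (b,)))
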