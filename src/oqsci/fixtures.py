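"""Synthetic molecular-integral fixtures.

Small FCIDUMP-style instances (2-8 spatial orbitals) so every stage of the
toolkit is testable without external chemistry software or downloads.  The
``toy2`` instance uses textbook-scale minimal-basis H2-like integrals; the
others are parametric generators with exact integral symmetries built in.
"""

from __future__ import annotations

import numpy as np

from .determinants import MolecularIntegrals, SpinOrbitalBasis

__all__ = ["make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("toy2", "toy4", "hubbard_like", "random")


def _symmetrize_g(g: np.ndarray) -> np.ndarray:
    """Average over the 8-fold permutation group to enforce exact symmetry."""
    out = np.zeros_like(g)
    for perm in (
        (0, 1, 2, 3),
        (1, 0, 2, 3),
        (0, 1, 3, 2),
        (1, 0, 3, 2),
        (2, 3, 0, 1),
        (2, 3, 1, 0),
        (3, 2, 0, 1),
        (3, 2, 1, 0),
    ):
        out += np.transpose(g, perm)
    return out / 8.0


def _toy2() -> tuple[SpinOrbitalBasis, MolecularIntegrals]:
    """Minimal-basis H2-like two-orbital, two-electron instance.

    Integral magnitudes are at the scale of a stretched covalent bond in a
    minimal basis (energies in Hartree); the exact values are a fixed
    synthetic choice, not taken from any particular geometry.
    """
    h = np.array([[-1.2524, 0.0], [0.0, -0.4759]])
    g = np.zeros((2, 2, 2, 2))
    g[0, 0, 0, 0] = 0.6746
    g[1, 1, 1, 1] = 0.6975
    g[0, 0, 1, 1] = g[1, 1, 0, 0] = 0.6636
    for p, q in ((0, 1), (1, 0)):
        g[p, q, q, p] = g[p, q, p, q] = g[q, p, p, q] = g[q, p, q, p] = 0.1813
    basis = SpinOrbitalBasis(M=2, n_alpha=1, n_beta=1)
    return basis, MolecularIntegrals(e_core=0.7137, h=h, g=g)


def _hubbard_like(
    M: int, n_alpha: int, n_beta: int, t: float = 1.0, U: float = 2.0
) -> tuple[SpinOrbitalBasis, MolecularIntegrals]:
    """Open chain with nearest-neighbour hopping -t and on-site repulsion U."""
    h = np.zeros((M, M))
    for i in range(M - 1):
        h[i, i + 1] = h[i + 1, i] = -t
    g = np.zeros((M, M, M, M))
    for i in range(M):
        g[i, i, i, i] = U
    basis = SpinOrbitalBasis(M=M, n_alpha=n_alpha, n_beta=n_beta)
    return basis, MolecularIntegrals(e_core=0.0, h=h, g=g)


def _random(
    M: int, n_alpha: int, n_beta: int, seed: int, coupling: float = 0.1
) -> tuple[SpinOrbitalBasis, MolecularIntegrals]:
    """Decaying-magnitude random instance.

    Orbital energies ascend (aufbau-consistent), off-diagonal one-electron
    couplings and two-electron integrals decay exponentially with index
    distance so the instance is nontrivial but bounded, with the HF
    determinant retaining dominant ground-state overlap.
    """
    rng = np.random.default_rng(seed)
    diag = np.sort(rng.uniform(-2.0, -0.2, size=M))
    h = np.diag(diag)
    for p in range(M):
        for q in range(p + 1, M):
            val = coupling * rng.normal() * np.exp(-0.5 * (q - p))
            h[p, q] = h[q, p] = val
    g = coupling * rng.normal(size=(M, M, M, M))
    idx = np.arange(M)
    decay = np.exp(
        -0.5 * np.abs(idx[:, None, None, None] - idx[None, :, None, None])
        - 0.5 * np.abs(idx[None, None, :, None] - idx[None, None, None, :])
    )
    g = _symmetrize_g(g * decay)
    # a repulsive on-site contribution keeps the spectrum physically sane
    for i in range(M):
        g[i, i, i, i] = abs(g[i, i, i, i]) + 0.5
    basis = SpinOrbitalBasis(M=M, n_alpha=n_alpha, n_beta=n_beta)
    return basis, MolecularIntegrals(e_core=rng.uniform(0.0, 1.0), h=h, g=g)


def make_fixture(
    name: str,
    M: int = 4,
    n_alpha: int = 2,
    n_beta: int = 2,
    seed: int = 0,
) -> tuple[SpinOrbitalBasis, MolecularIntegrals]:
    """Build a named synthetic instance.

    ``toy2`` ignores the size arguments (it is fixed at M=2, 1 alpha + 1
    beta electron); ``toy4`` is the 4-orbital random instance at a fixed
    seed so it is stable across calls.
    """
    if name == "toy2":
        return _toy2()
    if name == "toy4":
        return _random(4, 2, 2, seed=1234)
    if name == "hubbard_like":
        return _hubbard_like(M, n_alpha, n_beta)
    if name == "random":
        return _random(M, n_alpha, n_beta, seed)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
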