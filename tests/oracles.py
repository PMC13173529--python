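"""Independent brute-force oracles used to validate the implementation.

Everything here is built from first principles with numpy only — explicit
creation/annihilation operator matrices in the full 2^(2M) occupation-number
basis — and deliberately shares no code with the package internals it
checks.  Mode q (blocked spin-orbital order: alpha block first) corresponds
to bit q of the basis-state index, and the fermionic sign of acting with a
ladder operator on mode q is (-1)**(number of occupied modes below q).
"""

from __future__ import annotations

import numpy as np


def annihilation_matrix(q: int, n_modes: int) -> np.ndarray:
    dim = 1 << n_modes
    a = np.zeros((dim, dim))
    low_mask = (1 << q) - 1
    for b in range(dim):
        if (b >> q) & 1:
            sign = (-1) ** bin(b & low_mask).count("1")
            a[b ^ (1 << q), b] = sign
    return a


def dense_hamiltonian(e_core: float, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Second-quantized H as a dense 2^(2M) x 2^(2M) matrix.

    H = E_core + sum_{sigma,pq} h_pq a+_{p sigma} a_{q sigma}
      + 1/2 sum_{sigma,tau,pqrs} (pq|rs) a+_{p sigma} a+_{r tau}
                                         a_{s tau} a_{q sigma}
    with (pq|rs) in chemists' notation and spin orbital (sigma, i) at mode
    sigma * M + i.
    """
    M = h.shape[0]
    n = 2 * M
    dim = 1 << n
    ann = [annihilation_matrix(q, n) for q in range(n)]
    cre = [a.T for a in ann]
    H = e_core * np.eye(dim)
    for sigma in (0, 1):
        off = sigma * M
        for p in range(M):
            for q in range(M):
                if h[p, q] != 0.0:
                    H += h[p, q] * cre[off + p] @ ann[off + q]
    for sigma in (0, 1):
        for tau in (0, 1):
            so, to = sigma * M, tau * M
            for p in range(M):
                for q in range(M):
                    for r in range(M):
                        for s in range(M):
                            val = g[p, q, r, s]
                            if val != 0.0:
                                H += (
                                    0.5
                                    * val
                                    * cre[so + p]
                                    @ cre[to + r]
                                    @ ann[to + s]
                                    @ ann[so + q]
                                )
    return H


def sector_indices(M: int, n_alpha: int, n_beta: int) -> list[int]:
    """Basis-state indices with the given per-spin particle numbers."""
    out = []
    mask = (1 << M) - 1
    for b in range(1 << (2 * M)):
        if (
            bin(b & mask).count("1") == n_alpha
            and bin(b >> M).count("1") == n_beta
        ):
            out.append(b)
    return out


def sector_hamiltonian(
    e_core: float, h: np.ndarray, g: np.ndarray, n_alpha: int, n_beta: int
) -> tuple[np.ndarray, list[int]]:
    M = h.shape[0]
    H = dense_hamiltonian(e_core, h, g)
    idx = sector_indices(M, n_alpha, n_beta)
    return H[np.ix_(idx, idx)], idx
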