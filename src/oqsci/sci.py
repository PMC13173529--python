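"""Subspace CI: interaction matrices, diagonalization, and Heatbath CI.

A configuration subspace is an ordered, duplicate-free determinant list D.
Projecting the Hamiltonian onto D gives the K x K interaction matrix
H_kl = <Phi_k|H|Phi_l>, whose lowest eigenpairs define the variational
subspace wavefunction.  Heatbath CI (HCI) grows D iteratively, retaining
external determinants Phi_l for which |H_kl v_k| > delta for some member
Phi_k, then halves delta until a dimension cap is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .determinants import (
    Determinant,
    MolecularIntegrals,
    SpinOrbitalBasis,
    connected_determinants,
    excitation_degree,
    hartree_fock_determinant,
    slater_condon_element,
)

__all__ = [
    "SubspaceWavefunction",
    "build_interaction_matrix",
    "solve_subspace",
    "hci_expand",
    "hci_run",
    "collate_neighborhood",
]

#: subspace size above which the iterative sparse eigensolver is used
DENSE_CUTOFF = 400


@dataclass
class SubspaceWavefunction:
    """An eigenstate |Psi_j> = sum_k v_k |Phi_k> of the projected Hamiltonian."""

    dets: list[Determinant]
    coeffs: np.ndarray
    energy: float
    root_index: int = 0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if len(self.dets) != self.coeffs.shape[0]:
            raise ValueError("determinant list and coefficient vector disagree")
        norm = np.linalg.norm(self.coeffs)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"coefficients are not normalized (|v| = {norm})")

    def coefficient_map(self) -> dict[Determinant, float]:
        return dict(zip(self.dets, self.coeffs))


def build_interaction_matrix(
    D: list[Determinant], ints: MolecularIntegrals
) -> sp.csr_matrix:
    """Sparse symmetric matrix of Slater-Condon elements over D."""
    if len(set(D)) != len(D):
        raise ValueError("determinant list contains duplicates")
    K = len(D)
    rows, cols, vals = [], [], []
    for k in range(K):
        diag = slater_condon_element(D[k], D[k], ints)
        rows.append(k)
        cols.append(k)
        vals.append(diag)
        for l in range(k + 1, K):
            if excitation_degree(D[k], D[l]) > 2:
                continue
            el = slater_condon_element(D[k], D[l], ints)
            if el != 0.0:
                rows += [k, l]
                cols += [l, k]
                vals += [el, el]
    return sp.csr_matrix((vals, (rows, cols)), shape=(K, K))


def solve_subspace(
    D: list[Determinant],
    ints: MolecularIntegrals,
    n_roots: int = 1,
    dense_cutoff: int = DENSE_CUTOFF,
) -> list[SubspaceWavefunction]:
    """Lowest ``n_roots`` eigenpairs of the interaction matrix over D.

    Dense diagonalization below ``dense_cutoff``; Lanczos (``eigsh``) above.
    The sign convention fixes the largest-magnitude coefficient positive.
    """
    K = len(D)
    if not 1 <= n_roots <= K:
        raise ValueError(f"need 1 <= n_roots <= K, got {n_roots} with K={K}")
    H = build_interaction_matrix(D, ints)
    if K <= dense_cutoff or n_roots >= K - 1:
        w, V = np.linalg.eigh(H.toarray())
    else:
        try:
            w, V = spla.eigsh(H, k=n_roots, which="SA")
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError("sparse eigensolver failed to converge") from exc
        order = np.argsort(w)
        w, V = w[order], V[:, order]
    out = []
    for j in range(n_roots):
        v = V[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        out.append(
            SubspaceWavefunction(list(D), v, float(w[j]), root_index=j)
        )
    return out


def hci_expand(
    psi: SubspaceWavefunction, delta: float, ints: MolecularIntegrals
) -> list[Determinant]:
    """One Heatbath screening pass: D ∪ {Phi_l : |H_kl v_k| > delta}.

    The screening uses matrix-element magnitudes only; the result is the
    input list followed by the admitted external determinants in
    lexicographic order.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    M = ints.M
    basis = _basis_of(psi.dets[0], M)
    members = set(psi.dets)
    admitted: set[Determinant] = set()
    for phi_k, v_k in zip(psi.dets, psi.coeffs):
        bound = abs(v_k)
        if bound == 0.0:
            continue
        for phi_l in connected_determinants(phi_k, basis):
            if phi_l in members or phi_l in admitted:
                continue
            if abs(slater_condon_element(phi_k, phi_l, ints)) * bound > delta:
                admitted.add(phi_l)
    return list(psi.dets) + sorted(admitted)


def _basis_of(d: Determinant, M: int) -> SpinOrbitalBasis:
    na, nb = d.popcounts()
    return SpinOrbitalBasis(M=M, n_alpha=na, n_beta=nb)


@dataclass
class HciLevel:
    """Per-delta-level trace entry of an HCI run."""

    delta: float
    size: int
    energy: float


def hci_run(
    ints: MolecularIntegrals,
    basis: SpinOrbitalBasis,
    delta0: float = 0.1,
    D_cap: int = 10_000,
    delta_min: float = 1e-12,
    n_roots: int = 1,
) -> tuple[SubspaceWavefunction, list[HciLevel]]:
    """Full HCI with the delta-halving schedule.

    Starting from {HF} with delta = delta0, each level alternates screening
    (``hci_expand``) and diagonalization until no new determinant passes the
    criterion, then delta is halved.  The run stops when an expansion would
    push |D| beyond ``D_cap`` or delta underflows ``delta_min``.
    """
    if delta0 <= 0 or D_cap < 1:
        raise ValueError("delta0 must be positive and D_cap >= 1")
    D = [hartree_fock_determinant(basis)]
    psi = solve_subspace(D, ints, n_roots=1)[0]
    trace = [HciLevel(delta=float("inf"), size=1, energy=psi.energy)]
    delta = delta0
    while delta >= delta_min:
        while True:
            expanded = hci_expand(psi, delta, ints)
            if len(expanded) == len(psi.dets):
                break
            if len(expanded) > D_cap:
                return psi, trace
            psi = solve_subspace(expanded, ints, n_roots=1)[0]
            trace.append(HciLevel(delta=delta, size=len(expanded), energy=psi.energy))
        if len(psi.dets) >= D_cap:
            break
        delta /= 2.0
    return psi, trace


def collate_neighborhood(
    subspaces: list[SubspaceWavefunction], D_cap: int
) -> list[Determinant]:
    """Deduplicated union of several subspaces, truncated to ``D_cap``.

    Each determinant is ranked by the largest |coefficient| it attains in any
    source subspace; ties break lexicographically on the determinant.
    """
    best: dict[Determinant, float] = {}
    for psi in subspaces:
        for d, v in zip(psi.dets, psi.coeffs):
            mag = abs(float(v))
            if mag > best.get(d, -1.0):
                best[d] = mag
    ranked = sorted(best.items(), key=lambda item: (-item[1], item[0]))
    return [d for d, _ in ranked[:D_cap]]


# ---------------------------------------------------------------------------
# plain-text subspace dumps


def dump_subspace(psi: SubspaceWavefunction, M: int, path) -> None:
    """Write determinants as (alpha, beta) hex masks plus a coefficient column."""
    from pathlib import Path

    lines = [f"# M={M} K={len(psi.dets)} energy={psi.energy:.12f}"]
    for d, v in zip(psi.dets, psi.coeffs):
        lines.append(f"{d.occ_alpha:x} {d.occ_beta:x} {v: .16e}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_subspace(path) -> tuple[list[Determinant], np.ndarray, float, int]:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    header = dict(
        tok.split("=") for tok in lines[0].lstrip("# ").split() if "=" in tok
    )
    dets, coeffs = [], []
    for line in lines[1:]:
        if not line.strip():
            continue
        a, b, v = line.split()
        dets.append(Determinant(int(a, 16), int(b, 16)))
        coeffs.append(float(v))
    return dets, np.array(coeffs), float(header["energy"]), int(header["M"])
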