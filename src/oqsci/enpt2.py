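"""Epstein-Nesbet second-order perturbation theory and PT2 -> 0 extrapolation.

The model Hamiltonian is the full Hamiltonian block inside the configuration
subspace D plus only diagonal elements outside it; the subspace eigenstates
are then exact zeroth-order states and the second-order correction is

    e_PT2 = - sum_{Phi_k not in D} |<Phi_k|V|Psi>|^2 / (<Phi_k|H|Phi_k> - e)

with <Phi_k|V|Psi> = sum_{Phi_l in D} H_kl v_l.  For the ground state every
summand is non-positive, and the correction vanishes as D approaches the
full CI space — the basis of the linear extrapolation of subspace energy
against PT2 correction to the zero-correction (FCI) point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .determinants import (
    MolecularIntegrals,
    SpinOrbitalBasis,
    connected_determinants,
    slater_condon_element,
)
from .sci import SubspaceWavefunction

__all__ = ["PT2Record", "enpt2_correction", "extrapolate_to_zero"]


@dataclass(frozen=True)
class PT2Record:
    """One (subspace energy, PT2 correction) checkpoint."""

    qsci_energy: float
    pt2: float
    subspace_size: int

    @property
    def total(self) -> float:
        return self.qsci_energy + self.pt2


def enpt2_correction(
    psi: SubspaceWavefunction,
    ints: MolecularIntegrals,
    basis: SpinOrbitalBasis,
    denom_tol: float = 1e-12,
) -> float:
    """Deterministic Epstein-Nesbet second-order correction for ``psi``.

    External determinants are enumerated by walking singles/doubles from
    every member of D and accumulating perturber amplitudes in a hash-keyed
    accumulator, so memory is bounded by the connected external space.
    """
    members = set(psi.dets)
    amplitudes: dict = {}
    for phi_l, v_l in zip(psi.dets, psi.coeffs):
        if v_l == 0.0:
            continue
        for phi_k in connected_determinants(phi_l, basis):
            if phi_k in members:
                continue
            el = slater_condon_element(phi_k, phi_l, ints)
            if el != 0.0:
                amplitudes[phi_k] = amplitudes.get(phi_k, 0.0) + el * v_l
    correction = 0.0
    for phi_k, amp in amplitudes.items():
        denom = slater_condon_element(phi_k, phi_k, ints) - psi.energy
        if abs(denom) < denom_tol:
            raise ZeroDivisionError(
                f"vanishing Epstein-Nesbet denominator for determinant "
                f"(alpha={phi_k.occ_alpha:#x}, beta={phi_k.occ_beta:#x})"
            )
        correction -= amp * amp / denom
    return correction


def extrapolate_to_zero(
    records: list[PT2Record],
) -> tuple[float, float, float]:
    """Extrapolate the subspace energy to the PT2 = 0 point by OLS.

    Fits ``qsci_energy = intercept + slope * pt2`` over the records and
    returns ``(intercept, slope, r_squared)``; the intercept estimates the
    FCI energy.  Regressing the correlation energy instead of the total
    energy shifts intercept and data identically, so the total-energy fit is
    used directly.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to extrapolate")
    x = np.array([r.pt2 for r in records], dtype=float)
    y = np.array([r.qsci_energy for r in records], dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("records share a single PT2 abscissa; cannot fit")
    A = np.column_stack([np.ones_like(x), x])
    (intercept, slope), res, _, _ = np.linalg.lstsq(A, y, rcond=None)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0
    else:
        ss_res = float(np.sum((y - A @ np.array([intercept, slope])) ** 2))
        r2 = 1.0 - ss_res / ss_tot
    return float(intercept), float(slope), r2
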