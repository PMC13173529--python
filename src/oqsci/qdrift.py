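"""Stochastic (qDRIFT) real-time evolution emulated by statevector simulation.

qDRIFT compiles e^{-iHt} for H = sum_j h_j sigma_j by drawing N Pauli terms
i.i.d. with probability p_j = |h_j| / lambda (lambda the l1 norm of the
non-identity part) and appending the fixed-angle exponential
e^{-i lambda t sgn(h_j) sigma_j / N} for each draw.  The segment count for
target diamond-norm precision epsilon is N = ceil(2 lambda^2 t^2 / epsilon),
decoupling circuit depth from the number of Hamiltonian terms.

The rotation convention is exactly the exponent above — the full angle
theta = lambda t sgn(h_j) / N multiplies sigma_j with no extra 1/2 — applied
through the identity e^{-i theta sigma} = cos(theta) I - i sin(theta) sigma.
Identity terms contribute only a global phase; they are excluded from
sampling and their coefficient tracked as an energy offset.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .determinants import Determinant
from .measurements import MeasurementSet
from .pauli import PauliHamiltonian, masks_to_string, pauli_action

__all__ = [
    "QdriftSequence",
    "qdrift_sample_count",
    "sample_qdrift_sequence",
    "propagate_statevector",
    "sample_measurements",
    "apply_readout_noise",
    "run_time_grid",
]

#: statevector simulation refuses registers above this many qubits
DEFAULT_QUBIT_CAP = 16


@dataclass
class QdriftSequence:
    """One realization of the stochastic propagator.

    ``rotations`` is an ordered list of ((x, z) Pauli masks, angle); every
    angle has magnitude lambda * t / N with the sign of the drawn
    coefficient.
    """

    rotations: list[tuple[tuple[int, int], float]]
    t: float
    n_segments: int
    n_qubits: int
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.rotations)

    def to_gate_list(self) -> list[dict]:
        """Generic JSON-able gate list [{'pauli': word, 'angle': theta}, ...]."""
        return [
            {"pauli": masks_to_string(x, z, self.n_qubits), "angle": angle}
            for (x, z), angle in self.rotations
        ]

    def dump_json(self, path: str | Path) -> Path:
        out = Path(path)
        out.write_text(json.dumps(self.to_gate_list(), indent=1))
        return out


def qdrift_sample_count(lambda_norm: float, t: float, epsilon: float) -> int:
    """Segment count N = ceil(2 lambda^2 t^2 / epsilon)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if t < 0:
        raise ValueError("evolution time must be non-negative")
    return math.ceil(2.0 * lambda_norm**2 * t**2 / epsilon)


def sample_qdrift_sequence(
    H: PauliHamiltonian, t: float, epsilon: float, seed: int | np.random.SeedSequence
) -> QdriftSequence:
    """Draw one qDRIFT realization of e^{-iHt}; reproducible given the seed."""
    offset, sampled = H.split_identity()
    if len(sampled) == 0:
        raise ValueError("Hamiltonian has no non-identity terms to sample")
    keys = sorted(sampled.coeffs)
    coeffs = np.array([sampled.coeffs[k] for k in keys])
    lam = float(np.abs(coeffs).sum())
    N = qdrift_sample_count(lam, t, epsilon)
    rng = np.random.default_rng(seed)
    rotations: list[tuple[tuple[int, int], float]] = []
    if N > 0:
        p = np.abs(coeffs) / lam
        draws = rng.choice(len(keys), size=N, p=p)
        base_angle = lam * t / N
        for j in draws:
            rotations.append((keys[j], base_angle * math.copysign(1.0, coeffs[j])))
    seed_repr = seed if isinstance(seed, int) else None
    return QdriftSequence(
        rotations=rotations, t=t, n_segments=N, n_qubits=H.n_qubits, seed=seed_repr
    )


def basis_state(ref: Determinant, n_qubits: int) -> np.ndarray:
    M = n_qubits // 2
    state = np.zeros(1 << n_qubits, dtype=complex)
    state[ref.spin_orbital_mask(M)] = 1.0
    return state


def propagate_statevector(
    ref: Determinant, seq: QdriftSequence, qubit_cap: int = DEFAULT_QUBIT_CAP
) -> np.ndarray:
    """Apply the sequence's Pauli rotations in order to |ref>.

    Each rotation is e^{-i theta sigma} = cos(theta) I - i sin(theta) sigma,
    with sigma applied through bit masks and phase tables, never as a dense
    2^n matrix.
    """
    n = seq.n_qubits
    if n > qubit_cap:
        raise ValueError(f"{n} qubits exceeds the statevector cap of {qubit_cap}")
    state = basis_state(ref, n)
    idx = np.arange(1 << n)
    for (x, z), theta in seq.rotations:
        flipped, phase = pauli_action(x, z, idx)
        sigma_state = np.empty_like(state)
        sigma_state[flipped] = phase * state
        state = math.cos(theta) * state - 1j * math.sin(theta) * sigma_state
    return state


def sample_measurements(
    state: np.ndarray,
    shots: int,
    seed: int | np.random.SeedSequence,
    provenance: dict | None = None,
) -> MeasurementSet:
    """Draw ``shots`` i.i.d. computational-basis outcomes from |amplitude|^2."""
    probs = np.abs(state) ** 2
    total = probs.sum()
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"state is not normalized (sum |a|^2 = {total})")
    n_qubits = int(np.log2(state.shape[0]))
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, probs / total)
    counts: dict[str, int] = {}
    for index in np.nonzero(draws)[0]:
        bits = "".join("1" if (index >> q) & 1 else "0" for q in range(n_qubits))
        counts[bits] = int(draws[index])
    return MeasurementSet(counts, n_qubits, provenance=provenance or {})


def apply_readout_noise(
    ms: MeasurementSet, p_flip: float, seed: int | np.random.SeedSequence
) -> MeasurementSet:
    """Flip every bit of every shot independently with probability p_flip.

    A crude readout-error fixture: corrupted shots generally leave the
    correct particle sector, which is what the rectification stage of the
    sampling loop must tolerate.
    """
    if not 0.0 <= p_flip <= 1.0:
        raise ValueError("p_flip must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    noisy: dict[str, int] = {}
    for bits, count in sorted(ms.counts.items()):
        base = np.array([ch == "1" for ch in bits])
        flips = rng.random((count, ms.n_qubits)) < p_flip
        for row in flips:
            out = base ^ row
            key = "".join("1" if b else "0" for b in out)
            noisy[key] = noisy.get(key, 0) + 1
    return MeasurementSet(noisy, ms.n_qubits, dict(ms.provenance))


def run_time_grid(
    H: PauliHamiltonian,
    ref: Determinant,
    tau: float,
    K: int,
    n_instances: int,
    shots: int,
    epsilon: float,
    seed: int,
    qubit_cap: int = DEFAULT_QUBIT_CAP,
) -> list[MeasurementSet]:
    """Collect measurement sets at t = k*tau for k = 1..K.

    At every time step, ``n_instances`` independent qDRIFT realizations are
    each propagated and measured with ``shots`` shots; the per-step sets are
    aggregated.  The whole grid is a pure function of (inputs, seed).
    """
    root = np.random.SeedSequence(seed)
    step_seeds = root.spawn(K)
    grids: list[MeasurementSet] = []
    for k in range(1, K + 1):
        inst_seeds = step_seeds[k - 1].spawn(2 * n_instances)
        step = MeasurementSet(
            {},
            H.n_qubits,
            provenance={"time_index": k, "t": k * tau, "seed": seed},
        )
        for inst in range(n_instances):
            seq = sample_qdrift_sequence(H, k * tau, epsilon, inst_seeds[2 * inst])
            state = propagate_statevector(ref, seq, qubit_cap=qubit_cap)
            ms = sample_measurements(
                state,
                shots,
                inst_seeds[2 * inst + 1],
                provenance={"time_index": k, "instance": inst, "seed": seed},
            )
            step = step.merge(ms)
        grids.append(step)
    return grids
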