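"""Occupancy-guided configuration sampling and the QSCI driver loop.

This is the heart of the package.  Measured bitstrings from time-evolved
states are distilled into a per-spin-orbital occupancy distribution

    P_occ^(sigma)(chi_i = 1)  ∝  (1/N_shots) sum_k <b_k| a†_{sigma,i} a_{sigma,i} |b_k>

(the shot-averaged bit value, since under Jordan-Wigner the number operator
reads the computational-basis bit directly).  Measured strings that already
carry the correct per-spin electron counts are *rectified* — admitted to the
configuration pool as determinants — while every shot, valid or not,
contributes to the occupancy statistics.

The distribution then biases single/double excitation sampling away from
dominant configurations Phi_k of the current subspace wavefunction: occupied
indices are drawn with the normalized occupancy weights restricted to
orbitals occupied in Phi_k, virtual indices with weights proportional to
(1 - mean occupancy) restricted to orbitals empty in Phi_k (each restriction
renormalized, which makes every channel a proper distribution).  Sampled
candidates Phi_l are ranked by the screening metric

    d(Phi_l) = |H_kl| * P(Phi_l)

and the best scorers are appended to the subspace, which is re-diagonalized
each round.  Candidates are sector-valid by construction, so readout noise
can degrade only the *quality* of the sampling prior, never the particle
sector of the variational space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .determinants import (
    Determinant,
    MolecularIntegrals,
    SpinOrbitalBasis,
    hartree_fock_determinant,
    slater_condon_element,
)
from .enpt2 import PT2Record, enpt2_correction
from .measurements import MeasurementSet
from .sci import SubspaceWavefunction, solve_subspace

logger = logging.getLogger(__name__)

__all__ = [
    "OccupancyDistribution",
    "QSCIConfig",
    "RoundTrace",
    "occupancy_distribution",
    "transform_weights",
    "rectify_measurements",
    "sample_excitations",
    "screen_candidates",
    "qsci_run",
]

_CHANNELS = ("single_a", "single_b", "double_aa", "double_bb", "double_ab")


@dataclass
class OccupancyDistribution:
    """Per-spin occupancy statistics of a measurement set.

    ``mean_occ`` holds the raw shot-averaged bit values (rows: alpha, beta;
    columns: spatial orbitals), each entry in [0, 1].  ``norm_occ`` is the
    per-spin normalized selection weight used for occupied-index draws.
    """

    mean_occ: np.ndarray
    norm_occ: np.ndarray

    @classmethod
    def from_mean(cls, mean_occ: np.ndarray) -> "OccupancyDistribution":
        mean_occ = np.asarray(mean_occ, dtype=float)
        if np.any(mean_occ < -1e-12) or np.any(mean_occ > 1 + 1e-12):
            raise ValueError("mean occupancies must lie in [0, 1]")
        norm = np.zeros_like(mean_occ)
        for s in range(2):
            total = mean_occ[s].sum()
            if total > 0:
                norm[s] = mean_occ[s] / total
        return cls(mean_occ=mean_occ, norm_occ=norm)


def occupancy_distribution(
    ms: MeasurementSet, basis: SpinOrbitalBasis
) -> OccupancyDistribution:
    """Shot-weighted mean occupancy of every spin orbital (blocked order)."""
    if ms.n_shots == 0:
        raise ValueError("measurement set has zero shots")
    if ms.n_qubits != basis.n_spin_orbitals:
        raise ValueError(
            f"bitstring length {ms.n_qubits} != 2M = {basis.n_spin_orbitals}"
        )
    M = basis.M
    totals = np.zeros(2 * M)
    for bits, count in ms.counts.items():
        totals += count * np.frombuffer(bits.encode(), dtype=np.uint8).astype(
            float
        ) - count * ord("0")
    mean = (totals / ms.n_shots).reshape(2, M)
    return OccupancyDistribution.from_mean(mean)


def transform_weights(
    dist: OccupancyDistribution, mode: str = "identity"
) -> OccupancyDistribution:
    """Optionally reshape the sampling prior.

    ``fractional_boost`` maps the mean occupancy n -> n(1-n) before
    renormalization, suppressing fully occupied/empty orbitals in favour of
    fractionally occupied ones where delocalization lives.
    """
    if mode == "identity":
        return dist
    if mode == "fractional_boost":
        return OccupancyDistribution.from_mean(dist.mean_occ * (1.0 - dist.mean_occ))
    raise ValueError(f"unknown transform mode {mode!r}")


def rectify_measurements(
    ms: MeasurementSet, basis: SpinOrbitalBasis
) -> set[Determinant]:
    """Distinct measured bitstrings with the correct per-spin popcounts."""
    out: set[Determinant] = set()
    for bits in ms.counts:
        d = Determinant.from_bitstring(bits, basis.M)
        if d.sector_valid(basis):
            out.add(d)
    return out


def _restricted_weights(weights: np.ndarray, indices: list[int]) -> np.ndarray | None:
    w = weights[indices]
    total = w.sum()
    if total <= 0.0:
        return None
    return w / total


def sample_excitations(
    phi_k: Determinant,
    dist: OccupancyDistribution,
    n_samples: int,
    seed: int | np.random.Generator,
    channel_probs: dict[str, float] | None = None,
) -> dict[Determinant, float]:
    """Draw occupancy-biased single/double excitations away from ``phi_k``.

    Each draw first picks a channel (single alpha/beta, same-spin double,
    opposite-spin double) — uniformly over the channels whose index pools
    have positive weight unless ``channel_probs`` overrides the mixture —
    then the excitation indices, occupied from the normalized occupancy
    weights and virtual from the complementary (1 - mean) weights, each
    restricted to ``phi_k`` and renormalized.  Candidates are returned
    merged, keeping the largest recorded product probability per distinct
    determinant; every candidate is sector-valid by construction.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    M = dist.mean_occ.shape[1]
    occ_lists = [phi_k.alpha_list(), phi_k.beta_list()]
    vir_lists = [
        [i for i in range(M) if not (phi_k.occ_alpha >> i) & 1],
        [i for i in range(M) if not (phi_k.occ_beta >> i) & 1],
    ]
    occ_w = [
        _restricted_weights(dist.norm_occ[s], occ_lists[s]) for s in range(2)
    ]
    vir_w = [
        _restricted_weights(1.0 - dist.mean_occ[s], vir_lists[s]) for s in range(2)
    ]

    def channel_ok(name: str) -> bool:
        if name == "single_a":
            return occ_w[0] is not None and vir_w[0] is not None
        if name == "single_b":
            return occ_w[1] is not None and vir_w[1] is not None
        if name == "double_aa":
            return (
                occ_w[0] is not None
                and vir_w[0] is not None
                and np.count_nonzero(occ_w[0]) >= 2
                and np.count_nonzero(vir_w[0]) >= 2
            )
        if name == "double_bb":
            return (
                occ_w[1] is not None
                and vir_w[1] is not None
                and np.count_nonzero(occ_w[1]) >= 2
                and np.count_nonzero(vir_w[1]) >= 2
            )
        return all(w is not None for w in occ_w + vir_w)

    available = [c for c in _CHANNELS if channel_ok(c)]
    skipped = set(_CHANNELS) - set(available)
    if skipped:
        logger.debug("channels skipped for lack of weighted orbitals: %s", skipped)
    if not available:
        return {}
    if channel_probs:
        p = np.array([channel_probs.get(c, 0.0) for c in available])
        if p.sum() <= 0:
            return {}
        p = p / p.sum()
    else:
        p = np.full(len(available), 1.0 / len(available))

    def draw_one(weights: np.ndarray, pool: list[int]) -> tuple[int, float]:
        j = rng.choice(len(pool), p=weights)
        return pool[j], float(weights[j])

    def draw_two(weights: np.ndarray, pool: list[int]) -> tuple[int, int, float]:
        # distinct pair; recorded probability is the printed product of the
        # two marginal weights
        j1 = rng.choice(len(pool), p=weights)
        rest = weights.copy()
        rest[j1] = 0.0
        rest = rest / rest.sum()
        j2 = rng.choice(len(pool), p=rest)
        return pool[j1], pool[j2], float(weights[j1] * weights[j2])

    candidates: dict[Determinant, float] = {}
    channels = rng.choice(len(available), size=n_samples, p=p)
    for ch_idx in channels:
        name = available[ch_idx]
        if name in ("single_a", "single_b"):
            s = 0 if name == "single_a" else 1
            pidx, wp = draw_one(occ_w[s], occ_lists[s])
            qidx, wq = draw_one(vir_w[s], vir_lists[s])
            prob = wp * wq
            masks = [phi_k.occ_alpha, phi_k.occ_beta]
            masks[s] = masks[s] ^ (1 << pidx) | (1 << qidx)
            cand = Determinant(masks[0], masks[1])
        elif name in ("double_aa", "double_bb"):
            s = 0 if name == "double_aa" else 1
            pidx, qidx, w_occ = draw_two(occ_w[s], occ_lists[s])
            ridx, sidx, w_vir = draw_two(vir_w[s], vir_lists[s])
            prob = w_occ * w_vir
            masks = [phi_k.occ_alpha, phi_k.occ_beta]
            masks[s] = (
                masks[s] ^ (1 << pidx) ^ (1 << qidx) | (1 << ridx) | (1 << sidx)
            )
            cand = Determinant(masks[0], masks[1])
        else:  # opposite-spin double
            pidx, wp = draw_one(occ_w[0], occ_lists[0])
            qidx, wq = draw_one(occ_w[1], occ_lists[1])
            ridx, wr = draw_one(vir_w[0], vir_lists[0])
            sidx, ws = draw_one(vir_w[1], vir_lists[1])
            prob = wp * wq * wr * ws
            cand = Determinant(
                phi_k.occ_alpha ^ (1 << pidx) | (1 << ridx),
                phi_k.occ_beta ^ (1 << qidx) | (1 << sidx),
            )
        if prob > candidates.get(cand, -1.0):
            candidates[cand] = prob
    return candidates


def screen_candidates(
    candidates: dict[Determinant, float],
    phi_k: Determinant,
    ints: MolecularIntegrals,
) -> list[tuple[Determinant, float, float]]:
    """Score candidates with d(Phi_l) = |H_kl| * P(Phi_l).

    Returns (determinant, score, probability) triples sorted by descending
    score with a lexicographic determinant tie-break.
    """
    scored = []
    for cand, prob in candidates.items():
        score = abs(slater_condon_element(phi_k, cand, ints)) * prob
        scored.append((cand, score, prob))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


@dataclass
class QSCIConfig:
    """Hyperparameters of the occupancy-guided QSCI loop.

    Defaults follow the reference hardware-scale settings: subspace cap
    5e4, 10 sampling rounds per measurement set, 100 samples per screened
    configuration, screening threshold 1e-2 on |v_k|, wavefunction pruning
    threshold 1e-5.  ``append_per_round`` defaults to 10x the number of
    dominant configurations in the round.
    """

    D_max: int = 50_000
    N_rounds: int = 10
    N_samples: int = 100
    eps_screen: float = 1e-2
    eps_wf: float = 1e-5
    append_per_round: int | None = None
    seed: int = 0
    channel_probs: dict[str, float] | None = None
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.D_max < 1:
            raise ValueError("D_max must be >= 1")
        if self.eps_screen < 0 or self.eps_wf <= 0:
            raise ValueError("thresholds must be positive")
        if self.transform not in ("identity", "fractional_boost"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class RoundTrace:
    """One row of the per-round audit trace."""

    step: int
    round: int
    size: int
    energy: float
    pt2: float | None = None


def qsci_run(
    ints: MolecularIntegrals,
    basis: SpinOrbitalBasis,
    measurements: list[MeasurementSet],
    cfg: QSCIConfig,
) -> tuple[SubspaceWavefunction, list[PT2Record], list[RoundTrace]]:
    """Run the full occupancy-guided QSCI loop over a time grid.

    The subspace is seeded with the Hartree-Fock determinant plus the first
    step's rectified measurements.  For each time step's measurement set,
    ``N_rounds`` rounds each (1) diagonalize the current subspace, (2) prune
    members with |v| below ``eps_wf`` (HF is never pruned), (3) sample and
    screen excitations away from every dominant configuration
    (|v_k| > eps_screen), appending the top scorers, and (4) admit the
    step's rectified determinants.  Appending stops at ``D_max``.  After
    each step the subspace is re-solved and an Epstein-Nesbet correction is
    recorded, yielding the PT2Record sequence for extrapolation.
    """
    if not measurements:
        raise ValueError("at least one measurement set is required")
    for ms in measurements:
        if ms.n_qubits != basis.n_spin_orbitals:
            raise ValueError("measurement sets have the wrong qubit count")
    hf = hartree_fock_determinant(basis)
    rectified = [sorted(rectify_measurements(ms, basis)) for ms in measurements]
    D: list[Determinant] = [hf]
    members = {hf}
    for d in rectified[0]:
        if len(D) >= cfg.D_max:
            break
        if d not in members:
            D.append(d)
            members.add(d)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    trace: list[RoundTrace] = []
    records: list[PT2Record] = []
    psi = solve_subspace(D, ints)[0]

    for step_idx, ms in enumerate(measurements):
        dist = transform_weights(
            occupancy_distribution(ms, basis), cfg.transform
        )
        for rnd in range(cfg.N_rounds):
            psi = solve_subspace(D, ints)[0]
            coeff = psi.coefficient_map()
            # prune weakly weighted members (never HF)
            kept = [d for d in D if d == hf or abs(coeff[d]) >= cfg.eps_wf]
            if len(kept) != len(D):
                D = kept
                members = set(D)
            dominant = [d for d in D if abs(coeff.get(d, 0.0)) > cfg.eps_screen]
            pool: dict[Determinant, float] = {}
            for phi_k in dominant:
                cands = sample_excitations(
                    phi_k, dist, cfg.N_samples, rng, cfg.channel_probs
                )
                for cand, score, _ in screen_candidates(cands, phi_k, ints):
                    if cand in members or score <= 0.0:
                        continue
                    if score > pool.get(cand, -1.0):
                        pool[cand] = score
            budget = (
                cfg.append_per_round
                if cfg.append_per_round is not None
                else 10 * max(len(dominant), 1)
            )
            ranked = sorted(pool.items(), key=lambda item: (-item[1], item[0]))
            for cand, _ in ranked[:budget]:
                if len(D) >= cfg.D_max:
                    break
                D.append(cand)
                members.add(cand)
            for d in rectified[step_idx]:
                if len(D) >= cfg.D_max:
                    break
                if d not in members:
                    D.append(d)
                    members.add(d)
            trace.append(
                RoundTrace(step=step_idx, round=rnd, size=len(D), energy=psi.energy)
            )
        psi = solve_subspace(D, ints)[0]
        pt2 = enpt2_correction(psi, ints, basis)
        records.append(PT2Record(psi.energy, pt2, len(D)))
        trace.append(
            RoundTrace(
                step=step_idx,
                round=cfg.N_rounds,
                size=len(D),
                energy=psi.energy,
                pt2=pt2,
            )
        )
    return psi, records, trace
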