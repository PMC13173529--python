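"""Occupancy statistics, rectification, excitation sampling, QSCI driver."""

import numpy as np
import pytest

from oqsci import (
    Determinant,
    MeasurementSet,
    MolecularIntegrals,
    OccupancyDistribution,
    QSCIConfig,
    SpinOrbitalBasis,
    fci_space,
    hartree_fock_determinant,
    jordan_wigner,
    occupancy_distribution,
    qsci_run,
    rectify_measurements,
    run_time_grid,
    sample_excitations,
    screen_candidates,
    solve_subspace,
    transform_weights,
)
from oqsci.qdrift import apply_readout_noise


class TestOccupancyDistribution:
    def test_pure_hf_shots(self):
        basis = SpinOrbitalBasis(3, 2, 1)
        hf = hartree_fock_determinant(basis)
        ms = MeasurementSet({hf.to_bitstring(3): 500}, 6)
        dist = occupancy_distribution(ms, basis)
        np.testing.assert_allclose(dist.mean_occ[0], [1, 1, 0], atol=1e-14)
        np.testing.assert_allclose(dist.mean_occ[1], [1, 0, 0], atol=1e-14)
        assert dist.norm_occ[0].sum() == pytest.approx(1.0)

    def test_complementary_pair_is_half_everywhere(self):
        basis = SpinOrbitalBasis(2, 1, 1)
        ms = MeasurementSet({"0110": 40, "1001": 40}, 4)
        dist = occupancy_distribution(ms, basis)
        np.testing.assert_allclose(dist.mean_occ, 0.5, atol=1e-14)

    def test_matches_direct_tallying_oracle(self):
        rng = np.random.default_rng(5)
        basis = SpinOrbitalBasis(3, 2, 1)
        counts = {}
        for _ in range(20):
            bits = "".join(rng.choice(["0", "1"], size=6))
            counts[bits] = counts.get(bits, 0) + int(rng.integers(1, 9))
        ms = MeasurementSet(counts, 6)
        dist = occupancy_distribution(ms, basis)
        flat = np.zeros(6)
        for bits, c in counts.items():
            flat += c * np.array([int(ch) for ch in bits])
        expected = (flat / ms.n_shots).reshape(2, 3)
        np.testing.assert_allclose(dist.mean_occ, expected, atol=1e-12)

    def test_zero_shots_rejected(self):
        basis = SpinOrbitalBasis(2, 1, 1)
        with pytest.raises(ValueError):
            occupancy_distribution(MeasurementSet({}, 4), basis)


class TestTransformWeights:
    def test_endpoints_vanish_under_fractional_boost(self):
        dist = OccupancyDistribution.from_mean(
            np.array([[1.0, 0.0, 0.5], [1.0, 0.5, 0.25]])
        )
        boosted = transform_weights(dist, "fractional_boost")
        assert boosted.mean_occ[0, 0] == 0.0
        assert boosted.mean_occ[0, 1] == 0.0
        # 0.5 maximizes n(1-n)
        assert boosted.mean_occ[0, 2] == pytest.approx(0.25)
        assert np.argmax(boosted.norm_occ[1]) == 1

    def test_identity_idempotent(self):
        dist = OccupancyDistribution.from_mean(np.array([[0.3, 0.7], [0.1, 0.9]]))
        assert transform_weights(dist, "identity") is dist


class TestRectify:
    def test_noiseless_hf_measurement(self):
        basis = SpinOrbitalBasis(3, 2, 1)
        hf = hartree_fock_determinant(basis)
        ms = MeasurementSet({hf.to_bitstring(3): 64}, 6)
        assert rectify_measurements(ms, basis) == {hf}

    def test_complemented_shots_leave_asymmetric_sector(self):
        basis = SpinOrbitalBasis(3, 2, 1)
        hf = hartree_fock_determinant(basis)
        complemented = "".join(
            "0" if ch == "1" else "1" for ch in hf.to_bitstring(3)
        )
        ms = MeasurementSet({complemented: 64}, 6)
        assert rectify_measurements(ms, basis) == set()

    def test_matches_popcount_filter_oracle(self):
        rng = np.random.default_rng(11)
        basis = SpinOrbitalBasis(3, 2, 1)
        counts = {}
        for _ in range(40):
            bits = "".join(rng.choice(["0", "1"], size=6))
            counts[bits] = counts.get(bits, 0) + 1
        ms = MeasurementSet(counts, 6)
        got = rectify_measurements(ms, basis)
        expected = {
            Determinant.from_bitstring(b, 3)
            for b in counts
            if b[:3].count("1") == 2 and b[3:].count("1") == 1
        }
        assert got == expected


class TestSampleExcitations:
    def test_uniform_weights_give_uniform_singles(self):
        basis = SpinOrbitalBasis(4, 2, 2)
        hf = hartree_fock_determinant(basis)
        dist = OccupancyDistribution.from_mean(np.full((2, 4), 0.5))
        rng = np.random.default_rng(31)
        counts: dict = {}
        n_draws = 10_000
        for _ in range(n_draws):
            for cand in sample_excitations(hf, dist, 1, rng):
                counts[cand] = counts.get(cand, 0) + 1
        # each of the 4 alpha singles has channel prob 1/5 and pair prob 1/4
        p = (1 / 5) * (1 / 4)
        sigma = np.sqrt(n_draws * p * (1 - p))
        for i in (0, 1):
            for a in (2, 3):
                cand = Determinant(hf.occ_alpha ^ (1 << i) | (1 << a), hf.occ_beta)
                assert abs(counts[cand] - n_draws * p) < 3 * sigma

    def test_concentrated_weights_give_deterministic_single(self):
        basis = SpinOrbitalBasis(4, 2, 2)
        hf = hartree_fock_determinant(basis)
        mean = np.zeros((2, 4))
        mean[0, 1] = 1.0  # only occupied alpha orbital 1 carries weight
        mean[0, 2] = 0.0  # virtual weight 1-mean concentrates on 2 and 3
        mean[0, 3] = 1.0  # ... kill virtual orbital 3
        mean[1, :2] = 1.0  # fully weight the occupied beta orbitals equally
        dist = OccupancyDistribution.from_mean(mean)
        cands = sample_excitations(hf, dist, 400, seed=7,
                                   channel_probs={"single_a": 1.0})
        expected = Determinant(hf.occ_alpha ^ 0b0010 | 0b0100, hf.occ_beta)
        assert set(cands) == {expected}
        assert cands[expected] == pytest.approx(1.0)

    def test_probabilities_match_product_formula(self):
        """Recorded P(Phi_l) equals the stated per-channel product, computed
        here by exhaustive enumeration of the restricted weights."""
        basis = SpinOrbitalBasis(4, 2, 2)
        hf = hartree_fock_determinant(basis)
        rng = np.random.default_rng(13)
        mean = rng.uniform(0.1, 0.9, size=(2, 4))
        dist = OccupancyDistribution.from_mean(mean)
        cands = sample_excitations(hf, dist, 5000, seed=3)
        # independent recomputation of the restricted, renormalized weights
        occ = [0, 1]
        vir = [2, 3]
        w_occ = {
            s: dist.norm_occ[s][occ] / dist.norm_occ[s][occ].sum()
            for s in (0, 1)
        }
        w_vir = {
            s: (1 - dist.mean_occ[s][vir]) / (1 - dist.mean_occ[s][vir]).sum()
            for s in (0, 1)
        }
        for cand, prob in cands.items():
            da = hf.occ_alpha ^ cand.occ_alpha
            db = hf.occ_beta ^ cand.occ_beta
            holes_a = [i for i in occ if (da >> i) & 1]
            parts_a = [a for a in vir if (da >> a) & 1]
            holes_b = [i for i in occ if (db >> i) & 1]
            parts_b = [a for a in vir if (db >> a) & 1]
            expected = 1.0
            for s, holes, parts in ((0, holes_a, parts_a), (1, holes_b, parts_b)):
                for i in holes:
                    expected *= w_occ[s][occ.index(i)]
                for a in parts:
                    expected *= w_vir[s][vir.index(a)]
            assert prob == pytest.approx(expected, rel=1e-12)
            assert cand.sector_valid(basis)

    def test_channel_skipped_when_no_weighted_orbitals(self):
        basis = SpinOrbitalBasis(2, 2, 0)  # no alpha virtuals, no beta electrons
        d = hartree_fock_determinant(basis)
        dist = OccupancyDistribution.from_mean(np.full((2, 2), 0.5))
        assert sample_excitations(d, dist, 100, seed=0) == {}


class TestScreening:
    def test_scores_are_magnitude_times_probability(self, toy4):
        basis, ints = toy4
        hf = hartree_fock_determinant(basis)
        from oqsci import connected_determinants, slater_condon_element

        cands = {d: 0.1 for d in list(connected_determinants(hf, basis))[:6]}
        scored = screen_candidates(cands, hf, ints)
        for d, score, prob in scored:
            assert score == pytest.approx(
                abs(slater_condon_element(hf, d, ints)) * prob
            )
        scores = [s for _, s, _ in scored]
        assert scores == sorted(scores, reverse=True)

    def test_zero_probability_gives_zero_score(self, toy4):
        basis, ints = toy4
        hf = hartree_fock_determinant(basis)
        from oqsci import connected_determinants

        d = next(iter(connected_determinants(hf, basis)))
        assert screen_candidates({d: 0.0}, hf, ints)[0][1] == 0.0


def _noiseless_grids(basis, ints, seed=11, K=3, n_instances=5, shots=256):
    H = jordan_wigner(basis, ints)
    ref = hartree_fock_determinant(basis)
    return run_time_grid(
        H, ref, tau=2 * np.pi / 5, K=K, n_instances=n_instances,
        shots=shots, epsilon=1.0, seed=seed,
    )


class TestQsciRun:
    def test_uncoupled_hamiltonian_stays_at_hf(self):
        # diagonal h plus Coulomb-only g: every off-diagonal element vanishes
        M = 3
        h = np.diag([-1.5, -1.0, -0.5])
        g = np.zeros((M, M, M, M))
        for p in range(M):
            for q in range(M):
                g[p, p, q, q] = 0.3
        ints = MolecularIntegrals(e_core=0.2, h=h, g=g)
        basis = SpinOrbitalBasis(M, 2, 1)
        hf = hartree_fock_determinant(basis)
        ms = MeasurementSet({hf.to_bitstring(M): 128}, 2 * M)
        cfg = QSCIConfig(D_max=50, N_rounds=3, N_samples=40, seed=1)
        psi, _, _ = qsci_run(ints, basis, [ms], cfg)
        assert psi.dets == [hf]
        from oqsci import slater_condon_element

        assert psi.energy == pytest.approx(slater_condon_element(hf, hf, ints))

    def test_reaches_fci_with_full_cap(self, toy4, toy4_fci):
        basis, ints = toy4
        _, psi_fci = toy4_fci
        grids = _noiseless_grids(basis, ints)
        cfg = QSCIConfig(
            D_max=36, N_rounds=5, N_samples=60, eps_wf=1e-12, seed=2
        )
        psi, records, trace = qsci_run(ints, basis, grids, cfg)
        assert psi.energy == pytest.approx(psi_fci.energy, abs=1e-6)
        assert records[-1].pt2 == pytest.approx(0.0, abs=1e-10)

    def test_energy_checkpoints_non_increasing(self, toy4):
        basis, ints = toy4
        grids = _noiseless_grids(basis, ints, seed=23)
        cfg = QSCIConfig(D_max=36, N_rounds=3, N_samples=40, eps_wf=1e-12, seed=4)
        _, records, _ = qsci_run(ints, basis, grids, cfg)
        energies = [r.qsci_energy for r in records]
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_deterministic_given_seed(self, toy4):
        basis, ints = toy4
        grids = _noiseless_grids(basis, ints, seed=29, K=2)
        cfg = QSCIConfig(D_max=20, N_rounds=2, N_samples=30, seed=8)
        out1 = qsci_run(ints, basis, grids, cfg)
        out2 = qsci_run(ints, basis, grids, cfg)
        assert out1[0].dets == out2[0].dets
        assert out1[0].energy == out2[0].energy
        np.testing.assert_array_equal(out1[0].coeffs, out2[0].coeffs)

    def test_sector_conserved_under_readout_noise(self, toy4):
        basis, ints = toy4
        grids = _noiseless_grids(basis, ints, seed=31, K=2)
        noisy = [apply_readout_noise(g, 0.05, seed=i) for i, g in enumerate(grids)]
        cfg = QSCIConfig(D_max=36, N_rounds=3, N_samples=40, seed=9)
        psi, _, _ = qsci_run(ints, basis, noisy, cfg)
        for d in psi.dets:
            assert d.sector_valid(basis)

    def test_empty_measurements_rejected(self, toy4):
        basis, ints = toy4
        with pytest.raises(ValueError):
            qsci_run(ints, basis, [], QSCIConfig())

    def test_dmax_cap_respected(self, toy4):
        basis, ints = toy4
        grids = _noiseless_grids(basis, ints, seed=37, K=2)
        cfg = QSCIConfig(D_max=12, N_rounds=3, N_samples=50, seed=10)
        psi, _, trace = qsci_run(ints, basis, grids, cfg)
        assert len(psi.dets) <= 12
        assert all(row.size <= 12 for row in trace)
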