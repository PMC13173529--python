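# oqsci — occupancy-guided, time-evolved quantum-selected CI

`oqsci` is a classical, fully testable toolkit for **quantum-selected
configuration interaction (QSCI)** in molecular electronic structure.  It
emulates the quantum stage of the workflow — stochastic (qDRIFT) real-time
evolution of a Hartree–Fock reference, measured in the computational basis —
with an exact statevector simulator, then runs the classical stage for real:
measured bitstrings drive an occupancy-guided configuration-sampling loop,
the selected subspace is diagonalized, perturbatively corrected
(Epstein–Nesbet PT2), and extrapolated to the zero-correction point as an
FCI estimate.  Heatbath CI (HCI) is built in as the classical benchmark.

It is aimed at method developers who want every stage of a QSCI pipeline —
fermionic algebra, qubit mapping, stochastic compilation, measurement
statistics, selection heuristics, perturbation theory — as small, separately
testable pieces that run on a laptop.

## The method

Given molecular integrals (FCIDUMP), a configuration subspace
D = {|Φ_k⟩} of Slater determinants defines the projected eigenproblem

    H v_j = ε_j v_j,     H_kl = ⟨Φ_k|H|Φ_l⟩  (Slater–Condon rules)

Selected-CI methods grow D iteratively.  HCI admits externals satisfying
|H_kl v_k| > δ and halves δ until a dimension cap is hit.  The QSCI variant
implemented here instead biases the expansion with measurement data:

1. **Evolve & measure.**  Under Jordan–Wigner (blocked spin-orbital order)
   the propagator e^{-iHt} is compiled stochastically with qDRIFT: terms of
   H = Σ_j h_j σ_j are drawn with probability p_j = |h_j|/λ (λ = Σ_j|h_j|)
   and each contributes a fixed-angle exponential e^{-iλt·sgn(h_j)σ_j/N},
   with N = ⌈2λ²t²/ε⌉ segments.  The evolved state is measured in the
   computational basis over a time grid t = kτ.
2. **Occupancy statistics.**  Each spin orbital's mean measured bit value
   gives the occupancy distribution P_occ^(σ)(χ_i = 1); sector-valid
   bitstrings are *rectified* — admitted directly as determinants, so
   higher-order excitations can enter in one shot.
3. **Guided expansion.**  Single/double excitations away from dominant
   configurations (|v_k| > ε_screen) are sampled with occupied indices
   weighted by the normalized occupancies and virtual indices by the
   complementary weights, then ranked by the screening metric
   d(Φ_l) = |H_kl|·P(Φ_l); top scorers are appended and the subspace
   re-diagonalized, up to D_max.
4. **Correct & extrapolate.**  The Epstein–Nesbet second-order correction
   ε^(PT2) = −Σ_{Φ_k∉D} |⟨Φ_k|V|Ψ⟩|²/(⟨Φ_k|H|Φ_k⟩ − ε) captures the missed
   exterior correlation; since ε^(PT2) → 0 as D → D_FCI, regressing ε
   against ε^(PT2) and reading the intercept at zero estimates the FCI
   energy.

All candidate configurations are sector-valid by construction, so readout
noise can degrade only the *quality* of the sampling prior, never the
particle sector of the variational space.

## Worked example

A bundled 4-orbital, 2α+2β synthetic instance (8 qubits, FCI dimension 36):

```sh
oqsci fixture --name toy4 --out toy4.fcidump
oqsci evolve toy4.fcidump --steps 5 --instances 10 --shots 256 \
      --epsilon 1.0 --seed 42 --out meas
oqsci qsci toy4.fcidump --measurements 'meas/step_*.txt' --seed 0 --out out
oqsci hci  toy4.fcidump --dcap 36 --out hci_out
```

prints

```
final energy -4.8164724182 Ha over 36 determinants -> out
HCI energy -4.8164724182 Ha over 36 determinants (FCI space: 36)
```

With an uncapped subspace both routes land on the dense FCI energy
(−4.8164724182 Ha) and the recorded PT2 correction is 0 — the completeness
limit.  Capping the subspace shows the correction at work: with
`D_max: 20` in a YAML config the run reports a variational energy of
−4.8162904912 Ha, a correction of −0.000175680821 Ha, and a corrected total
of −4.8164661721 Ha, recovering most of the 1.8×10⁻⁴ Ha gap to FCI from
outside the 20-determinant subspace.

The `evolve` step's bookkeeping mirrors a hardware-scale budget: 5 time
steps × 50 instances × 1024 shots would be 256,000 shots per geometry.

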