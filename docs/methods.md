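# Methods

This note records the model choices, conventions, parameter defaults and
known limitations of the `oqsci` implementation.

## Representations and conventions

**Determinants.**  A Slater determinant is a pair of occupation bitmasks
over M spatial orbitals, one per spin channel.  Spin orbitals use *blocked*
ordering: index i ∈ [0, M) is the alpha spatial orbital i, index M+i the
beta one.  This keeps each spin's occupancy vector contiguous, which the
occupancy-sampling stage reads directly off measurement bitstrings; the
interleaved alternative was rejected for that reason.  Two determinants are
equal iff both masks are equal, and the bitwise ordering of the masks is the
deterministic lexicographic tie-break used everywhere a ranking needs one.

**Fermionic phase.**  Masks are ordered by ascending spin-orbital index;
moving one electron contributes (−1)^(number of occupied spin orbitals
strictly between the two indices), and doubles apply the two moves
sequentially, pairing holes and particles in ascending order.  Any
self-consistent convention passes the dense-oracle tests; this one is fixed
for reproducibility, and the test suite checks the full Slater–Condon
matrix entrywise against a second-quantized Hamiltonian assembled from
explicit ladder-operator matrices.

**Integrals.**  Stored dense: h (M×M, symmetric) and g (M⁴, chemists'
notation (pq|rs), 8-fold symmetry enforced on construction within 1e−8,
never assumed).  Dense storage is deliberate for the target sizes (M ≤ ~24
in tests); indices are 0-based internally and translated to FCIDUMP's
1-based form only at the I/O boundary.  The FCIDUMP reader ignores unknown
namelist keys, accepts comma- or whitespace-separated headers, expands each
two-electron line to its full 8-fold class, and reports parse errors with
line numbers; the writer emits one canonical representative per class and
refuses asymmetric one-electron blocks.

**Qubit mapping.**  Jordan–Wigner, fixed (not Bravyi–Kitaev): qubit i's
computational-basis bit equals spin-orbital i's occupancy, which is exactly
what the occupancy-distribution estimator assumes when it averages bits.
Pauli strings are held symplectically as (x, z) masks with the canonical
phase W(x,z) = i^{|x∧z|} X^x Z^z, so coefficient arithmetic is exact integer
mask algebra.  Measurement bitstrings are written qubit-0-first (leftmost
character = spin orbital 0) in every text format.  Coefficients of the
mapped molecular Hamiltonian are real; terms with |h_j| ≤ drop_tol are
removed after merging.  drop_tol defaults to 1e−10 — below
integral-symmetry noise, above float epsilon.

## Subspace CI and Heatbath CI

The interaction matrix over a subspace D is sparse-assembled from
Slater–Condon elements (pairs beyond double excitations skipped).
Diagonalization is dense below K = 400 and Lanczos (`scipy.sparse.linalg.
eigsh`) above; the switch point is an argument because the fixtures are
small while realistic subspaces are not.  The eigenvector sign convention
(largest-magnitude coefficient positive) makes runs comparable.  Only the
ground state (root 0) is targeted by the drivers.

HCI screening uses matrix-element *magnitudes* (the fermionic sign depends
only on orbitals common to both determinants and is irrelevant to a
threshold test).  The reference implementation scans each member's
connected determinants directly; at each δ level, expansion and
re-diagonalization alternate until no new determinant passes, then δ is
halved (δ₀ = 0.1), stopping when an expansion would exceed the dimension
cap or δ underflows 1e−12.  The per-level trace (δ, |D|, ε) is returned so
any schedule difference against other HCI codes is auditable.

## Epstein–Nesbet PT2

The model Hamiltonian is the exact block on D plus bare diagonals outside,
so the subspace eigenstate is an exact zeroth-order state and the
denominator uses the *variational* ε, not Møller–Plesset orbital energies.
The sum over external determinants is deterministic (no stochastic
estimator): perturber amplitudes ⟨Φ_k|V|Ψ⟩ = Σ_l H_kl v_l are accumulated
in a hash-keyed map while walking singles/doubles from every member, so
memory is bounded by the connected external space.  Denominators smaller
than 1e−12 raise, naming the offending determinant.  The PT2 → 0
extrapolation is unweighted OLS of subspace energy against correction; the
correlation-energy variant shifts data and intercept by the same constant
(asserted by test), so the total-energy fit is used directly.

## qDRIFT emulation

One realization draws N = ⌈2λ²t²/ε⌉ terms i.i.d. with p_j = |h_j|/λ and
applies e^{−iθσ} with the *full* angle θ = λt·sgn(h_j)/N (no ½ factor) via
cos θ·I − i sin θ·σ, with σ acting through bit masks and phase tables —
never a 2ⁿ×2ⁿ matrix.  Identity terms are excluded from sampling and from
λ (they only contribute a global phase) and tracked as an energy offset.
The statevector cap defaults to 16 qubits.  The target precision ε is a
configuration choice (default 0.5 in the CLI, 1.0 in the bundled
pipelines): it controls segment counts qualitatively and is not tied to any
hardware depth figure.  Measurement grids are collected up front for each
time step from the fixed Hartree–Fock reference and reused; adaptive
reference updating is out of scope.  A readout-noise fixture flips each bit
independently with probability p_flip to exercise the rectification path.

## Occupancy-guided sampling

The conditional occupied-index distribution is implemented as: restrict the
normalized occupancy weights to the orbitals occupied in Φ_k and
renormalize; virtual indices symmetrically use (1 − n̄) — the complement of
the *raw mean* occupancy, which is the only quantity with a physical [0,1]
scale — restricted to empty orbitals and renormalized.  This reading makes
every channel a proper probability distribution.  Channel choice (single α,
single β, same-spin double αα/ββ, opposite-spin double αβ) is uniform over
the channels whose pools have positive weight, overridable in the config;
channels without usable orbitals are skipped and logged.  The recorded
candidate probability is the product of the drawn marginals; duplicates
across draws are merged keeping the maximum recorded probability, since
summing would conflate sampling multiplicity with probability.  Screening
scores are |H_kl|·P(Φ_l) with Φ_k the generating dominant configuration; a
candidate generated by several dominants keeps its maximum score, and
zero-score (symmetry-disconnected) candidates are never appended.

The driver loops time steps outermost and sampling rounds innermost.  Each
round: solve, prune members with |v| < ε_WF (the Hartree–Fock determinant
is never pruned), sample and screen from every dominant configuration,
append up to the round budget (default 10× the number of dominants), then
admit the step's rectified determinants; appending stops at D_max.  After
each step the subspace is re-solved and an Epstein–Nesbet correction
recorded, giving one PT2 checkpoint per time step for the extrapolation.
Rectified determinants of the first step also seed the initial subspace
alongside Hartree–Fock.

Defaults mirror hardware-scale settings: D_max = 5×10⁴, N_rounds = 10,
N_samples = 100, ε_screen = 10⁻², ε_WF = 10⁻⁵, τ = 2π/5 with K = 5 time
steps, 50 instances × 1024 shots per step.  Tests and the acceptance script
run the same loop at reduced sizes (8-qubit instance, 10 instances × 256
shots, D_max = FCI dimension 36) — chosen so the dense FCI reference is
exactly computable and the whole pipeline completes in seconds.

Pruning can in principle raise the variational energy between rounds by up
to the weight it removes; monotonicity of the energy trace is therefore
guaranteed only for negligible ε_WF, which is how the invariant tests run.

## Synthetic fixtures

No external chemistry software is required.  `toy2` is a two-orbital,
two-electron instance with integral magnitudes at the scale of a stretched
covalent bond in a minimal basis (its FCI energy, −1.1371 Ha, has the
familiar magnitude of such systems, but the numbers are a fixed synthetic
choice).  `hubbard_like` is an open chain with hopping −t and on-site U.
`random` draws a symmetric one-electron matrix with ascending diagonal and
exponentially decaying couplings, and a two-electron tensor symmetrized
exactly over its 8-fold group with the same index-distance decay plus a
repulsive on-site floor — nontrivial but bounded, with the Hartree–Fock
determinant keeping dominant ground-state overlap, which the sampling loop
presumes.  What these fixtures do *not* emulate: realistic integral sparsity
patterns, point-group symmetry, near-degenerate dissociation regimes, or
hardware noise beyond independent bit flips.  Passing tests demonstrate
algorithmic correctness and noise-path robustness at desk scale, not
chemical accuracy on real molecules.

Register sizing for real targets is provided by a small contracted-shell
table (e.g. silane: 21 spatial orbitals / 42 qubits in 6-31G, 38 / 76 in
cc-pVDZ with spherical d functions).

## Numerical choices and degenerate inputs

- Subspace coefficients are L2-normalized (checked to 1e−10); duplicate
  determinants in a subspace are an input error, not silently deduplicated.
- Collation of several subspaces ranks each determinant by the largest
  |coefficient| over its sources, lexicographic tie-break, truncated to the
  cap.
- Zero-shot measurement sets, empty Hamiltonians, non-normalized states,
  infeasible active-space splits and FCIDUMP parity violations all raise
  with specific messages rather than propagating NaNs.
- Seeds: every stochastic component takes an explicit seed or
  `numpy.random` Generator/SeedSequence; grid runs spawn per-step,
  per-instance children deterministically, so whole pipelines are pure
  functions of (inputs, seed).

## Known limitations

- Statevector emulation limits registers to ~16 qubits; the classical
  stages (Slater–Condon, HCI, PT2) scale further but are pure Python and
  not tuned for production subspace sizes.
- The double-excitation magnitude precomputation used by large-scale HCI
  codes is not implemented; the per-determinant scan is the reference path.
- Excited-state selection, semistochastic PT2, symmetry handling (point
  group, S²), non-orthonormal references and hardware transpilation are out
  of scope.
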