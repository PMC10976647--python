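# Methods

## The model

The package computes ground and excited electronic states of small molecules
on simulated quantum hardware. The electronic Hamiltonian in second
quantization,

    H = E_nuc + Σ_pq h_pq a†_p a_q + ½ Σ_pqrs ⟨pq|rs⟩ a†_p a†_q a_s a_r,

is mapped to qubits with the Jordan–Wigner transformation (one qubit per
spin-orbital, Z strings on lower indices preserving the anticommutation
relations), giving a sparse sum of Pauli strings H = Σ_i h_i P̂_i.

Excited states are reached by the folded-spectrum device: for a target energy
ω, the operator (H − ω)² shares the eigenvectors of H but its eigenvalues are
(E_i − ω)², so its ground state is the eigenstate of H closest in energy to
ω. Minimizing ⟨Ψ(θ)|(H − ω)²|Ψ(θ)⟩ over the parameters of a variational
circuit is therefore a direct excited-state method, at the cost of measuring
an operator with up to the square of the Hamiltonian's term count. Exact,
phase-tracked Pauli algebra reduces that count sharply (15 → 24 strings for
H₂ rather than 225), and partitioning into commuting groups (qubit-wise or
general commutativity, greedy clique cover) reduces the number of distinct
circuit evaluations further (24 strings → 2 generally-commuting groups).

The ansatz is unitary coupled cluster with singles and doubles, Trotterized
at order 1 with the occupied-index-major excitation ordering, each
exponentiated generator string compiled as a Pauli gadget (basis changes,
CNOT ladder, central Rz, mirrored uncompute; 2(w−1) CNOTs for a weight-w
string).

### Excitation list and reference states

The completeness of the ordered single-step Trotter expansion is relative to
the determinant being excited. The excitation list of each run is therefore
enumerated from that run's own reference determinant (the first determinant
for a two-determinant reference), not from the Hartree–Fock determinant;
for the Hartree–Fock reference this reduces to the usual ground-state UCCSD
ansatz, with 3 excitations for H₂ and 8 for LiH. With the list tied to the
HF determinant instead, global optimization over the full parameter range
cannot represent several LiH excited eigenstates from their references
(folded-cost floors of 3·10⁻⁴–1.5·10⁻³ Ha²); with the reference-relative
list every listed state of both molecules is recovered to ≤ 10⁻⁶ Ha on the
exact backend.

References are built by exciting the Hartree–Fock determinant and
spin-symmetrizing where needed: triplets are represented by their Ms = 1
single-determinant component, open-shell singlets by an equal-weight
two-determinant superposition. The relative sign in each singlet is stated
in the Jordan–Wigner fermionic sign convention of this package; the catalog
in `fsvqe.references` documents every determinant, and tests verify each
reference overlaps its target eigenstate dominantly.

### Target-energy (ω) selection

For a fresh, untracked run, ω defaults to the Hamiltonian expectation in the
reference state (computed classically). Along a geometry scan, ω is tracked:
ω_{k+1} = E_k and θ warm-starts from θ_k. Note one documented failure mode
of the default: a two-determinant reference that mixes appreciably with
lower eigenstates has ⟨H⟩ below its target eigenvalue, and can point the
fold at a neighbouring state (LiH S4's reference expectation lies closer to
T3, 25 vs 64 mHa, and the run then converges — correctly, per the method's
semantics — to T3). Validation experiments that aim at a specific
eigenvalue therefore pass ω explicitly.

## Optimization

* **Exact (statevector) backend** — deterministic BFGS on the exact cost,
  followed by self-consistent re-folding (ω replaced by the measured energy,
  which deepens the attained minimum) and a few deterministically jittered
  restarts if the folded cost has not reached its known floor of zero.
* **Sampled and noisy backends** — SPSA with Spall gain sequences
  (α = 0.602, γ = 0.101, A = 10% of the iteration budget, a = 0.15,
  c = 0.1), exactly two cost evaluations per iteration, seeded and
  reproducible. Shots per evaluation follow the inverse-exponential schedule
  s(t) = s_max − (s_max − s_min)·e^(−kt) with s_min = 1000, s_max = 10000,
  k = 0.01; the final measurement uses 30,000 shots. The stated termination
  criterion (smoothed gradient-estimate norm < 10⁻⁹) cannot trigger under
  shot noise, so the iteration budget (default 300 per point; scans
  warm-start from the previous geometry) is the effective stop.
* **Post-processing** — per-parameter quadratic refinement (5 probes at
  ±0.05 rad, move to the fitted vertex only if convex and the measured cost
  does not increase) and rounding of near-special angles (0, ±π/2, ±π
  within 0.02 rad, kept only if the measured cost does not increase).
  Optimizer variables are scaled by c = 2 relative to physical gadget
  angles.

## Noise model and mitigation

After every gate, the touched qubits see a depolarizing channel (error
probability p₁ = 10⁻⁴ for one-qubit, p₂ = 10⁻³ for two-qubit gates at the
experimental level; the two-qubit probability is applied per qubit as
1 − √(1−p₂) so the pair error totals p₂), then amplitude damping over the
gate duration (t_g1 = 35 ns, t_g2 = 300 ns) with T₁ = 290 µs, and pure
dephasing derived from the *total* coherence time T₂ = 145 µs
(Γ_φ = 1/T₂ − 1/(2T₁)). Readout flips each measured bit with
p_SPAM = 10⁻². Idle qubits do not decohere during other qubits' gates (a
documented simplification). A scale factor λ ∈ [0, 1] interpolates all
parameters between the ideal device (λ = 0, with finite stand-ins
T₁ = 2000 µs, T₂ = 1000 µs) and the experimental magnitudes (λ = 1):
geometrically for T₁/T₂, linearly for everything else. All channels are
verified completely positive and trace preserving.

Mitigation combines two layers, applied per commuting measurement group:

* **SPAM inversion** — per-qubit symmetric confusion matrices extracted from
  p_SPAM, tensor-inverted on the measured distribution, followed by
  sort-based Euclidean projection onto the probability simplex (valid for
  p_SPAM < ½).
* **Zero-noise extrapolation** — global unitary folding G → G(G†G)^((γ−1)/2)
  at γ = 1, 3, 5, 7 scales gate noise while preserving the logical circuit;
  the group's summed expectation is fitted with an unweighted quadratic
  E_γ = a + bγ + cγ², and the γ = 0 intercept is the mitigated value. Fit
  residuals are reported with every run, and the 4× shot overhead is logged.

For the 4-qubit folded operator, the off-diagonal generally-commuting group
(the eight full-support X/Y strings with an even number of Y's) is
simultaneously diagonalized by one fixed, documented layer — a CNOT fan from
qubit 0 followed by a Hadamard on qubit 0 — whose correctness is asserted by
an explicit diagonality check of every conjugated member. General synthesis
of measurement circuits for arbitrary commuting groups is out of scope;
general commutativity is otherwise used for partition counting only.

## Synthetic data: the integral fixtures

Fixtures are generated by an in-repo restricted Hartree–Fock engine over
contracted s-type Gaussians (closed-form overlap, kinetic, nuclear-attraction
and repulsion integrals via the Boys function). Both shipped systems need
only s functions: H₂ in the STO-3G basis (4 spin-orbitals; bond lengths
0.50–2.00 Å, nine points), and LiH in a minimal s-orbitals-only basis (the
p shell of the Li STO-3G set is absent; 6 spin-orbitals, 4 electrons, no
frozen core; 1.595 Å). The engine reproduces the literature H₂/STO-3G
restricted Hartree–Fock energy (−1.11671 Ha at 1.4 a₀). Molecular-orbital
phases are made continuous along the scan before the integrals are
transformed, so committed fixtures warm-start cleanly. Each fixture carries
the electron/orbital counts, nuclear repulsion, spin-orbital integrals
(physicist notation, interleaved α/β ordering), the Hartree–Fock energy used
as a load-time consistency check, and the MO coefficient and overlap
matrices.

What the fixtures do *not* emulate: larger basis sets, p/d functions,
frozen-core treatments, relativistic or vibrational effects — so passing
tests show the algorithmic pipeline is correct on these model systems, not
that the energies are experimentally accurate (the s-only LiH basis in
particular is a deliberately poor physical description).

## Numerical choices

* Pauli coefficients are pruned below 10⁻¹²; phases of string products are
  tracked exactly as integer powers of i, so the folded operator's term
  count (24 for H₂) is independent of ω and structural cancellations are
  exact.
* (H − ωI)² is squared directly rather than expanded as H² − 2ωH + ω²I.
* The greedy clique cover colors vertices in decreasing non-commuting-degree
  order with lexicographic tie-breaks, seeding all diagonal strings into one
  shared group (they are always co-measurable); it is deterministic and
  makes no optimality claim (minimum clique cover is NP-hard).
* Qubit 0 is the leftmost Pauli letter, the leftmost bitstring character and
  the first Kronecker factor, everywhere.
* The statevector backend evaluates expectations by contracting the cached
  dense operator matrix (identical, by regrouping invariance, to the
  grouped-measurement estimate on exact distributions — asserted in tests).
* Dense realizations are guarded at 12 qubits, density matrices at 8.

## Problem sizes

The shipped experiments run on one CPU core: the shot-sampled H₂ scan uses
5 bond lengths × 3 excited states with a 300-iteration SPSA budget per point
(≈ 25 s total), and the mitigated run simulates 4 folding factors × 5
measurement groups of a ≈ 200-gate circuit on the 16-dimensional density
matrix (≈ 12 s).

## Known limitations

* With 30,000-shot final measurements, a single energy estimate of the H₂
  S2 state near equilibrium has σ ≈ 0.4 mHa — individual scan points can
  approach or cross the 1 kcal/mol line on unlucky draws, exactly as the
  spread of errors across points and runs shows.
* The default fresh-ω rule can target a neighbouring state when the
  reference is strongly mixed (see above); the parameter-continuity penalty
  η‖θ − θ_prev‖² (η = 0.1) is available for flagged scan points.
* SPSA gains are not auto-calibrated; pathological cost scales may need
  manual gain adjustment.
* The noise model omits leakage, crosstalk and idle-qubit decoherence.
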