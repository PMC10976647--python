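# fsvqe — folded-spectrum VQE for molecular excited states

`fsvqe` computes ground **and excited** electronic states of small molecules
on simulated quantum hardware. The variational quantum eigensolver (VQE)
minimizes ⟨Ψ(θ)|H|Ψ(θ)⟩ and so only reaches the ground state; `fsvqe`
instead minimizes the expectation of the **folded operator**

    F_ω = (H − ω)²,

which shares the eigenvectors of the Hamiltonian H while its eigenvalues
(E_i − ω)² reorder so that the eigenstate closest in energy to the target ω
becomes the ground state. Scanning ω therefore reaches any excited state
with the same circuits as a ground-state calculation.

The price is an operator with up to the square of the Hamiltonian's term
count. The package makes this tractable with exact phase-tracked Pauli
algebra (for H₂/STO-3G, 15 Hamiltonian strings fold into just 24, not 225)
and with commuting-group partitioning of the measurements (those 24 strings
need only 2 circuit evaluations under general commutativity).

Included: Jordan–Wigner Hamiltonians from packaged molecular-integral
fixtures (H₂/STO-3G on a bond-length grid, LiH in an s-orbitals-only
minimal basis), the ordered Trotterized UCCSD ansatz compiled to Pauli
gadgets, statevector / finite-shot / density-matrix simulators, a tunable
device noise model, SPSA optimization with a shot scheduler and
post-optimization refinement, potential-energy-surface scans with state
tracking, and SPAM + zero-noise-extrapolation error mitigation. The target
audience is quantum-algorithm and quantum-chemistry researchers studying
excited-state methods on near-term devices.

## Worked example

Compute the first excited singlet of H₂ at 0.74 Å on the exact backend:

```sh
$ fsvqe run h2_sto3g_0.74 S1 --backend statevector
state  geometry  energy_hartree  fci_hartree  error_kcal  omega        converged  evaluations
S1     0.740     -0.16835243     -0.16835243  +0.0000     -0.16835243  True       143
```

The run prepares the spin-symmetrized open-shell reference
(|1001⟩ − |0110⟩)/√2, sets the fold target ω to the reference energy,
minimizes ⟨F_ω⟩ over the three UCCSD amplitudes, and reports the final
Hamiltonian expectation (−0.16835 Ha) next to the eigenvalue of the dense
Hamiltonian it should match — here agreeing to the printed precision, i.e.
an error below 10⁻⁸ Ha.

The same thing as a library call:

```python
from fsvqe import (packaged_fixture, build_hamiltonian, solve_state,
                   ExactBackend, H2_REFERENCES, target_energy)

mi = packaged_fixture("h2_sto3g_0.74")
h = build_hamiltonian(mi)                      # 15 Pauli strings
res = solve_state(mi, H2_REFERENCES["S1"], ExactBackend(), hamiltonian=h)
print(res.energy, target_energy(h, H2_REFERENCES["S1"], mi.n_electrons))
# -0.16835243299... -0.16835243299...
```

Other entry points: `fsvqe groups` prints term and commuting-group counts
(15 strings / 5 qubit-wise groups / 2 general groups for the H₂
Hamiltonian), `fsvqe fci` tabulates dense-diagonalization eigenvalues,
`fsvqe pes` runs a tracked excited-state scan over the packaged geometry
grid, and `fsvqe mitigate` produces a SPAM+ZNE-mitigated noisy energy with
its extrapolation series.

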