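"""Regenerate the packaged molecular-integral fixtures.

Runs the in-repo restricted Hartree-Fock engine (s-type Gaussians only) for
H2/STO-3G on a bond-length grid and for LiH in a minimal s-orbitals-only
basis, applies MO phase continuity along each scan, and writes the fixtures
under src/fsvqe/data/.  Offline and deterministic; run from the repo root:

    python scripts/generate_fixtures.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from fsvqe.minimal_rhf import BOHR_PER_ANGSTROM, run_rhf, spin_orbital_integrals
from fsvqe.molham import MOCoefficients, MolecularIntegrals, fix_mo_phases, save_integrals

H2_GRID = [0.5, 0.65, 0.74, 0.9, 1.1, 1.3, 1.5, 1.75, 2.0]   # angstrom
LIH_GRID = [1.595]

OUT = Path(__file__).resolve().parents[1] / "src" / "fsvqe" / "data"


def scan(molecule: str, atoms_of, grid, basis_label: str) -> None:
    prev_mo: MOCoefficients | None = None
    for r in grid:
        res = run_rhf(atoms_of(r))
        mo = MOCoefficients(matrix=res.mo_coeff, overlap=res.overlap,
                            geometry_id=f"{r:.3f}")
        if prev_mo is not None:
            mo, warnings = fix_mo_phases(prev_mo, mo)
            for w in warnings:
                print(f"  warning: {w}")
            res.mo_coeff = mo.matrix
        prev_mo = mo
        one, two = spin_orbital_integrals(res)
        mi = MolecularIntegrals(
            n_spin_orbitals=one.shape[0],
            n_electrons=res.n_electrons,
            e_nuclear=res.e_nuclear,
            one_body=one,
            two_body=two,
            geometry_id=f"{r:.3f}",
            basis_label=basis_label,
            molecule=molecule,
            hf_energy=res.e_total,
            mo=mo,
        )
        name = f"{molecule.lower()}_{basis_label.lower().replace('-', '')}_{r:.2f}"
        save_integrals(mi, OUT / f"{name}.molint")
        print(f"{name}: E_HF = {res.e_total:.10f} Ha")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scan("H2",
         lambda r: [("H", np.zeros(3)),
                    ("H", np.array([0.0, 0.0, r * BOHR_PER_ANGSTROM]))],
         H2_GRID, "STO-3G")
    # LiH "minimal basis with only s orbitals": the p shell of the Li STO-3G
    # basis is simply absent from the s-only engine.
    scan("LiH",
         lambda r: [("Li", np.zeros(3)),
                    ("H", np.array([0.0, 0.0, r * BOHR_PER_ANGSTROM]))],
         LIH_GRID, "s-minimal")


if __name__ == "__main__":
    main()
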