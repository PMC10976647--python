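"""Jordan-Wigner qubit Hamiltonians from molecular integral fixtures.

A fixture file carries everything needed to rebuild a molecule's
second-quantized electronic Hamiltonian: spin-orbital counts, nuclear
repulsion, one-body integrals ``h_pq`` and physicist-notation two-body
integrals ``<pq|rs>``, plus the RHF energy (used as a consistency check) and
the MO coefficient / overlap matrices needed for phase continuity along a
geometry scan.

Conventions (fixed across the whole package):

* spin-orbitals are interleaved, ``p = 2*i + sigma`` with alpha even and beta
  odd on spatial orbital ``i``;
* qubit ``j`` hosts spin-orbital ``j`` under Jordan-Wigner; ``|0>`` is empty,
  ``|1>`` occupied, and the vacuum maps to ``|0...0>``;
* the JW Z-string dresses all qubits with index **below** ``j``;
* the electronic Hamiltonian is
  ``H = E_nuc + sum_pq h_pq a+_p a_q + 1/2 sum_pqrs <pq|rs> a+_p a+_q a_s a_r``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .pauli import PauliSum, PauliError, sum_combine, sum_multiply

__all__ = [
    "MolecularIntegrals",
    "MOCoefficients",
    "FixtureError",
    "load_integrals",
    "save_integrals",
    "packaged_fixture",
    "list_packaged_fixtures",
    "jw_map_ladder",
    "build_hamiltonian",
    "number_operator",
    "hf_determinant",
    "fix_mo_phases",
]


class FixtureError(ValueError):
    """Malformed molecular-integral fixture file."""


@dataclass
class MOCoefficients:
    """RHF molecular-orbital coefficients at one geometry.

    ``matrix`` is atomic-orbital x molecular-orbital; ``overlap`` is the AO
    overlap metric under which the columns are normalized.
    """

    matrix: np.ndarray
    overlap: np.ndarray
    geometry_id: str = ""


@dataclass
class MolecularIntegrals:
    """Spin-orbital integrals of one molecule at one geometry (Hartree)."""

    n_spin_orbitals: int
    n_electrons: int
    e_nuclear: float
    one_body: np.ndarray          # N x N, h_pq
    two_body: np.ndarray          # N^4 physicist <pq|rs>
    geometry_id: str = ""
    basis_label: str = ""
    molecule: str = ""
    hf_energy: float | None = None
    mo: MOCoefficients | None = None

    def validate(self) -> None:
        n = self.n_spin_orbitals
        if n <= 0 or self.n_electrons <= 0:
            raise FixtureError("orbital and electron counts must be positive")
        if self.n_electrons > n:
            raise FixtureError("n_electrons exceeds n_spin_orbitals")
        if self.one_body.shape != (n, n):
            raise FixtureError("one_body has wrong shape")
        if self.two_body.shape != (n, n, n, n):
            raise FixtureError("two_body has wrong shape")
        if not np.allclose(self.one_body, self.one_body.T, atol=1e-10):
            raise FixtureError("one_body is not symmetric")
        # permutational symmetries of real-orbital integrals in physicist
        # notation: <pq|rs> = <qp|sr> = <rq|ps> = <rs|pq>
        tb = self.two_body
        if not (np.allclose(tb, tb.transpose(1, 0, 3, 2), atol=1e-10)
                and np.allclose(tb, tb.transpose(2, 3, 0, 1), atol=1e-10)):
            raise FixtureError("two_body lacks the required index symmetries")


# ---------------------------------------------------------------------------
# fixture text format
#
# Key/value header lines, then labelled sparse array blocks:
#   one_body:   lines "p q value"
#   two_body:   lines "p q r s value"
#   mo_coefficients: / overlap:  dense rows of floats

_HEADER_KEYS = {"format", "molecule", "basis_label", "geometry_id",
                "n_spin_orbitals", "n_electrons", "e_nuclear", "hf_energy"}


def save_integrals(mi: MolecularIntegrals, path: str | Path,
                   threshold: float = 1e-12) -> None:
    mi.validate()
    n = mi.n_spin_orbitals
    lines = [
        "format molint-1",
        f"molecule {mi.molecule}",
        f"basis_label {mi.basis_label}",
        f"geometry_id {mi.geometry_id}",
        f"n_spin_orbitals {n}",
        f"n_electrons {mi.n_electrons}",
        f"e_nuclear {float(mi.e_nuclear)!r}",
    ]
    if mi.hf_energy is not None:
        lines.append(f"hf_energy {float(mi.hf_energy)!r}")
    lines.append("one_body:")
    for p in range(n):
        for q in range(p, n):  # symmetric: store upper triangle
            v = mi.one_body[p, q]
            if abs(v) > threshold:
                lines.append(f"{p} {q} {float(v)!r}")
    lines.append("two_body:")
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    v = mi.two_body[p, q, r, s]
                    if abs(v) > threshold and (p, q, r, s) <= _canonical_pqrs(p, q, r, s):
                        lines.append(f"{p} {q} {r} {s} {float(v)!r}")
    if mi.mo is not None:
        lines.append("mo_coefficients:")
        for row in mi.mo.matrix:
            lines.append(" ".join(repr(float(x)) for x in row))
        lines.append("overlap:")
        for row in mi.mo.overlap:
            lines.append(" ".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def _canonical_pqrs(p, q, r, s):
    """Representative of the <pq|rs> symmetry orbit (minimum index tuple)."""
    return min((p, q, r, s), (q, p, s, r), (r, s, p, q), (s, r, q, p))


def load_integrals(path: str | Path | io.TextIOBase) -> MolecularIntegrals:
    """Parse a molint fixture, verifying invariants on load."""
    if isinstance(path, io.TextIOBase):
        text = path.read()
        name = "<stream>"
    else:
        text = Path(path).read_text()
        name = str(path)
    header: dict[str, str] = {}
    blocks: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.endswith(":"):
            current = blocks.setdefault(line[:-1], [])
            continue
        if current is None:
            key, _, val = line.partition(" ")
            if key not in _HEADER_KEYS:
                raise FixtureError(f"{name}: unknown header field {key!r}")
            header[key] = val.strip()
        else:
            current.append(line)

    for req in ("n_spin_orbitals", "n_electrons", "e_nuclear"):
        if req not in header:
            raise FixtureError(f"{name}: missing required field {req!r}")
    if "one_body" not in blocks or "two_body" not in blocks:
        raise FixtureError(f"{name}: missing integral block")

    n = int(header["n_spin_orbitals"])
    one = np.zeros((n, n))
    for line in blocks["one_body"]:
        parts = line.split()
        if len(parts) != 3:
            raise FixtureError(f"{name}: malformed one_body line {line!r}")
        p, q, v = int(parts[0]), int(parts[1]), float(parts[2])
        one[p, q] = v
        one[q, p] = v
    two = np.zeros((n, n, n, n))
    for line in blocks["two_body"]:
        parts = line.split()
        if len(parts) != 5:
            raise FixtureError(f"{name}: malformed two_body line {line!r}")
        p, q, r, s = (int(x) for x in parts[:4])
        v = float(parts[4])
        for idx in {(p, q, r, s), (q, p, s, r), (r, s, p, q), (s, r, q, p)}:
            two[idx] = v

    mo = None
    if "mo_coefficients" in blocks:
        cmat = np.array([[float(x) for x in line.split()]
                         for line in blocks["mo_coefficients"]])
        smat = np.array([[float(x) for x in line.split()]
                         for line in blocks.get("overlap", [])])
        mo = MOCoefficients(matrix=cmat, overlap=smat,
                            geometry_id=header.get("geometry_id", ""))

    mi = MolecularIntegrals(
        n_spin_orbitals=n,
        n_electrons=int(header["n_electrons"]),
        e_nuclear=float(header["e_nuclear"]),
        one_body=one,
        two_body=two,
        geometry_id=header.get("geometry_id", ""),
        basis_label=header.get("basis_label", ""),
        molecule=header.get("molecule", ""),
        hf_energy=float(header["hf_energy"]) if "hf_energy" in header else None,
        mo=mo,
    )
    try:
        mi.validate()
    except FixtureError as exc:
        raise FixtureError(f"{name}: {exc}") from exc
    return mi


def packaged_fixture(name: str) -> MolecularIntegrals:
    """Load a fixture shipped inside the package, e.g. ``h2_sto3g_0.74``."""
    ref = resources.files("fsvqe.data").joinpath(f"{name}.molint")
    with resources.as_file(ref) as path:
        return load_integrals(path)


def list_packaged_fixtures(prefix: str = "") -> list[str]:
    names = []
    for entry in resources.files("fsvqe.data").iterdir():
        if entry.name.endswith(".molint") and entry.name.startswith(prefix):
            names.append(entry.name[:-len(".molint")])
    return sorted(names)


# ---------------------------------------------------------------------------
# Jordan-Wigner mapping

def jw_map_ladder(j: int, dagger: bool, n: int) -> PauliSum:
    """JW image of the ladder operator on spin-orbital ``j`` of ``n``.

    ``a+_j = Z_0 ... Z_{j-1} (X_j - i Y_j)/2`` and the annihilator is the
    Hermitian conjugate; the Z dressing preserves the canonical
    anticommutation relations, and occupation maps to the qubit ``|1>``.
    """
    if not 0 <= j < n:
        raise PauliError(f"orbital index {j} out of range for {n} qubits")
    z_prefix = "Z" * j
    suffix = "I" * (n - j - 1)
    sign = -0.5j if dagger else 0.5j
    return PauliSum(n, {
        z_prefix + "X" + suffix: 0.5,
        z_prefix + "Y" + suffix: sign,
    })


def _ladder_product(indices: list[tuple[int, bool]], n: int) -> PauliSum:
    """JW image of an ordered product of ladder operators."""
    out = jw_map_ladder(*indices[0], n)
    for j, dag in indices[1:]:
        out = sum_multiply(out, jw_map_ladder(j, dag, n))
    return out


def build_hamiltonian(mi: MolecularIntegrals, tol: float = 1e-10) -> PauliSum:
    """JW-mapped electronic Hamiltonian as a PauliSum (coefficients in Hartree).

    Every term with a creation and an annihilation operator on the same
    spin-orbital (``h_pp``, ``<pr|pr>``, ``<pr|rp>``) lands on a diagonal
    (I/Z-only) Pauli string, which is what makes the single-counts evaluation
    of the diagonal part of the operator possible.
    """
    mi.validate()
    n = mi.n_spin_orbitals
    h = PauliSum(n, {"I" * n: mi.e_nuclear})
    for p in range(n):
        for q in range(n):
            c = mi.one_body[p, q]
            if abs(c) < tol:
                continue
            term = _ladder_product([(p, True), (q, False)], n).scaled(c)
            h = sum_combine(h, term, tol=0.0)
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            for r in range(n):
                for s in range(n):
                    if r == s:
                        continue
                    c = 0.5 * mi.two_body[p, q, r, s]
                    if abs(c) < tol:
                        continue
                    term = _ladder_product(
                        [(p, True), (q, True), (s, False), (r, False)], n
                    ).scaled(c)
                    h = sum_combine(h, term, tol=0.0)
    return h.real_part().pruned(tol)


def number_operator(n: int) -> PauliSum:
    """JW particle-number operator ``sum_j a+_j a_j = sum_j (I - Z_j)/2``."""
    terms: dict[str, float] = {"I" * n: n / 2.0}
    for j in range(n):
        terms["I" * j + "Z" + "I" * (n - j - 1)] = -0.5
    return PauliSum(n, terms)


def hf_determinant(mi: MolecularIntegrals) -> str:
    """Occupation bitstring of the Hartree-Fock determinant (aufbau filling of
    the interleaved spin-orbitals), qubit 0 leftmost."""
    n, ne = mi.n_spin_orbitals, mi.n_electrons
    return "1" * ne + "0" * (n - ne)


# ---------------------------------------------------------------------------
# MO phase continuity along a geometry scan

def fix_mo_phases(prev: MOCoefficients, next_: MOCoefficients,
                  swap_tol: float = 0.8) -> tuple[MOCoefficients, list[str]]:
    """Align MO phases of ``next_`` with ``prev`` along a scan.

    Computes ``P = C_k^T S_k C_{k+1}``; a diagonal entry near -1 flags a phase
    jump in the corresponding MO, whose column in ``C_{k+1}`` is negated.  A
    diagonal magnitude far from 1 indicates an orbital-character swap between
    the geometries; that is reported as a warning string, not silently
    corrected.  Returns the rectified coefficients and the warning list.
    """
    if prev.matrix.shape != next_.matrix.shape:
        raise FixtureError("MO coefficient shape mismatch between geometries")
    p = prev.matrix.T @ prev.overlap @ next_.matrix
    diag = np.diag(p)
    fixed = next_.matrix.copy()
    warnings: list[str] = []
    for i, d in enumerate(diag):
        if abs(d) < swap_tol:
            warnings.append(
                f"MO {i}: |diagonal overlap| = {abs(d):.3f} suggests an "
                f"orbital-character swap between {prev.geometry_id} and "
                f"{next_.geometry_id}")
        if d < 0:
            fixed[:, i] = -fixed[:, i]
    return MOCoefficients(matrix=fixed, overlap=next_.overlap,
                          geometry_id=next_.geometry_id), warnings
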