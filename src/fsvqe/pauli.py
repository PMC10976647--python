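"""Phase-exact Pauli-string algebra.

Qubit-mapped molecular operators are stored as sparse real/complex-weighted
sums of Pauli strings (tensor products of the single-qubit operators
I, X, Y, Z).  This module provides the exact multiplicative algebra of such
strings, the two commutativity notions used for measurement grouping
(qubit-wise and general commutativity), and the algebraic construction of the
folded-spectrum operator (H - omega)^2 whose ground state is the eigenstate of
H closest in energy to the target omega.

Conventions
-----------
* A Pauli label is a string over the alphabet ``IXYZ`` with one letter per
  qubit; **qubit 0 is the leftmost letter**.  The same convention is used for
  the Kronecker order of matrix realizations and for bitstrings everywhere in
  the package.
* Phases arising from single-qubit products are powers of ``i`` and are
  tracked exactly (as an integer exponent), so that cancellations in operator
  products are exact and term counting is reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, TextIO

import numpy as np

__all__ = [
    "PauliString",
    "PauliSum",
    "FoldedOperator",
    "pauli_multiply",
    "commutes_qubitwise",
    "commutes_general",
    "fold_spectrum",
    "read_operator",
    "write_operator",
]

PAULI_LETTERS = "IXYZ"

#: single-qubit matrices, indexed by letter
PAULI_MATRICES = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}

# Single-qubit product table: (a, b) -> (result letter, phase exponent k)
# meaning  a @ b = i**k * result.
_PROD: dict[tuple[str, str], tuple[str, int]] = {}
for _a in PAULI_LETTERS:
    _PROD[("I", _a)] = (_a, 0)
    _PROD[(_a, "I")] = (_a, 0)
    _PROD[(_a, _a)] = ("I", 0)
_PROD[("X", "Y")] = ("Z", 1)
_PROD[("Y", "X")] = ("Z", 3)
_PROD[("Y", "Z")] = ("X", 1)
_PROD[("Z", "Y")] = ("X", 3)
_PROD[("Z", "X")] = ("Y", 1)
_PROD[("X", "Z")] = ("Y", 3)

_I_POWERS = (1.0 + 0.0j, 1.0j, -1.0 + 0.0j, -1.0j)

#: default coefficient pruning tolerance (numerical dust from phase arithmetic)
DEFAULT_TOL = 1e-12

#: guard rail for dense matrix realizations
MAX_DENSE_QUBITS = 12


class PauliError(ValueError):
    """Invalid Pauli-algebra input (length mismatch, bad label, ...)."""


class ResourceGuardError(RuntimeError):
    """Dense realization requested above the qubit guard rail."""


@dataclass(frozen=True)
class PauliString:
    """A tensor product of single-qubit Paulis, e.g. ``XIZY``."""

    label: str

    def __post_init__(self) -> None:
        if not self.label or any(c not in PAULI_LETTERS for c in self.label):
            raise PauliError(f"invalid Pauli label {self.label!r}")

    @property
    def n_qubits(self) -> int:
        return len(self.label)

    @property
    def weight(self) -> int:
        """Number of non-identity positions."""
        return sum(1 for c in self.label if c != "I")

    def is_diagonal(self) -> bool:
        return all(c in "IZ" for c in self.label)

    def to_matrix(self) -> np.ndarray:
        return _label_matrix(self.label)

    def __str__(self) -> str:
        return self.label


def _check_same_length(a: str, b: str) -> None:
    if len(a) != len(b):
        raise PauliError(f"qubit count mismatch: {a!r} vs {b!r}")


def pauli_multiply(p: PauliString | str, q: PauliString | str) -> tuple[complex, PauliString]:
    """Matrix product of two Pauli strings.

    Returns ``(phase, r)`` with ``phase`` in ``{+1, -1, +i, -i}`` such that
    ``phase * r`` equals the matrix product ``p @ q``.  Single-qubit phases
    multiply across positions and are tracked exactly.
    """
    pl = p.label if isinstance(p, PauliString) else p
    ql = q.label if isinstance(q, PauliString) else q
    _check_same_length(pl, ql)
    k = 0
    out = []
    for a, b in zip(pl, ql):
        c, dk = _PROD[(a, b)]
        out.append(c)
        k += dk
    return _I_POWERS[k % 4], PauliString("".join(out))


def commutes_qubitwise(p: PauliString | str, q: PauliString | str) -> bool:
    """Qubit-wise commutativity: at every position the letters are equal or
    at least one is the identity."""
    pl = p.label if isinstance(p, PauliString) else p
    ql = q.label if isinstance(q, PauliString) else q
    _check_same_length(pl, ql)
    return all(a == b or a == "I" or b == "I" for a, b in zip(pl, ql))


def commutes_general(p: PauliString | str, q: PauliString | str) -> bool:
    """General commutativity: the number of positions with distinct non-identity
    letters is even (the strings commute as matrices)."""
    pl = p.label if isinstance(p, PauliString) else p
    ql = q.label if isinstance(q, PauliString) else q
    _check_same_length(pl, ql)
    odd = sum(1 for a, b in zip(pl, ql) if a != "I" and b != "I" and a != b)
    return odd % 2 == 0


def _label_matrix(label: str) -> np.ndarray:
    m = PAULI_MATRICES[label[0]]
    for c in label[1:]:
        m = np.kron(m, PAULI_MATRICES[c])
    return m


class PauliSum:
    """A sparse weighted sum of Pauli strings on a fixed qubit register.

    Terms are held as a mapping ``label -> complex coefficient``; coefficients
    with magnitude below the pruning tolerance are dropped on construction and
    after every algebraic operation.  A Hermitian operator has all-real
    coefficients (Pauli strings form a Hermitian basis).
    """

    __slots__ = ("n_qubits", "terms")

    def __init__(self, n_qubits: int, terms: Mapping[str, complex] | None = None,
                 tol: float = DEFAULT_TOL):
        if n_qubits < 1:
            raise PauliError("n_qubits must be positive")
        self.n_qubits = int(n_qubits)
        self.terms: dict[str, complex] = {}
        if terms:
            for label, coeff in terms.items():
                if len(label) != n_qubits:
                    raise PauliError(f"label {label!r} does not act on {n_qubits} qubits")
                if any(c not in PAULI_LETTERS for c in label):
                    raise PauliError(f"invalid Pauli label {label!r}")
                if abs(coeff) >= tol:
                    self.terms[label] = complex(coeff)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[tuple[str, complex]]:
        return iter(self.terms.items())

    def __repr__(self) -> str:
        return f"PauliSum(n_qubits={self.n_qubits}, n_terms={len(self.terms)})"

    def copy(self) -> "PauliSum":
        out = PauliSum(self.n_qubits)
        out.terms = dict(self.terms)
        return out

    @property
    def identity_label(self) -> str:
        return "I" * self.n_qubits

    def coefficient(self, label: str) -> complex:
        return self.terms.get(label, 0.0 + 0.0j)

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return all(abs(c.imag) <= tol for c in self.terms.values())

    def labels(self) -> list[str]:
        return sorted(self.terms)

    def diagonal_labels(self) -> list[str]:
        return sorted(l for l in self.terms if all(c in "IZ" for c in l))

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "PauliSum") -> "PauliSum":
        return sum_combine(self, other)

    def __sub__(self, other: "PauliSum") -> "PauliSum":
        return sum_combine(self, other.scaled(-1.0))

    def __matmul__(self, other: "PauliSum") -> "PauliSum":
        return sum_multiply(self, other)

    def scaled(self, factor: complex) -> "PauliSum":
        out = PauliSum(self.n_qubits)
        out.terms = {l: factor * c for l, c in self.terms.items()}
        return out

    def pruned(self, tol: float = DEFAULT_TOL) -> "PauliSum":
        out = PauliSum(self.n_qubits)
        out.terms = {l: c for l, c in self.terms.items() if abs(c) >= tol}
        return out

    def real_part(self) -> "PauliSum":
        """Drop (tiny) imaginary parts of the coefficients."""
        out = PauliSum(self.n_qubits)
        out.terms = {l: complex(c.real, 0.0) for l, c in self.terms.items()}
        return out

    def to_matrix(self) -> np.ndarray:
        """Dense 2^n x 2^n realization (Kronecker order: qubit 0 leftmost)."""
        if self.n_qubits > MAX_DENSE_QUBITS:
            raise ResourceGuardError(
                f"dense realization refused for {self.n_qubits} qubits "
                f"(guard rail {MAX_DENSE_QUBITS})")
        dim = 2 ** self.n_qubits
        m = np.zeros((dim, dim), dtype=complex)
        for label, coeff in self.terms.items():
            m += coeff * _label_matrix(label)
        return m

    @staticmethod
    def from_matrix(matrix: np.ndarray, n_qubits: int, tol: float = DEFAULT_TOL) -> "PauliSum":
        """Decompose a matrix onto the Pauli basis via the trace inner product
        ``c_P = tr(P @ M) / 2^n``.  Exact inverse of :meth:`to_matrix`."""
        if n_qubits > MAX_DENSE_QUBITS:
            raise ResourceGuardError("decomposition refused above guard rail")
        dim = 2 ** n_qubits
        if matrix.shape != (dim, dim):
            raise PauliError("matrix shape does not match qubit count")
        terms: dict[str, complex] = {}
        for label in _all_labels(n_qubits):
            c = np.trace(_label_matrix(label) @ matrix) / dim
            if abs(c) >= tol:
                terms[label] = c
        return PauliSum(n_qubits, terms, tol=tol)


def _all_labels(n_qubits: int) -> Iterator[str]:
    if n_qubits == 1:
        yield from PAULI_LETTERS
        return
    for rest in _all_labels(n_qubits - 1):
        for c in PAULI_LETTERS:
            yield c + rest


def sum_combine(a: PauliSum, b: PauliSum, tol: float = DEFAULT_TOL) -> PauliSum:
    """Termwise sum with pruning of coefficients below ``tol``."""
    if a.n_qubits != b.n_qubits:
        raise PauliError("qubit count mismatch in sum")
    terms = dict(a.terms)
    for label, coeff in b.terms.items():
        terms[label] = terms.get(label, 0.0) + coeff
    out = PauliSum(a.n_qubits)
    out.terms = {l: c for l, c in terms.items() if abs(c) >= tol}
    return out


def sum_multiply(a: PauliSum, b: PauliSum, tol: float = DEFAULT_TOL) -> PauliSum:
    """Operator product, distributing the phase-exact string product over all
    term pairs and merging duplicate labels.

    For Hermitian ``a == b`` the cross terms generated by anticommuting string
    pairs cancel exactly, because the two phases are equal and opposite and the
    float coefficient product is identical on both sides.
    """
    if a.n_qubits != b.n_qubits:
        raise PauliError("qubit count mismatch in product")
    acc: dict[str, complex] = {}
    for la, ca in a.terms.items():
        for lb, cb in b.terms.items():
            phase, r = pauli_multiply(la, lb)
            acc[r.label] = acc.get(r.label, 0.0) + phase * ca * cb
    out = PauliSum(a.n_qubits)
    out.terms = {l: c for l, c in acc.items() if abs(c) >= tol}
    return out


@dataclass
class FoldedOperator:
    """The folded-spectrum operator (H - omega)^2 together with its parent.

    ``folded`` shares the eigenvectors of ``base``; its eigenvalues are
    ``(E_i - omega)^2``, so its ground state is the eigenstate of ``base``
    closest in energy to the target ``omega`` (in Hartree).
    """

    base: PauliSum
    omega: float
    folded: PauliSum = field(repr=False)

    @property
    def n_terms(self) -> int:
        return len(self.folded)


def fold_spectrum(h: PauliSum, omega: float, tol: float = DEFAULT_TOL) -> FoldedOperator:
    """Construct (H - omega I)^2 by direct phase-tracked squaring.

    The shifted operator is squared directly (rather than expanding
    ``H^2 - 2 omega H + omega^2``) so that the surviving term count does not
    depend on ``omega``.  Requires a Hermitian ``h`` (real coefficients); the
    result is Hermitian with a nonnegative spectrum.
    """
    if not h.is_hermitian():
        raise PauliError("fold_spectrum requires a Hermitian operator (real coefficients)")
    shifted = h.copy()
    ident = h.identity_label
    shifted.terms[ident] = shifted.terms.get(ident, 0.0) - omega
    folded = sum_multiply(shifted, shifted, tol=tol).real_part().pruned(tol)
    return FoldedOperator(base=h, omega=float(omega), folded=folded)


# -- plain-text operator format -------------------------------------------
#
# One term per line: "LABEL real_coeff [imag_coeff]"; a header line gives the
# qubit count.  The writer emits round-trip-exact float reprs.

def write_operator(s: PauliSum, fh: TextIO) -> None:
    fh.write(f"n_qubits {s.n_qubits}\n")
    for label in sorted(s.terms):
        c = s.terms[label]
        if c.imag == 0.0:
            fh.write(f"{label} {c.real!r}\n")
        else:
            fh.write(f"{label} {c.real!r} {c.imag!r}\n")


def read_operator(fh: TextIO) -> PauliSum:
    header = fh.readline().split()
    if len(header) != 2 or header[0] != "n_qubits":
        raise PauliError("operator file must start with 'n_qubits <int>'")
    n = int(header[1])
    terms: dict[str, complex] = {}
    for line in fh:
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (2, 3):
            raise PauliError(f"malformed operator line: {line!r}")
        label = parts[0]
        re = float(parts[1])
        im = float(parts[2]) if len(parts) == 3 else 0.0
        terms[label] = complex(re, im)
    out = PauliSum(n, tol=0.0)
    for label, c in terms.items():
        if len(label) != n or any(ch not in PAULI_LETTERS for ch in label):
            raise PauliError(f"invalid label {label!r} in operator file")
        out.terms[label] = c
    return out
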