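"""Reference states, the ordered Trotterized UCC ansatz, and simulators.

The ansatz is unitary coupled cluster with singles and doubles (UCCSD),
Trotterized at order 1 with a fixed excitation ordering: iterating through the
occupied indices ``j`` of the reference determinant in ascending order, all
spin-conserving single excitations involving ``j`` are appended, then all such
doubles, with deduplication across ``j``.  Each exponentiated generator string
becomes a Pauli gadget (basis changes, CNOT ladder, central Rz, mirrored
uncompute), so a weight-``w`` string costs ``2(w-1)`` CNOTs.

Three execution models are provided:

* exact statevector simulation (amplitudes, no sampling);
* finite-shot sampling from the exact distribution;
* density-matrix simulation under a tunable noise model: a depolarizing
  channel after every gate (error probability ``p1``/``p2``), followed by
  thermal relaxation (T1) and pure dephasing derived from the total coherence
  time T2 over the gate duration, plus a symmetric readout flip ``p_spam``
  per measured bit.  Noise acts on the touched qubits only; idle qubits do
  not decohere during other gates.  All parameters scale with a factor
  ``lambda`` in [0, 1]: geometrically for T1/T2 between their ideal and
  experimental values, linearly for everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np

from .measurement import Counts
from .pauli import PauliError, PauliSum, ResourceGuardError, sum_multiply
from .molham import jw_map_ladder

__all__ = [
    "Gate",
    "ParameterizedCircuit",
    "Excitation",
    "ReferenceState",
    "NoiseParams",
    "enumerate_excitations",
    "excitation_generator",
    "compile_ucc",
    "prepare_reference",
    "simulate_statevector",
    "sample_counts",
    "scale_noise",
    "simulate_noisy",
    "rotation_gates",
]

MAX_STATEVECTOR_QUBITS = 12
MAX_DENSITY_QUBITS = 8

_H = np.array([[1, 1], [1, -1]], dtype=complex) / math.sqrt(2)
_X = np.array([[0, 1], [1, 0]], dtype=complex)
_S = np.array([[1, 0], [0, 1j]], dtype=complex)
_SDG = _S.conj().T
_PAULI1 = {
    "X": _X,
    "Y": np.array([[0, -1j], [1j, 0]], dtype=complex),
    "Z": np.array([[1, 0], [0, -1]], dtype=complex),
}


@dataclass(frozen=True)
class Gate:
    """One circuit element.

    ``name`` is one of ``X, H, S, SDG, RZ, CNOT``.  For RZ, either ``angle``
    is a fixed rotation angle or ``slot``/``mult`` bind the angle to
    ``mult * theta[slot]`` at simulation time.
    """

    name: str
    qubits: tuple[int, ...]
    angle: float | None = None
    slot: int | None = None
    mult: float = 1.0

    def bound_angle(self, theta: Sequence[float]) -> float:
        if self.slot is not None:
            return self.mult * float(theta[self.slot])
        return float(self.angle or 0.0)

    def dagger(self) -> "Gate":
        if self.name == "S":
            return replace(self, name="SDG")
        if self.name == "SDG":
            return replace(self, name="S")
        if self.name == "RZ":
            if self.slot is not None:
                return replace(self, mult=-self.mult)
            return replace(self, angle=-(self.angle or 0.0))
        return self  # X, H, CNOT are self-inverse


@dataclass
class ParameterizedCircuit:
    """Ordered gate list with named parameter slots."""

    n_qubits: int
    gates: list[Gate] = field(default_factory=list)
    n_slots: int = 0

    def append(self, gate: Gate) -> None:
        self.gates.append(gate)

    def extend(self, gates: Iterable[Gate]) -> None:
        self.gates.extend(gates)

    def __len__(self) -> int:
        return len(self.gates)

    def concatenated(self, other: "ParameterizedCircuit | Sequence[Gate]") -> "ParameterizedCircuit":
        extra = other.gates if isinstance(other, ParameterizedCircuit) else list(other)
        n_slots = self.n_slots
        if isinstance(other, ParameterizedCircuit):
            n_slots = max(n_slots, other.n_slots)
        return ParameterizedCircuit(self.n_qubits, list(self.gates) + list(extra), n_slots)

    def inverse(self) -> "ParameterizedCircuit":
        return ParameterizedCircuit(
            self.n_qubits, [g.dagger() for g in reversed(self.gates)], self.n_slots)

    # line-per-gate plain-text serialization
    def write(self, fh: TextIO) -> None:
        fh.write(f"n_qubits {self.n_qubits} n_slots {self.n_slots}\n")
        for g in self.gates:
            qubits = " ".join(str(q) for q in g.qubits)
            if g.name == "RZ":
                if g.slot is not None:
                    fh.write(f"RZ {qubits} slot {g.slot} {g.mult!r}\n")
                else:
                    fh.write(f"RZ {qubits} angle {g.angle!r}\n")
            else:
                fh.write(f"{g.name} {qubits}\n")

    @staticmethod
    def read(fh: TextIO) -> "ParameterizedCircuit":
        header = fh.readline().split()
        circ = ParameterizedCircuit(int(header[1]), n_slots=int(header[3]))
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            name = parts[0]
            if name == "RZ":
                if parts[2] == "slot":
                    circ.append(Gate("RZ", (int(parts[1]),), slot=int(parts[3]),
                                     mult=float(parts[4])))
                else:
                    circ.append(Gate("RZ", (int(parts[1]),), angle=float(parts[3])))
            elif name == "CNOT":
                circ.append(Gate("CNOT", (int(parts[1]), int(parts[2]))))
            else:
                circ.append(Gate(name, (int(parts[1]),)))
        return circ


# ---------------------------------------------------------------------------
# excitations and the UCC ansatz

@dataclass(frozen=True)
class Excitation:
    """A spin-conserving single (rank 1) or double (rank 2) excitation."""

    rank: int
    occupied: tuple[int, ...]
    virtual: tuple[int, ...]
    slot: int

    def __post_init__(self) -> None:
        if self.rank not in (1, 2) or len(self.occupied) != self.rank \
                or len(self.virtual) != self.rank:
            raise ValueError("rank/index mismatch in excitation")
        # alpha = even index, beta = odd: spin composition must be conserved
        occ_spins = sorted(i % 2 for i in self.occupied)
        vir_spins = sorted(a % 2 for a in self.virtual)
        if occ_spins != vir_spins:
            raise ValueError("excitation does not conserve spin")


def enumerate_excitations(reference: str, n: int) -> list[Excitation]:
    """Ordered spin-conserving singles and doubles from a reference determinant.

    ``reference`` is an occupation bitstring (qubit 0 leftmost).  For each
    occupied index ``j`` in ascending order, all not-yet-emitted singles
    involving ``j`` are appended, then all such doubles; parameter slots are
    assigned in emission order.
    """
    if len(reference) != n or any(c not in "01" for c in reference):
        raise ValueError("reference must be a length-n occupation bitstring")
    occ = [i for i, c in enumerate(reference) if c == "1"]
    vir = [i for i, c in enumerate(reference) if c == "0"]
    seen: set[tuple] = set()
    out: list[Excitation] = []

    def emit(rank, occupied, virtual):
        key = (rank, occupied, virtual)
        if key in seen:
            return
        seen.add(key)
        out.append(Excitation(rank=rank, occupied=occupied, virtual=virtual,
                              slot=len(out)))

    for j in occ:
        for a in vir:
            if a % 2 == j % 2:
                emit(1, (j,), (a,))
        for i1 in occ:
            for i2 in occ:
                if i2 <= i1 or j not in (i1, i2):
                    continue
                for a1 in vir:
                    for a2 in vir:
                        if a2 <= a1:
                            continue
                        if sorted((i1 % 2, i2 % 2)) == sorted((a1 % 2, a2 % 2)):
                            emit(2, (i1, i2), (a1, a2))
    return out


def excitation_generator(e: Excitation, n: int) -> PauliSum:
    """JW image of the anti-Hermitian generator ``T_e - T_e^+``.

    For a single ``i -> a``, ``T = a+_a a_i``; for a double
    ``(i, j) -> (a, b)``, ``T = a+_a a+_b a_j a_i``.  All coefficients of the
    result are purely imaginary and its matrix realization is anti-Hermitian.
    """
    if e.rank == 1:
        (i,), (a,) = e.occupied, e.virtual
        ladder = [(a, True), (i, False)]
    else:
        (i, j), (a, b) = e.occupied, e.virtual
        ladder = [(a, True), (b, True), (j, False), (i, False)]
    t = jw_map_ladder(*ladder[0], n)
    for idx, dag in ladder[1:]:
        t = sum_multiply(t, jw_map_ladder(idx, dag, n))
    # T - T^+: Pauli strings are Hermitian, so conjugating T just conjugates
    # the coefficients; the difference keeps 2i * Im(coeff).
    gen = PauliSum(n)
    for label, c in t.terms.items():
        v = 2j * c.imag
        if abs(v) > 1e-14:
            gen.terms[label] = v
    return gen


def _pauli_gadget(label: str, slot: int, mult: float) -> list[Gate]:
    """Circuit for exp(-i (mult * theta[slot]) / 2 * P) with P = ``label``."""
    support = [q for q, c in enumerate(label) if c != "I"]
    if not support:
        return []
    pre: list[Gate] = []
    post: list[Gate] = []
    for q in support:
        c = label[q]
        if c == "X":
            pre.append(Gate("H", (q,)))
            post.append(Gate("H", (q,)))
        elif c == "Y":
            pre.extend([Gate("SDG", (q,)), Gate("H", (q,))])
            post.extend([Gate("H", (q,)), Gate("S", (q,))])
    ladder = [Gate("CNOT", (support[k], support[k + 1]))
              for k in range(len(support) - 1)]
    rz = [Gate("RZ", (support[-1],), slot=slot, mult=mult)]
    return pre + ladder + rz + list(reversed(ladder)) + post


def compile_ucc(excitations: Sequence[Excitation], n_qubits: int,
                scaling: float = 2.0) -> ParameterizedCircuit:
    """Trotterized UCC circuit: one Pauli gadget per generator string.

    Strings within one excitation's generator are emitted in lexicographic
    label order.  The bound physical amplitude of excitation ``e`` is
    ``scaling * theta[e.slot]``: the optimizer works in variables scaled down
    by ``scaling`` (default 2.0), which stretches its effective step length.
    """
    circ = ParameterizedCircuit(n_qubits, n_slots=len(excitations))
    for e in excitations:
        gen = excitation_generator(e, n_qubits)
        for label in sorted(gen.terms):
            r = gen.terms[label].imag  # generator term is i * r * P
            # exp(theta * i r P) = exp(-i (-2 r theta) / 2 P)
            circ.extend(_pauli_gadget(label, e.slot, -2.0 * r * scaling))
    return circ


# ---------------------------------------------------------------------------
# reference states

@dataclass
class ReferenceState:
    """One determinant, or an equal-weight (+/-) pair of determinants."""

    determinants: list[str]
    amplitudes: list[float]
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.determinants) <= 2:
            raise ValueError("reference supports at most two determinants")
        lengths = {len(d) for d in self.determinants}
        if len(lengths) != 1:
            raise ValueError("determinant length mismatch")
        counts = {d.count("1") for d in self.determinants}
        if len(counts) != 1:
            raise ValueError("determinants must share the electron count")
        norm = math.sqrt(sum(a * a for a in self.amplitudes))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("amplitudes must be normalized")

    @property
    def n_qubits(self) -> int:
        return len(self.determinants[0])

    def statevector(self) -> np.ndarray:
        v = np.zeros(2 ** self.n_qubits, dtype=complex)
        for d, a in zip(self.determinants, self.amplitudes):
            v[int(d, 2)] = a
        return v


def prepare_reference(r: ReferenceState) -> ParameterizedCircuit:
    """Compile a reference state to gates.

    A single determinant costs one X per occupied qubit.  An equal-weight
    two-determinant superposition (|D1> +/- |D2>)/sqrt(2) uses a Hadamard on
    the first differing qubit, a CNOT fan onto the other differing qubits and
    X gates fixing the occupations (plus an Rz(pi) realizing the relative
    minus sign, up to global phase).
    """
    circ = ParameterizedCircuit(r.n_qubits)
    if len(r.determinants) == 1:
        for q, c in enumerate(r.determinants[0]):
            if c == "1":
                circ.append(Gate("X", (q,)))
        return circ

    d1, d2 = r.determinants
    a1, a2 = r.amplitudes
    if abs(abs(a1) - abs(a2)) > 1e-9:
        raise ValueError("two-determinant references must be equal weight")
    diff = [q for q in range(r.n_qubits) if d1[q] != d2[q]]
    pivot = diff[0]
    circ.append(Gate("H", (pivot,)))
    if a1 * a2 < 0:
        circ.append(Gate("RZ", (pivot,), angle=math.pi))
    for q in diff[1:]:
        circ.append(Gate("CNOT", (pivot, q)))
    # branch with diff qubits all 0 must become D1, the all-1 branch D2
    for q in range(r.n_qubits):
        if (q in diff and d1[q] == "1") or (q not in diff and d1[q] == "1"):
            circ.append(Gate("X", (q,)))
    return circ


# ---------------------------------------------------------------------------
# statevector simulation

def _apply_1q(state: np.ndarray, u: np.ndarray, q: int, n: int) -> np.ndarray:
    state = np.tensordot(u, state, axes=([1], [q]))
    return np.moveaxis(state, 0, q)

def _apply_cnot(state: np.ndarray, control: int, target: int) -> np.ndarray:
    # swap the target axis halves on the control=1 slice
    idx: list[slice | int] = [slice(None)] * state.ndim
    idx[control] = 1
    sl = state[tuple(idx)]
    state[tuple(idx)] = np.flip(sl, axis=target - (1 if target > control else 0))
    return state


def _gate_unitary(g: Gate, theta: Sequence[float]) -> np.ndarray:
    if g.name == "X":
        return _X
    if g.name == "H":
        return _H
    if g.name == "S":
        return _S
    if g.name == "SDG":
        return _SDG
    if g.name == "RZ":
        a = g.bound_angle(theta)
        return np.array([[np.exp(-0.5j * a), 0], [0, np.exp(0.5j * a)]],
                        dtype=complex)
    raise PauliError(f"no single-qubit unitary for gate {g.name}")


def simulate_statevector(c: ParameterizedCircuit, theta: Sequence[float] = (),
                         init: np.ndarray | None = None) -> np.ndarray:
    """Exact amplitudes of the circuit output (norm 1 to machine precision).

    Starts from ``|0...0>`` unless ``init`` is given.  Index convention:
    amplitude ``v[i]`` belongs to the bitstring of ``i`` with qubit 0 as the
    most significant (leftmost) bit.
    """
    n = c.n_qubits
    if n > MAX_STATEVECTOR_QUBITS:
        raise ResourceGuardError(f"statevector refused for {n} qubits")
    if init is None:
        state = np.zeros((2,) * n, dtype=complex)
        state[(0,) * n] = 1.0
    else:
        state = np.array(init, dtype=complex).reshape((2,) * n)
    for g in c.gates:
        if g.name == "CNOT":
            state = _apply_cnot(state, *g.qubits)
        else:
            state = _apply_1q(state, _gate_unitary(g, theta), g.qubits[0], n)
    return state.reshape(-1)


def rotation_gates(post_rotation: Sequence[str]) -> list[Gate]:
    """Measurement-basis layer for a QWC group's per-qubit tags."""
    gates: list[Gate] = []
    for q, tag in enumerate(post_rotation):
        if tag == "X-basis":
            gates.append(Gate("H", (q,)))
        elif tag == "Y-basis":
            gates.extend([Gate("SDG", (q,)), Gate("H", (q,))])
        elif tag != "none":
            raise PauliError(f"unknown rotation tag {tag!r}")
    return gates


def sample_counts(state: np.ndarray, post_rotation: Sequence[str] | Sequence[Gate] | None,
                  shots: int, rng: np.random.Generator | int) -> Counts:
    """Multinomial draw from the (rotated) state's measurement distribution."""
    if shots < 1:
        raise ValueError("shots must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n = int(round(math.log2(state.size)))
    if post_rotation:
        gates = (rotation_gates(post_rotation)
                 if isinstance(post_rotation[0], str) else list(post_rotation))
        rot = ParameterizedCircuit(n, gates)
        state = simulate_statevector(rot, init=state)
    probs = np.abs(state) ** 2
    probs = probs / probs.sum()
    draws = rng.multinomial(shots, probs)
    hist = {format(i, f"0{n}b"): int(k) for i, k in enumerate(draws) if k}
    return Counts(histogram=hist, shots=shots)


# ---------------------------------------------------------------------------
# noise model

@dataclass
class NoiseParams:
    """Tunable noise model parameters (defaults: experimental magnitudes).

    T1/T2 in microseconds, gate times in nanoseconds; ``p1``/``p2`` are the
    one- and two-qubit depolarizing error probabilities and ``p_spam`` the
    per-qubit symmetric readout flip probability.  The ideal (lambda = 0)
    coherence times are finite stand-ins two orders of magnitude above the
    circuit length: T1 = 2000 us, T2 = 1000 us.
    """

    t1: float = 290.0
    t2: float = 145.0
    t_gate1: float = 35.0
    t_gate2: float = 300.0
    p1: float = 1e-4
    p2: float = 1e-3
    p_spam: float = 1e-2
    lambda_scale: float = 1.0

    T1_IDEAL: float = field(default=2000.0, repr=False)
    T2_IDEAL: float = field(default=1000.0, repr=False)

    def __post_init__(self) -> None:
        if self.t2 > 2.0 * self.t1 + 1e-9:
            raise ValueError("T2 cannot exceed 2*T1")
        for p in (self.p1, self.p2, self.p_spam):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def is_noiseless(self) -> bool:
        return self.p1 == 0 and self.p2 == 0 and self.p_spam == 0 and \
            self.t_gate1 == 0 and self.t_gate2 == 0


def scale_noise(base: NoiseParams, lam: float) -> NoiseParams:
    """Interpolate the noise level: geometric in T1/T2 between ideal and
    experimental values, linear in everything else.

    ``lam = 0`` is the ideal device, ``lam = 1`` reproduces ``base``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return NoiseParams(
        t1=base.T1_IDEAL ** (1.0 - lam) * base.t1 ** lam,
        t2=base.T2_IDEAL ** (1.0 - lam) * base.t2 ** lam,
        t_gate1=lam * base.t_gate1,
        t_gate2=lam * base.t_gate2,
        p1=lam * base.p1,
        p2=lam * base.p2,
        p_spam=lam * base.p_spam,
        lambda_scale=lam,
    )


def _depolarizing_kraus_1q(p: float) -> list[np.ndarray]:
    """Kraus set of the 1-qubit depolarizing channel
    rho -> (1-p) rho + p I/2."""
    if p == 0:
        return []
    ops = [math.sqrt(1.0 - 0.75 * p) * np.eye(2, dtype=complex)]
    ops += [math.sqrt(0.25 * p) * m for m in _PAULI1.values()]
    return ops


def _thermal_kraus(t_ns: float, t1_us: float, t2_us: float) -> list[np.ndarray]:
    """Amplitude damping (T1) composed with pure dephasing so that the total
    off-diagonal decay over ``t`` is exp(-t/T2); T2 is the *total* coherence
    time, with pure-dephasing rate 1/T2 - 1/(2 T1)."""
    if t_ns == 0:
        return []
    t_us = t_ns * 1e-3
    g = 1.0 - math.exp(-t_us / t1_us) if np.isfinite(t1_us) else 0.0
    gamma_phi = max(0.0, 1.0 / t2_us - 0.5 / t1_us) if np.isfinite(t2_us) else 0.0
    lam = 1.0 - math.exp(-2.0 * gamma_phi * t_us)
    ad = [np.array([[1, 0], [0, math.sqrt(1 - g)]], dtype=complex),
          np.array([[0, math.sqrt(g)], [0, 0]], dtype=complex)]
    pd = [np.array([[1, 0], [0, math.sqrt(1 - lam)]], dtype=complex),
          np.array([[0, 0], [0, math.sqrt(lam)]], dtype=complex)]
    out = []
    for a in pd:
        for b in ad:
            k = a @ b
            if np.any(np.abs(k) > 1e-15):
                out.append(k)
    return out


def per_gate_kraus(np_: NoiseParams, two_qubit: bool) -> list[np.ndarray]:
    """Composed per-touched-qubit Kraus set (depolarizing then thermal) for a
    one-qubit gate, or the per-qubit factor applied to each qubit of a
    two-qubit gate (the two-qubit depolarizing probability is applied as
    1 - sqrt(1 - p2) per qubit so the pair error totals p2)."""
    if two_qubit:
        p_eff = 1.0 - math.sqrt(max(0.0, 1.0 - np_.p2))
        t = np_.t_gate2
    else:
        p_eff = np_.p1
        t = np_.t_gate1
    dep = _depolarizing_kraus_1q(p_eff)
    th = _thermal_kraus(t, np_.t1, np_.t2)
    if not dep:
        return th
    if not th:
        return dep
    return [b @ a for a in dep for b in th]


def _dm_apply_1q(rho: np.ndarray, u: np.ndarray, q: int, n: int) -> np.ndarray:
    rho = np.tensordot(u, rho, axes=([1], [q]))
    rho = np.moveaxis(rho, 0, q)
    rho = np.tensordot(rho, u.conj(), axes=([n + q], [1]))
    return np.moveaxis(rho, -1, n + q)


def _dm_apply_kraus_1q(rho: np.ndarray, kraus: list[np.ndarray], q: int,
                       n: int) -> np.ndarray:
    if not kraus:
        return rho
    out = np.zeros_like(rho)
    for k in kraus:
        out += _dm_apply_1q(rho, k, q, n)
    return out


def _dm_apply_cnot(rho: np.ndarray, control: int, target: int, n: int) -> np.ndarray:
    idx: list[slice | int] = [slice(None)] * rho.ndim
    idx[control] = 1
    sl = rho[tuple(idx)]
    rho[tuple(idx)] = np.flip(sl, axis=target - (1 if target > control else 0))
    jdx: list[slice | int] = [slice(None)] * rho.ndim
    jdx[n + control] = 1
    sl = rho[tuple(jdx)]
    ax = n + target - (1 if n + target > n + control else 0)
    rho[tuple(jdx)] = np.flip(sl, axis=ax)
    return rho


def noisy_probabilities(c: ParameterizedCircuit, theta: Sequence[float],
                        noise: NoiseParams) -> np.ndarray:
    """Measurement distribution of the circuit under the noise model,
    including the readout-flip channel.  Density-matrix evolution; trace is
    preserved to numerical precision."""
    n = c.n_qubits
    if n > MAX_DENSITY_QUBITS:
        raise ResourceGuardError(f"density matrix refused for {n} qubits")
    rho = np.zeros((2,) * (2 * n), dtype=complex)
    rho[(0,) * (2 * n)] = 1.0
    for g in c.gates:
        if g.name == "CNOT":
            rho = _dm_apply_cnot(rho, g.qubits[0], g.qubits[1], n)
            kraus = per_gate_kraus(noise, two_qubit=True)
            for q in g.qubits:
                rho = _dm_apply_kraus_1q(rho, kraus, q, n)
        else:
            rho = _dm_apply_1q(rho, _gate_unitary(g, theta), g.qubits[0], n)
            kraus = per_gate_kraus(noise, two_qubit=False)
            rho = _dm_apply_kraus_1q(rho, kraus, g.qubits[0], n)
    dim = 2 ** n
    probs = np.real(np.diag(rho.reshape(dim, dim))).copy()
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    if noise.p_spam > 0:
        flip = np.array([[1 - noise.p_spam, noise.p_spam],
                         [noise.p_spam, 1 - noise.p_spam]])
        pt = probs.reshape((2,) * n)
        for q in range(n):
            pt = np.moveaxis(np.tensordot(flip, pt, axes=([1], [q])), 0, q)
        probs = pt.reshape(-1)
    return probs


def simulate_noisy(c: ParameterizedCircuit, theta: Sequence[float],
                   noise: NoiseParams, shots: int,
                   rng: np.random.Generator | int) -> Counts:
    """Finite-shot counts from the noisy measurement distribution."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    probs = noisy_probabilities(c, theta, noise)
    draws = rng.multinomial(shots, probs)
    n = c.n_qubits
    hist = {format(i, f"0{n}b"): int(k) for i, k in enumerate(draws) if k}
    return Counts(histogram=hist, shots=shots)
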