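"""Ansatz compilation, reference states, simulators and the noise model."""

import io
import math

import numpy as np
import pytest
from scipy.linalg import expm

from fsvqe.circuits import (Gate, NoiseParams, ParameterizedCircuit,
                            ReferenceState, _pauli_gadget, compile_ucc,
                            enumerate_excitations, excitation_generator,
                            noisy_probabilities, per_gate_kraus,
                            prepare_reference, sample_counts, scale_noise,
                            simulate_noisy, simulate_statevector)
from fsvqe.molham import number_operator
from fsvqe.pauli import PauliSum

_GATE1 = {
    "X": np.array([[0, 1], [1, 0]], complex),
    "H": np.array([[1, 1], [1, -1]], complex) / math.sqrt(2),
    "S": np.diag([1, 1j]).astype(complex),
    "SDG": np.diag([1, -1j]).astype(complex),
}


def circuit_unitary(circ, theta=()):
    """Independent dense-unitary build of a circuit (kron per gate)."""
    n = circ.n_qubits
    dim = 2 ** n
    u = np.eye(dim, dtype=complex)
    for g in circ.gates:
        if g.name == "CNOT":
            m = np.eye(dim, dtype=complex) * 0
            c, t = g.qubits
            for i in range(dim):
                bits = list(format(i, f"0{n}b"))
                if bits[c] == "1":
                    bits[t] = "0" if bits[t] == "1" else "1"
                m[int("".join(bits), 2), i] = 1.0
        else:
            if g.name == "RZ":
                a = g.bound_angle(theta)
                one = np.diag([np.exp(-0.5j * a), np.exp(0.5j * a)])
            else:
                one = _GATE1[g.name]
            ops = [np.eye(2, dtype=complex)] * n
            ops[g.qubits[0]] = one
            m = ops[0]
            for o in ops[1:]:
                m = np.kron(m, o)
        u = m @ u
    return u


# ---------------------------------------------------------------------------
# excitations

def test_excitation_counts():
    assert len(enumerate_excitations("1100", 4)) == 3
    assert len(enumerate_excitations("111100", 6)) == 8
    assert enumerate_excitations("1111", 4) == []   # no virtual orbitals


def test_excitation_ordering_is_occupied_index_major():
    ex = enumerate_excitations("1100", 4)
    kinds = [(e.rank, e.occupied, e.virtual) for e in ex]
    assert kinds == [(1, (0,), (2,)), (2, (0, 1), (2, 3)), (1, (1,), (3,))]


def test_excitations_conserve_spin():
    for e in enumerate_excitations("111100", 6):
        assert sorted(i % 2 for i in e.occupied) == sorted(a % 2 for a in e.virtual)


def test_single_generator_structure():
    ex = enumerate_excitations("1100", 4)
    g = excitation_generator(ex[0], 4)       # single 0 -> 2
    assert len(g) == 2
    assert all(PauliSum(4, {l: 1}).labels()[0].count("I") == 1 for l, _ in g)
    m = g.to_matrix()
    assert np.allclose(m, -m.conj().T)       # anti-Hermitian


def test_double_generator_structure():
    ex = enumerate_excitations("1100", 4)
    g = excitation_generator(ex[1], 4)       # double (0,1) -> (2,3)
    assert len(g) == 8
    assert all(all(c != "I" for c in l) for l, _ in g)  # weight 4
    m = g.to_matrix()
    assert np.allclose(m, -m.conj().T)
    u = expm(0.37 * m)
    assert np.allclose(u @ u.conj().T, np.eye(16), atol=1e-12)


# ---------------------------------------------------------------------------
# gadget compilation

def test_gadget_single_z_is_one_rz():
    gates = _pauli_gadget("ZI", slot=0, mult=1.0)
    assert len(gates) == 1 and gates[0].name == "RZ"


@pytest.mark.parametrize("label", ["ZZ", "XYZ", "XXYY", "YZZZX"])
def test_gadget_cnot_count(label):
    w = sum(1 for c in label if c != "I")
    gates = _pauli_gadget(label, slot=0, mult=1.0)
    assert sum(1 for g in gates if g.name == "CNOT") == 2 * (w - 1)


@pytest.mark.parametrize("label", ["ZZ", "XY", "YXZ", "XXYY"])
def test_gadget_implements_pauli_rotation(label):
    theta = [0.813]
    circ = ParameterizedCircuit(len(label), _pauli_gadget(label, 0, mult=1.0))
    u = circuit_unitary(circ, theta)
    p = PauliSum(len(label), {label: 1.0}).to_matrix()
    assert np.allclose(u, expm(-0.5j * theta[0] * p), atol=1e-12)


def test_compiled_ucc_equals_exponential_product(rng):
    ex = enumerate_excitations("1100", 4)
    theta = rng.normal(size=3)
    scaling = 2.0
    circ = compile_ucc(ex, 4, scaling=scaling)
    u = np.eye(16, dtype=complex)
    for e in ex:
        gen = excitation_generator(e, 4)
        for label in sorted(gen.terms):
            r = gen.terms[label].imag
            p = PauliSum(4, {label: 1.0}).to_matrix()
            u = expm(1j * scaling * theta[e.slot] * r * p) @ u
    ref = np.zeros(16, complex)
    ref[int("1100", 2)] = 1.0
    assert np.allclose(simulate_statevector(circ, theta, init=ref), u @ ref,
                       atol=1e-10)


def test_ucc_identity_at_zero_angles():
    ex = enumerate_excitations("1100", 4)
    circ = compile_ucc(ex, 4)
    ref = np.zeros(16, complex)
    ref[int("1100", 2)] = 1.0
    assert np.allclose(simulate_statevector(circ, np.zeros(3), init=ref), ref)


def test_ansatz_conserves_particle_number(rng):
    ex = enumerate_excitations("111100", 6)
    circ = compile_ucc(ex, 6)
    num = number_operator(6).to_matrix()
    ref = np.zeros(64, complex)
    ref[int("111100", 2)] = 1.0
    for _ in range(3):
        v = simulate_statevector(circ, rng.normal(size=8), init=ref)
        assert np.real(v.conj() @ num @ v) == pytest.approx(4.0, abs=1e-10)


# ---------------------------------------------------------------------------
# reference states

def test_prepare_hf_determinant():
    v = simulate_statevector(prepare_reference(ReferenceState(["1100"], [1.0])))
    expected = np.zeros(16)
    expected[int("1100", 2)] = 1.0
    assert np.allclose(v, expected)


@pytest.mark.parametrize("sign", [1.0, -1.0])
def test_prepare_two_determinant_superposition(sign):
    r = ReferenceState(["1001", "0110"], [1 / math.sqrt(2), sign / math.sqrt(2)])
    v = simulate_statevector(prepare_reference(r))
    target = r.statevector()
    phase = v[int("1001", 2)] / target[int("1001", 2)]
    assert abs(abs(phase) - 1.0) < 1e-12
    assert np.allclose(v, phase * target, atol=1e-12)


def test_reference_energy_is_diagonal_matrix_element(h2_ham):
    r = ReferenceState(["1010"], [1.0])
    v = simulate_statevector(prepare_reference(r))
    m = h2_ham.to_matrix()
    idx = int("1010", 2)
    assert np.real(v.conj() @ m @ v) == pytest.approx(m[idx, idx].real, abs=1e-12)


def test_reference_validation():
    with pytest.raises(ValueError):
        ReferenceState(["10", "01", "11"], [0.6, 0.6, 0.5])
    with pytest.raises(ValueError):
        ReferenceState(["10", "11"], [0.7, 0.7])  # electron count differs
    with pytest.raises(ValueError):
        ReferenceState(["10"], [0.5])             # not normalized


# ---------------------------------------------------------------------------
# simulators

def test_statevector_matches_dense_unitary(rng):
    gates = [Gate("H", (0,)), Gate("CNOT", (0, 2)), Gate("SDG", (1,)),
             Gate("RZ", (2,), angle=0.3), Gate("X", (1,)),
             Gate("CNOT", (2, 1)), Gate("S", (0,))]
    circ = ParameterizedCircuit(3, gates)
    v = simulate_statevector(circ)
    u = circuit_unitary(circ)
    init = np.zeros(8)
    init[0] = 1.0
    assert np.allclose(v, u @ init, atol=1e-12)
    assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)


def test_sample_counts_deterministic_under_seed():
    state = np.ones(4, complex) / 2.0
    c1 = sample_counts(state, None, 5000, 42)
    c2 = sample_counts(state, None, 5000, 42)
    assert c1.histogram == c2.histogram


def test_sample_counts_basis_state():
    state = np.zeros(4, complex)
    state[2] = 1.0
    c = sample_counts(state, None, 100, 0)
    assert c.histogram == {"10": 100}


def test_sample_counts_binomial_width():
    state = np.array([1.0, 1.0], complex) / math.sqrt(2)
    c = sample_counts(state, None, 10 ** 6, 3)
    freq = c.histogram["0"] / 10 ** 6
    assert abs(freq - 0.5) < 3 * 0.0005


def test_circuit_serialization_roundtrip():
    gates = [Gate("H", (0,)), Gate("CNOT", (0, 1)),
             Gate("RZ", (1,), slot=0, mult=-1.5), Gate("RZ", (0,), angle=0.25)]
    circ = ParameterizedCircuit(2, gates, n_slots=1)
    buf = io.StringIO()
    circ.write(buf)
    buf.seek(0)
    back = ParameterizedCircuit.read(buf)
    assert back.n_qubits == 2 and back.n_slots == 1
    assert back.gates == circ.gates


# ---------------------------------------------------------------------------
# noise model

def test_scale_noise_reproduces_tabulated_row():
    s = scale_noise(NoiseParams(), 0.4)
    assert s.t1 == pytest.approx(924, abs=1)
    assert s.t2 == pytest.approx(461, abs=1)
    assert s.t_gate1 == pytest.approx(14.0)
    assert s.t_gate2 == pytest.approx(120.0)
    assert s.p1 == pytest.approx(4e-5)
    assert s.p2 == pytest.approx(4e-4)
    assert s.p_spam == pytest.approx(4e-3)


def test_scale_noise_endpoints():
    z = scale_noise(NoiseParams(), 0.0)
    assert z.t1 == pytest.approx(2000.0) and z.p1 == 0 and z.p_spam == 0
    one = scale_noise(NoiseParams(), 1.0)
    assert one.t1 == pytest.approx(290.0) and one.p2 == pytest.approx(1e-3)
    with pytest.raises(ValueError):
        scale_noise(NoiseParams(), 1.2)


def test_noise_params_validation():
    with pytest.raises(ValueError):
        NoiseParams(t1=10.0, t2=25.0)   # T2 > 2 T1
    with pytest.raises(ValueError):
        NoiseParams(p_spam=1.5)


def test_zero_noise_matches_ideal_distribution():
    gates = [Gate("H", (0,)), Gate("CNOT", (0, 1))]
    circ = ParameterizedCircuit(2, gates)
    noiseless = scale_noise(NoiseParams(), 0.0)
    probs = noisy_probabilities(circ, [], noiseless)
    ideal = np.abs(simulate_statevector(circ)) ** 2
    assert np.allclose(probs, ideal, atol=1e-12)


def test_amplitude_damping_closed_form():
    """An excited qubit idling through n gates decays as exp(-n t / T1)."""
    noise = NoiseParams(t1=100.0, t2=100.0, t_gate1=1000.0, t_gate2=0.0,
                        p1=0.0, p2=0.0, p_spam=0.0)
    n_gates = 11
    gates = [Gate("X", (0,))] + [Gate("RZ", (0,), angle=0.0)] * (n_gates - 1)
    probs = noisy_probabilities(ParameterizedCircuit(1, gates), [], noise)
    assert probs[1] == pytest.approx(math.exp(-n_gates * 1e-3 * 1000 / 100),
                                     abs=1e-12)


def test_full_spam_randomizes_readout():
    noise = NoiseParams(p_spam=0.5, p1=0.0, p2=0.0, t_gate1=0.0, t_gate2=0.0)
    circ = ParameterizedCircuit(1, [Gate("X", (0,))])
    probs = noisy_probabilities(circ, [], noise)
    assert np.allclose(probs, [0.5, 0.5])


@pytest.mark.parametrize("two_qubit", [False, True])
def test_per_gate_channel_is_cptp(two_qubit):
    """Choi positivity and trace preservation of the composed channel."""
    noise = scale_noise(NoiseParams(), 0.7)
    kraus = per_gate_kraus(noise, two_qubit=two_qubit)
    total = sum(k.conj().T @ k for k in kraus)
    assert np.allclose(total, np.eye(2), atol=1e-12)
    choi = sum(np.kron(k, np.eye(2)) @ np.outer([1, 0, 0, 1], [1, 0, 0, 1])
               @ np.kron(k, np.eye(2)).conj().T for k in kraus)
    assert np.min(np.linalg.eigvalsh(choi)) > -1e-12


def test_noisy_counts_reproducible_and_trace_preserved():
    noise = scale_noise(NoiseParams(), 0.3)
    circ = ParameterizedCircuit(2, [Gate("H", (0,)), Gate("CNOT", (0, 1))])
    c1 = simulate_noisy(circ, [], noise, 2000, 5)
    c2 = simulate_noisy(circ, [], noise, 2000, 5)
    assert c1.histogram == c2.histogram
    assert sum(c1.histogram.values()) == 2000
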