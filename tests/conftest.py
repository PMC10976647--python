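import numpy as np
import pytest

from fsvqe.molham import build_hamiltonian, packaged_fixture


@pytest.fixture(scope="session")
def h2_mi():
    return packaged_fixture("h2_sto3g_0.74")


@pytest.fixture(scope="session")
def h2_ham(h2_mi):
    return build_hamiltonian(h2_mi)


@pytest.fixture(scope="session")
def lih_mi():
    return packaged_fixture("lih_sminimal_1.59")


@pytest.fixture(scope="session")
def lih_ham(lih_mi):
    return build_hamiltonian(lih_mi)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pauli_sum(rng, n_qubits, n_terms, hermitian=True):
    """Random sparse Pauli sum for oracle comparisons."""
    from fsvqe.pauli import PauliSum
    letters = "IXYZ"
    terms = {}
    for _ in range(n_terms):
        label = "".join(rng.choice(list(letters)) for _ in range(n_qubits))
        coeff = rng.normal()
        if not hermitian:
            coeff = coeff + 1j * rng.normal()
        terms[label] = terms.get(label, 0.0) + coeff
    return PauliSum(n_qubits, terms)
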