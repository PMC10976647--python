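"""The folded-spectrum VQE optimization loop.

A run minimizes the expectation of the folded operator (H - omega)^2 over the
parameters of the ordered Trotterized UCCSD ansatz applied to an excited
reference state.  Execution models: exact statevector (deterministic
quasi-Newton optimization), ideal finite-shot sampling, and the noisy
density-matrix simulator (both driven by SPSA with an increasing shot
schedule, followed by quadratic refinement and parameter rounding).  Along a
potential-energy scan the converged parameters and energy of one geometry
warm-start the next (state tracking), with an optional parameter-continuity
penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .circuits import (ParameterizedCircuit, ReferenceState, compile_ucc,
                       enumerate_excitations, NoiseParams, prepare_reference,
                       rotation_gates, sample_counts, simulate_statevector,
                       noisy_probabilities)
from .measurement import (Counts, MeasurementGroup, estimate_operator,
                          group_operator)
from .molham import MolecularIntegrals, build_hamiltonian
from .pauli import FoldedOperator, PauliSum, fold_spectrum

__all__ = [
    "CostSpec",
    "SPSAConfig",
    "ShotSchedule",
    "PESRun",
    "ExactBackend",
    "SampledBackend",
    "NoisyBackend",
    "GroupedOperator",
    "evaluate_cost",
    "spsa_minimize",
    "shots_at",
    "quadratic_refine",
    "round_parameters",
    "fci_energies",
    "sector_energies",
    "target_energy",
    "solve_state",
    "scan_pes",
]

HARTREE_TO_KCAL = 627.5094740631


class OptimizationError(RuntimeError):
    """Cost diverged; the partial trace is attached as ``.trace``."""

    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# grouped operators and execution backends

class GroupedOperator:
    """An operator with lazily built QWC measurement groups and a lazily
    cached dense matrix (used by the statevector fast path)."""

    def __init__(self, operator: PauliSum):
        self.operator = operator
        self._groups: list[MeasurementGroup] | None = None
        self._matrix: np.ndarray | None = None

    @property
    def groups(self) -> list[MeasurementGroup]:
        if self._groups is None:
            self._groups = group_operator(self.operator, "QWC")
        return self._groups

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = self.operator.to_matrix()
        return self._matrix

    @staticmethod
    def build(operator: PauliSum) -> "GroupedOperator":
        return GroupedOperator(operator)


class ExactBackend:
    """Statevector execution: exact expectations / measurement distributions.

    The expectation fast path contracts the cached dense operator matrix with
    the exact state; it coincides with the grouped-measurement estimate on
    exact distributions (regrouping invariance), which the test suite asserts
    through :func:`fsvqe.measurement.estimate_operator`.
    """

    kind = "statevector"

    def expectation_value(self, circuit: ParameterizedCircuit,
                          theta: Sequence[float], grouped: GroupedOperator) -> float:
        state = simulate_statevector(circuit, theta)
        return float(np.real(state.conj() @ grouped.matrix @ state))

    def group_distributions(self, circuit: ParameterizedCircuit,
                            theta: Sequence[float], grouped: GroupedOperator,
                            shots: int):
        state = simulate_statevector(circuit, theta)
        n = circuit.n_qubits
        out = []
        for g in grouped.groups:
            rot = ParameterizedCircuit(n, rotation_gates(g.post_rotation))
            rotated = simulate_statevector(rot, init=state)
            probs = np.abs(rotated) ** 2
            out.append({format(i, f"0{n}b"): p for i, p in enumerate(probs)
                        if p > 1e-300})
        return out


class SampledBackend:
    """Ideal hardware with finite sampling: multinomial counts per group."""

    kind = "sampled"

    def __init__(self, rng: np.random.Generator | int = 0):
        self.rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    def group_distributions(self, circuit, theta, grouped: GroupedOperator,
                            shots: int):
        state = simulate_statevector(circuit, theta)
        return [sample_counts(state, g.post_rotation, shots, self.rng)
                for g in grouped.groups]


class NoisyBackend:
    """Density-matrix execution under the scaled noise model."""

    kind = "noisy"

    def __init__(self, noise: NoiseParams, rng: np.random.Generator | int = 0):
        self.noise = noise
        self.rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    def group_distributions(self, circuit, theta, grouped: GroupedOperator,
                            shots: int):
        n = circuit.n_qubits
        out = []
        for g in grouped.groups:
            meas = circuit.concatenated(rotation_gates(g.post_rotation))
            probs = noisy_probabilities(meas, theta, self.noise)
            draws = self.rng.multinomial(shots, probs)
            hist = {format(i, f"0{n}b"): int(k) for i, k in enumerate(draws) if k}
            out.append(Counts(histogram=hist, shots=shots))
        return out


Backend = ExactBackend | SampledBackend | NoisyBackend


# ---------------------------------------------------------------------------
# cost function

@dataclass
class CostSpec:
    """What to minimize: a grouped operator evaluated on an ansatz circuit,
    optionally regularized toward the previous scan point's parameters."""

    grouped: GroupedOperator
    circuit: ParameterizedCircuit
    omega: float | None = None
    eta: float = 0.0
    theta_prev: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.eta > 0 and self.theta_prev is None:
            raise ValueError("a continuity penalty requires theta_prev")


def evaluate_cost(spec: CostSpec, theta: Sequence[float], backend: Backend,
                  shots: int = 10000) -> float:
    """<Psi(theta)|O|Psi(theta)> estimated from grouped measurements, plus
    ``eta * ||theta - theta_prev||^2`` when the continuity penalty is on."""
    theta = np.asarray(theta, dtype=float)
    if hasattr(backend, "expectation_value"):
        value = backend.expectation_value(spec.circuit, theta, spec.grouped)
    else:
        dists = backend.group_distributions(spec.circuit, theta, spec.grouped, shots)
        value = estimate_operator(spec.grouped.operator, spec.grouped.groups, dists)
    if spec.eta > 0:
        value += spec.eta * float(np.sum((theta - spec.theta_prev) ** 2))
    return value


# ---------------------------------------------------------------------------
# SPSA with shot scheduling

@dataclass
class SPSAConfig:
    """Spall-form gain sequences ``a_k = a/(A + k + 1)^alpha`` and
    ``c_k = c/(k + 1)^gamma``; termination on a smoothed gradient-estimate
    norm below ``grad_tol`` or on ``max_iter``."""

    a: float = 0.15
    c: float = 0.1
    A: float | None = None       # defaults to 10% of max_iter
    alpha: float = 0.602
    gamma: float = 0.101
    max_iter: int = 400
    grad_tol: float = 1e-9
    grad_window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0 or self.grad_tol <= 0:
            raise ValueError("gains and tolerance must be positive")


@dataclass
class ShotSchedule:
    """Inverse-exponential shot scheduler
    ``s(t) = round(s_max - (s_max - s_min) * exp(-k t))``; monotone
    nondecreasing from ``s_min`` at t = 0 toward ``s_max``."""

    s_min: int = 1000
    s_max: int = 10000
    rate: float = 0.01
    final_shots: int = 30000

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.s_min > self.s_max:
            raise ValueError("invalid shot schedule")


def shots_at(sched: ShotSchedule, t: int) -> int:
    if t < 0:
        raise ValueError("iteration index must be nonnegative")
    return int(round(sched.s_max - (sched.s_max - sched.s_min)
                     * math.exp(-sched.rate * t)))


def spsa_minimize(cost: Callable[[np.ndarray, int], float], theta0: Sequence[float],
                  cfg: SPSAConfig, sched: ShotSchedule
                  ) -> tuple[np.ndarray, list[dict]]:
    """Simultaneous-perturbation stochastic approximation.

    Per iteration: draw a Rademacher perturbation, evaluate the cost at the
    two perturbed points (exactly two evaluations regardless of dimension),
    and step along the simultaneous-perturbation gradient estimate.  Fully
    reproducible from the config seed.  Returns the final parameters and a
    per-iteration trace (theta, cost values, gradient-estimate norm, shots).
    """
    theta = np.array(theta0, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    big_a = cfg.A if cfg.A is not None else 0.1 * cfg.max_iter
    trace: list[dict] = []
    recent: list[float] = []
    for t in range(cfg.max_iter):
        s = shots_at(sched, t)
        ck = cfg.c / (t + 1) ** cfg.gamma
        delta = rng.integers(0, 2, size=theta.size) * 2.0 - 1.0
        y_plus = cost(theta + ck * delta, s)
        y_minus = cost(theta - ck * delta, s)
        if not (np.isfinite(y_plus) and np.isfinite(y_minus)):
            raise OptimizationError("cost diverged during SPSA", trace)
        ghat = (y_plus - y_minus) / (2.0 * ck) * delta  # 1/delta_i == delta_i
        ak = cfg.a / (big_a + t + 1) ** cfg.alpha
        theta = theta - ak * ghat
        gnorm = float(np.linalg.norm(ghat))
        recent.append(gnorm)
        if len(recent) > cfg.grad_window:
            recent.pop(0)
        trace.append({"iter": t, "theta": theta.copy(), "cost_plus": y_plus,
                      "cost_minus": y_minus, "grad_norm": gnorm, "shots": s})
        if len(recent) == cfg.grad_window and \
                float(np.mean(recent)) < cfg.grad_tol:
            break
    return theta, trace


# ---------------------------------------------------------------------------
# post-optimization processing

def quadratic_refine(cost: Callable[[np.ndarray], float], theta: Sequence[float],
                     probe_radius: float = 0.05, n_probe: int = 5) -> np.ndarray:
    """Per-parameter parabolic refinement around a converged solution.

    Probes ``n_probe`` points across ``+/- probe_radius``, fits a parabola by
    least squares, and moves to its vertex when the fit is convex and the
    evaluated cost does not increase; a non-convex local fit leaves the
    parameter unchanged.  Never returns a point with (measured) higher cost.
    """
    theta = np.array(theta, dtype=float)
    current = cost(theta)
    offsets = np.linspace(-probe_radius, probe_radius, n_probe)
    for i in range(theta.size):
        values = []
        for d in offsets:
            trial = theta.copy()
            trial[i] += d
            values.append(cost(trial))
        coeffs = np.polyfit(offsets, values, 2)
        if coeffs[0] <= 0:
            continue  # negative curvature: not near a minimum along this axis
        vertex = -coeffs[1] / (2.0 * coeffs[0])
        vertex = float(np.clip(vertex, -2 * probe_radius, 2 * probe_radius))
        trial = theta.copy()
        trial[i] += vertex
        trial_cost = cost(trial)
        if trial_cost <= current:
            theta, current = trial, trial_cost
    return theta


ROUND_CANDIDATES = (0.0, 0.5 * math.pi, -0.5 * math.pi, math.pi, -math.pi)


def round_parameters(cost: Callable[[np.ndarray], float], theta: Sequence[float],
                     scaling: float = 2.0, tol: float = 0.02) -> np.ndarray:
    """Snap near-special physical angles (0, +/-pi/2, +/-pi) to their exact
    values, keeping each rounding only if the evaluated cost does not
    increase.  ``scaling`` converts optimizer variables to physical angles."""
    theta = np.array(theta, dtype=float)
    current = cost(theta)
    for i in range(theta.size):
        phys = scaling * theta[i]
        for cand in ROUND_CANDIDATES:
            if abs(phys - cand) < tol and phys != cand:
                trial = theta.copy()
                trial[i] = cand / scaling
                trial_cost = cost(trial)
                if trial_cost <= current:
                    theta, current = trial, trial_cost
                break
    return theta


# ---------------------------------------------------------------------------
# exact diagonalization references

def fci_energies(h: PauliSum) -> np.ndarray:
    """All eigenvalues of the qubit Hamiltonian, ascending (Hartree)."""
    return np.linalg.eigvalsh(h.to_matrix())


def _sector_indices(n_qubits: int, n_electrons: int) -> np.ndarray:
    return np.array([i for i in range(2 ** n_qubits)
                     if bin(i).count("1") == n_electrons])


def sector_energies(h: PauliSum, n_electrons: int
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenpairs of the particle-number sector (H commutes with the JW
    number operator, so the sector submatrix is exact).

    Returns ``(energies, vectors, basis_indices)``: vectors are columns in the
    sector basis, ``basis_indices`` maps sector rows to full-register states.
    """
    idx = _sector_indices(h.n_qubits, n_electrons)
    sub = h.to_matrix()[np.ix_(idx, idx)]
    w, v = np.linalg.eigh(sub)
    return w, v, idx


def target_energy(h: PauliSum, reference: ReferenceState,
                  n_electrons: int) -> float:
    """FCI energy of the eigenstate with maximal overlap onto ``reference``
    (the state the folded-spectrum run is aimed at)."""
    w, v, idx = sector_energies(h, n_electrons)
    ref = reference.statevector()[idx]
    overlaps = np.abs(v.conj().T @ ref) ** 2
    return float(w[int(np.argmax(overlaps))])


# ---------------------------------------------------------------------------
# single-point FS-VQE

@dataclass
class StateResult:
    """Outcome of one FS-VQE (or plain VQE) run at one geometry."""

    label: str
    geometry_id: str
    energy: float                 # final <H> at final_shots, Hartree
    omega: float | None
    theta: np.ndarray
    converged: bool
    n_evaluations: int
    cost_final: float
    trace: list = field(default_factory=list, repr=False)


def build_ansatz(mi: MolecularIntegrals, reference: ReferenceState,
                 scaling: float = 2.0) -> ParameterizedCircuit:
    """Reference preparation followed by the ordered UCCSD ansatz.

    The excitation list is enumerated from the reference's (first, dominant)
    determinant: the completeness of the single-step Trotterized UCC expansion
    under the fixed excitation ordering is relative to the determinant being
    excited, so an excited-state run uses the excitations of its own
    reference.  For the Hartree-Fock reference this reduces to the usual
    ground-state UCCSD ansatz.
    """
    excitations = enumerate_excitations(reference.determinants[0],
                                        mi.n_spin_orbitals)
    return prepare_reference(reference).concatenated(
        compile_ucc(excitations, mi.n_spin_orbitals, scaling=scaling))


def solve_state(mi: MolecularIntegrals, reference: ReferenceState,
                backend: Backend, *, omega: float | None = "auto",
                theta0: np.ndarray | None = None,
                cfg: SPSAConfig | None = None,
                sched: ShotSchedule | None = None,
                scaling: float = 2.0, eta: float = 0.0,
                theta_prev: np.ndarray | None = None,
                hamiltonian: PauliSum | None = None,
                grouped_h: GroupedOperator | None = None) -> StateResult:
    """One folded-spectrum VQE run (or plain VQE when ``omega`` is None).

    ``omega="auto"`` targets the expectation of H in the reference state; a
    float targets that energy; None minimizes <H> directly (ground state).
    The final energy is always the Hamiltonian expectation measured at
    ``sched.final_shots`` (exact on the statevector backend).
    """
    cfg = cfg or SPSAConfig()
    sched = sched or ShotSchedule()
    h = hamiltonian if hamiltonian is not None else build_hamiltonian(mi)
    grouped_h = grouped_h or GroupedOperator.build(h)
    circuit = build_ansatz(mi, reference, scaling=scaling)

    if omega == "auto":
        ref_state = reference.statevector()
        omega = float(np.real(ref_state.conj() @ h.to_matrix() @ ref_state))
    if omega is None:
        grouped_cost = grouped_h
    else:
        folded = fold_spectrum(h, float(omega))
        grouped_cost = GroupedOperator.build(folded.folded)

    spec = CostSpec(grouped=grouped_cost, circuit=circuit, omega=omega,
                    eta=eta, theta_prev=theta_prev)
    n_params = circuit.n_slots
    theta = np.zeros(n_params) if theta0 is None else np.array(theta0, dtype=float)
    evals = 0

    def shot_cost(th: np.ndarray, shots: int) -> float:
        nonlocal evals
        evals += 1
        return evaluate_cost(spec, th, backend, shots)

    trace: list = []
    if n_params == 0:
        # the reference is already the trial state (no excitations apply)
        converged = True
    elif isinstance(backend, ExactBackend):
        def exact_cost(spec_, th):
            nonlocal evals
            evals += 1
            return evaluate_cost(spec_, th, backend)

        theta, spec, converged = _optimize_exact(h, spec, theta, backend,
                                                 exact_cost)
    else:
        theta, trace = spsa_minimize(shot_cost, theta, cfg, sched)
        final_cost = lambda th: shot_cost(th, sched.final_shots)
        theta = quadratic_refine(final_cost, theta)
        theta = round_parameters(final_cost, theta, scaling=scaling)
        converged = True

    cost_final = shot_cost(theta, sched.final_shots)
    energy = _final_energy(spec, grouped_h, theta, backend, sched.final_shots)
    return StateResult(label=reference.label, geometry_id=mi.geometry_id,
                       energy=energy, omega=None if omega is None else float(omega),
                       theta=theta, converged=converged, n_evaluations=evals,
                       cost_final=cost_final, trace=trace)


def _optimize_exact(h: PauliSum, spec: CostSpec, theta0: np.ndarray,
                    backend: ExactBackend, cost_fn=None
                    ) -> tuple[np.ndarray, CostSpec, bool]:
    """Deterministic minimization on the statevector backend.

    For a folded cost, the target energy is iterated to self-consistency
    (``omega`` replaced by the measured energy after each round, which deepens
    the correct minimum), and a few deterministically perturbed restarts are
    tried if the folded cost has not reached its known floor of zero.
    """
    grouped_h = GroupedOperator.build(h)
    if cost_fn is None:
        cost_fn = lambda spec_, th: evaluate_cost(spec_, th, backend)

    def run(spec_, th0):
        res = minimize(lambda th: cost_fn(spec_, th), th0,
                       method="BFGS", options={"gtol": 1e-12, "maxiter": 1000})
        return res.x, float(res.fun), bool(res.success or np.linalg.norm(res.jac) < 1e-7)

    theta, cost, ok = run(spec, theta0)
    if spec.omega is None:
        return theta, spec, ok

    for _ in range(4):  # self-consistent refolding
        energy = backend.expectation_value(spec.circuit, theta, grouped_h)
        if abs(energy - spec.omega) < 1e-10 and cost < 1e-12:
            break
        folded = fold_spectrum(h, energy)
        spec = CostSpec(grouped=GroupedOperator.build(folded.folded),
                        circuit=spec.circuit, omega=energy, eta=spec.eta,
                        theta_prev=spec.theta_prev)
        theta, cost, ok = run(spec, theta)
    if cost > 1e-9:  # restarts from deterministically jittered starts
        rng = np.random.default_rng(7)
        for _ in range(3):
            cand, ccost, cok = run(spec, theta0 + 0.1 * rng.standard_normal(theta0.size))
            if ccost < cost:
                theta, cost, ok = cand, ccost, cok
                energy = backend.expectation_value(spec.circuit, theta, grouped_h)
                folded = fold_spectrum(h, energy)
                spec = CostSpec(grouped=GroupedOperator.build(folded.folded),
                                circuit=spec.circuit, omega=energy, eta=spec.eta,
                                theta_prev=spec.theta_prev)
                theta, cost, ok = run(spec, theta)
            if cost < 1e-12:
                break
    return theta, spec, ok and cost < 1e-9


def _final_energy(spec: CostSpec, grouped_h: GroupedOperator, theta,
                  backend: Backend, shots: int) -> float:
    if hasattr(backend, "expectation_value"):
        return backend.expectation_value(spec.circuit, theta, grouped_h)
    dists = backend.group_distributions(spec.circuit, theta, grouped_h, shots)
    return estimate_operator(grouped_h.operator, grouped_h.groups, dists)


# ---------------------------------------------------------------------------
# potential-energy scan with state tracking

@dataclass
class PESRun:
    """A geometry scan for a set of electronic states.

    When tracking is on, the target energy for point k+1 is the energy
    recorded at point k (``omega_{k+1} = E_k``) and the parameters warm-start
    from ``theta_k``.
    """

    geometries: list[str]
    states: list[str]
    results: dict[tuple[str, str], StateResult] = field(default_factory=dict)

    def energies(self, state: str) -> list[float]:
        return [self.results[(g, state)].energy for g in self.geometries]

    def omegas(self, state: str) -> list[float | None]:
        return [self.results[(g, state)].omega for g in self.geometries]


def scan_pes(fixtures: Sequence[MolecularIntegrals],
             references: dict[str, ReferenceState],
             states: Sequence[str], backend_factory: Callable[[], Backend],
             *, cfg: SPSAConfig | None = None,
             sched: ShotSchedule | None = None, scaling: float = 2.0,
             track: bool = True, eta_points: set[str] | None = None,
             eta: float = 0.1) -> PESRun:
    """FS-VQE along an ascending geometry scan with state tracking.

    ``backend_factory`` builds a fresh backend per state (so seeds are
    independent).  ``eta_points`` names geometry ids where the parameter
    continuity penalty (weight ``eta``) is engaged.  A non-converged point is
    flagged in its result and the scan continues.
    """
    geometries = [mi.geometry_id for mi in fixtures]
    if geometries != sorted(geometries, key=float):
        raise ValueError("fixtures must be ordered by ascending geometry")
    run = PESRun(geometries=list(geometries), states=list(states))
    for label in states:
        backend = backend_factory()
        theta_prev: np.ndarray | None = None
        omega_prev: float | None = None
        for mi in fixtures:
            use_eta = eta_points is not None and mi.geometry_id in eta_points \
                and theta_prev is not None
            try:
                result = solve_state(
                    mi, references[label], backend,
                    omega="auto" if omega_prev is None else omega_prev,
                    theta0=theta_prev if track else None,
                    cfg=cfg, sched=sched, scaling=scaling,
                    eta=eta if use_eta else 0.0,
                    theta_prev=theta_prev if use_eta else None)
            except OptimizationError as exc:
                result = StateResult(label=label, geometry_id=mi.geometry_id,
                                     energy=math.nan, omega=omega_prev,
                                     theta=theta_prev, converged=False,
                                     n_evaluations=0, cost_final=math.nan,
                                     trace=exc.trace)
            run.results[(mi.geometry_id, label)] = result
            if track and result.converged:
                theta_prev = result.theta
                omega_prev = result.energy
        # fresh state for the next electronic state
    return run
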