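"""Restricted Hartree-Fock over contracted s-type Gaussian basis sets.

Both molecular systems shipped with this package (H2 in the STO-3G basis, LiH
in a minimal basis restricted to s orbitals) are described entirely by s-type
contracted Gaussians, for which every required integral (overlap, kinetic,
nuclear attraction, two-electron repulsion) has a classical closed form in
terms of the Boys function F0.  This module implements those closed forms, a
plain SCF loop with symmetric orthogonalization, and the assembly of
spin-orbital integrals in the conventions used by the rest of the package:

* spatial orbitals are RHF canonical MOs, ordered by orbital energy;
* spin-orbitals are interleaved, ``p = 2*i + sigma`` with ``sigma = 0`` for
  alpha and ``1`` for beta on spatial orbital ``i``;
* the two-body array holds antisymmetrized-free physicist-notation integrals
  ``h[p,q,r,s] = <pq|rs>`` (charge-cloud ``(pr|qs)`` with spin deltas
  ``sigma_p == sigma_r`` and ``sigma_q == sigma_s``), so the electronic
  Hamiltonian is ``sum h_pq a+_p a_q + 1/2 sum <pq|rs> a+_p a+_q a_s a_r``.

All quantities in Hartree atomic units unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

# STO-3G s shells: (exponents, contraction coefficients) for normalized
# primitives.  H uses the zeta = 1.24 scaled hydrogen exponents.
STO3G_S_SHELLS: dict[str, list[tuple[tuple[float, ...], tuple[float, ...]]]] = {
    "H": [
        ((3.42525091, 0.62391373, 0.16885540),
         (0.15432897, 0.53532814, 0.44463454)),
    ],
    "Li": [
        ((16.1195750, 2.9362007, 0.7946505),
         (0.15432897, 0.53532814, 0.44463454)),
        ((0.6362897, 0.1478601, 0.0480887),
         (-0.09996723, 0.39951283, 0.70011547)),
    ],
}

NUCLEAR_CHARGE = {"H": 1, "Li": 3}


@dataclass
class ContractedS:
    """A normalized contracted s-type Gaussian on a nuclear center."""

    center: np.ndarray
    exponents: np.ndarray
    coefficients: np.ndarray  # includes primitive and contraction norms

    @staticmethod
    def build(center, shell) -> "ContractedS":
        exps = np.asarray(shell[0], dtype=float)
        raw = np.asarray(shell[1], dtype=float)
        # primitive normalization (2a/pi)^(3/4)
        prim_norm = (2.0 * exps / np.pi) ** 0.75
        coeff = raw * prim_norm
        # normalize the contracted function
        self_overlap = 0.0
        for a, ca in zip(exps, coeff):
            for b, cb in zip(exps, coeff):
                self_overlap += ca * cb * (np.pi / (a + b)) ** 1.5
        coeff = coeff / np.sqrt(self_overlap)
        return ContractedS(np.asarray(center, dtype=float), exps, coeff)


def boys_f0(x: np.ndarray | float) -> np.ndarray | float:
    """F0(x) = (1/2) sqrt(pi/x) erf(sqrt(x)), with the x -> 0 limit of 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    mask = x > 1e-12
    xm = x[mask]
    out[mask] = 0.5 * np.sqrt(np.pi / xm) * erf(np.sqrt(xm))
    return out if out.ndim else float(out)


def _pair_quantities(ga: ContractedS, gb: ContractedS):
    a = ga.exponents[:, None]
    b = gb.exponents[None, :]
    p = a + b
    mu = a * b / p
    rab2 = float(np.dot(ga.center - gb.center, ga.center - gb.center))
    kab = np.exp(-mu * rab2)
    coeff = ga.coefficients[:, None] * gb.coefficients[None, :]
    centers = (a[..., None] * ga.center + b[..., None] * gb.center) / p[..., None]
    return p, mu, rab2, kab, coeff, centers


def overlap(ga: ContractedS, gb: ContractedS) -> float:
    p, mu, rab2, kab, coeff, _ = _pair_quantities(ga, gb)
    return float(np.sum(coeff * (np.pi / p) ** 1.5 * kab))


def kinetic(ga: ContractedS, gb: ContractedS) -> float:
    p, mu, rab2, kab, coeff, _ = _pair_quantities(ga, gb)
    t = mu * (3.0 - 2.0 * mu * rab2) * (np.pi / p) ** 1.5 * kab
    return float(np.sum(coeff * t))


def nuclear_attraction(ga: ContractedS, gb: ContractedS,
                       nuclei: list[tuple[np.ndarray, int]]) -> float:
    p, mu, rab2, kab, coeff, centers = _pair_quantities(ga, gb)
    total = 0.0
    for pos, charge in nuclei:
        rpc2 = np.sum((centers - pos) ** 2, axis=-1)
        v = -charge * 2.0 * np.pi / p * kab * boys_f0(p * rpc2)
        total += float(np.sum(coeff * v))
    return total


def electron_repulsion(ga, gb, gc, gd) -> float:
    """Charge-cloud integral (ab|cd) over contracted s functions."""
    p, _, _, kab, cab, pab = _pair_quantities(ga, gb)
    q, _, _, kcd, ccd, pcd = _pair_quantities(gc, gd)
    pf = p[:, :, None, None]
    qf = q[None, None, :, :]
    kf = kab[:, :, None, None] * kcd[None, None, :, :]
    cf = cab[:, :, None, None] * ccd[None, None, :, :]
    diff = pab[:, :, None, None, :] - pcd[None, None, :, :, :]
    rpq2 = np.sum(diff ** 2, axis=-1)
    val = 2.0 * np.pi ** 2.5 / (pf * qf * np.sqrt(pf + qf)) * kf \
        * boys_f0(pf * qf / (pf + qf) * rpq2)
    return float(np.sum(cf * val))


@dataclass
class RHFResult:
    e_total: float          # HF total energy, Hartree
    e_nuclear: float        # nuclear repulsion, Hartree
    mo_energies: np.ndarray
    mo_coeff: np.ndarray    # AO x MO
    overlap: np.ndarray     # AO x AO
    hcore: np.ndarray       # AO x AO
    eri_ao: np.ndarray      # (ab|cd), chemist notation, AO basis
    n_electrons: int


def run_rhf(atoms: list[tuple[str, np.ndarray]], max_cycles: int = 200,
            conv: float = 1e-12) -> RHFResult:
    """SCF for a closed-shell molecule described by s-type STO-3G shells.

    ``atoms`` is a list of (element symbol, position in bohr).
    """
    basis = [ContractedS.build(pos, shell)
             for sym, pos in atoms for shell in STO3G_S_SHELLS[sym]]
    nuclei = [(np.asarray(pos, dtype=float), NUCLEAR_CHARGE[sym]) for sym, pos in atoms]
    nbf = len(basis)
    n_electrons = sum(z for _, z in nuclei)
    if n_electrons % 2:
        raise ValueError("closed-shell RHF requires an even electron count")
    nocc = n_electrons // 2

    s = np.array([[overlap(a, b) for b in basis] for a in basis])
    t = np.array([[kinetic(a, b) for b in basis] for a in basis])
    v = np.array([[nuclear_attraction(a, b, nuclei) for b in basis] for a in basis])
    hcore = t + v
    eri = np.zeros((nbf,) * 4)
    for i in range(nbf):
        for j in range(nbf):
            for k in range(nbf):
                for l in range(nbf):
                    eri[i, j, k, l] = electron_repulsion(basis[i], basis[j],
                                                         basis[k], basis[l])

    e_nuc = 0.0
    for i in range(len(nuclei)):
        for j in range(i + 1, len(nuclei)):
            rij = np.linalg.norm(nuclei[i][0] - nuclei[j][0])
            e_nuc += nuclei[i][1] * nuclei[j][1] / rij

    # symmetric orthogonalization
    sval, svec = np.linalg.eigh(s)
    x = svec @ np.diag(sval ** -0.5) @ svec.T

    dm = np.zeros((nbf, nbf))
    e_old = 0.0
    mo_e = np.zeros(nbf)
    c = np.zeros((nbf, nbf))
    for _ in range(max_cycles):
        j = np.einsum("pqrs,rs->pq", eri, dm)
        k = np.einsum("prqs,rs->pq", eri, dm)
        f = hcore + j - 0.5 * k
        fo = x.T @ f @ x
        mo_e, co = np.linalg.eigh(fo)
        c = x @ co
        cocc = c[:, :nocc]
        dm_new = 2.0 * cocc @ cocc.T
        e_elec = 0.5 * np.sum(dm_new * (hcore + f))
        if abs(e_elec - e_old) < conv and np.max(np.abs(dm_new - dm)) < 1e-10:
            dm = dm_new
            e_old = e_elec
            break
        dm = dm_new
        e_old = e_elec

    return RHFResult(e_total=e_old + e_nuc, e_nuclear=e_nuc, mo_energies=mo_e,
                     mo_coeff=c, overlap=s, hcore=hcore, eri_ao=eri,
                     n_electrons=n_electrons)


def spin_orbital_integrals(res: RHFResult) -> tuple[np.ndarray, np.ndarray]:
    """Interleaved spin-orbital one-body h_pq and physicist two-body <pq|rs>.

    Returns ``(one_body, two_body)`` with ``N = 2 * n_spatial`` spin-orbitals,
    ``p = 2*i + sigma`` (alpha = 0, beta = 1).
    """
    c = res.mo_coeff
    h_mo = c.T @ res.hcore @ c
    eri_mo = np.einsum("pi,qj,rk,sl,pqrs->ijkl", c, c, c, c, res.eri_ao,
                       optimize=True)  # (ij|kl) chemist, MO basis
    nmo = c.shape[1]
    n = 2 * nmo
    one = np.zeros((n, n))
    two = np.zeros((n, n, n, n))
    for p in range(n):
        for q in range(n):
            if p % 2 == q % 2:
                one[p, q] = h_mo[p // 2, q // 2]
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s_ in range(n):
                    if p % 2 == r % 2 and q % 2 == s_ % 2:
                        # <pq|rs> = (pr|qs) in chemist notation
                        two[p, q, r, s_] = eri_mo[p // 2, r // 2, q // 2, s_ // 2]
    return one, two
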