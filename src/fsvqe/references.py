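"""Reference-state catalog for the shipped molecules.

Excited-state targeting needs a reference with significant overlap onto the
target eigenstate.  These references are built by exciting the Hartree-Fock
determinant and, for open-shell singlets and Ms = 0 triplet components,
spin-symmetrizing into an equal-weight two-determinant superposition.
Triplets are represented by their Ms = 1 single-determinant component.

Occupation bitstrings use the interleaved spin-orbital convention: qubit
``2*i`` is the alpha and ``2*i + 1`` the beta spin-orbital of spatial orbital
``i``; qubit 0 is leftmost.

H2/STO-3G (spatial orbitals sigma_g, sigma_u):

==========  =====================================  =====================
state       configuration                          reference
==========  =====================================  =====================
ground      (sigma_g)^2                            ``1100``
T1          (sigma_g)(sigma_u), Ms = 1             ``1010``
S1          open-shell singlet (sg su)             (``1001`` - ``0110``)/sqrt2
S2          (sigma_u)^2                            ``0011``
==========  =====================================  =====================

LiH s-only minimal basis (spatial orbitals sigma_1..sigma_3, HF = s1^2 s2^2);
the eight excited states in energy order with their dominant configurations:

==========  =====================================  =====================
T1          s1^2 s2 s3 triplet, Ms = 1             ``111010``
S1          s1^2 (s2 s3) open-shell singlet        (``111001`` - ``110110``)/sqrt2
S2          s1^2 s3^2                              ``110011``
T2          s1 s2^2 s3 triplet, Ms = 1             ``101110``
S3          s1 s2^2 s3 open-shell singlet          (``011110`` - ``101101``)/sqrt2
T3          s1 s2 s3^2 triplet, Ms = 1             ``101011``
S4          s1 s2 s3^2 open-shell singlet          (``100111`` - ``011011``)/sqrt2
S5          s2^2 s3^2                              ``001111``
==========  =====================================  =====================

The relative sign inside each two-determinant singlet is stated after the
Jordan-Wigner fermionic sign convention of this package (Z strings on lower
qubit indices); it is the sign for which the superposition carries the
open-shell *singlet* rather than the Ms = 0 triplet component.
"""

from __future__ import annotations

import math

from .circuits import ReferenceState

_RT2 = 1.0 / math.sqrt(2.0)

H2_REFERENCES: dict[str, ReferenceState] = {
    "ground": ReferenceState(["1100"], [1.0], label="ground"),
    "T1": ReferenceState(["1010"], [1.0], label="T1"),
    "S1": ReferenceState(["1001", "0110"], [_RT2, -_RT2], label="S1"),
    "S2": ReferenceState(["0011"], [1.0], label="S2"),
}

#: the three excited states of H2 in energy order
H2_EXCITED = ("T1", "S1", "S2")

LIH_REFERENCES: dict[str, ReferenceState] = {
    "ground": ReferenceState(["111100"], [1.0], label="ground"),
    "T1": ReferenceState(["111010"], [1.0], label="T1"),
    "S1": ReferenceState(["111001", "110110"], [_RT2, -_RT2], label="S1"),
    "S2": ReferenceState(["110011"], [1.0], label="S2"),
    "T2": ReferenceState(["101110"], [1.0], label="T2"),
    "S3": ReferenceState(["011110", "101101"], [_RT2, -_RT2], label="S3"),
    "T3": ReferenceState(["101011"], [1.0], label="T3"),
    "S4": ReferenceState(["100111", "011011"], [_RT2, -_RT2], label="S4"),
    "S5": ReferenceState(["001111"], [1.0], label="S5"),
}

#: the eight excited states of LiH in energy order
LIH_EXCITED = ("T1", "S1", "S2", "T2", "S3", "T3", "S4", "S5")


def references_for(molecule: str) -> dict[str, ReferenceState]:
    key = molecule.upper()
    if key == "H2":
        return H2_REFERENCES
    if key == "LIH":
        return LIH_REFERENCES
    raise KeyError(f"no reference catalog for molecule {molecule!r}")
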