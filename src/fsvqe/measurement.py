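"""Partitioning Pauli sums into simultaneously measurable groups.

Evaluating a molecular operator term by term would cost one circuit execution
per Pauli string.  Strings that commute — qubit-wise (QWC) or in the general
matrix sense (GC) — can share a single measurement, so the evaluation cost is
set by the number of groups in a clique cover of the commutation graph, not by
the term count.  Finding the minimum clique cover is NP-hard; this module uses
a deterministic greedy heuristic (sequential coloring of the complement graph,
largest-degree-first with lexicographic tie-breaking) which reproduces the
known group counts for the shipped systems but makes no optimality claim.

Diagonal (I/Z-only) strings all commute with one another in both modes and are
always evaluable from one and the same counts histogram, so they are seeded
into a single shared group before the greedy pass.

Bitstring convention: the leftmost character of a histogram key is qubit 0,
matching the Pauli label convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np

from .pauli import (PauliError, PauliSum, commutes_general, commutes_qubitwise)

__all__ = [
    "MeasurementGroup",
    "Counts",
    "build_commutation_graph",
    "clique_cover",
    "group_operator",
    "assign_post_rotation",
    "expectation_from_counts",
    "estimate_operator",
]

Mode = Literal["QWC", "GC"]


class CoverageError(ValueError):
    """A label of the operator is not covered by any measurement group."""


@dataclass
class MeasurementGroup:
    """A set of mutually commuting Pauli labels sharing one measurement.

    For QWC groups ``post_rotation`` holds one per-qubit basis-change tag from
    ``{"none", "X-basis", "Y-basis"}``; rotating every member accordingly
    yields an I/Z-only string, measurable in the computational basis.
    """

    members: list[str]
    mode: Mode
    post_rotation: list[str] | None = None

    def __post_init__(self) -> None:
        commutes = commutes_qubitwise if self.mode == "QWC" else commutes_general
        for i, a in enumerate(self.members):
            for b in self.members[i + 1:]:
                if not commutes(a, b):
                    raise PauliError(
                        f"{a} and {b} do not commute under {self.mode}")

    @property
    def n_qubits(self) -> int:
        return len(self.members[0])


@dataclass
class Counts:
    """Bitstring histogram from repeated measurement of one circuit."""

    histogram: dict[str, int]
    shots: int

    def __post_init__(self) -> None:
        total = sum(self.histogram.values())
        if total != self.shots:
            raise ValueError(f"histogram totals {total} != shots {self.shots}")
        if any(v < 0 for v in self.histogram.values()):
            raise ValueError("negative count")

    def probabilities(self) -> dict[str, float]:
        return {b: c / self.shots for b, c in self.histogram.items()}


def build_commutation_graph(s: PauliSum | Iterable[str], mode: Mode) -> nx.Graph:
    """Graph over the labels of ``s`` with an edge iff the pair commutes
    under ``mode``."""
    labels = sorted(s.terms) if isinstance(s, PauliSum) else sorted(s)
    if not labels:
        raise PauliError("cannot build a commutation graph for an empty sum")
    commutes = commutes_qubitwise if mode == "QWC" else commutes_general
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if commutes(a, b):
                g.add_edge(a, b)
    g.graph["mode"] = mode
    return g


def clique_cover(graph: nx.Graph) -> list[MeasurementGroup]:
    """Deterministic greedy clique cover of a commutation graph.

    Equivalent to coloring the complement graph: vertices are visited in
    order of decreasing non-commuting degree (lexicographic tie-break) and
    placed in the first existing group whose members all commute with them.
    Diagonal strings are seeded into one shared group first.
    """
    mode: Mode = graph.graph.get("mode", "QWC")
    labels = list(graph.nodes)
    n_all = len(labels)
    diagonal = sorted(l for l in labels if all(c in "IZ" for c in l))
    rest = [l for l in labels if l not in set(diagonal)]
    # complement degree = number of non-commuting pairs
    comp_degree = {l: n_all - 1 - graph.degree(l) for l in labels}
    rest.sort(key=lambda l: (-comp_degree[l], l))

    groups: list[list[str]] = []
    if diagonal:
        groups.append(diagonal)
    for label in rest:
        placed = False
        for g in groups:
            if all(graph.has_edge(label, m) for m in g):
                g.append(label)
                placed = True
                break
        if not placed:
            groups.append([label])
    return [MeasurementGroup(members=sorted(g), mode=mode) for g in groups]


def group_operator(s: PauliSum, mode: Mode = "QWC",
                   with_rotations: bool = True) -> list[MeasurementGroup]:
    """Convenience: commutation graph + clique cover (+ QWC post-rotations)."""
    groups = clique_cover(build_commutation_graph(s, mode))
    if mode == "QWC" and with_rotations:
        groups = [assign_post_rotation(g) for g in groups]
    return groups


def assign_post_rotation(g: MeasurementGroup) -> MeasurementGroup:
    """Per-qubit basis-change tags diagonalizing every member of a QWC group.

    A Hadamard (X-basis tag) is applied where any member carries X, and the
    adjoint-phase-then-Hadamard sequence (Y-basis tag) where any member
    carries Y.  Within a QWC group the non-identity letter at a position is
    unique, so the assignment is well defined.
    """
    if g.mode != "QWC":
        raise PauliError("post-rotation synthesis is only supported for QWC groups")
    n = g.n_qubits
    tags = ["none"] * n
    for label in g.members:
        for q, c in enumerate(label):
            if c == "X":
                tags[q] = "X-basis"
            elif c == "Y":
                tags[q] = "Y-basis"
    return MeasurementGroup(members=g.members, mode=g.mode, post_rotation=tags)


def rotated_label(label: str, post_rotation: Sequence[str]) -> str:
    """The I/Z-only image of ``label`` after the group's post-rotation."""
    out = []
    for c, tag in zip(label, post_rotation):
        if c == "I":
            out.append("I")
        elif c == "Z":
            if tag != "none":
                raise PauliError(f"rotation {tag} clashes with Z in {label}")
            out.append("Z")
        elif (c == "X" and tag == "X-basis") or (c == "Y" and tag == "Y-basis"):
            out.append("Z")
        else:
            raise PauliError(f"rotation tags do not diagonalize {label}")
    return "".join(out)


def _diagonal_expectation(dist: Mapping[str, float], label: str) -> float:
    if any(c not in "IZ" for c in label):
        raise PauliError(f"label {label} is not diagonal; rotate first")
    z_pos = [i for i, c in enumerate(label) if c == "Z"]
    total = 0.0
    for bitstring, weight in dist.items():
        parity = sum(1 for i in z_pos if bitstring[i] == "1") % 2
        total += weight * (1.0 - 2.0 * parity)
    return total


def expectation_from_counts(c: Counts, label: str) -> float:
    """Expectation of a diagonal Pauli string from a counts histogram:
    ``sum_i lambda_i count_i / s`` with ``lambda_i = (-1)^popcount`` on the
    label's Z positions."""
    return _diagonal_expectation(c.probabilities(), label)


def estimate_operator(s: PauliSum, groups: Sequence[MeasurementGroup],
                      counts: Sequence[Counts | Mapping[str, float]]) -> float:
    """Weighted sum of per-string expectations read from grouped measurements.

    ``counts[i]`` holds the histogram (or an exact probability distribution)
    measured for ``groups[i]`` after its post-rotation.  The identity label
    needs no measurement; every other label of ``s`` must appear in exactly
    one group.  Returns the estimate in the units of the coefficients
    (Hartree for molecular operators).
    """
    if len(groups) != len(counts):
        raise ValueError("one Counts per group required")
    owner: dict[str, int] = {}
    for gi, g in enumerate(groups):
        for label in g.members:
            owner.setdefault(label, gi)
    total = 0.0
    ident = s.identity_label
    for label, coeff in s.terms.items():
        if label == ident:
            total += coeff.real
            continue
        if label not in owner:
            raise CoverageError(f"label {label} not covered by any group")
        gi = owner[label]
        g = groups[gi]
        rot = rotated_label(label, g.post_rotation) if g.post_rotation else label
        dist = counts[gi].probabilities() if isinstance(counts[gi], Counts) else counts[gi]
        total += coeff.real * _diagonal_expectation(dist, rot)
    return total
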