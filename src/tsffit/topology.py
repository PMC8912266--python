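"""Bond-graph queries: topological separation, Hessian-element weighting,
and enumeration of internal coordinates.

The Cartesian-Hessian objective weights each Hessian element by how many
bonds separate its two atoms: 1-1 elements (both Cartesian components on
the same atom) get 0.0, 1-2 and 1-3 interactions get 0.031, 1-4
interactions (terminal atoms of a torsion) get 0.31, and everything further
apart — including disconnected fragments — gets 0.031 again. Zeroing the
1-1 block is what lets the fit represent a saddle point as a minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .structures import MolecularSystem

__all__ = [
    "DISCONNECTED",
    "bond_separation",
    "separation_matrix",
    "hessian_pair_weight",
    "InternalCoordinateTable",
    "enumerate_internals",
]

DISCONNECTED = "disconnected"

W_SAME_ATOM = 0.0
W_NEAR = 0.031    # 1-2 and 1-3 interactions
W_TORSION = 0.31  # 1-4 interactions
W_FAR = 0.031     # separation > 3 bonds, and disconnected pairs


def bond_graph(system: MolecularSystem) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(system.n_atoms))
    g.add_edges_from(system.bonds)
    return g


def bond_separation(system: MolecularSystem, i: int, j: int):
    """Shortest bond-path length between atoms i and j; 0 when i == j;
    :data:`DISCONNECTED` when no path exists."""
    n = system.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range: ({i}, {j})")
    if i == j:
        return 0
    g = bond_graph(system)
    try:
        return nx.shortest_path_length(g, i, j)
    except nx.NetworkXNoPath:
        return DISCONNECTED


def separation_matrix(system: MolecularSystem) -> np.ndarray:
    """All-pairs bond separations; -1 encodes disconnected."""
    n = system.n_atoms
    sep = -np.ones((n, n), dtype=int)
    g = bond_graph(system)
    for i, dists in nx.all_pairs_shortest_path_length(g):
        for j, d in dists.items():
            sep[i, j] = d
    return sep


def hessian_pair_weight(separation) -> float:
    """Topological weight for a Hessian element given its atoms' separation."""
    if separation == 0:
        return W_SAME_ATOM
    if separation in (1, 2):
        return W_NEAR
    if separation == 3:
        return W_TORSION
    return W_FAR


@dataclass
class InternalCoordinateTable:
    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    torsions: list[tuple[int, int, int, int]] = field(default_factory=list)
    impropers: list[tuple[int, int, int, int]] = field(default_factory=list)


def enumerate_internals(system: MolecularSystem) -> InternalCoordinateTable:
    """All bonds, angles (vertex central) and proper torsions of the bond
    graph, duplicate-free under reversal. Impropers are not perceived
    automatically; they follow the parameter file."""
    g = bond_graph(system)
    bonds = sorted(tuple(sorted(e)) for e in g.edges)

    angles = []
    for j in sorted(g.nodes):
        for i, k in combinations(sorted(g.neighbors(j)), 2):
            angles.append((i, j, k))

    torsions = []
    for j, k in bonds:
        for i in g.neighbors(j):
            if i == k:
                continue
            for l in g.neighbors(k):
                if l == j or l == i:
                    continue
                quad = (i, j, k, l)
                if quad[::-1] < quad:
                    quad = quad[::-1]
                torsions.append(quad)
    torsions = sorted(set(torsions))

    return InternalCoordinateTable(bonds=bonds, angles=angles, torsions=torsions)
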