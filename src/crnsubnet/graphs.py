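"""Graph views of a CRN and neighbor counts by reaction type.

The CRN bipartite hypergraph induces a *reaction monopartite graph*: a
directed graph whose nodes are reactions, with an arc from reaction ``i``
to reaction ``j`` whenever some species is a product of ``i`` and a
reactant of ``j``.  Self-arcs are legal (a reaction producing one of its
own reactants).

All count tables returned here are pandas DataFrames indexed by element
name, with one column per reaction-type code.  Depth-2 neighbor counts use
distinct-node semantics: a cell counts the *set* of reactions at that
depth, computed independently of depth 1, so every cell is monotone
non-decreasing under adding reactions to the network — the property that
makes the compatibility constraints sound (no false negatives).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Network, ReactionType

__all__ = [
    "ReactionGraph",
    "build_monopartite",
    "reaction_neighbor_type_counts",
    "species_incidence_type_counts",
    "species_reach_type_counts",
]


@dataclass(frozen=True)
class ReactionGraph:
    """Directed reaction-to-reaction graph as a boolean adjacency matrix.

    ``adjacency[i, j]`` is True iff reaction ``i`` has a product species
    that is a reactant of reaction ``j``.
    """

    reaction_names: tuple[str, ...]
    adjacency: np.ndarray

    @property
    def arcs(self) -> set[tuple[str, str]]:
        ii, jj = np.nonzero(self.adjacency)
        return {(self.reaction_names[i], self.reaction_names[j]) for i, j in zip(ii, jj)}

    def to_edge_list(self) -> str:
        """Debug dump: one ``source<TAB>dest`` line per arc, sorted."""
        return "\n".join(f"{a}\t{b}" for a, b in sorted(self.arcs)) + "\n"


def build_monopartite(net: Network) -> ReactionGraph:
    """Project the bipartite hypergraph onto reactions."""
    produces = net.product > 0  # species x reactions
    consumes = net.reactant > 0
    adjacency = (produces.T.astype(int) @ consumes.astype(int)) > 0
    return ReactionGraph(tuple(net.reaction_names), adjacency)


def _type_indicator(net: Network) -> tuple[list[str], np.ndarray]:
    """One-hot reactions-by-type matrix and the sorted type-code universe."""
    types = [t.code for t in net.reaction_types()]
    universe = sorted(set(types))
    col = {t: k for k, t in enumerate(universe)}
    ind = np.zeros((net.num_reactions, len(universe)), dtype=int)
    for j, t in enumerate(types):
        ind[j, col[t]] = 1
    return universe, ind


def reaction_neighbor_type_counts(
    g: ReactionGraph, net: Network, direction: str
) -> pd.DataFrame:
    """Counts of 1-step and 2-step neighbors by reaction type.

    ``direction`` is ``"predecessor"`` or ``"successor"``.  A 2-step
    predecessor is a predecessor of a 1-step predecessor (and likewise for
    successors); depth-1 and depth-2 sets are counted independently, as
    distinct nodes.

    Columns are a MultiIndex (depth in {1, 2}, type code).
    """
    if direction not in ("predecessor", "successor"):
        raise ValueError(f"unknown direction {direction!r}")
    adj = g.adjacency
    if direction == "predecessor":
        adj = adj.T  # adj[r, x]: x is a 1-step predecessor of r
    d1 = adj
    d2 = (adj.astype(int) @ adj.astype(int)) > 0
    universe, ind = _type_indicator(net)
    counts = np.hstack([d1.astype(int) @ ind, d2.astype(int) @ ind])
    columns = pd.MultiIndex.from_tuples(
        [(1, t) for t in universe] + [(2, t) for t in universe], names=["depth", "type"]
    )
    return pd.DataFrame(counts, index=list(net.reaction_names), columns=columns)


def species_incidence_type_counts(net: Network, role: str) -> pd.DataFrame:
    """Per species: number of reactions (by type) where the species has a
    positive coefficient in the given role (``"reactant"`` or
    ``"product"``).  Incidence, not multiplicity: a coefficient of 2 counts
    once."""
    if role == "reactant":
        inc = net.reactant > 0
    elif role == "product":
        inc = net.product > 0
    else:
        raise ValueError(f"unknown role {role!r}")
    universe, ind = _type_indicator(net)
    counts = inc.astype(int) @ ind
    return pd.DataFrame(counts, index=list(net.species_names), columns=universe)


def species_reach_type_counts(net: Network, direction: str) -> pd.DataFrame:
    """Per species: reactions (by type) reachable within two reaction hops.

    Forward: hop 1 reaches every reaction consuming the species; hop 2
    reaches every reaction consuming a product of a hop-1 reaction.
    Reverse: same walk on the arc-reversed graph (reactions producing the
    species, then reactions producing their reactants).  "Within two
    steps": the depth-1 and depth-2 reaction sets are unioned.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    g = build_monopartite(net)
    if direction == "forward":
        d1 = net.reactant > 0  # species x reactions consumed-by
        adj = g.adjacency
    else:
        d1 = net.product > 0
        adj = g.adjacency.T
    d2 = (d1.astype(int) @ adj.astype(int)) > 0
    within = d1 | d2
    universe, ind = _type_indicator(net)
    counts = within.astype(int) @ ind
    return pd.DataFrame(counts, index=list(net.species_names), columns=universe)
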