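"""Constraint matrices and compatibility vectors.

Every network gets one *reaction* constraint matrix and one *species*
constraint matrix.  A reference element is compatible with a target
element when the categorical entry matches (reactions: equal reaction
type, constraint RC1) and every count cell of the reference row is <= the
corresponding target cell:

* reactions — RC2/RC3: 1-step and 2-step predecessor/successor counts by
  type on the reaction monopartite graph;
* species — SC1/SC2: reactant/product incidence counts by type;
  SC3/SC4: reactions reachable within two hops forward/reverse, by type.

The <= test is sound because every count is monotone under network
growth: an element of a true embedded copy of the reference can never be
rejected.  Count columns for types absent from one network are implicit
zeros, never a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Network
from .graphs import (
    build_monopartite,
    reaction_neighbor_type_counts,
    species_incidence_type_counts,
    species_reach_type_counts,
)

__all__ = [
    "ConstraintMatrix",
    "CompatibilityVector",
    "reaction_constraint_matrix",
    "species_constraint_matrix",
    "compatibility_vector",
]


@dataclass
class ConstraintMatrix:
    """Per-element constraint rows for one network.

    ``categorical`` holds the reaction-type code for reaction matrices and
    is None for species matrices.  ``counts`` has one row per element;
    column labels are ``#<block><depth?>-<typecode>`` strings.
    """

    kind: str  # "reaction" | "species"
    element_names: list[str]
    categorical: list[str] | None
    counts: pd.DataFrame

    def to_csv(self) -> str:
        """Debug dump: element name, type (reactions), count columns."""
        df = self.counts.copy()
        if self.categorical is not None:
            df.insert(0, "type", self.categorical)
        return df.to_csv(index_label=self.kind)


@dataclass
class CompatibilityVector:
    """Admissible target elements per reference element."""

    kind: str
    reference_names: list[str]
    compatible: list[set[str]]

    @property
    def set_sizes(self) -> list[int]:
        return [len(s) for s in self.compatible]

    def is_feasible(self) -> bool:
        return all(self.compatible)


def _prefix(df: pd.DataFrame, block: str) -> pd.DataFrame:
    if isinstance(df.columns, pd.MultiIndex):
        cols = [f"#{block}{depth}-{t}" for depth, t in df.columns]
    else:
        cols = [f"#{block}-{t}" for t in df.columns]
    out = df.copy()
    out.columns = cols
    return out


def reaction_constraint_matrix(net: Network) -> ConstraintMatrix:
    """RC1 categorical column plus RC2 (predecessor) and RC3 (successor)
    depth-1/2 count blocks."""
    g = build_monopartite(net)
    pred = _prefix(reaction_neighbor_type_counts(g, net, "predecessor"), "p")
    succ = _prefix(reaction_neighbor_type_counts(g, net, "successor"), "s")
    counts = pd.concat([pred, succ], axis=1)
    return ConstraintMatrix(
        kind="reaction",
        element_names=list(net.reaction_names),
        categorical=[t.code for t in net.reaction_types()],
        counts=counts,
    )


def species_constraint_matrix(net: Network) -> ConstraintMatrix:
    """SC1 (reactant incidence), SC2 (product incidence), SC3 (forward
    reach), SC4 (reverse reach) count blocks."""
    blocks = [
        _prefix(species_incidence_type_counts(net, "reactant"), "r"),
        _prefix(species_incidence_type_counts(net, "product"), "q"),
        _prefix(species_reach_type_counts(net, "forward"), "f"),
        _prefix(species_reach_type_counts(net, "reverse"), "b"),
    ]
    return ConstraintMatrix(
        kind="species",
        element_names=list(net.species_names),
        categorical=None,
        counts=pd.concat(blocks, axis=1),
    )


def compatibility_vector(
    ref_cm: ConstraintMatrix, target_cm: ConstraintMatrix
) -> CompatibilityVector:
    """Target elements admissible for each reference element.

    Implemented as one categorical-equality comparison plus one broadcast
    elementwise <= comparison of a reference row against all target rows;
    identical by construction to the row-by-row definition.
    """
    if ref_cm.kind != target_cm.kind:
        raise ValueError(
            f"cannot compare {ref_cm.kind!r} constraints with {target_cm.kind!r}"
        )
    columns = sorted(set(ref_cm.counts.columns) | set(target_cm.counts.columns))
    ref = ref_cm.counts.reindex(columns=columns, fill_value=0).to_numpy()
    tgt = target_cm.counts.reindex(columns=columns, fill_value=0).to_numpy()
    target_names = np.asarray(target_cm.element_names, dtype=object)
    if ref_cm.categorical is not None:
        tgt_cat = np.asarray(target_cm.categorical, dtype=object)
    compatible: list[set[str]] = []
    for i in range(ref.shape[0]):
        mask = (tgt >= ref[i]).all(axis=1)
        if ref_cm.categorical is not None:
            mask &= tgt_cat == ref_cm.categorical[i]
        compatible.append(set(target_names[mask]))
    return CompatibilityVector(
        kind=ref_cm.kind,
        reference_names=list(ref_cm.element_names),
        compatible=compatible,
    )
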