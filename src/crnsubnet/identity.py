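"""Structural-identity evaluation of mapping pairs and full discovery.

A *mapping pair* (injective species map + injective reaction map from
reference into target) selects a submatrix of the target stoichiometry
matrices with rows ordered by the species map and columns by the reaction
map.  The pair is a structurally-identical-subnet (sis) pair when that
submatrix equals the reference's matrices exactly:

* strong identity — reactant AND product matrices both match;
* weak identity — the standard (product - reactant) matrices match, i.e.
  the subnet can reproduce the reference's dynamics under suitable rate
  laws.

Matching the submatrix alone is not enough: a mapped target reaction must
not involve any *unmapped* species, otherwise ``A -> C`` would "match"
inside ``A' + B' -> C'`` merely because B' falls outside the selected
rows.  Since the compared matrices are column-wise non-negative (absolute
values, for the signed standard matrix), that no-extra-species condition
is exactly equality of the (absolute) column totals, which is how it is
evaluated here.

Candidate pairs are evaluated in stacked batches: the row/column index
arrays of ``m`` pairs are applied to the target matrices in one fancy-
indexing operation, giving an ``(m, n_s, n_r)`` comparison against the
broadcast reference.  Batch results are elementwise identical to one-at-
a-time evaluation, and neither the batch size nor the worker count can
change a discovery result.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .constraints import (
    compatibility_vector,
    reaction_constraint_matrix,
    species_constraint_matrix,
)
from .core import Network
from .search import count_assignments, iter_mappings

__all__ = [
    "IDENTITY_MODES",
    "MappingPair",
    "DiscoveryResult",
    "evaluate_batch",
    "find_subnets",
    "brute_force_sis_pairs",
]

IDENTITY_MODES = ("strong", "weak")

#: largest species-mapping count that is materialized (rather than
#: re-enumerated for every reaction mapping) during discovery
_SPECIES_CACHE_LIMIT = 10**6


@dataclass(frozen=True)
class MappingPair:
    """Injective species and reaction maps, reference name -> target name."""

    species: dict[str, str]
    reactions: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.species.values())) != len(self.species):
            raise ValueError("species mapping is not injective")
        if len(set(self.reactions.values())) != len(self.reactions):
            raise ValueError("reaction mapping is not injective")

    def to_dict(self) -> dict[str, dict[str, str]]:
        return {"species": dict(self.species), "reactions": dict(self.reactions)}

    def __hash__(self) -> int:
        return hash(
            (frozenset(self.species.items()), frozenset(self.reactions.items()))
        )


@dataclass
class DiscoveryResult:
    """Outcome of a subnet-discovery run.

    ``truncated`` is True when the mapping-pair budget stopped the search
    before exhausting the candidate space; every pair in
    ``sis_mapping_pairs`` re-verifies under :func:`evaluate_batch`.
    """

    reference_name: str
    target_name: str
    identity_mode: str
    sis_mapping_pairs: list[MappingPair] = field(default_factory=list)
    truncated: bool = False
    num_pairs_evaluated: int = 0
    log10_pair_estimate: float = float("-inf")

    @property
    def is_subnet(self) -> bool:
        return bool(self.sis_mapping_pairs)


def _check_mode(mode: str) -> None:
    if mode not in IDENTITY_MODES:
        raise ValueError(f"identity mode must be one of {IDENTITY_MODES}, got {mode!r}")


def _pair_indices(
    ref: Network, target: Network, pairs: Sequence[MappingPair]
) -> tuple[np.ndarray, np.ndarray]:
    """(m, n_s) species-row and (m, n_r) reaction-column index arrays."""
    rows = np.empty((len(pairs), ref.num_species), dtype=np.intp)
    cols = np.empty((len(pairs), ref.num_reactions), dtype=np.intp)
    for k, pair in enumerate(pairs):
        try:
            for i, s in enumerate(ref.species_names):
                rows[k, i] = target.species_index(pair.species[s])
            for j, r in enumerate(ref.reaction_names):
                cols[k, j] = target.reaction_index(pair.reactions[r])
        except KeyError as exc:
            raise ValueError(f"pair {k} references unknown element {exc}") from exc
    return rows, cols


def _compare_stacked(
    ref_mats: tuple[np.ndarray, ...],
    tgt_mats: tuple[np.ndarray, ...],
    rows: np.ndarray,
    cols: np.ndarray,
) -> np.ndarray:
    ok = np.ones(rows.shape[0], dtype=bool)
    r3 = rows[:, :, None]
    c3 = cols[:, None, :]
    for ref_m, tgt_m in zip(ref_mats, tgt_mats):
        ok &= (tgt_m[r3, c3] == ref_m).all(axis=(1, 2))
        # mapped target reactions must involve no unmapped species; with
        # non-negative (absolute) columns this is column-total equality
        ref_tot = np.abs(ref_m).sum(axis=0)
        tgt_tot = np.abs(tgt_m).sum(axis=0)
        ok &= (tgt_tot[cols] == ref_tot).all(axis=1)
    return ok


def _mode_matrices(
    ref: Network, target: Network, mode: str
) -> tuple[tuple[np.ndarray, ...], tuple[np.ndarray, ...]]:
    if mode == "strong":
        return (ref.reactant, ref.product), (target.reactant, target.product)
    return (ref.standard_stoichiometry(),), (target.standard_stoichiometry(),)


def evaluate_batch(
    ref: Network,
    target: Network,
    pairs: Sequence[MappingPair],
    mode: str = "strong",
) -> np.ndarray:
    """Boolean sis verdict per mapping pair, evaluated as one stacked
    comparison."""
    _check_mode(mode)
    if not pairs:
        return np.zeros(0, dtype=bool)
    rows, cols = _pair_indices(ref, target, pairs)
    ref_mats, tgt_mats = _mode_matrices(ref, target, mode)
    return _compare_stacked(ref_mats, tgt_mats, rows, cols)


def _species_rows(
    mapping: dict[str, str], ref: Network, target: Network
) -> np.ndarray:
    return np.fromiter(
        (target.species_index(mapping[s]) for s in ref.species_names),
        dtype=np.intp,
        count=ref.num_species,
    )


def _reaction_cols(
    mapping: dict[str, str], ref: Network, target: Network
) -> np.ndarray:
    return np.fromiter(
        (target.reaction_index(mapping[r]) for r in ref.reaction_names),
        dtype=np.intp,
        count=ref.num_reactions,
    )


def find_subnets(
    ref: Network,
    target: Network,
    mode: str = "strong",
    max_mapping_pairs: float = 1e12,
    batch_size: int = 1000,
    num_processes: int = 1,
    first_only: bool = False,
) -> DiscoveryResult:
    """Full constraint-pruned discovery of sis mapping pairs.

    Builds reaction and species constraint matrices for both networks,
    intersects them into compatibility vectors, lazily enumerates the
    cross product of reaction mappings (outer) and species mappings
    (inner), and evaluates candidates in stacked batches, optionally split
    across worker processes.  The result does not depend on ``batch_size``
    or ``num_processes``.

    When the product bound on mapping pairs exceeds ``max_mapping_pairs``
    the search evaluates at most that many pairs and reports
    ``truncated=True``.  ``first_only`` stops at the first sis pair.
    An absent subnet is a normal empty result, not an error.
    """
    _check_mode(mode)
    if ref.num_species == 0 or ref.num_reactions == 0:
        raise ValueError("reference network is empty")
    if target.num_species == 0 or target.num_reactions == 0:
        raise ValueError("target network is empty")
    if max_mapping_pairs < 1 or batch_size < 1 or num_processes < 1:
        raise ValueError("max_mapping_pairs, batch_size, num_processes must be >= 1")

    result = DiscoveryResult(
        reference_name=ref.name, target_name=target.name, identity_mode=mode
    )
    # weak identity == strong identity of the net (canonical) forms, so
    # weak-mode constraints must be computed on those forms or true weak
    # matches (e.g. A->B inside A+C->B+C) would be pruned.
    cref = ref if mode == "strong" else ref.canonical_weak_form()
    ctgt = target if mode == "strong" else target.canonical_weak_form()
    rcv = compatibility_vector(
        reaction_constraint_matrix(cref), reaction_constraint_matrix(ctgt)
    )
    scv = compatibility_vector(
        species_constraint_matrix(cref), species_constraint_matrix(ctgt)
    )
    result.log10_pair_estimate = count_assignments(rcv) + count_assignments(scv)
    if not (rcv.is_feasible() and scv.is_feasible()):
        return result

    bound = 1
    for s in rcv.compatible:
        bound *= len(s)
    for s in scv.compatible:
        bound *= len(s)
    result.truncated = bound > max_mapping_pairs
    budget = min(bound, int(max_mapping_pairs))

    ref_mats, tgt_mats = _mode_matrices(ref, target, mode)

    species_bound = 1
    for s in scv.compatible:
        species_bound *= len(s)

    def species_row_iter() -> Iterator[np.ndarray]:
        for m in iter_mappings(scv):
            yield _species_rows(m, ref, target)

    cached_species: list[np.ndarray] | None = None
    if species_bound <= _SPECIES_CACHE_LIMIT:
        cached_species = list(species_row_iter())

    def candidate_indices() -> Iterator[tuple[np.ndarray, np.ndarray]]:
        produced = 0
        for rmap in iter_mappings(rcv):
            cols = _reaction_cols(rmap, ref, target)
            srows = cached_species if cached_species is not None else species_row_iter()
            for srow in srows:
                yield srow, cols
                produced += 1
                if produced >= budget:
                    return

    def flush(chunk_rows: list[np.ndarray], chunk_cols: list[np.ndarray]) -> Iterator[bool]:
        rows = np.stack(chunk_rows)
        cols = np.stack(chunk_cols)
        n = rows.shape[0]
        if num_processes > 1 and n > batch_size:
            splits = [
                (rows[i : i + batch_size], cols[i : i + batch_size])
                for i in range(0, n, batch_size)
            ]
            with ProcessPoolExecutor(max_workers=num_processes) as pool:
                results = pool.map(
                    _worker_compare,
                    [(ref_mats, tgt_mats, r, c) for r, c in splits],
                )
                for res in results:
                    yield from res
        else:
            for i in range(0, n, batch_size):
                yield from _compare_stacked(
                    ref_mats, tgt_mats, rows[i : i + batch_size], cols[i : i + batch_size]
                )

    pending_rows: list[np.ndarray] = []
    pending_cols: list[np.ndarray] = []
    flush_size = batch_size * num_processes

    def consume(verdicts: Iterator[bool]) -> bool:
        """Count evaluations in order; True when the search should stop."""
        for k, ok in enumerate(verdicts):
            result.num_pairs_evaluated += 1
            if ok:
                srow, cols = pending_rows[k], pending_cols[k]
                result.sis_mapping_pairs.append(
                    MappingPair(
                        species={
                            s: target.species_names[srow[i]]
                            for i, s in enumerate(ref.species_names)
                        },
                        reactions={
                            r: target.reaction_names[cols[j]]
                            for j, r in enumerate(ref.reaction_names)
                        },
                    )
                )
                if first_only:
                    return True
        return False

    for srow, cols in candidate_indices():
        pending_rows.append(srow)
        pending_cols.append(cols)
        if len(pending_rows) >= flush_size:
            if consume(flush(pending_rows, pending_cols)):
                return result
            pending_rows, pending_cols = [], []
    if pending_rows:
        consume(flush(pending_rows, pending_cols))
    return result


def _worker_compare(
    args: tuple[tuple[np.ndarray, ...], tuple[np.ndarray, ...], np.ndarray, np.ndarray],
) -> list[bool]:
    ref_mats, tgt_mats, rows, cols = args
    return list(_compare_stacked(ref_mats, tgt_mats, rows, cols))


def brute_force_sis_pairs(
    ref: Network, target: Network, mode: str = "strong"
) -> list[MappingPair]:
    """Reference oracle: evaluate ALL mapping pairs with no constraints.

    Exponential; intended for networks with at most a handful of species
    and reactions (tests and self-checks).
    """
    import itertools

    _check_mode(mode)

    def is_identical(ref_m: np.ndarray, tgt_m: np.ndarray, ssel, rsel) -> bool:
        # the inferred subnet keeps the mapped reactions' FULL columns: any
        # participation of an unmapped species breaks identity
        unmapped = [i for i in range(target.num_species) if i not in set(ssel)]
        for j_ref, j_tgt in enumerate(rsel):
            for i_ref, i_tgt in enumerate(ssel):
                if tgt_m[i_tgt, j_tgt] != ref_m[i_ref, j_ref]:
                    return False
            for i_tgt in unmapped:
                if tgt_m[i_tgt, j_tgt] != 0:
                    return False
        return True

    if mode == "strong":
        mats = [(ref.reactant, target.reactant), (ref.product, target.product)]
    else:
        mats = [(ref.standard_stoichiometry(), target.standard_stoichiometry())]
    out: list[MappingPair] = []
    for rsel in itertools.permutations(range(target.num_reactions), ref.num_reactions):
        for ssel in itertools.permutations(range(target.num_species), ref.num_species):
            if all(is_identical(rm, tm, ssel, rsel) for rm, tm in mats):
                out.append(
                    MappingPair(
                        species={
                            s: target.species_names[ssel[i]]
                            for i, s in enumerate(ref.species_names)
                        },
                        reactions={
                            r: target.reaction_names[rsel[j]]
                            for j, r in enumerate(ref.reaction_names)
                        },
                    )
                )
    return out
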