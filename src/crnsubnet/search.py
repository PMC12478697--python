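"""Counting and enumeration of injective element mappings.

The naive search space for a reference with ``m_r`` reactions / ``m_s``
species inside a target with ``n_r`` / ``n_s`` is

    C(n_r, m_r) m_r!  *  C(n_s, m_s) m_s!

ordered selections of target reactions times ordered selections of target
species.  Compatibility vectors cut this down; the remaining injective
assignments are enumerated by backtracking, reference elements in
ascending compatibility-set size, candidates in sorted name order, so the
output order is deterministic.
"""

from __future__ import annotations

import math
from typing import Iterator

from .constraints import CompatibilityVector
from .core import NetworkDims

__all__ = [
    "mapping_pair_count",
    "log10_mapping_pair_count",
    "count_assignments",
    "iter_mappings",
    "enumerate_mappings",
]


def mapping_pair_count(ref: NetworkDims, target: NetworkDims) -> int:
    """Exact number of unconstrained mapping pairs (big integer).

    Returns 0 when the reference exceeds the target in either dimension
    (no injective mapping exists).
    """
    if ref.num_reactions > target.num_reactions or ref.num_species > target.num_species:
        return 0
    return (
        math.comb(target.num_reactions, ref.num_reactions)
        * math.factorial(ref.num_reactions)
        * math.comb(target.num_species, ref.num_species)
        * math.factorial(ref.num_species)
    )


def log10_mapping_pair_count(ref: NetworkDims, target: NetworkDims) -> float:
    """log10 of :func:`mapping_pair_count`; -inf when the count is 0."""
    n = mapping_pair_count(ref, target)
    return math.log10(n) if n else float("-inf")


def count_assignments(cv: CompatibilityVector) -> float:
    """log10 of the product of compatibility-set sizes.

    This is an upper bound on the number of injective assignments (exact
    counting is a matrix permanent); the bound is cheap, monotone, and is
    what budget decisions need.  Returns -inf when any set is empty (no
    assignment exists, so nothing need be enumerated).
    """
    total = 0.0
    for s in cv.compatible:
        if not s:
            return float("-inf")
        total += math.log10(len(s))
    return total


def iter_mappings(cv: CompatibilityVector) -> Iterator[dict[str, str]]:
    """Yield every injective mapping consistent with ``cv``.

    Reference elements are assigned in ascending set-size order (ties by
    name), candidates tried in sorted name order; each yielded dict is
    keyed in the original reference order.  Yields nothing if any set is
    empty.
    """
    n = len(cv.reference_names)
    if n == 0 or not cv.is_feasible():
        return
    order = sorted(range(n), key=lambda i: (len(cv.compatible[i]), cv.reference_names[i]))
    candidates = [sorted(cv.compatible[i]) for i in order]
    assignment: list[str | None] = [None] * n
    used: set[str] = set()

    def backtrack(depth: int) -> Iterator[dict[str, str]]:
        if depth == n:
            yield {
                cv.reference_names[i]: assignment[i]  # type: ignore[misc]
                for i in range(n)
            }
            return
        i = order[depth]
        for cand in candidates[depth]:
            if cand in used:
                continue
            used.add(cand)
            assignment[i] = cand
            yield from backtrack(depth + 1)
            used.discard(cand)
        assignment[i] = None

    yield from backtrack(0)


def enumerate_mappings(
    cv: CompatibilityVector, limit: int
) -> tuple[list[dict[str, str]], bool]:
    """First ``limit`` injective mappings plus a truncation flag.

    The flag is True iff at least one further mapping existed beyond the
    limit.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    out: list[dict[str, str]] = []
    it = iter_mappings(cv)
    for mapping in it:
        if len(out) == limit:
            return out, True
        out.append(mapping)
    return out, False
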