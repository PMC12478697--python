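"""Monte-Carlo significance of subnet discovery.

Small networks arise by chance; before reading anything into a discovered
subnet one should know how likely a reference of that size is to occur in
a random network.  The null distribution is estimated empirically:
generate ``k_r`` random references and ``k_t`` random targets of the SAME
size (equal sizes make subnet identity whole-network identity), count the
strongly identical (reference, target) pairs, and report the fraction.

The fraction is floored at ``1 / (k_r * k_t)`` before taking -log10 (zero
matches is still only evidence of rarity at the sampled resolution) and
the -log10 value is capped at 5; at the default k_r=100, k_t=1000 the
floor itself yields the cap, so a reported 5 means the sweep found at
most one match.  The same type distribution must be used for references
and targets — the null has to match the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NetworkDims
from .identity import find_subnets
from .randnet import ReactionTypeDistribution, make_random_network

__all__ = [
    "SignificanceEstimate",
    "estimate_null_fraction",
    "significance_grid",
    "grid_to_csv",
]

DEFAULT_K_R = 100
DEFAULT_K_T = 1000
NEG_LOG10_CAP = 5.0


@dataclass(frozen=True)
class SignificanceEstimate:
    """Estimated chance occurrence rate for one network size."""

    dims: NetworkDims
    fraction: float
    neg_log10: float
    k_r: int
    k_t: int
    seed: int | None


def _neg_log10(fraction: float, k_r: int, k_t: int) -> float:
    floored = max(fraction, 1.0 / (k_r * k_t))
    return min(-np.log10(floored), NEG_LOG10_CAP)


def estimate_null_fraction(
    dims: NetworkDims,
    k_r: int = DEFAULT_K_R,
    k_t: int = DEFAULT_K_T,
    dist: ReactionTypeDistribution | None = None,
    seed: int | None = None,
    max_mapping_pairs: float = 1e7,
) -> SignificanceEstimate:
    """Fraction of random same-size (reference, target) pairs that are
    strongly structurally identical; deterministic for a given seed."""
    if k_r < 1 or k_t < 1:
        raise ValueError("k_r and k_t must be >= 1")
    dist = dist or ReactionTypeDistribution.uniform()
    rng = np.random.default_rng(seed)
    refs = [
        make_random_network(dims, dist=dist, rng=rng, name=f"ref{i}")
        for i in range(k_r)
    ]
    targets = [
        make_random_network(dims, dist=dist, rng=rng, name=f"tgt{i}")
        for i in range(k_t)
    ]
    matches = 0
    for ref in refs:
        for tgt in targets:
            res = find_subnets(
                ref,
                tgt,
                mode="strong",
                max_mapping_pairs=max_mapping_pairs,
                first_only=True,
            )
            if res.is_subnet:
                matches += 1
    fraction = matches / (k_r * k_t)
    return SignificanceEstimate(
        dims=dims,
        fraction=fraction,
        neg_log10=float(_neg_log10(fraction, k_r, k_t)),
        k_r=k_r,
        k_t=k_t,
        seed=seed,
    )


def significance_grid(
    min_dims: NetworkDims,
    max_dims: NetworkDims,
    k_r: int = DEFAULT_K_R,
    k_t: int = DEFAULT_K_T,
    dist: ReactionTypeDistribution | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Grid of estimates over network sizes; rows are reaction counts,
    columns species counts, cells :class:`SignificanceEstimate`."""
    if (
        min_dims.num_species > max_dims.num_species
        or min_dims.num_reactions > max_dims.num_reactions
    ):
        raise ValueError("min_dims must not exceed max_dims")
    seq = np.random.SeedSequence(seed)
    species_range = range(min_dims.num_species, max_dims.num_species + 1)
    reaction_range = range(min_dims.num_reactions, max_dims.num_reactions + 1)
    cells: dict[int, dict[int, SignificanceEstimate]] = {}
    children = seq.spawn(len(reaction_range) * len(species_range))
    k = 0
    for nr in reaction_range:
        cells[nr] = {}
        for ns in species_range:
            cell_seed = int(children[k].generate_state(1)[0] % (2**31))
            k += 1
            cells[nr][ns] = estimate_null_fraction(
                NetworkDims(ns, nr), k_r=k_r, k_t=k_t, dist=dist, seed=cell_seed
            )
    df = pd.DataFrame(cells).T  # rows = reactions, columns = species
    df.index.name = "num_reactions"
    df.columns.name = "num_species"
    return df


def grid_to_csv(grid: pd.DataFrame) -> str:
    """CSV of the grid's -log10 values to 2 decimals (annotate with the
    integer part, e.g. 1 means a significance level of 0.1)."""
    out = grid.map(lambda est: f"{est.neg_log10:.2f}")
    return out.to_csv()
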