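"""Random CRN generation and reference-embedded target fixtures.

A reaction is classified by its (number of reactants, number of products)
pair; the canonical universe is the 16 types with each count in
{0, 1, 2, 3}.  Networks are generated reaction by reaction: a type is
drawn from a :class:`ReactionTypeDistribution`, then reactant and product
species are drawn uniformly without replacement from the species pool,
all with coefficient 1.  The default distribution is uniform over the 16
types; an empirical distribution (e.g. one estimated from a model corpus)
can be supplied instead.

:func:`make_embedded_pair` builds matched (reference, target) fixtures in
three steps: a preliminary target with the leftover reaction count and
the full species pool; a reference drawn over species randomly selected
from that pool; and a merge of the two with the reference's reactions
renamed and the target's species and reaction orders shuffled.  The
ground-truth mapping pair is recorded and re-verified (strong identity)
before the pair is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import Network, NetworkDims, ReactionType
from .identity import MappingPair, evaluate_batch

__all__ = [
    "CANONICAL_TYPES",
    "ReactionTypeDistribution",
    "EmbeddedPair",
    "make_random_network",
    "make_embedded_pair",
]

#: the 16 canonical reaction types: counts 0..3 on each side
CANONICAL_TYPES: tuple[ReactionType, ...] = tuple(
    ReactionType(i, j) for i in range(4) for j in range(4)
)


@dataclass(frozen=True)
class ReactionTypeDistribution:
    """Probability distribution over reaction types."""

    types: tuple[ReactionType, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.types) != len(self.probabilities):
            raise ValueError("types and probabilities differ in length")
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")

    @classmethod
    def uniform(cls, types: tuple[ReactionType, ...] = CANONICAL_TYPES) -> "ReactionTypeDistribution":
        n = len(types)
        return cls(tuple(types), tuple([1.0 / n] * n))

    @classmethod
    def point_mass(cls, rtype: ReactionType | tuple[int, int]) -> "ReactionTypeDistribution":
        return cls((ReactionType(*rtype),), (1.0,))

    def sample(self, rng: np.random.Generator) -> ReactionType:
        k = rng.choice(len(self.types), p=np.asarray(self.probabilities))
        return self.types[k]


@dataclass(frozen=True)
class EmbeddedPair:
    """A reference network, a target that embeds it, and where it landed."""

    reference: Network
    target: Network
    ground_truth: MappingPair


def _rng(seed: int | None, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _draw_reaction(
    rng: np.random.Generator,
    num_species: int,
    dist: ReactionTypeDistribution,
    max_retries: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """One reactant/product coefficient column pair over the species pool."""
    for _ in range(max_retries):
        rtype = dist.sample(rng)
        if max(rtype.num_reactants, rtype.num_products) <= num_species:
            break
    else:
        raise ValueError(
            f"no feasible reaction type for a pool of {num_species} species"
        )
    react = np.zeros(num_species)
    prod = np.zeros(num_species)
    if rtype.num_reactants:
        react[rng.choice(num_species, size=int(rtype.num_reactants), replace=False)] = 1.0
    if rtype.num_products:
        prod[rng.choice(num_species, size=int(rtype.num_products), replace=False)] = 1.0
    return react, prod


def make_random_network(
    dims: NetworkDims,
    dist: ReactionTypeDistribution | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    name: str = "random",
    species_prefix: str = "S",
    reaction_prefix: str = "R",
) -> Network:
    """Random network with exactly ``dims.num_reactions`` reactions over a
    pool of exactly ``dims.num_species`` species (unused species remain as
    isolated rows so the dimensions are exact).  Deterministic for a given
    seed."""
    dist = dist or ReactionTypeDistribution.uniform()
    gen = _rng(seed, rng)
    ns, nr = dims.num_species, dims.num_reactions
    reactant = np.zeros((ns, nr))
    product = np.zeros((ns, nr))
    for j in range(nr):
        reactant[:, j], product[:, j] = _draw_reaction(gen, ns, dist)
    return Network(
        name=name,
        species_names=[f"{species_prefix}{i}" for i in range(ns)],
        reaction_names=[f"{reaction_prefix}{j}" for j in range(nr)],
        reactant=reactant,
        product=product,
    )


def make_embedded_pair(
    ref_dims: NetworkDims,
    target_dims: NetworkDims,
    dist: ReactionTypeDistribution | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EmbeddedPair:
    """Reference randomly embedded in a larger target, with ground truth.

    Requires the target to exceed the reference in reaction count and to
    be at least as large in species count.
    """
    if target_dims.num_species < ref_dims.num_species:
        raise ValueError("target must have at least as many species as reference")
    if target_dims.num_reactions <= ref_dims.num_reactions:
        raise ValueError("target must have strictly more reactions than reference")
    dist = dist or ReactionTypeDistribution.uniform()
    gen = _rng(seed, rng)

    n_prelim = target_dims.num_reactions - ref_dims.num_reactions
    ns_t = target_dims.num_species
    prelim_react = np.zeros((ns_t, n_prelim))
    prelim_prod = np.zeros((ns_t, n_prelim))
    for j in range(n_prelim):
        prelim_react[:, j], prelim_prod[:, j] = _draw_reaction(gen, ns_t, dist)

    # reference species are drawn (without replacement) from the target pool
    pool = gen.choice(ns_t, size=ref_dims.num_species, replace=False)
    ref = make_random_network(ref_dims, dist=dist, rng=gen, name="reference")

    # embed a copy of the reference over the selected pool species
    ns_r, nr_r = ref_dims.num_species, ref_dims.num_reactions
    embed_react = np.zeros((ns_t, nr_r))
    embed_prod = np.zeros((ns_t, nr_r))
    embed_react[pool, :] = ref.reactant
    embed_prod[pool, :] = ref.product

    target_react = np.hstack([prelim_react, embed_react])
    target_prod = np.hstack([prelim_prod, embed_prod])
    species_names = [f"X{i}" for i in range(ns_t)]
    reaction_names = [f"J{j}" for j in range(target_dims.num_reactions)]

    # randomize: shuffle species rows and reaction columns
    sperm = gen.permutation(ns_t)
    rperm = gen.permutation(target_dims.num_reactions)
    target = Network(
        name="target",
        species_names=[species_names[i] for i in sperm],
        reaction_names=[reaction_names[j] for j in rperm],
        reactant=target_react[np.ix_(sperm, rperm)],
        product=target_prod[np.ix_(sperm, rperm)],
    )

    ground_truth = MappingPair(
        species={
            ref.species_names[i]: species_names[pool[i]] for i in range(ns_r)
        },
        reactions={
            ref.reaction_names[k]: reaction_names[n_prelim + k] for k in range(nr_r)
        },
    )
    if not evaluate_batch(ref, target, [ground_truth], mode="strong")[0]:
        raise AssertionError("embedded-pair self-check failed")  # pragma: no cover
    return EmbeddedPair(reference=ref, target=target, ground_truth=ground_truth)


def write_fixture(pair: EmbeddedPair, directory) -> None:
    """Emit reference/target (reaction dialect + SBML) and the ground
    truth (JSON) into ``directory``."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "reference.txt").write_text(pair.reference.to_reaction_string())
    (d / "target.txt").write_text(pair.target.to_reaction_string())
    (d / "reference.xml").write_text(pair.reference.to_sbml())
    (d / "target.xml").write_text(pair.target.to_sbml())
    (d / "ground_truth.json").write_text(
        json.dumps(pair.ground_truth.to_dict(), indent=2)
    )
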