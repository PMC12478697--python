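# Methods

## Network model

A chemical reaction network is stored as ordered species and reaction
name lists plus two non-negative `float` matrices (species × reactions):
the reactant matrix `R` of consumption coefficients and the product
matrix `P` of production coefficients. `S = P − R` is the standard
stoichiometry matrix. Coefficients are compared exactly (they are data,
not estimates); non-integer stoichiometries are accepted. Species order
is order of first appearance (SBML: `listOfSpecies` document order),
reaction order is document order, so parses are bit-for-bit
reproducible.

SBML reading is structural only: rate laws, events, rules, compartment
volumes and units are ignored. Reversible reactions are split into
`_fwd`/`_rev` irreversible halves because the constraint system operates
on directed hyperarcs; boundary species are ordinary rows; modifiers
(catalysts declared outside the reactant list) are not entered into the
matrices.

### Reaction types

A reaction's type is the pair (total reactant stoichiometry, total
product stoichiometry), i.e. coefficient sums, so `2A -> A + B` is type
(2,2). Counting summed coefficients rather than distinct species keeps
the hyperarc multiset semantics and makes the type constraint sound for
stoichiometry-sensitive strong identity; it also makes the type test
exactly the "no unmapped species in a mapped reaction" column-total test
(below). Types are displayed as two concatenated digits ("21") when both
counts are single digits.

## Structural identity

A mapping pair (injective species map, injective reaction map) selects a
submatrix of the target with rows ordered by the species map and columns
by the reaction map. The pair is a sis (structurally identical subnet)
pair when

1. the selected submatrix equals the reference matrix exactly, and
2. no mapped target reaction involves an unmapped species.

Condition 2 is essential: without it `A -> C` would "occur" inside
`A' + B' -> C'` because B' simply falls outside the selected rows, which
contradicts the hypergraph reading of a reaction (an arc with *all* its
endpoints). For the non-negative matrices compared under strong identity
(and for |S| under weak identity) condition 2 is equivalent to equality
of column totals, which vectorizes to one comparison per batch.

Strong identity applies conditions 1–2 to `R` and `P`; weak identity to
`S` only. Strong implies weak. Weak identity of two networks is exactly
strong identity of their *net forms* `R' = max(R−P, 0)`,
`P' = max(P−R, 0)`; this identity is used below.

## Constraint system

Both networks get a reaction constraint matrix and a species constraint
matrix; a reference element is compatible with a target element iff the
categorical entry matches and every count cell is ≤ the target's.

* RC1 — reaction types equal (categorical).
* RC2/RC3 — counts, by type, of 1-step and 2-step predecessor/successor
  reactions in the reaction monopartite graph (arc from reaction `i` to
  `j` when a product of `i` is a reactant of `j`; self-arcs allowed).
* SC1/SC2 — counts, by type, of reactions in which the species is a
  reactant / a product (incidence, not multiplicity).
* SC3/SC4 — counts, by type, of reactions reachable from the species
  within two reaction hops forward / reverse ("within" = union of the
  1-hop and 2-hop sets).

Depth-2 neighbor counts use distinct-node set semantics, computed
independently of depth 1 (a reaction may contribute to both columns).
Set semantics — rather than path counts — is what makes every cell
monotone non-decreasing under adding reactions to a network, and
monotonicity is what makes the ≤ test sound: an element of a true
embedded copy can never be rejected (no false negatives; verified over
hundreds of random embeddings in the test suite). Count columns for
types absent from one network are implicit zeros, never a mismatch. The
compatibility test is evaluated as one categorical equality plus one
broadcast elementwise ≤ of a reference row against all target rows,
provably identical to the row-by-row definition.

For weak-mode discovery the constraint matrices are built from the net
forms of both networks. Building them from the raw matrices would
falsely prune weak matches — e.g. `A -> B` (type (1,1)) weakly matches
`2A -> A + B` and catalytic variants whose raw types differ — breaking
the no-false-negative contract.

## Search and evaluation

The product of compatibility-set sizes bounds the number of injective
assignments (the exact count is a matrix permanent — deliberately not
computed; the cheap, monotone bound is what budget decisions need, and
it is what `log10` assignment counts report). If the reaction-bound ×
species-bound product exceeds `max_mapping_pairs` (default 1e12) the run
is marked truncated and evaluates at most that many pairs.

Injective mappings are enumerated by backtracking, reference elements in
ascending compatibility-set size (ties by name), candidates in sorted
name order — a deterministic order chosen for pruning power; reaction
mappings form the outer loop of the cross product (their sets are
usually smaller after RC1), species mappings the inner loop. Species
mappings are materialized once when their bound is ≤ 1e6, else
re-enumerated per outer iteration.

Candidates are verified in stacked batches: the row/column index arrays
of `m` pairs fancy-index the target matrices into an `(m, n_s, n_r)`
block compared against the broadcast reference. Default batch size is
1000; larger batches showed no further benefit. Batches can be split
across worker processes; results are consumed in submission order, so
neither batch size nor worker count can change the result (asserted in
tests). Speedups themselves are hardware-dependent and are not asserted
anywhere.

## Random networks and embeddings

The generator draws each reaction's type from a configurable
distribution over the 16 canonical types (reactant and product counts
each in {0..3}), then draws reactant and product species uniformly
without replacement from the pool, all coefficients 1. The default
distribution is uniform over the 16 types: the empirical type
distribution of curated model repositories is not published in a usable
form, so the package ships a neutral default and accepts any
distribution as input. Unused species remain as isolated rows so
dimensions are exact. Generation is deterministic given a seed.

Embedded fixtures follow a three-step recipe: (1) a preliminary target
with `MrT − MrR` reactions over all `MsT` species; (2) a reference over
`MsR` species selected without replacement from that pool; (3) a merge
of the preliminary target with a copy of the reference (renamed
reactions), followed by a uniform shuffle of species and reaction
order. The ground-truth mapping pair is recorded and re-verified under
strong identity before the fixture is returned, so every fixture carries
a constructive guarantee.

What the generator does *not* emulate: coefficients > 1, conserved
moieties, hub species with power-law degree, modifier/catalyst
annotations, or any empirical type distribution. Passing tests on these
fixtures therefore certify the algorithm's correctness contracts
(soundness, oracle equivalence, determinism), not performance or
discovery rates on curated repository models.

## Significance

The chance-occurrence probability of a network size is estimated by
generating `k_r` references and `k_t` targets of that same size (equal
sizes make subnet identity whole-network identity) and reporting the
fraction of strongly identical pairs. Defaults are `k_r = 100`,
`k_t = 1000`. The fraction is floored at `1/(k_r·k_t)` before taking
−log10 (a zero count only bounds the rate at the sampled resolution) and
capped at 5; at the default sample size the floor itself reaches the
cap, so a reported 5 means at most one match was seen. References and
targets must use the same type distribution — the null must match the
generator — and all grid values are therefore distribution-relative.

## Study sizes used in the checks

The acceptance checks run the 20-species/20-reaction reference in the
100×100 target for the analytic count ($\lfloor\log_{10}\rfloor = 78$)
and for the constrained-bound study; the latter uses 1000 random
embeddings because the log10 bound distribution is heavy-tailed and a
few dozen samples do not pin the median (measured medians: ~2.5
reactions, ~5.2 species, ~7.7–7.8 pairs, i.e. the ~10^3 / 10^5 / 10^8
magnitudes; reduction factor ~10^70.5). Oracle-equivalence checks use
references up to 3×3 against targets up to 4×4, where exhaustive
enumeration of all mapping pairs is feasible; recovery checks embed 5×5
references in 20×20 targets. Null-distribution smoke checks run reduced
grids (k_r·k_t ≤ 1e3 per cell); full-default grids are available through
the CLI.

## Known limitations

* Exact injective-assignment counts (permanents) are not computed; the
  product bound can overestimate by orders of magnitude on highly
  overlapping compatibility sets.
* All verifying mapping pairs are reported; automorphic duplicates of
  the same induced subnet are not collapsed.
* The Antimony model dialect is not read; use SBML or the plain-text
  reaction dialect.
* Truncated runs (`truncated=True`) prove nothing about absence: the
  budget bounds work, not the search space.
* Process parallelism pays off only when batches are large; on small
  problems worker startup dominates.
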