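"""Core chemical-reaction-network (CRN) representation.

A CRN is held as a pair of non-negative stoichiometry matrices over an
ordered species list (rows) and reaction list (columns): the *reactant*
matrix of consumption coefficients and the *product* matrix of production
coefficients.  Their difference is the *standard* stoichiometry matrix,
which fully determines the network's possible dynamics (for suitable rate
laws) and is therefore the object compared under weak identity.

Networks can be read from SBML (Level 2/3 core) or from a one-reaction-per-
line plain-text dialect::

    J1: 2 A + B -> C
    J2: -> A          # zero-reactant (source) reaction

Rate laws, events, compartment volumes and units are deliberately ignored:
only structure is compared.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Network",
    "NetworkDims",
    "ReactionType",
    "ParseError",
    "parse_network",
    "parse_reaction_string",
    "parse_sbml",
]


class ParseError(ValueError):
    """Raised when a model document cannot be parsed."""


class NetworkDims(NamedTuple):
    """Size of a network: species count and reaction count (both >= 1)."""

    num_species: int
    num_reactions: int


class ReactionType(NamedTuple):
    """Classification of a reaction by its total reactant and product
    stoichiometry (sum of coefficients on each side).

    ``2A -> A + B`` is type ``(2, 2)``; a synthesis reaction ``-> A`` is
    ``(0, 1)``.
    """

    num_reactants: int | float
    num_products: int | float

    @property
    def code(self) -> str:
        """Two-digit display encoding, e.g. ``(2, 1)`` -> ``"21"``.

        Falls back to ``"a-b"`` when either count exceeds 9 or is
        non-integer.
        """
        a, b = self.num_reactants, self.num_products
        if float(a).is_integer() and float(b).is_integer():
            a, b = int(a), int(b)
            if 0 <= a <= 9 and 0 <= b <= 9:
                return f"{a}{b}"
        return f"{a}-{b}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def _as_type(num_reactants: float, num_products: float) -> ReactionType:
    def norm(x: float) -> int | float:
        return int(x) if float(x).is_integer() else float(x)

    return ReactionType(norm(num_reactants), norm(num_products))


@dataclass
class Network:
    """A named CRN with reactant and product stoichiometry matrices.

    Rows follow ``species_names`` order, columns follow ``reaction_names``
    order.  Both matrices are non-negative and share one shape.
    """

    name: str
    species_names: list[str]
    reaction_names: list[str]
    reactant: np.ndarray
    product: np.ndarray

    def __post_init__(self) -> None:
        self.reactant = np.asarray(self.reactant, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        ns, nr = len(self.species_names), len(self.reaction_names)
        if self.reactant.shape != (ns, nr) or self.product.shape != (ns, nr):
            raise ValueError(
                f"stoichiometry matrices must have shape ({ns}, {nr}); got "
                f"{self.reactant.shape} and {self.product.shape}"
            )
        if len(set(self.species_names)) != ns:
            raise ValueError("duplicate species names")
        if len(set(self.reaction_names)) != nr:
            raise ValueError("duplicate reaction names")
        if not (np.isfinite(self.reactant).all() and np.isfinite(self.product).all()):
            raise ValueError("stoichiometry coefficients must be finite")
        if (self.reactant < 0).any() or (self.product < 0).any():
            raise ValueError("stoichiometry coefficients must be non-negative")
        self._species_index = {s: i for i, s in enumerate(self.species_names)}
        self._reaction_index = {r: j for j, r in enumerate(self.reaction_names)}

    # -- basic queries ----------------------------------------------------

    @property
    def num_species(self) -> int:
        return len(self.species_names)

    @property
    def num_reactions(self) -> int:
        return len(self.reaction_names)

    @property
    def dims(self) -> NetworkDims:
        return NetworkDims(self.num_species, self.num_reactions)

    def species_index(self, name: str) -> int:
        return self._species_index[name]

    def reaction_index(self, name: str) -> int:
        return self._reaction_index[name]

    def standard_stoichiometry(self) -> np.ndarray:
        """product - reactant; the matrix that governs weak identity."""
        return self.product - self.reactant

    def reaction_type(self, reaction: int | str) -> ReactionType:
        """Type of one reaction: (total reactant, total product)
        stoichiometry."""
        j = reaction if isinstance(reaction, int) else self._reaction_index[reaction]
        if not 0 <= j < self.num_reactions:
            raise IndexError(f"reaction index {j} out of range")
        return _as_type(self.reactant[:, j].sum(), self.product[:, j].sum())

    def reaction_types(self) -> list[ReactionType]:
        return [self.reaction_type(j) for j in range(self.num_reactions)]

    def canonical_weak_form(self) -> "Network":
        """Net-form network: reactant' = max(R-P, 0), product' = max(P-R, 0).

        Two networks are weakly identical (equal standard matrices) exactly
        when their net forms are strongly identical, so the constraint
        machinery for weak mode runs on this form.
        """
        s = self.standard_stoichiometry()
        return Network(
            name=self.name,
            species_names=list(self.species_names),
            reaction_names=list(self.reaction_names),
            reactant=np.maximum(-s, 0.0),
            product=np.maximum(s, 0.0),
        )

    # -- serialization ----------------------------------------------------

    def to_reaction_string(self) -> str:
        """Serialize to the plain-text reaction dialect."""

        def side(col: np.ndarray) -> str:
            terms = []
            for i, c in enumerate(col):
                if c == 0:
                    continue
                coef = "" if c == 1 else (f"{int(c)} " if float(c).is_integer() else f"{c} ")
                terms.append(f"{coef}{self.species_names[i]}")
            return " + ".join(terms)

        lines = []
        for j, rname in enumerate(self.reaction_names):
            lines.append(f"{rname}: {side(self.reactant[:, j])} -> {side(self.product[:, j])}")
        return "\n".join(lines) + "\n"

    def to_sbml(self) -> str:
        """Serialize to SBML Level 3 (structure only, mass-action-free)."""
        import libsbml

        doc = libsbml.SBMLDocument(3, 2)
        model = doc.createModel()
        model.setId(_sanitize_id(self.name) or "model")
        comp = model.createCompartment()
        comp.setId("default")
        comp.setConstant(True)
        comp.setSize(1.0)
        for s in self.species_names:
            sp = model.createSpecies()
            sp.setId(s)
            sp.setCompartment("default")
            sp.setConstant(False)
            sp.setBoundaryCondition(False)
            sp.setHasOnlySubstanceUnits(False)
        for j, rname in enumerate(self.reaction_names):
            rxn = model.createReaction()
            rxn.setId(rname)
            rxn.setReversible(False)
            for i, c in enumerate(self.reactant[:, j]):
                if c:
                    ref = rxn.createReactant()
                    ref.setSpecies(self.species_names[i])
                    ref.setStoichiometry(float(c))
                    ref.setConstant(True)
            for i, c in enumerate(self.product[:, j]):
                if c:
                    ref = rxn.createProduct()
                    ref.setSpecies(self.species_names[i])
                    ref.setStoichiometry(float(c))
                    ref.setConstant(True)
        return libsbml.writeSBMLToString(doc)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Network(name={self.name!r}, species={self.num_species}, "
            f"reactions={self.num_reactions})"
        )


def _sanitize_id(name: str) -> str:
    return re.sub(r"\W", "_", name)


# -- plain-text dialect ---------------------------------------------------

_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?([A-Za-z_][\w.]*)\s*$")


def _parse_side(text: str, line_no: int) -> list[tuple[str, float]]:
    text = text.strip()
    if not text:
        return []
    out: list[tuple[str, float]] = []
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(f"line {line_no}: cannot parse term {term.strip()!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        out.append((m.group(2), coef))
    return out


def parse_reaction_string(source: str, name: str = "network") -> Network:
    """Parse the one-reaction-per-line dialect ``NAME: a A + b B -> c C``.

    Reaction names are optional (``Jk`` is generated); a trailing ``;`` and
    ``#``/``//`` comments are tolerated.  Species order is order of first
    appearance; reaction order is line order.
    """
    species: list[str] = []
    seen: set[str] = set()
    reactions: list[tuple[str, list[tuple[str, float]], list[tuple[str, float]]]] = []
    rnames: set[str] = set()
    for line_no, raw in enumerate(source.splitlines(), start=1):
        line = re.split(r"#|//", raw)[0].strip().rstrip(";").strip()
        if not line:
            continue
        if "->" not in line:
            raise ParseError(f"line {line_no}: missing '->' in {raw.strip()!r}")
        head, _, body = line.partition("->")
        if ":" in head:
            rname, _, lhs = head.partition(":")
            rname = rname.strip()
        else:
            rname, lhs = f"J{len(reactions)}", head
        if not rname:
            raise ParseError(f"line {line_no}: empty reaction name")
        if rname in rnames:
            raise ParseError(f"line {line_no}: duplicate reaction id {rname!r}")
        rnames.add(rname)
        lhs_terms = _parse_side(lhs, line_no)
        rhs_terms = _parse_side(body, line_no)
        for s, _ in lhs_terms + rhs_terms:
            if s not in seen:
                seen.add(s)
                species.append(s)
        reactions.append((rname, lhs_terms, rhs_terms))
    sidx = {s: i for i, s in enumerate(species)}
    ns, nr = len(species), len(reactions)
    reactant = np.zeros((ns, nr))
    product = np.zeros((ns, nr))
    for j, (_, lhs_terms, rhs_terms) in enumerate(reactions):
        for s, c in lhs_terms:
            reactant[sidx[s], j] += c
        for s, c in rhs_terms:
            product[sidx[s], j] += c
    return Network(
        name=name,
        species_names=species,
        reaction_names=[r for r, _, _ in reactions],
        reactant=reactant,
        product=product,
    )


# -- SBML -----------------------------------------------------------------


def parse_sbml(source: str, name: str | None = None) -> Network:
    """Parse an SBML (Level 2/3 core) document into a :class:`Network`.

    Only reaction structure is read.  Reversible reactions are split into
    two irreversible reactions suffixed ``_fwd`` / ``_rev`` (the constraint
    system operates on directed hyperarcs).  Boundary species are ordinary
    rows; modifiers are ignored.
    """
    import libsbml

    doc = libsbml.readSBMLFromString(source)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise ParseError("document contains no SBML model")
    species = [model.getSpecies(i).getId() for i in range(model.getNumSpecies())]
    if len(set(species)) != len(species):
        raise ParseError("duplicate species id in SBML model")
    sidx = {s: i for i, s in enumerate(species)}

    rnames: list[str] = []
    cols: list[tuple[np.ndarray, np.ndarray]] = []
    seen_r: set[str] = set()
    ns = len(species)
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = rxn.getId()
        if rid in seen_r:
            raise ParseError(f"duplicate reaction id {rid!r}")
        seen_r.add(rid)
        react = np.zeros(ns)
        prod = np.zeros(ns)
        for refs, vec in ((rxn.getListOfReactants(), react), (rxn.getListOfProducts(), prod)):
            for k in range(refs.size()):
                ref = refs.get(k)
                sp = ref.getSpecies()
                if sp not in sidx:
                    raise ParseError(
                        f"reaction {rid!r} references undeclared species {sp!r}"
                    )
                stoich = ref.getStoichiometry()
                if np.isnan(stoich):
                    stoich = 1.0
                vec[sidx[sp]] += stoich
        if rxn.getReversible():
            rnames.extend([f"{rid}_fwd", f"{rid}_rev"])
            cols.append((react, prod))
            cols.append((prod, react))
        else:
            rnames.append(rid)
            cols.append((react, prod))
    if cols:
        reactant = np.column_stack([c[0] for c in cols])
        product = np.column_stack([c[1] for c in cols])
    else:
        reactant = np.zeros((ns, 0))
        product = np.zeros((ns, 0))
    return Network(
        name=name or model.getId() or "model",
        species_names=species,
        reaction_names=rnames,
        reactant=reactant,
        product=product,
    )


def parse_network(source: str, dialect: str = "reaction-string", name: str | None = None) -> Network:
    """Parse ``source`` in the stated dialect (``sbml`` or
    ``reaction-string``)."""
    if dialect == "sbml":
        return parse_sbml(source, name=name)
    if dialect == "reaction-string":
        return parse_reaction_string(source, name=name or "network")
    raise ValueError(f"unknown dialect {dialect!r}")
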