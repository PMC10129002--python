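"""Data model and structural analysis of chemical reaction networks.

A chemical reaction network (CRN) is a finite set of reactions between
*complexes* — non-negative integer combinations of species such as ``A + B``
or the empty complex ``0``.  Each reaction carries a rate-constant symbol.
Under mass-action kinetics the rate of a reaction is its rate constant times
the product of the concentrations of its source-complex species, raised to
their stoichiometric coefficients.

The structural quantities exposed here are the standard ones of chemical
reaction network theory:

* the stoichiometric matrix ``S`` (columns are reaction vectors,
  product minus source) and its rank ``s``,
* the number of distinct complexes ``n`` and of linkage classes ``l``
  (connected components of the undirected complex graph),
* the deficiency ``delta = n - l - s`` (a non-negative integer), and
* weak reversibility (every reaction lies on a directed cycle of the
  complex graph; equivalently, every linkage class is strongly connected).

All linear algebra is exact (rational arithmetic via sympy); symbolic
correctness downstream depends on exact ranks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import sympy as sp

__all__ = [
    "Complex",
    "Reaction",
    "CRN",
    "ParseError",
    "parse_network",
    "parse_complex",
    "reaction_vector",
    "stoichiometric_matrix",
    "deficiency",
    "is_weakly_reversible",
    "mass_action_rhs",
    "species_symbol",
]


class ParseError(ValueError):
    """Raised for malformed reaction-list input; carries the line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class Complex:
    """A non-negative integer combination of species (a node of the graph).

    Zero coefficients are omitted; the empty complex is written ``0``.
    Complexes compare by coefficient multiset, so ``A + B`` equals ``B + A``.
    """

    coefficients: tuple[tuple[str, int], ...]  # sorted by species name

    def __init__(self, coefficients: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(coefficients)
        for sp_name, c in items.items():
            if c < 0:
                raise ValueError(f"negative coefficient for {sp_name}")
        object.__setattr__(
            self,
            "coefficients",
            tuple(sorted((s, c) for s, c in items.items() if c != 0)),
        )

    # -- mapping-ish helpers -------------------------------------------------
    def as_dict(self) -> dict[str, int]:
        return dict(self.coefficients)

    def __getitem__(self, species: str) -> int:
        return self.as_dict().get(species, 0)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.coefficients)

    def is_zero(self) -> bool:
        return not self.coefficients

    def shift(self, delta: Mapping[str, int]) -> "Complex":
        """Return the complex obtained by adding an integer species vector.

        Raises ValueError if any resulting coefficient would be negative.
        """
        out = self.as_dict()
        for s, d in delta.items():
            out[s] = out.get(s, 0) + d
        return Complex(out)

    def vector(self, species_order: Sequence[str]) -> tuple[int, ...]:
        d = self.as_dict()
        return tuple(d.get(s, 0) for s in species_order)

    def __str__(self) -> str:
        if not self.coefficients:
            return "0"
        terms = []
        for s, c in self.coefficients:
            terms.append(s if c == 1 else f"{c} {s}")
        return " + ".join(terms)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Complex({str(self)!r})"


@dataclass(frozen=True)
class Reaction:
    """A directed edge ``source -> product`` labelled with a rate symbol."""

    id: str
    source: Complex
    product: Complex
    rate_symbol: str

    def __post_init__(self):
        if self.source == self.product:
            raise ValueError(f"reaction {self.id}: source equals product")

    def __str__(self) -> str:
        return f"{self.id}: {self.source} -> {self.product} [{self.rate_symbol}]"


def species_symbol(name: str) -> sp.Symbol:
    """Concentration symbol for a species (lower-cased name, positive)."""
    return sp.Symbol(name.lower(), positive=True)


@dataclass
class CRN:
    """A chemical reaction network: ordered species plus ordered reactions.

    Species order is the canonical axis order for every matrix derived from
    the network, so results are reproducible from the input file alone.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    def __init__(self, species: Sequence[str], reactions: Sequence[Reaction]):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        seen_ids: set[str] = set()
        seen_pairs: set[tuple[Complex, Complex]] = set()
        seen_rates: set[str] = set()
        sp_set = set(self.species)
        for r in self.reactions:
            if r.id in seen_ids:
                raise ValueError(f"duplicate reaction id {r.id}")
            seen_ids.add(r.id)
            pair = (r.source, r.product)
            if pair in seen_pairs:
                raise ValueError(f"duplicate reaction {r.source} -> {r.product}")
            seen_pairs.add(pair)
            if r.rate_symbol in seen_rates:
                raise ValueError(f"duplicate rate symbol {r.rate_symbol}")
            seen_rates.add(r.rate_symbol)
            for s in (*r.source.species, *r.product.species):
                if s not in sp_set:
                    raise ValueError(f"reaction {r.id} uses unknown species {s}")

    # -- structure ----------------------------------------------------------
    @cached_property
    def complexes(self) -> tuple[Complex, ...]:
        """Distinct complexes in order of first appearance."""
        seen: dict[Complex, None] = {}
        for r in self.reactions:
            seen.setdefault(r.source)
            seen.setdefault(r.product)
        return tuple(seen)

    @cached_property
    def complex_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.complexes)
        for r in self.reactions:
            g.add_edge(r.source, r.product)
        return g

    @cached_property
    def n_complexes(self) -> int:
        return len(self.complexes)

    @cached_property
    def n_linkage_classes(self) -> int:
        return nx.number_connected_components(self.complex_graph.to_undirected())

    @cached_property
    def stoich_matrix(self) -> sp.Matrix:
        return stoichiometric_matrix(self)

    @cached_property
    def stoich_rank(self) -> int:
        return self.stoich_matrix.rank()

    @cached_property
    def deficiency(self) -> int:
        return deficiency(self)

    @cached_property
    def is_weakly_reversible(self) -> bool:
        return is_weakly_reversible(self)

    def summary(self) -> dict:
        return {
            "species": len(self.species),
            "reactions": len(self.reactions),
            "n": self.n_complexes,
            "l": self.n_linkage_classes,
            "s": self.stoich_rank,
            "deficiency": self.deficiency,
            "weakly_reversible": self.is_weakly_reversible,
        }

    def to_text(self) -> str:
        return "\n".join(str(r) for r in self.reactions) + "\n"

    def __str__(self) -> str:
        return self.to_text()


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s*)?([A-Za-z_][A-Za-z0-9_:']*)$")


def parse_complex(text: str) -> Complex:
    """Parse ``+``-separated ``coeff species`` terms; ``0`` is the empty complex."""
    text = text.strip()
    if text == "0":
        return Complex({})
    coeffs: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ValueError(f"malformed complex term {term!r}")
        coeff = int(m.group(1) or 1)
        if coeff < 1:
            raise ValueError(f"zero coefficient in term {term!r}")
        name = m.group(2)
        coeffs[name] = coeffs.get(name, 0) + coeff
    return Complex(coeffs)


_LINE_RE = re.compile(
    r"^(?P<id>[A-Za-z0-9_]+)\s*:\s*(?P<src>[^-<>]*?)\s*"
    r"(?P<arrow><->|->)\s*(?P<prod>[^\[\]]*?)\s*\[\s*(?P<rate>[A-Za-z0-9_]+)\s*\]$"
)


def parse_network(text: str) -> CRN:
    """Parse a reaction-list string into a :class:`CRN`.

    Grammar, one reaction per line::

        ID: <complex> -> <complex> [rate_symbol]

    ``#`` starts a comment; blank lines are ignored; the reversible shorthand
    ``<->`` expands into two reactions with ``_f``/``_r`` suffixed ids and
    rate symbols.  Species order is first appearance in the input.
    """
    species: dict[str, None] = {}
    reactions: list[Reaction] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _LINE_RE.match(line)
        if not m:
            raise ParseError(f"malformed reaction line {raw.strip()!r}", line_no)
        try:
            src = parse_complex(m.group("src"))
            prod = parse_complex(m.group("prod"))
        except ValueError as exc:
            raise ParseError(str(exc), line_no) from exc
        for c in (src, prod):
            for s in c.species:
                species.setdefault(s)
        rid, rate = m.group("id"), m.group("rate")
        try:
            if m.group("arrow") == "<->":
                reactions.append(Reaction(rid + "_f", src, prod, rate + "_f"))
                reactions.append(Reaction(rid + "_r", prod, src, rate + "_r"))
            else:
                reactions.append(Reaction(rid, src, prod, rate))
        except ValueError as exc:
            raise ParseError(str(exc), line_no) from exc
    try:
        return CRN(tuple(species), reactions)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------

def reaction_vector(r: Reaction, species_order: Sequence[str]) -> tuple[int, ...]:
    """Product minus source as an integer vector over ``species_order``."""
    s, p = r.source.as_dict(), r.product.as_dict()
    return tuple(p.get(x, 0) - s.get(x, 0) for x in species_order)


def stoichiometric_matrix(crn: CRN) -> sp.Matrix:
    """Species-by-reaction matrix of reaction vectors (exact integers)."""
    rows = len(crn.species)
    cols = len(crn.reactions)
    mat = sp.zeros(rows, cols)
    for j, r in enumerate(crn.reactions):
        for i, v in enumerate(reaction_vector(r, crn.species)):
            mat[i, j] = v
    return mat


def deficiency(crn: CRN) -> int:
    """``n - l - s``: complexes minus linkage classes minus stoichiometric rank."""
    d = crn.n_complexes - crn.n_linkage_classes - crn.stoich_matrix.rank()
    assert d >= 0, "deficiency must be non-negative"
    return d


def is_weakly_reversible(crn: CRN) -> bool:
    """True iff every linkage class of the complex graph is strongly connected."""
    g = crn.complex_graph
    for comp in nx.connected_components(g.to_undirected()):
        sub = g.subgraph(comp)
        if not nx.is_strongly_connected(sub):
            return False
    return True


def mass_action_monomial(source: Complex, species_order: Sequence[str]) -> sp.Expr:
    """Product of concentrations raised to source coefficients."""
    mono: sp.Expr = sp.Integer(1)
    for s, c in source.coefficients:
        mono *= species_symbol(s) ** c
    return mono


def mass_action_rhs(
    crn: CRN, rate_values: Mapping[str, object] | None = None
) -> dict[str, sp.Expr]:
    """Mass-action ODE right-hand sides, one symbolic expression per species.

    ``rate_values`` maps rate symbols to numbers or sympy expressions; any
    symbol left unassigned stays symbolic (as a positive symbol).
    """
    rate_values = dict(rate_values or {})
    rhs = {s: sp.Integer(0) for s in crn.species}
    for r in crn.reactions:
        k = rate_values.get(r.rate_symbol, sp.Symbol(r.rate_symbol, positive=True))
        rate = sp.sympify(k) * mass_action_monomial(r.source, crn.species)
        for s, v in zip(crn.species, reaction_vector(r, crn.species)):
            if v:
                rhs[s] = rhs[s] + v * rate
    return rhs
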