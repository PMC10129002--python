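"""Network translation to weakly reversible, deficiency-zero generalized CRNs.

A *network translation* shifts reactions — replacing a reaction by one with
the same stoichiometric difference (e.g. ``A + B -> B`` by ``A -> 0``) while
keeping the original mass-action rate monomial.  The result is a
*generalized* CRN (GCRN): a directed graph whose vertices carry a
stoichiometric complex ``y`` (governing the reaction vectors) and a kinetic
complex ``y~`` (governing the rates; the reaction's original source).

When two reactions with distinct original sources land on the same
translated source vertex, the vertex is split into one copy per kinetic
complex and the copies are connected by *phantom edges*: edges between
identical stoichiometric complexes, which contribute nothing to the ODEs
and whose rate symbols ``sigma_i`` are free parameters.

The goal of the search is a translation whose stoichiometric and
kinetic-order graphs are both weakly reversible with *effective deficiency*
(deficiency of the stoichiometric CRN) and *kinetic deficiency* (deficiency
of the kinetic-order CRN) both zero; Theorem-style parametrization of the
positive steady states then applies (see :mod:`crnsteady.parametrization`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import sympy as sp

from .core import CRN, Complex, Reaction, mass_action_monomial, species_symbol

__all__ = [
    "Translation",
    "GVertex",
    "GEdge",
    "GCRN",
    "TranslationFailure",
    "apply_translation",
    "insert_phantom_edges",
    "effective_deficiency",
    "kinetic_deficiency",
    "find_translation",
]


@dataclass(frozen=True)
class Translation:
    """Per-reaction integer shift vectors ``h_r`` (reaction id -> species map).

    Reactions absent from ``shifts`` are left unshifted.  Translated source
    and product complexes must stay componentwise non-negative.
    """

    shifts: tuple[tuple[str, tuple[tuple[str, int], ...]], ...]

    def __init__(self, shifts: Mapping[str, Mapping[str, int]] | None = None):
        norm = tuple(
            (rid, tuple(sorted((s, c) for s, c in h.items() if c != 0)))
            for rid, h in sorted((shifts or {}).items())
        )
        object.__setattr__(self, "shifts", tuple((r, h) for r, h in norm if h))

    def shift_of(self, reaction_id: str) -> dict[str, int]:
        for rid, h in self.shifts:
            if rid == reaction_id:
                return dict(h)
        return {}

    @property
    def is_identity(self) -> bool:
        return not self.shifts


@dataclass(frozen=True, order=True)
class GVertex:
    """A GCRN vertex: a stoichiometric complex paired with a kinetic complex."""

    stoich: Complex
    kinetic: Complex

    def __str__(self) -> str:
        if self.stoich == self.kinetic:
            return str(self.stoich)
        return f"{self.stoich}<{self.kinetic}>"


@dataclass(frozen=True)
class GEdge:
    tail: GVertex
    head: GVertex
    label: str  # rate symbol (effective) or sigma symbol (phantom)
    reaction_id: str | None = None

    @property
    def phantom(self) -> bool:
        return self.reaction_id is None


class TranslationFailure(RuntimeError):
    """Structured search failure: names the first unsatisfied property.

    ``budget_exhausted`` distinguishes running out of search budget from a
    completed (but incomplete-by-design) search that found nothing.
    """

    def __init__(self, reason: str, budget_exhausted: bool = False):
        super().__init__(reason)
        self.reason = reason
        self.budget_exhausted = budget_exhausted


@dataclass
class GCRN:
    """A generalized CRN produced by translating a mass-action CRN."""

    crn: CRN  # the original (sub)network
    translation: Translation
    vertices: tuple[GVertex, ...]
    edges: tuple[GEdge, ...]

    # -- basic views --------------------------------------------------------
    @property
    def effective_edges(self) -> tuple[GEdge, ...]:
        return tuple(e for e in self.edges if not e.phantom)

    @property
    def phantom_edges(self) -> tuple[GEdge, ...]:
        return tuple(e for e in self.edges if e.phantom)

    @property
    def sigma_symbols(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.phantom_edges)

    @cached_property
    def stoich_graph(self) -> nx.DiGraph:
        """Directed graph on distinct stoichiometric complexes (phantom edges
        become self-loops and are omitted)."""
        g = nx.DiGraph()
        g.add_nodes_from({v.stoich for v in self.vertices})
        for e in self.effective_edges:
            g.add_edge(e.tail.stoich, e.head.stoich)
        return g

    @cached_property
    def kinetic_graph(self) -> nx.MultiDiGraph:
        """Directed multigraph on distinct kinetic complexes, all edges."""
        g = nx.MultiDiGraph()
        g.add_nodes_from({v.kinetic for v in self.vertices})
        for e in self.edges:
            g.add_edge(e.tail.kinetic, e.head.kinetic, label=e.label)
        return g

    # -- properties ----------------------------------------------------------
    def is_weakly_reversible_stoich(self) -> bool:
        return _all_components_strong(self.stoich_graph)

    def is_weakly_reversible_kinetic(self) -> bool:
        return _all_components_strong(nx.DiGraph(self.kinetic_graph))

    @cached_property
    def effective_deficiency(self) -> int:
        return effective_deficiency(self)

    @cached_property
    def kinetic_deficiency(self) -> int:
        return kinetic_deficiency(self)

    def is_wr_dz(self) -> bool:
        return (
            self.is_weakly_reversible_stoich()
            and self.is_weakly_reversible_kinetic()
            and self.effective_deficiency == 0
            and self.kinetic_deficiency == 0
        )

    def first_failed_property(self) -> str | None:
        if not self.is_weakly_reversible_stoich():
            return "stoichiometric graph not weakly reversible"
        if not self.is_weakly_reversible_kinetic():
            return "kinetic-order graph not weakly reversible"
        if self.effective_deficiency != 0:
            return f"effective deficiency {self.effective_deficiency} != 0"
        if self.kinetic_deficiency != 0:
            return f"kinetic deficiency {self.kinetic_deficiency} != 0"
        return None

    # -- dynamics ------------------------------------------------------------
    def mass_action_rhs(self) -> dict[str, sp.Expr]:
        """ODE right-hand sides generated by the GCRN.

        Effective edges contribute ``k_r * x^{y~(tail)} * (y(head)-y(tail))``;
        phantom edges contribute nothing (identical stoichiometric
        complexes).  By construction this is symbolically identical to the
        original network's mass-action RHS.
        """
        rhs = {s: sp.Integer(0) for s in self.crn.species}
        for e in self.effective_edges:
            k = sp.Symbol(e.label, positive=True)
            mono = mass_action_monomial(e.tail.kinetic, self.crn.species)
            hd, tl = e.head.stoich.as_dict(), e.tail.stoich.as_dict()
            for s in set(hd) | set(tl):
                v = hd.get(s, 0) - tl.get(s, 0)
                if v:
                    rhs[s] = rhs[s] + v * k * mono
        return rhs


def _all_components_strong(g: nx.DiGraph) -> bool:
    for comp in nx.connected_components(g.to_undirected()):
        if not nx.is_strongly_connected(g.subgraph(comp)):
            return False
    return True


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def apply_translation(
    crn: CRN,
    translation: Translation,
    *,
    sigma_start: int = 1,
    with_phantoms: bool = True,
) -> GCRN:
    """Build the GCRN obtained by shifting each reaction by ``h_r``.

    Vertices are the distinct translated complexes; a translated source
    vertex carrying several distinct kinetic complexes is split into one
    copy per kinetic complex (phantom edges are added by
    :func:`insert_phantom_edges` unless ``with_phantoms`` is False).
    Raises ValueError when a shift produces a negative coefficient.
    """
    # translated (stoich) source/product per reaction
    shifted: dict[str, tuple[Complex, Complex]] = {}
    for r in crn.reactions:
        h = translation.shift_of(r.id)
        try:
            src = r.source.shift(h)
            prod = r.product.shift(h)
        except ValueError as exc:
            raise ValueError(
                f"translation of {r.id} yields a negative coefficient"
            ) from exc
        shifted[r.id] = (src, prod)

    # kinetic complexes carried by each stoichiometric complex
    kinetics_at: dict[Complex, list[Complex]] = {}
    for r in crn.reactions:
        src, _ = shifted[r.id]
        lst = kinetics_at.setdefault(src, [])
        if r.source not in lst:
            lst.append(r.source)

    def copies_of(stoich: Complex) -> list[GVertex]:
        kins = kinetics_at.get(stoich, [])
        if not kins:
            # never a source: keeps its stoichiometric complex as kinetic
            return [GVertex(stoich, stoich)]
        # canonical order: the unshifted copy (kinetic == stoich) first,
        # then by coefficient tuple
        kins = sorted(kins, key=lambda c: (c != stoich, c.coefficients))
        return [GVertex(stoich, k) for k in kins]

    all_stoich: dict[Complex, None] = {}
    for r in crn.reactions:
        src, prod = shifted[r.id]
        all_stoich.setdefault(src)
        all_stoich.setdefault(prod)
    vertices: list[GVertex] = []
    natural: dict[Complex, GVertex] = {}
    for c in all_stoich:
        vs = copies_of(c)
        vertices.extend(vs)
        natural[c] = vs[0]

    vertex_by_pair = {(v.stoich, v.kinetic): v for v in vertices}
    edges: list[GEdge] = []
    for r in crn.reactions:
        src, prod = shifted[r.id]
        tail = vertex_by_pair[(src, r.source)]
        head = natural[prod]
        edges.append(GEdge(tail, head, r.rate_symbol, r.id))

    gcrn = GCRN(crn=crn, translation=translation, vertices=tuple(vertices), edges=tuple(edges))
    if with_phantoms:
        gcrn = insert_phantom_edges(gcrn, sigma_start=sigma_start)
    return gcrn


def insert_phantom_edges(gcrn: GCRN, *, sigma_start: int = 1) -> GCRN:
    """Connect split vertex copies with phantom edges, keeping the kinetic
    graph weakly reversible with as few phantom edges as practical.

    For each stoichiometric complex carried by ``k >= 2`` copies, a directed
    cycle through the copies (canonical kinetic-complex order) is inserted;
    phantom edges that are not needed for weak reversibility are then
    dropped greedily in insertion order, so a 2-way split keeps a single
    phantom edge whenever an effective path closes the cycle.  Fresh
    ``sigma`` symbols are numbered in order of insertion.
    """
    groups: dict[Complex, list[GVertex]] = {}
    for v in gcrn.vertices:
        groups.setdefault(v.stoich, []).append(v)

    candidate: list[tuple[GVertex, GVertex]] = []
    for stoich, vs in groups.items():
        if len(vs) < 2:
            continue
        for a, b in zip(vs, vs[1:] + vs[:1]):
            candidate.append((a, b))
    if not candidate:
        return gcrn

    effective = [e for e in gcrn.edges if not e.phantom]

    def kinetic_wr(phantoms: Sequence[tuple[GVertex, GVertex]]) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from({v.kinetic for v in gcrn.vertices})
        for e in effective:
            g.add_edge(e.tail.kinetic, e.head.kinetic)
        for a, b in phantoms:
            g.add_edge(a.kinetic, b.kinetic)
        return _all_components_strong(g)

    kept = list(candidate)
    if kinetic_wr(kept):
        for pair in list(kept):
            trial = [p for p in kept if p != pair]
            if kinetic_wr(trial):
                kept = trial
    # when even the full cycle leaves the kinetic graph non-WR the GCRN is
    # kept as-is; the property check reports the failure downstream

    phantom_edges = tuple(
        GEdge(a, b, f"sigma{sigma_start + i}", None) for i, (a, b) in enumerate(kept)
    )
    return GCRN(
        crn=gcrn.crn,
        translation=gcrn.translation,
        vertices=gcrn.vertices,
        edges=tuple(effective) + phantom_edges,
    )


# ---------------------------------------------------------------------------
# deficiencies
# ---------------------------------------------------------------------------

def _rank_int(vectors: Iterable[Sequence[int]]) -> int:
    vecs = [list(v) for v in vectors]
    if not vecs:
        return 0
    return sp.Matrix(vecs).rank()


def effective_deficiency(gcrn: GCRN) -> int:
    """Deficiency of the stoichiometric CRN ``(G', y)``.

    Nodes are the distinct stoichiometric complexes; phantom edges drop out
    (self-loops); the rank uses the effective edges' reaction vectors.
    """
    g = gcrn.stoich_graph
    n = g.number_of_nodes()
    l = nx.number_connected_components(g.to_undirected())
    species = gcrn.crn.species
    vecs = [
        [h - t for h, t in zip(e.head.stoich.vector(species), e.tail.stoich.vector(species))]
        for e in gcrn.effective_edges
    ]
    return n - l - _rank_int(vecs)


def kinetic_deficiency(gcrn: GCRN) -> int:
    """Deficiency of the kinetic-order CRN ``(G', y~)``.

    Nodes are the distinct kinetic complexes; the rank uses the kinetic
    differences of *all* edges, phantom edges included.
    """
    g = nx.DiGraph(gcrn.kinetic_graph)
    n = g.number_of_nodes()
    l = nx.number_connected_components(g.to_undirected())
    species = gcrn.crn.species
    vecs = [
        [h - t for h, t in zip(e.head.kinetic.vector(species), e.tail.kinetic.vector(species))]
        for e in gcrn.edges
    ]
    return n - l - _rank_int(vecs)


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _candidate_shifts(
    crn: CRN, r: Reaction, max_support: int, max_coeff: int
) -> list[dict[str, int]]:
    """Candidate non-zero shift vectors for one reaction, graded lex order.

    Candidates: negatives of sub-complexes of source AND product (catalyst
    removal) and differences ``s_other - source`` toward every other source
    complex of the subnetwork.  Shifts creating negative complexes are
    rejected outright.
    """
    src, prod = r.source.as_dict(), r.product.as_dict()
    cands: dict[tuple[tuple[str, int], ...], dict[str, int]] = {}

    def consider(h: dict[str, int]):
        h = {s: c for s, c in h.items() if c != 0}
        if not h:
            return
        if len(h) > max_support or any(abs(c) > max_coeff for c in h.values()):
            return
        for base in (src, prod):
            for s, c in h.items():
                if base.get(s, 0) + c < 0:
                    return
        cands.setdefault(tuple(sorted(h.items())), h)

    # catalyst removal: any non-zero sub-complex of min(source, product)
    common = {s: min(src.get(s, 0), prod.get(s, 0)) for s in set(src) & set(prod)}
    common = {s: c for s, c in common.items() if c > 0}
    if common:
        names = sorted(common)
        ranges = [range(common[s] + 1) for s in names]
        for combo in itertools.product(*ranges):
            consider({s: -c for s, c in zip(names, combo)})

    # shift the source onto another source complex of the subnetwork
    sources = {rr.source for rr in crn.reactions}
    for other in sources:
        if other == r.source:
            continue
        o = other.as_dict()
        consider({s: o.get(s, 0) - src.get(s, 0) for s in set(o) | set(src)})

    def grade(h: dict[str, int]):
        return (sum(abs(c) for c in h.values()), tuple(sorted(h.items())))

    return sorted(cands.values(), key=grade)


def find_translation(
    crn: CRN,
    *,
    max_support: int = 2,
    max_coeff: int = 2,
    budget: int = 5000,
    sigma_start: int = 1,
) -> tuple[Translation, GCRN]:
    """Search for a translation making the network WR with both deficiencies 0.

    The search is deterministic and incomplete: subsets of reactions to
    shift are enumerated by increasing size, candidate shifts per reaction
    in graded lexicographic order, depth-first; the first full success wins.
    Raises :class:`TranslationFailure` on failure, with
    ``budget_exhausted`` set when the evaluation budget ran out (as opposed
    to a completed search that found nothing — impossibility is not proven
    either way).
    """
    evaluations = 0
    last_failure = "no candidate translation found"

    def evaluate(shifts: Mapping[str, Mapping[str, int]]):
        nonlocal evaluations, last_failure
        evaluations += 1
        try:
            g = apply_translation(crn, Translation(shifts), sigma_start=sigma_start)
        except ValueError:
            return None
        failed = g.first_failed_property()
        if failed is None:
            return g
        last_failure = failed
        return None

    # identity first: an already WR and DZ network needs no search
    g = evaluate({})
    if g is not None:
        return g.translation, g

    cand = {r.id: _candidate_shifts(crn, r, max_support, max_coeff) for r in crn.reactions}
    rids = [r.id for r in crn.reactions if cand[r.id]]

    for depth in range(1, len(rids) + 1):
        for subset in itertools.combinations(rids, depth):
            for combo in itertools.product(*(cand[rid] for rid in subset)):
                if evaluations >= budget:
                    raise TranslationFailure(
                        f"search budget exhausted after {evaluations} evaluations "
                        f"(last failure: {last_failure})",
                        budget_exhausted=True,
                    )
                g = evaluate(dict(zip(subset, combo)))
                if g is not None:
                    return g.translation, g
    raise TranslationFailure(last_failure)
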