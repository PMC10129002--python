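"""Symbolic steady-state parametrization of WR, deficiency-zero GCRNs.

For a weakly reversible translated network whose kinetic deficiency is
zero, the positive complex-balanced equilibria admit a monomial
parametrization built from the kinetic-order graph:

* the *tree constant* ``K_i`` of a vertex ``i`` is the sum, over all
  spanning trees of the kinetic-order graph directed toward ``i``, of the
  products of the edge labels (matrix-tree theorem);
* for each edge ``i -> i'`` of a chosen spanning forest over the kinetic
  vertices (the forest need not be a subgraph), ``kappa = K_{i'} / K_i``
  and the *kinetic difference* ``y~(i') - y~(i)`` gives one row of a
  matrix ``M``;
* with ``H`` a generalized inverse of ``M`` (``M H M = M``) and ``B`` a
  full-column-rank integer basis of ``ker M``, the steady state of species
  ``j`` is ``prod_e kappa_e^{H[j,e]} * prod_t tau_t^{B[j,t]}`` with free
  positive parameters ``tau``.

When additionally the effective deficiency is zero, this set is exactly
the positive steady-state set of the original (sub)network.

All arithmetic is exact.  ``H`` is constructed from a Smith normal form
``U M V = S`` as ``H = V S^+ U``: deterministic, rational, and integer
whenever the invariant factors of ``M`` are all 1 (the common case here),
which keeps the monomial exponents integral and the printed solutions
radical-free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import sympy as sp

from .core import Complex, species_symbol
from .translation import GCRN

__all__ = [
    "TreeConstants",
    "ForestData",
    "SteadyStateSolution",
    "UnsupportedNetwork",
    "tree_constants",
    "tree_constants_enumerated",
    "tree_constants_laplacian",
    "choose_spanning_forest",
    "forest_data",
    "smith_normal_form",
    "generalized_inverse",
    "kernel_basis",
    "parametrize",
]


class UnsupportedNetwork(RuntimeError):
    """Raised when the parametrization preconditions fail (e.g. positive
    kinetic deficiency, for which additional conditions would have to be
    checked and no parametrization is attempted here)."""


# ---------------------------------------------------------------------------
# tree constants
# ---------------------------------------------------------------------------

def _edge_weight(label: str) -> sp.Symbol:
    return sp.Symbol(label, positive=True)


def tree_constants_laplacian(graph: nx.MultiDiGraph) -> dict[Complex, sp.Expr]:
    """Tree constants via signed minors of the symbolic out-degree Laplacian.

    ``K_i`` equals the determinant of the Laplacian with row and column
    ``i`` deleted (Tutte's directed matrix-tree theorem), computed per
    weakly connected component.  Isolated vertices get ``K = 1``.
    """
    out: dict[Complex, sp.Expr] = {}
    und = graph.to_undirected(as_view=False)
    for comp in nx.connected_components(und):
        nodes = sorted(comp, key=lambda c: c.coefficients)
        idx = {v: i for i, v in enumerate(nodes)}
        m = len(nodes)
        if m == 1:
            out[nodes[0]] = sp.Integer(1)
            continue
        L = sp.zeros(m, m)
        for u, v, data in graph.edges(data=True):
            if u not in idx or u == v:
                continue
            w = _edge_weight(data["label"])
            L[idx[u], idx[u]] += w
            L[idx[u], idx[v]] -= w
        for v in nodes:
            i = idx[v]
            minor = L.copy()
            minor.col_del(i)
            minor.row_del(i)
            out[v] = sp.expand(minor.det(method="berkowitz"))
    return out


def tree_constants_enumerated(graph: nx.MultiDiGraph) -> dict[Complex, sp.Expr]:
    """Tree constants by explicit enumeration of spanning in-trees.

    A spanning tree toward ``i`` picks exactly one out-edge for every other
    vertex of the component such that all paths lead to ``i``.  Exponential;
    intended for small graphs and as the independent cross-check.
    """
    out: dict[Complex, sp.Expr] = {}
    und = graph.to_undirected(as_view=False)
    for comp in nx.connected_components(und):
        nodes = sorted(comp, key=lambda c: c.coefficients)
        if len(nodes) == 1:
            out[nodes[0]] = sp.Integer(1)
            continue
        out_edges: dict[Complex, list[tuple[Complex, sp.Symbol]]] = {v: [] for v in nodes}
        for u, v, data in graph.edges(data=True):
            if u in out_edges and u != v:
                out_edges[u].append((v, _edge_weight(data["label"])))
        for root in nodes:
            others = [v for v in nodes if v != root]
            total: sp.Expr = sp.Integer(0)
            for choice in itertools.product(*(out_edges[v] for v in others)):
                succ = {v: c[0] for v, c in zip(others, choice)}
                # follow the functional graph: every vertex must reach root
                ok = True
                for v in others:
                    seen = set()
                    cur = v
                    while cur != root:
                        if cur in seen or cur not in succ:
                            ok = False
                            break
                        seen.add(cur)
                        cur = succ[cur]
                    if not ok:
                        break
                if ok:
                    term: sp.Expr = sp.Integer(1)
                    for _, w in choice:
                        term *= w
                    total += term
            out[root] = sp.expand(total)
    return out


@dataclass(frozen=True)
class TreeConstants:
    """Per-vertex tree constants of a kinetic-order graph."""

    K: dict[Complex, sp.Expr]

    def __getitem__(self, vertex: Complex) -> sp.Expr:
        return self.K[vertex]


def tree_constants(graph: nx.MultiDiGraph, *, cross_check: bool | None = None) -> TreeConstants:
    """Compute tree constants; cross-check the two routes on small graphs.

    ``cross_check=None`` (default) enables the enumeration cross-check
    whenever every component has at most 8 vertices.
    """
    K = tree_constants_laplacian(graph)
    if cross_check is None:
        cross_check = graph.number_of_nodes() <= 8
    if cross_check:
        K2 = tree_constants_enumerated(graph)
        for v, k in K.items():
            assert sp.expand(k - K2[v]) == 0, f"matrix-tree mismatch at {v}"
    return TreeConstants(K=K)


# ---------------------------------------------------------------------------
# spanning forest and exact linear algebra
# ---------------------------------------------------------------------------

def choose_spanning_forest(graph: nx.MultiDiGraph) -> list[tuple[Complex, Complex]]:
    """Deterministic spanning forest over the kinetic vertices.

    Per weakly connected component: a breadth-first tree of the undirected
    graph rooted at the canonically smallest vertex, edges oriented away
    from the root.  ``n - l`` edges in total.  (Any forest over the vertex
    set would do, subgraph or not; this one uses only actual adjacencies
    and is reproducible.)
    """
    forest: list[tuple[Complex, Complex]] = []
    und = nx.Graph()
    und.add_nodes_from(graph.nodes)
    und.add_edges_from((u, v) for u, v, _ in graph.edges(data=True) if u != v)
    for comp in nx.connected_components(und):
        nodes = sorted(comp, key=lambda c: c.coefficients)
        root = nodes[0]
        seen = {root}
        frontier = [root]
        while frontier:
            nxt: list[Complex] = []
            for u in frontier:
                for v in sorted(und.neighbors(u), key=lambda c: c.coefficients):
                    if v not in seen:
                        seen.add(v)
                        forest.append((u, v))
                        nxt.append(v)
            frontier = nxt
    return forest


def smith_normal_form(M: sp.Matrix) -> tuple[sp.Matrix, sp.Matrix, sp.Matrix]:
    """Integer Smith-style diagonalization ``U M V = S`` with unimodular U, V.

    ``S`` is (rectangular) diagonal with positive pivots; the divisibility
    chain is not enforced, which is immaterial for the generalized inverse
    and kernel extraction below.  Deterministic pivoting: smallest absolute
    value, row-major tie-break.
    """
    A = M.copy()
    m, n = A.shape
    U = sp.eye(m)
    V = sp.eye(n)
    t = 0
    while t < min(m, n):
        # pick pivot: smallest |value| among non-zeros of the submatrix
        piv = None
        for i in range(t, m):
            for j in range(t, n):
                if A[i, j] != 0 and (piv is None or abs(A[i, j]) < abs(A[piv[0], piv[1]])):
                    piv = (i, j)
        if piv is None:
            break
        i0, j0 = piv
        if i0 != t:
            A.row_swap(t, i0)
            U.row_swap(t, i0)
        if j0 != t:
            A.col_swap(t, j0)
            V.col_swap(t, j0)
        if A[t, t] < 0:
            A[t, :] = -A[t, :]
            U[t, :] = -U[t, :]
        # clear row and column t; re-pivot when remainders appear
        while True:
            done = True
            for i in range(t + 1, m):
                if A[i, t] != 0:
                    q = A[i, t] // A[t, t]
                    if q:
                        A[i, :] = A[i, :] - q * A[t, :]
                        U[i, :] = U[i, :] - q * U[t, :]
                    if A[i, t] != 0:
                        A.row_swap(t, i)
                        U.row_swap(t, i)
                        if A[t, t] < 0:
                            A[t, :] = -A[t, :]
                            U[t, :] = -U[t, :]
                        done = False
            for j in range(t + 1, n):
                if A[t, j] != 0:
                    q = A[t, j] // A[t, t]
                    if q:
                        A[:, j] = A[:, j] - q * A[:, t]
                        V[:, j] = V[:, j] - q * V[:, t]
                    if A[t, j] != 0:
                        A.col_swap(t, j)
                        V.col_swap(t, j)
                        if A[t, t] < 0:
                            A[t, :] = -A[t, :]
                            U[t, :] = -U[t, :]
                        done = False
            if done:
                break
        t += 1
    return U, A, V


def generalized_inverse(M: sp.Matrix) -> sp.Matrix:
    """A generalized inverse ``H`` with ``M H M = M`` via the Smith form.

    ``H = V S^+ U`` is exact rational and integer whenever the invariant
    factors of ``M`` are all 1.
    """
    U, S, V = smith_normal_form(M)
    m, n = M.shape
    Sp = sp.zeros(n, m)
    for t in range(min(m, n)):
        if S[t, t] != 0:
            Sp[t, t] = sp.Rational(1, S[t, t])
    H = V * Sp * U
    assert M * H * M == M
    return H


def kernel_basis(M: sp.Matrix) -> sp.Matrix:
    """Full-column-rank integer basis of ``ker M``.

    Columns of ``V`` matching zero columns of the Smith form; signs are
    normalized (positive leading entry) and columns sorted for stability.
    """
    U, S, V = smith_normal_form(M)
    m, n = M.shape
    cols = []
    for j in range(n):
        if j >= min(m, n) or S[j, j] == 0:
            col = V[:, j]
            lead = next((col[i] for i in range(n) if col[i] != 0), 1)
            if lead < 0:
                col = -col
            cols.append(tuple(col))
    cols.sort()
    B = sp.Matrix([list(c) for c in cols]).T if cols else sp.zeros(n, 0)
    if cols:
        assert (M * B).is_zero_matrix
    return B


@dataclass
class ForestData:
    """Forest edges with their kinetic-difference matrix and derived data.

    ``M`` has one row per forest edge (kinetic difference, head minus tail,
    over ``species``); ``H`` satisfies ``M H M = M``; columns of ``Bk``
    span ``ker M``; ``kappa[e]`` is the tree-constant ratio of edge ``e``.
    """

    forest: list[tuple[Complex, Complex]]
    species: tuple[str, ...]
    M: sp.Matrix
    H: sp.Matrix
    Bk: sp.Matrix
    kappa: dict[tuple[Complex, Complex], sp.Expr]


def forest_data(
    graph: nx.MultiDiGraph,
    forest: Sequence[tuple[Complex, Complex]],
    species: Sequence[str],
    constants: TreeConstants | None = None,
) -> ForestData:
    if constants is None:
        constants = tree_constants(graph)
    rows = []
    kappa: dict[tuple[Complex, Complex], sp.Expr] = {}
    for tail, head in forest:
        hv, tv = head.vector(species), tail.vector(species)
        rows.append([h - t for h, t in zip(hv, tv)])
        kappa[(tail, head)] = sp.cancel(constants[head] / constants[tail])
    M = sp.Matrix(rows) if rows else sp.zeros(0, len(species))
    H = generalized_inverse(M)
    Bk = kernel_basis(M)
    return ForestData(
        forest=list(forest), species=tuple(species), M=M, H=H, Bk=Bk, kappa=kappa
    )


# ---------------------------------------------------------------------------
# the parametrization
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateSolution:
    """Positive steady-state parametrization of one (sub)network.

    ``expressions`` maps each species appearing in the kinetic complexes to
    a symbolic expression in rate constants, phantom ``sigma`` parameters
    and kernel ``tau`` parameters; all strictly positive for positive
    parameter values.
    """

    expressions: dict[str, sp.Expr]
    free_sigma: tuple[str, ...]
    free_tau: tuple[str, ...]
    provenance: str = ""
    gcrn: GCRN | None = None

    def rename_parameters(self, mapping: Mapping[str, str]) -> "SteadyStateSolution":
        subs = {sp.Symbol(a, positive=True): sp.Symbol(b, positive=True) for a, b in mapping.items()}
        return SteadyStateSolution(
            expressions={s: e.subs(subs, simultaneous=True) for s, e in self.expressions.items()},
            free_sigma=tuple(mapping.get(x, x) for x in self.free_sigma),
            free_tau=tuple(mapping.get(x, x) for x in self.free_tau),
            provenance=self.provenance,
            gcrn=self.gcrn,
        )


def parametrize(gcrn: GCRN, *, tau_start: int = 1, provenance: str = "") -> SteadyStateSolution:
    """Monomial parametrization of the GCRN's positive steady states.

    Requires weak reversibility of both graphs and zero effective and
    kinetic deficiency; violations raise :class:`UnsupportedNetwork`
    naming the failed property (positive kinetic deficiency in particular
    is deliberately unsupported rather than silently mishandled).
    """
    failed = gcrn.first_failed_property()
    if failed is not None:
        raise UnsupportedNetwork(failed)

    graph = gcrn.kinetic_graph
    kin_species = tuple(
        s
        for s in gcrn.crn.species
        if any(v.kinetic[s] for v in gcrn.vertices)
    )
    constants = tree_constants(graph)
    forest = choose_spanning_forest(graph)
    data = forest_data(graph, forest, kin_species, constants)

    n_tau = data.Bk.cols
    taus = [sp.Symbol(f"tau{tau_start + t}", positive=True) for t in range(n_tau)]
    exprs: dict[str, sp.Expr] = {}
    for j, s in enumerate(kin_species):
        e: sp.Expr = sp.Integer(1)
        for col, (tail, head) in enumerate(data.forest):
            exp = data.H[j, col]
            if exp != 0:
                e *= data.kappa[(tail, head)] ** exp
        for t in range(n_tau):
            if data.Bk[j, t] != 0:
                e *= taus[t] ** data.Bk[j, t]
        exprs[s] = sp.powsimp(sp.cancel(e))
    return SteadyStateSolution(
        expressions=exprs,
        free_sigma=gcrn.sigma_symbols,
        free_tau=tuple(str(t) for t in taus),
        provenance=provenance,
        gcrn=gcrn,
    )
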