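"""Stitching subnetwork steady states into a whole-network solution.

For an independent decomposition, the positive steady-state set of the
whole mass-action system is the intersection of the subnetworks' sets, so
a steady state of the whole network is obtained by *merging*: for every
species shared by two subnetworks the two parametrized expressions are
equated, and each merge equation is solved for one free parameter, which
is then eliminated everywhere.

The surviving free parameters (phantom ``sigma``'s and kernel ``tau``'s)
are finally resolved against the network's conservation laws — the left
kernel of the stoichiometric matrix — given initial concentrations, and
the resolved solution supports reporting *absolute concentration
robustness* (ACR): a species has ACR when its steady-state concentration
is independent of every conserved quantity, i.e. of all initial
conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import sympy as sp

from .core import CRN, species_symbol
from .parametrization import SteadyStateSolution

__all__ = [
    "ConservationLaw",
    "MergedSolution",
    "ACRReport",
    "InconsistentMerge",
    "merge_solutions",
    "conservation_laws",
    "resolve_with_conservation",
    "acr_report",
]


class InconsistentMerge(RuntimeError):
    """No common positive steady state detectable among the subnetworks."""


def _psym(name: str) -> sp.Symbol:
    return sp.Symbol(name, positive=True)


def _param_sort_key(name: str) -> tuple[int, int]:
    # taus are preferred unknowns over sigmas; higher index = newer
    kind = 0 if name.startswith("tau") else 1
    digits = "".join(ch for ch in name if ch.isdigit())
    return (kind, -(int(digits) if digits else 0))


@dataclass
class MergedSolution:
    """Whole-network steady-state expressions with their free parameters."""

    expressions: dict[str, sp.Expr]
    remaining_free: tuple[str, ...]
    substitutions: list[tuple[str, sp.Expr]] = field(default_factory=list)
    residual_equations: list[sp.Expr] = field(default_factory=list)
    alternative_roots: list[tuple[str, tuple[sp.Expr, ...]]] = field(default_factory=list)
    conserved_values: dict[str, sp.Expr] = field(default_factory=dict)

    def free_symbols_present(self) -> tuple[str, ...]:
        used = set()
        for e in self.expressions.values():
            used |= {str(s) for s in e.free_symbols}
        return tuple(p for p in self.remaining_free if p in used)


def _positive_at_sample(expr: sp.Expr) -> bool:
    """Heuristic positivity check: evaluate with every symbol set to 1."""
    try:
        val = expr.subs({s: 1 for s in expr.free_symbols})
        val = sp.nsimplify(val).evalf()
        return bool(val.is_real and val > 0)
    except Exception:
        return False


def _joint_solve(eqs: Sequence[sp.Expr], syms: Sequence[sp.Symbol]) -> list[dict]:
    """Solve a coupled polynomial block; Groebner-basis route first (robust
    for numeric rational coefficients), generic solver as fallback."""
    try:
        polys = [sp.Poly(sp.expand(e), *syms) for e in eqs]
        tuples = sp.solve_poly_system(polys, *syms)
        return [dict(zip(syms, t)) for t in tuples]
    except Exception:
        pass
    try:
        return sp.solve(list(eqs), list(syms), dict=True)
    except Exception:
        return []


def _solve_for(eq: sp.Expr, unknown: sp.Symbol) -> tuple[sp.Expr, tuple[sp.Expr, ...]]:
    """Solve ``eq == 0`` for ``unknown``; return the positive branch and any
    other positive roots (potential multistationarity)."""
    roots = sp.solve(eq, unknown)
    pos = [sp.cancel(sp.together(r)) for r in roots if _positive_at_sample(r)]
    if not pos:
        raise InconsistentMerge(
            f"no positive solution of a merge/conservation equation for {unknown}"
        )
    return pos[0], tuple(pos[1:])


def merge_solutions(solutions: Sequence[SteadyStateSolution]) -> MergedSolution:
    """Merge per-subnetwork parametrizations into one solution.

    For each species appearing in several solutions the expressions are
    equated; each equation is solved for its newest free parameter
    (``tau`` preferred over ``sigma``) and the result substituted
    everywhere.  Equations that resist closed-form solving are retained in
    ``residual_equations``; a parameter-free equation that does not reduce
    to zero marks the merge as inconsistent.
    """
    if not solutions:
        raise ValueError("need at least one solution")

    # ensure globally unique parameter names
    names = list(itertools.chain.from_iterable(s.free_sigma + s.free_tau for s in solutions))
    if len(names) != len(set(names)):
        renamed = []
        n_sigma = n_tau = 0
        for sol in solutions:
            mapping = {}
            for x in sol.free_sigma:
                n_sigma += 1
                mapping[x] = f"sigma{n_sigma}"
            for x in sol.free_tau:
                n_tau += 1
                mapping[x] = f"tau{n_tau}"
            renamed.append(sol.rename_parameters(mapping))
        solutions = renamed

    free = list(itertools.chain.from_iterable(s.free_sigma + s.free_tau for s in solutions))
    species_order: list[str] = []
    for sol in solutions:
        for s in sol.expressions:
            if s not in species_order:
                species_order.append(s)

    exprs: dict[str, sp.Expr] = {}
    subs_log: list[tuple[str, sp.Expr]] = []
    residuals: list[sp.Expr] = []
    alternatives: list[tuple[str, tuple[sp.Expr, ...]]] = []
    solved: dict[sp.Symbol, sp.Expr] = {}

    def current(e: sp.Expr) -> sp.Expr:
        return sp.cancel(sp.together(e.subs(solved, simultaneous=False)))

    for sol in solutions:
        for s in sorted(sol.expressions, key=species_order.index):
            new = current(sol.expressions[s])
            if s not in exprs:
                exprs[s] = new
                continue
            old = current(exprs[s])
            eq = sp.together(old - new)
            eq = sp.numer(eq)  # positive denominators only
            if sp.expand(eq) == 0:
                continue
            params = sorted(
                (str(x) for x in eq.free_symbols if str(x) in free),
                key=_param_sort_key,
            )
            if not params:
                raise InconsistentMerge(
                    f"subnetworks disagree on species {s}: {sp.simplify(old - new)} != 0"
                )
            unknown = _psym(params[0])
            try:
                value, other = _solve_for(eq, unknown)
            except (NotImplementedError, InconsistentMerge):
                residuals.append(eq)
                continue
            if other:
                alternatives.append((str(unknown), other))
            solved[unknown] = value
            # keep earlier solved values closed under the new substitution
            for key in list(solved):
                solved[key] = sp.cancel(solved[key].subs(unknown, value))
            subs_log.append((str(unknown), value))
            free.remove(str(unknown))
            for sp_name in list(exprs):
                exprs[sp_name] = current(exprs[sp_name])

    exprs = {s: sp.powsimp(sp.cancel(e)) for s, e in exprs.items()}
    remaining = tuple(p for p in free)
    return MergedSolution(
        expressions=exprs,
        remaining_free=remaining,
        substitutions=subs_log,
        residual_equations=[current(r) for r in residuals],
        alternative_roots=alternatives,
    )


# ---------------------------------------------------------------------------
# conservation laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationLaw:
    """An integer left-kernel vector of S with its conserved-quantity symbol.

    ``weights @ x(t)`` is constant along trajectories; the conserved value
    is written in terms of initial concentrations (``b0 + d0`` style).
    """

    species: tuple[str, ...]
    weights: tuple[sp.Rational, ...]

    def lhs(self) -> sp.Expr:
        return sp.Add(*(w * species_symbol(s) for s, w in zip(self.species, self.weights) if w))

    def conserved_symbol(self) -> sp.Expr:
        return sp.Add(
            *(
                w * sp.Symbol(f"{s.lower()}0", positive=True)
                for s, w in zip(self.species, self.weights)
                if w
            )
        )

    def value_at(self, x0: Mapping[str, float]) -> sp.Expr:
        return sp.Add(*(w * sp.nsimplify(x0[s]) for s, w in zip(self.species, self.weights) if w))

    def __str__(self) -> str:
        return f"{self.lhs()} = {self.conserved_symbol()}"


def conservation_laws(crn: CRN) -> list[ConservationLaw]:
    """Integer basis of the left kernel of the stoichiometric matrix.

    The basis is scaled to primitive integer vectors with positive first
    non-zero entry; when a non-negative basis exists it is preferred
    (negative entries are cleared by adding suitable positive multiples of
    the other basis vectors, which succeeds for the usual "pool" laws).
    """
    S = crn.stoich_matrix
    null = S.T.nullspace()
    vecs = []
    for v in null:
        denoms = [sp.fraction(sp.nsimplify(x))[1] for x in v]
        scale = sp.ilcm(*[int(d) for d in denoms]) if denoms else 1
        iv = [sp.Integer(x * scale) for x in v]
        g = sp.igcd(*[int(x) for x in iv if x != 0]) or 1
        iv = [x / g for x in iv]
        first = next((x for x in iv if x != 0), 1)
        if first < 0:
            iv = [-x for x in iv]
        vecs.append(iv)
    # prefer a non-negative basis: replace a mixed-sign vector v by
    # +-v + m*u (u another basis vector, small m), which preserves the span
    def _normalize(v):
        g = sp.igcd(*[int(x) for x in v if x != 0]) or 1
        v = [x / g for x in v]
        first = next((x for x in v if x != 0), 1)
        return [-x for x in v] if first < 0 else v

    changed = True
    guard = 0
    while changed and guard < 100:
        changed = False
        guard += 1
        for i, v in enumerate(vecs):
            if all(x >= 0 for x in v):
                continue
            for j, u in enumerate(vecs):
                if i == j:
                    continue
                for m in (1, 2, 3):
                    for cand in (
                        [a + m * b for a, b in zip(v, u)],
                        [-a + m * b for a, b in zip(v, u)],
                    ):
                        if any(x != 0 for x in cand) and all(x >= 0 for x in cand):
                            vecs[i] = _normalize(cand)
                            changed = True
                            break
                    if changed:
                        break
                if changed:
                    break
            if changed:
                break
    laws = [ConservationLaw(species=crn.species, weights=tuple(v)) for v in vecs]
    assert len(laws) == len(crn.species) - S.rank()
    for law in laws:
        assert all(x == 0 for x in (sp.Matrix([list(law.weights)]) * S))
    return laws


# ---------------------------------------------------------------------------
# resolving free parameters against conserved quantities
# ---------------------------------------------------------------------------

def resolve_with_conservation(
    merged: MergedSolution,
    laws: Sequence[ConservationLaw],
    initial_values: Mapping[str, float] | None = None,
    rate_values: Mapping[str, float] | None = None,
) -> MergedSolution:
    """Solve the remaining free parameters from the conservation laws.

    Substituting the steady-state expressions into each law yields one
    equation per law in the free parameters.  Equations are solved
    sequentially whenever one involves a single unknown; remaining blocks
    are handed to the symbolic solver jointly.  Among multiple roots the
    positive branch is selected (checked at a sample point); extra positive
    roots are recorded as potential multistationarity.  Unsolved equations
    are returned symbolically in ``residual_equations``.
    """
    rate_subs = {
        _psym(k): sp.nsimplify(v) for k, v in (rate_values or {}).items()
    }
    exprs = {s: sp.cancel(e.subs(rate_subs)) for s, e in merged.expressions.items()}
    unknowns = [p for p in merged.remaining_free]

    # each conserved quantity enters as an atomic positive symbol Q<i>;
    # conserved_values records what it stands for (b0 + d0 style, or the
    # numeric value computed from the supplied initial concentrations)
    conserved_values: dict[str, sp.Expr] = {}
    equations: list[sp.Expr] = []
    for i, law in enumerate(laws, start=1):
        if initial_values:
            q: sp.Expr = law.value_at(initial_values)
            conserved_values[f"Q{i}"] = q
        else:
            q = sp.Symbol(f"Q{i}", positive=True)
            conserved_values[f"Q{i}"] = law.conserved_symbol()
        total = sp.Integer(0)
        ok = True
        for s, w in zip(law.species, law.weights):
            if w == 0:
                continue
            if s not in exprs:
                ok = False
                break
            total += w * exprs[s]
        if not ok:
            continue
        eq = sp.numer(sp.together(total - q))
        equations.append(eq)

    subs_log = list(merged.substitutions)
    alternatives = list(merged.alternative_roots)
    residuals: list[sp.Expr] = []
    pending = list(equations)

    def apply(sol_map: Mapping[sp.Symbol, sp.Expr]):
        nonlocal pending, exprs
        for sym, val in sol_map.items():
            name = str(sym)
            if name in unknowns:
                unknowns.remove(name)
            subs_log.append((name, val))
        exprs = {s: sp.cancel(e.subs(sol_map, simultaneous=True)) for s, e in exprs.items()}
        pending = [sp.numer(sp.together(p.subs(sol_map, simultaneous=True))) for p in pending]
        pending = [p for p in pending if sp.expand(p) != 0]

    progress = True
    while pending and progress:
        progress = False
        # single-unknown equations first
        for eq in list(pending):
            present = [u for u in unknowns if _psym(u) in eq.free_symbols]
            if len(present) == 1:
                try:
                    val, other = _solve_for(eq, _psym(present[0]))
                except (NotImplementedError, InconsistentMerge):
                    continue
                if other:
                    alternatives.append((present[0], other))
                pending.remove(eq)
                apply({_psym(present[0]): val})
                progress = True
                break
        if progress:
            continue
        # otherwise solve the smallest coupled block jointly
        present_all = [u for u in unknowns if any(_psym(u) in e.free_symbols for e in pending)]
        if not present_all:
            break
        sols = _joint_solve(pending, [_psym(u) for u in present_all])
        chosen = None
        for cand in sols:
            if all(_positive_at_sample(v) for v in cand.values()):
                chosen = cand
                break
        if chosen is None:
            break
        if len(sols) > 1:
            others = [c for c in sols if c is not chosen]
            for u in present_all:
                extra = tuple(c[_psym(u)] for c in others if _psym(u) in c and _positive_at_sample(c[_psym(u)]))
                if extra:
                    alternatives.append((u, extra))
        pending = []
        apply(chosen)
        progress = True

    residuals = [p for p in pending if sp.expand(p) != 0]
    return MergedSolution(
        expressions={s: sp.powsimp(sp.cancel(e)) for s, e in exprs.items()},
        remaining_free=tuple(unknowns),
        substitutions=subs_log,
        residual_equations=residuals,
        alternative_roots=alternatives,
        conserved_values=conserved_values,
    )


# ---------------------------------------------------------------------------
# absolute concentration robustness
# ---------------------------------------------------------------------------

@dataclass
class ACRReport:
    """Species-by-conserved-quantity dependence flags.

    ``depends[s][q]`` is True when the steady state of species ``s`` changes
    with conserved quantity ``q``; a species with no dependence on any
    conserved quantity has absolute concentration robustness.
    """

    quantities: tuple[str, ...]
    depends: dict[str, dict[str, bool]]
    note: str = ""

    def acr_species(self) -> tuple[str, ...]:
        return tuple(s for s, d in self.depends.items() if not any(d.values()))

    def has_acr(self, species: str) -> bool:
        return not any(self.depends[species].values())


def acr_report(
    resolved: MergedSolution,
    laws: Sequence[ConservationLaw],
    numeric_check: bool = True,
) -> ACRReport:
    """Dependence of each steady state on each conserved quantity.

    Requires a solution resolved symbolically in the conserved-quantity
    symbols (initial concentrations); dependence is decided by a symbolic
    partial derivative, optionally cross-checked numerically by
    finite perturbation of the conserved quantity.
    """
    leftover = resolved.free_symbols_present()
    if leftover:
        raise ValueError(f"free parameters not resolved: {leftover}")
    if not laws:
        return ACRReport(
            quantities=(),
            depends={s: {} for s in resolved.expressions},
            note="no conservation laws: every steady state is trivially "
            "independent of initial conditions",
        )

    # conserved quantities appear as the atomic symbols Q<i> introduced by
    # resolve_with_conservation; report rows use the b0 + d0 style names
    qsyms = [sp.Symbol(f"Q{i}", positive=True) for i in range(1, len(laws) + 1)]
    qnames = [str(law.conserved_symbol()) for law in laws]

    depends: dict[str, dict[str, bool]] = {}
    for s, e in resolved.expressions.items():
        e_q = e
        row: dict[str, bool] = {}
        for qs, qname in zip(qsyms, qnames):
            d = sp.simplify(sp.diff(e_q, qs))
            flag = d != 0
            if flag and numeric_check:
                # numeric confirmation at a sample point
                base = {x: sp.Rational(1) for x in e_q.free_symbols}
                v0 = e_q.subs(base)
                v1 = e_q.subs({**base, qs: sp.Rational(11, 10)})
                try:
                    flag = abs(float(v0 - v1)) > 1e-8 * max(1.0, abs(float(v0)))
                except (TypeError, ValueError):
                    flag = True
            row[qname] = bool(flag)
        depends[s] = row
    return ACRReport(quantities=tuple(qnames), depends=depends)
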