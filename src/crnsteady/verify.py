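"""Numeric oracles: ODE steady states, solution spot-checks, random fixtures.

These utilities validate the symbolic machinery against independent
numerics: stiff ODE integration of the mass-action system until the
residual ``max |dx/dt|`` is small, evaluation of a merged symbolic
solution at random positive parameter points, and seeded generation of
random weakly reversible deficiency-zero networks for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .assembly import MergedSolution
from .core import CRN, Complex, Reaction, mass_action_rhs, species_symbol

__all__ = [
    "SimulationResult",
    "numeric_steady_state",
    "check_solution",
    "random_wr_dz_network",
]


@dataclass
class SimulationResult:
    species: tuple[str, ...]
    final_state: np.ndarray
    residual: float
    converged: bool
    n_steps: int
    tol: float

    def state_dict(self) -> dict[str, float]:
        return dict(zip(self.species, map(float, self.final_state)))


def _rhs_func(crn: CRN, rate_values: Mapping[str, float]):
    rhs = mass_action_rhs(crn, rate_values)
    syms = [species_symbol(s) for s in crn.species]
    exprs = [rhs[s] for s in crn.species]
    f = sp.lambdify(syms, exprs, modules="numpy")

    def fun(t, x):
        return np.asarray(f(*x), dtype=float)

    return fun


def numeric_steady_state(
    crn: CRN,
    rate_values: Mapping[str, float],
    x0: Sequence[float],
    tol: float = 1e-10,
    t_max: float = 1e7,
) -> SimulationResult:
    """Integrate the mass-action ODEs until the residual drops below ``tol``.

    Stiff-capable (LSODA); integration proceeds in geometrically growing
    time chunks; non-convergence within the time budget is reported, never
    silently accepted.  Convergence is residual-based (``max |dx/dt|``),
    not state-difference-based, to avoid false convergence on slow
    manifolds.
    """
    x0 = np.asarray(list(x0), dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be non-negative")
    if any(v <= 0 for v in rate_values.values()):
        raise ValueError("rate constants must be positive")
    if not crn.reactions:
        return SimulationResult(crn.species, x0, 0.0, True, 0, tol)
    fun = _rhs_func(crn, rate_values)
    t_end = 1.0
    x = x0
    n_steps = 0
    while t_end <= t_max:
        sol = solve_ivp(fun, (0.0, t_end), x, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            break
        x = sol.y[:, -1]
        n_steps += sol.t.size
        residual = float(np.max(np.abs(fun(0.0, x))))
        if residual < tol:
            return SimulationResult(crn.species, x, residual, True, n_steps, tol)
        t_end *= 10.0
    residual = float(np.max(np.abs(fun(0.0, x))))
    return SimulationResult(crn.species, x, residual, residual < tol, n_steps, tol)


def check_solution(
    crn: CRN,
    merged: MergedSolution,
    n_samples: int = 20,
    seed: int = 0,
    tol: float = 1e-9,
) -> dict:
    """Evaluate the merged symbolic solution at random positive parameter
    points and assert that the full mass-action RHS vanishes.

    Rate constants and remaining free parameters are sampled log-uniformly
    in [0.1, 10]; the report pinpoints the first offending species and
    sample on failure.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    rhs = mass_action_rhs(crn)
    rate_syms = sorted(
        {sym for e in rhs.values() for sym in e.free_symbols} - {species_symbol(s) for s in crn.species},
        key=str,
    )
    free_syms = [sp.Symbol(p, positive=True) for p in merged.remaining_free]
    expr_syms = sorted(
        {sym for e in merged.expressions.values() for sym in e.free_symbols}, key=str
    )
    params = sorted(set(rate_syms) | set(free_syms) | set(expr_syms), key=str)
    species_exprs = [merged.expressions.get(s) for s in crn.species]
    if any(e is None for e in species_exprs):
        missing = [s for s, e in zip(crn.species, species_exprs) if e is None]
        return {"passed": False, "failures": [f"no expression for {m}" for m in missing]}
    f_state = sp.lambdify(params, species_exprs, modules="numpy")
    f_rhs = sp.lambdify(
        [species_symbol(s) for s in crn.species] + params,
        [rhs[s] for s in crn.species],
        modules="numpy",
    )
    failures = []
    for i in range(n_samples):
        vals = 10.0 ** rng.uniform(-1, 1, size=len(params))
        state = np.asarray(f_state(*vals), dtype=float)
        resid = np.asarray(f_rhs(*state, *vals), dtype=float)
        bad = np.abs(resid) >= tol
        if np.any(bad):
            j = int(np.argmax(np.abs(resid)))
            failures.append(
                f"sample {i}: species {crn.species[j]} residual {resid[j]:.3e}"
            )
    return {"passed": not failures, "failures": failures, "n_samples": n_samples}


def random_wr_dz_network(
    seed: int, n_species: int = 3, n_cycles: int = 1, max_retries: int = 200
) -> CRN:
    """Random weakly reversible deficiency-zero network, seeded.

    Built as a union of directed cycles over random small complexes
    (coefficients 0..2, at most 2 species per complex), retried until the
    deficiency is zero.  Weak reversibility holds by construction.
    """
    if n_species < 1 or n_cycles < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    species = [f"X{i + 1}" for i in range(n_species)]
    for _ in range(max_retries):
        complexes: list[Complex] = []
        reactions: list[Reaction] = []
        used_pairs: set[tuple[Complex, Complex]] = set()
        ok = True
        for _c in range(n_cycles):
            length = int(rng.integers(2, 4))
            cyc: list[Complex] = []
            attempts = 0
            while len(cyc) < length and attempts < 50:
                attempts += 1
                chosen = rng.choice(n_species, size=min(2, n_species), replace=False)
                coeffs = {
                    species[int(j)]: int(rng.integers(0, 3)) for j in chosen
                }
                c = Complex({k: v for k, v in coeffs.items() if v})
                if c not in cyc:
                    cyc.append(c)
            if len(cyc) < 2:
                ok = False
                break
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                if (a, b) in used_pairs:
                    ok = False
                    break
                used_pairs.add((a, b))
                idx = len(reactions) + 1
                reactions.append(Reaction(f"R{idx}", a, b, f"k{idx}"))
            if not ok:
                break
        if not ok or not reactions:
            continue
        present = {s for r in reactions for s in (*r.source.species, *r.product.species)}
        try:
            crn = CRN([s for s in species if s in present], reactions)
        except ValueError:
            continue
        if crn.deficiency == 0 and crn.is_weakly_reversible:
            return crn
    raise RuntimeError("retry budget exhausted generating a WR deficiency-zero network")
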