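"""End-to-end driver: decompose, translate, parametrize, merge, resolve.

This is the programmatic equivalent of the ``solve`` command: the network
is split into its finest independent decomposition; each subnetwork that
is not already weakly reversible with deficiency zero is translated; each
translated subnetwork is parametrized; the subnetwork solutions are merged
into a whole-network steady state; and the conservation laws are attached.
Subnetworks for which the translation search or parametrization fails are
reported individually while the rest of the network is still solved.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp

from .assembly import ConservationLaw, MergedSolution, conservation_laws, merge_solutions
from .core import CRN, mass_action_rhs, species_symbol
from .decomposition import Decomposition, finest_independent_decomposition, subnetwork
from .parametrization import SteadyStateSolution, UnsupportedNetwork, parametrize
from .translation import GCRN, Translation, TranslationFailure, apply_translation, find_translation

__all__ = ["SubnetworkResult", "PipelineResult", "solve_crn"]


@dataclass
class SubnetworkResult:
    index: int
    reaction_ids: tuple[str, ...]
    crn: CRN
    gcrn: GCRN | None = None
    solution: SteadyStateSolution | None = None
    error: str | None = None

    @property
    def solved(self) -> bool:
        return self.solution is not None


@dataclass
class PipelineResult:
    crn: CRN
    decomposition: Decomposition
    subnetworks: list[SubnetworkResult]
    merged: MergedSolution | None
    laws: list[ConservationLaw]

    @property
    def fully_solved(self) -> bool:
        return self.merged is not None and all(s.solved for s in self.subnetworks)

    def check_rhs_zero(self) -> bool:
        """Symbolic master check: merged expressions zero the full RHS."""
        if self.merged is None:
            return False
        rhs = mass_action_rhs(self.crn)
        subs = {
            species_symbol(s): e for s, e in self.merged.expressions.items()
        }
        for s, e in rhs.items():
            if species_symbol(s) not in subs and e != 0:
                return False
            if sp.simplify(sp.together(e.subs(subs)).doit()) != 0:
                return False
        return True


def solve_crn(
    crn: CRN,
    *,
    max_support: int = 2,
    max_coeff: int = 2,
    budget: int = 5000,
    user_shifts: dict[str, dict[str, int]] | None = None,
) -> PipelineResult:
    """Run the full analytic steady-state pipeline on a network.

    ``user_shifts`` bypasses the translation search with explicit shift
    vectors (reaction id -> integer species map), applied to whichever
    subnetwork contains those reactions.
    """
    dec = finest_independent_decomposition(crn)
    results: list[SubnetworkResult] = []
    sigma_counter = 1
    tau_counter = 1
    solutions: list[SteadyStateSolution] = []
    for i, cls in enumerate(dec.classes):
        sub = subnetwork(crn, cls)
        rids = tuple(crn.reactions[j].id for j in cls)
        res = SubnetworkResult(index=i, reaction_ids=rids, crn=sub)
        try:
            if user_shifts and any(rid in user_shifts for rid in rids):
                shifts = {rid: user_shifts[rid] for rid in rids if rid in user_shifts}
                gcrn = apply_translation(sub, Translation(shifts), sigma_start=sigma_counter)
            else:
                _, gcrn = find_translation(
                    sub,
                    max_support=max_support,
                    max_coeff=max_coeff,
                    budget=budget,
                    sigma_start=sigma_counter,
                )
            res.gcrn = gcrn
            sigma_counter += len(gcrn.phantom_edges)
            sol = parametrize(gcrn, tau_start=tau_counter, provenance=f"N{i + 1}")
            tau_counter += len(sol.free_tau)
            res.solution = sol
            solutions.append(sol)
        except (TranslationFailure, UnsupportedNetwork, ValueError) as exc:
            res.error = str(exc)
        results.append(res)

    merged = merge_solutions(solutions) if solutions else None
    laws = conservation_laws(crn)
    return PipelineResult(
        crn=crn, decomposition=dec, subnetworks=results, merged=merged, laws=laws
    )
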