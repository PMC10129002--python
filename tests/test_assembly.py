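"""Merging subnetwork solutions, conservation laws, resolution, ACR."""

import numpy as np
import pytest
import sympy as sp

import crnsteady as cs
from crnsteady.assembly import (
    InconsistentMerge,
    acr_report,
    conservation_laws,
    merge_solutions,
    resolve_with_conservation,
)
from crnsteady.core import parse_network


def sym(name):
    return sp.Symbol(name, positive=True)


class TestMerge:
    def test_tau_elimination_in_six_reaction_example(self, fig1_result):
        """Equating the shared species across the two subnetworks eliminates
        tau1 = sigma1*k2*k5*(sigma1 + k1)/(k1*k3*k4*k6)."""
        merged = fig1_result.merged
        assert merged.remaining_free == ("sigma1",)
        (name, value) = merged.substitutions[0]
        assert name == "tau1"
        k1, k2, k3, k4, k5, k6, s1 = [sym(x) for x in ("k1", "k2", "k3", "k4", "k5", "k6", "sigma1")]
        expected = s1 * k2 * k5 * (s1 + k1) / (k1 * k3 * k4 * k6)
        assert sp.simplify(value - expected) == 0

    def test_single_solution_unchanged(self, methods_crn):
        from crnsteady.decomposition import subnetwork
        from crnsteady.parametrization import parametrize
        from crnsteady.translation import find_translation

        sub = subnetwork(methods_crn, [1, 3])
        _, gcrn = find_translation(sub)
        sol = parametrize(gcrn)
        merged = merge_solutions([sol])
        assert merged.expressions == sol.expressions
        assert merged.substitutions == []

    def test_birth_death_closed_form(self, methods_result):
        merged = methods_result.merged
        k1, k2, k3, k4 = [sym(f"k{i}") for i in range(1, 5)]
        assert sp.simplify(merged.expressions["A"] - k1 * k4 / (k3 * k2)) == 0
        assert sp.simplify(merged.expressions["B"] - k2 / k4) == 0
        assert merged.remaining_free == ()

    def test_merged_expressions_zero_full_rhs(self, methods_result, fig1_result, crispri_result):
        for res in (methods_result, fig1_result, crispri_result):
            assert res.check_rhs_zero()

    def test_inconsistent_subnetworks_detected(self):
        from crnsteady.parametrization import SteadyStateSolution

        a = SteadyStateSolution({"X": sym("k1")}, (), ())
        b = SteadyStateSolution({"X": 2 * sym("k1")}, (), ())
        with pytest.raises(InconsistentMerge):
            merge_solutions([a, b])


class TestConservationLaws:
    def test_six_reaction_example(self, fig1_crn):
        laws = conservation_laws(fig1_crn)
        assert len(laws) == 1
        assert str(laws[0]) == "b + d = b0 + d0"

    def test_toggle_switch_gene_totals(self, crispri_crn):
        laws = conservation_laws(crispri_crn)
        rendered = {str(l) for l in laws}
        assert rendered == {"h + p = h0 + p0", "g + r = g0 + r0"}

    def test_pure_production_has_none(self):
        crn = parse_network("R1: 0 -> A [k1]")
        assert conservation_laws(crn) == []

    def test_insulin_pools(self, insulin_crn):
        laws = conservation_laws(insulin_crn)
        assert len(laws) == 5
        rendered = {str(l.lhs()) for l in laws}
        assert rendered == {
            "x11 + x12",
            "x10 + x12 + x9",
            "x13 + x14 + x15",
            "x16 + x17",
            "x18 + x19",
        }
        # non-negative integer weights
        for law in laws:
            assert all(w >= 0 for w in law.weights)

    def test_count_matches_rank_defect(self, methods_crn, fig1_crn, crispri_crn, insulin_crn):
        for crn in (methods_crn, fig1_crn, crispri_crn, insulin_crn):
            laws = conservation_laws(crn)
            assert len(laws) == len(crn.species) - crn.stoich_rank


class TestResolution:
    def test_free_parameter_solved_from_conserved_quantity(self, fig1_result):
        resolved = resolve_with_conservation(fig1_result.merged, fig1_result.laws)
        assert resolved.remaining_free == ()
        assert [n for n, _ in resolved.substitutions[-1:]] == ["sigma1"]
        # the resolved expressions still satisfy the conservation law
        Q1 = sym("Q1")
        b, d = resolved.expressions["B"], resolved.expressions["D"]
        assert sp.simplify(b + d - Q1) == 0

    def test_toggle_switch_quadratic_root(self, crispri_resolved):
        """The sgRNA1 steady state is the positive root of a quadratic whose
        coefficients combine the two conserved gene totals."""
        s = crispri_resolved.expressions["S"]
        k = {i: sym(f"k{i}") for i in range(1, 15)}
        Q1, Q2 = sym("Q1"), sym("Q2")  # h0+p0 and g0+r0
        alpha = k[3] * k[7] * k[12] / (k[4] * k[8] * k[11])
        Q = (
            -(1 + k[2] * k[5] * k[9] * k[12] * Q1 / (k[6] * k[10] * k[11] * k[14]))
            + k[1] * k[3] * k[7] * k[12] * Q2 / (k[4] * k[8] * k[11] * k[13])
        )
        C = k[1] * Q2 / k[13]
        expected = (Q + sp.sqrt(Q**2 + 4 * alpha * C)) / (2 * alpha)
        assert sp.simplify(s - expected) == 0

    def test_toggle_switch_unit_rates_value(self, crispri_resolved):
        s = crispri_resolved.expressions["S"]
        val = s.subs({x: 1 for x in s.free_symbols})
        assert sp.simplify(val - (sp.sqrt(5) - 1) / 2) == 0

    def test_numeric_initial_values(self, methods_result):
        resolved = resolve_with_conservation(
            methods_result.merged, methods_result.laws, initial_values={"A": 1, "B": 2}
        )
        assert resolved.remaining_free == ()


def _s_of_k(crispri_resolved):
    s = crispri_resolved.expressions["S"]
    ks = [sym(f"k{i}") for i in range(1, 15)]
    Q1, Q2 = sym("Q1"), sym("Q2")
    return sp.lambdify([*ks, Q1, Q2], s, modules="numpy"), 14


class TestToggleMonotonicity:
    """Finite-difference signs of the sgRNA1 steady state at random base
    points: increasing in the translation/unbinding group, decreasing in
    the competing group, and always increasing in the specific unbinding
    rate of the opposing complex."""

    increasing = (1, 6, 14, 10)
    decreasing = (2, 5, 9, 13)

    def test_monotone_directions(self, crispri_resolved):
        f, n = _s_of_k(crispri_resolved)
        rng = np.random.default_rng(17)
        for _ in range(10):
            base = 10 ** rng.uniform(-0.5, 0.5, size=n + 2)
            s0 = f(*base)
            assert s0 > 0
            for idx in self.increasing:
                pert = base.copy()
                pert[idx - 1] *= 1.05
                assert f(*pert) > s0
            for idx in self.decreasing:
                pert = base.copy()
                pert[idx - 1] *= 1.05
                assert f(*pert) < s0


class TestACR:
    def test_insulin_robust_species(self, insulin_acr):
        assert set(insulin_acr.acr_species()) == {
            "X2", "X3", "X4", "X5", "X6", "X7", "X8", "X20",
        }

    def test_surface_glut4_depends_on_everything(self, insulin_acr):
        row = insulin_acr.depends["X21"]
        assert all(row.values()) and len(row) == 5

    def test_lipid_pool_independent_of_kinase_totals(self, insulin_acr):
        for s in ("X13", "X14", "X15"):
            row = insulin_acr.depends[s]
            assert not row["x160 + x170"]
            assert not row["x180 + x190"]

    def test_no_conservation_laws_is_flagged_vacuous(self, methods_result):
        report = acr_report(
            resolve_with_conservation(methods_result.merged, methods_result.laws),
            methods_result.laws,
        )
        assert report.note
        assert set(report.acr_species()) == {"A", "B"}

    def test_symbolic_and_numeric_verdicts_agree(self, insulin_resolved, insulin_result):
        sym_rep = acr_report(insulin_resolved, insulin_result.laws, numeric_check=False)
        num_rep = acr_report(insulin_resolved, insulin_result.laws, numeric_check=True)
        assert sym_rep.depends == num_rep.depends

    def test_unresolved_parameters_rejected(self, fig1_result):
        with pytest.raises(ValueError):
            acr_report(fig1_result.merged, fig1_result.laws)
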